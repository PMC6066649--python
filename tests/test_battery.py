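import json

import numpy as np
import pytest

from aglkit.battery import (
    BatteryConfig,
    FoilConstructionError,
    ONSET_INTERVAL_MS,
    TilePoolExhaustedError,
    assign_tiles,
    battery_index,
    build_exposure_set,
    build_test_battery,
    make_mismatched_foil,
    make_missing_element_foil,
    read_battery,
    write_battery,
)
from aglkit.grammars import CategoryString, Grammar, TARGET_GRAMMARS, accepts, generate, register, unregister

TABLE1_COUNTS = {
    "correct": 20,
    "gen4": 10,
    "gen6": 6,
    "gen4_missing": 10,
    "gen6_missing": 6,
    "gen4_mismatch": 10,
    "missing": 10,
    "mismatch": 15,
}


class TestExposure:
    def test_default_exposure_set(self):
        items = build_exposure_set("Copy", rng=np.random.default_rng(0))
        assert len(items) == 30
        assert all(s.condition == "exposure" for s in items)
        assert all(accepts("Copy", s.categories) for s in items)
        ns = sorted(s.n_value for s in items)
        assert ns == [2] * 10 + [3] * 10 + [5] * 10

    def test_zero_exposure(self):
        cfg = BatteryConfig(exposure_count=0)
        assert build_exposure_set("Mirror", cfg, np.random.default_rng(0)) == []


class TestBatteryComposition:
    @pytest.mark.parametrize("grammar", TARGET_GRAMMARS)
    def test_table1_counts(self, grammar):
        items = build_test_battery(grammar, rng=np.random.default_rng(1))
        assert len(items) == 87
        counts = {}
        for s in items:
            counts[s.condition] = counts.get(s.condition, 0) + 1
        assert counts == TABLE1_COUNTS

    @pytest.mark.parametrize("grammar", TARGET_GRAMMARS)
    def test_grammatical_flag_matches_recognizer(self, grammar):
        for s in build_test_battery(grammar, rng=np.random.default_rng(2)):
            assert s.grammatical == accepts(grammar, s.categories)
            assert s.grammatical == (s.condition in ("correct", "gen4", "gen6"))

    def test_singleton_battery(self):
        cfg = BatteryConfig(counts={"correct": 1})
        items = build_test_battery("Copy", cfg, np.random.default_rng(0))
        assert len(items) == 1 and items[0].condition == "correct"

    @pytest.mark.parametrize("grammar", ["Mirror", "Copy"])
    def test_missing_foil_lengths_mirror_copy(self, grammar):
        items = build_test_battery(grammar, rng=np.random.default_rng(3))
        lengths = {
            len(s.categories)
            for s in items
            if s.condition in ("missing", "gen4_missing", "gen6_missing")
        }
        assert lengths == {3, 5, 7, 11}

    def test_missing_foil_lengths_abna(self):
        items = build_test_battery("ABnA", rng=np.random.default_rng(3))
        lengths = {
            len(s.categories)
            for s in items
            if s.condition in ("missing", "gen4_missing", "gen6_missing")
        }
        assert lengths == {3, 5, 7}

    def test_composition_seed_invariant(self):
        a = build_test_battery("Copy", rng=np.random.default_rng(10))
        b = build_test_battery("Copy", rng=np.random.default_rng(99))
        key = lambda items: sorted((s.condition, s.n_value, s.grammatical) for s in items)
        assert key(a) == key(b)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            BatteryConfig(counts={"bogus": 1})


class TestMissingFoil:
    def test_copy_published_example(self):
        rng = np.random.default_rng(0)
        foil = make_missing_element_foil(CategoryString("ABBABB"), "Copy", rng)
        assert len(foil) == 5
        assert not accepts("Copy", foil)

    def test_mirror_n6_gives_length_11(self):
        rng = np.random.default_rng(1)
        base = generate("Mirror", 6, rng)
        foil = make_missing_element_foil(base, "Mirror", rng)
        assert len(foil) == 11

    @pytest.mark.parametrize("grammar", TARGET_GRAMMARS)
    def test_always_rejected(self, grammar):
        """Spec-level stress: every constructed foil must be rejected."""
        rng = np.random.default_rng(5)
        for _ in range(70):
            for n in (2, 3, 4, 6):
                base = generate(grammar, n, rng)
                foil = make_missing_element_foil(base, grammar, rng)
                assert not accepts(grammar, foil)
                assert len(foil) == len(base) - 1

    def test_requires_grammatical_base(self):
        with pytest.raises(FoilConstructionError):
            make_missing_element_foil(CategoryString("ABB"), "Copy", np.random.default_rng(0))

    def test_infeasible_deletion(self):
        register(
            Grammar("_Any", "heuristic", lambda s: True, lambda n, rng: "A" * n),
            overwrite=True,
        )
        try:
            with pytest.raises(FoilConstructionError):
                make_missing_element_foil(CategoryString("AAAA"), "_Any", np.random.default_rng(0))
        finally:
            unregister("_Any")


class TestMismatchedFoil:
    def test_copy_published_example_shape(self):
        rng = np.random.default_rng(0)
        foil = make_mismatched_foil(CategoryString("ABBABB"), "Copy", rng)
        assert len(foil) == 6
        assert not accepts("Copy", foil)
        diffs = [i for i, (a, b) in enumerate(zip("ABBABB", foil.symbols)) if a != b]
        assert len(diffs) == 1

    @pytest.mark.parametrize("grammar", TARGET_GRAMMARS)
    def test_flip_is_involution(self, grammar):
        rng = np.random.default_rng(4)
        for n in (2, 3, 4):
            base = generate(grammar, n, rng)
            foil = make_mismatched_foil(base, grammar, rng)
            diffs = [i for i, (a, b) in enumerate(zip(base.symbols, foil.symbols)) if a != b]
            assert len(diffs) == 1
            i = diffs[0]
            restored = foil.symbols[:i] + base.symbols[i] + foil.symbols[i + 1 :]
            assert restored == base.symbols
            assert accepts(grammar, restored)

    def test_infeasible_flip(self):
        register(
            Grammar("_Any", "heuristic", lambda s: True, lambda n, rng: "A" * n),
            overwrite=True,
        )
        try:
            with pytest.raises(FoilConstructionError):
                make_mismatched_foil(CategoryString("AABB"), "_Any", np.random.default_rng(0))
        finally:
            unregister("_Any")


class TestAssignTiles:
    def test_timing_constants(self):
        spec = assign_tiles(CategoryString("ABBA"), np.random.default_rng(0))
        assert spec.timing.onset_ms == 166 == ONSET_INTERVAL_MS
        assert spec.timing.element_px == (20, 20)
        assert spec.timing.marker_px == (16, 20)

    def test_no_duplicate_tiles_in_10000_stimuli(self):
        rng = np.random.default_rng(8)
        for _ in range(10_000):
            spec = assign_tiles(CategoryString("AABABBAABABB"), rng)  # N=6 copy pattern
            assert len(set(spec.tiles)) == len(spec.tiles)

    def test_pool_exhaustion(self):
        with pytest.raises(TilePoolExhaustedError):
            assign_tiles(CategoryString("A" * 13), np.random.default_rng(0))

    def test_tiles_match_categories(self):
        spec = assign_tiles(CategoryString("ABAB"), np.random.default_rng(0))
        assert [t.category for t in spec.tiles] == list("ABAB")


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        items = build_test_battery("Mirror", rng=np.random.default_rng(6))
        path = tmp_path / "battery.json"
        write_battery(items, path)
        back = read_battery(path)
        assert back == items
        # file is valid JSON with the documented fields
        rec = json.loads(path.read_text())[0]
        assert set(rec) == {"id", "grammar", "condition", "n", "categories", "tiles", "grammatical", "timing"}

    def test_index_columns(self):
        items = build_test_battery("Copy", rng=np.random.default_rng(6))
        idx = battery_index(items)
        assert list(idx.columns) == ["stimulus_id", "grammar", "condition", "n", "length", "grammatical"]
        assert len(idx) == 87
        assert idx["grammatical"].sum() == 36  # 20 + 10 + 6
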