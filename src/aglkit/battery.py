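"""Exposure sets and the 87-item per-grammar test battery.

The default :class:`BatteryConfig` reproduces the published design: 30
grammatical exposure items (N in {2, 3, 5}) and eight test conditions
totalling 87 items — 20 correct items at the trained lengths, 10 + 6
generalization items at N = 4 and N = 6, missing-element foils at trained
and generalization lengths, and mismatched-element foils.  Foils are built
by single-symbol edits that the session's target grammar rejects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grammars import CategoryString, Grammar, get_grammar

SHAPES_PER_CATEGORY = 12

#: element onset interval at 6 frames per second, truncated to whole ms
ONSET_INTERVAL_MS = 1000 // 6  # = 166


class FoilConstructionError(ValueError):
    """No single edit of the requested kind yields a rejected string."""


class TilePoolExhaustedError(ValueError):
    """More symbols of one category than distinct shapes available."""


@dataclass(frozen=True)
class Tile:
    category: str
    shape_id: int  # 1..12 within category


@dataclass(frozen=True)
class Timing:
    onset_ms: int = ONSET_INTERVAL_MS
    element_px: tuple[int, int] = (20, 20)
    marker_px: tuple[int, int] = (16, 20)


@dataclass(frozen=True)
class StimulusSpec:
    """One test or exposure item: category pattern + tile identities + metadata."""

    stimulus_id: str
    grammar: str
    categories: CategoryString
    tiles: tuple[Tile, ...]
    n_value: int
    condition: str
    grammatical: bool
    timing: Timing = Timing()

    def __post_init__(self) -> None:
        if len(self.tiles) != len(self.categories):
            raise ValueError("tiles length must equal category string length")

    def to_record(self) -> dict:
        return {
            "id": self.stimulus_id,
            "grammar": self.grammar,
            "condition": self.condition,
            "n": self.n_value,
            "categories": self.categories.to_text(),
            "tiles": [[t.category, t.shape_id] for t in self.tiles],
            "grammatical": self.grammatical,
            "timing": {
                "onset_ms": self.timing.onset_ms,
                "element_px": list(self.timing.element_px),
                "marker_px": list(self.timing.marker_px),
            },
        }

    @classmethod
    def from_record(cls, rec: dict) -> "StimulusSpec":
        timing = rec.get("timing", {})
        return cls(
            stimulus_id=rec["id"],
            grammar=rec["grammar"],
            categories=CategoryString.from_text(rec["categories"]),
            tiles=tuple(Tile(c, int(i)) for c, i in rec["tiles"]),
            n_value=int(rec["n"]),
            condition=rec["condition"],
            grammatical=bool(rec["grammatical"]),
            timing=Timing(
                onset_ms=int(timing.get("onset_ms", ONSET_INTERVAL_MS)),
                element_px=tuple(timing.get("element_px", (20, 20))),
                marker_px=tuple(timing.get("marker_px", (16, 20))),
            ),
        )


#: test conditions, in canonical order; the three grammatical ones come first
GRAMMATICAL_CONDITIONS = ("correct", "gen4", "gen6")
FOIL_CONDITIONS = ("gen4_missing", "gen6_missing", "gen4_mismatch", "missing", "mismatch")
TEST_CONDITIONS = GRAMMATICAL_CONDITIONS + FOIL_CONDITIONS

_DEFAULT_COUNTS = {
    "correct": 20,
    "gen4": 10,
    "gen6": 6,
    "gen4_missing": 10,
    "gen6_missing": 6,
    "gen4_mismatch": 10,
    "missing": 10,
    "mismatch": 15,
}


@dataclass(frozen=True)
class BatteryConfig:
    counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    exposure_count: int = 30
    exposure_n: tuple[int, ...] = (2, 3, 5)
    test_n_seen: tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(TEST_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown test conditions: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()) or self.exposure_count < 0:
            raise ValueError("condition counts must be non-negative")

    @property
    def total_test_items(self) -> int:
        return sum(self.counts.get(c, 0) for c in TEST_CONDITIONS)


def make_missing_element_foil(
    s: CategoryString, grammar: str | Grammar, rng: np.random.Generator
) -> CategoryString:
    """Delete one symbol so that the result is rejected by ``grammar``.

    The deletion position is drawn uniformly over all positions whose
    removal yields rejection; marker slots are recomputed from the foil
    length using the grammar's own convention.
    """
    g = get_grammar(grammar)
    symbols = s.symbols
    if len(symbols) < 2:
        raise FoilConstructionError("string too short for a deletion foil")
    if not g.accepts(s):
        raise FoilConstructionError("missing-element foil requires a grammatical base")
    candidates = [
        i for i in range(len(symbols)) if not g.accepts(symbols[:i] + symbols[i + 1 :])
    ]
    if not candidates:
        raise FoilConstructionError(
            f"no single deletion of {symbols!r} is rejected by {g.name}"
        )
    i = int(rng.choice(candidates))
    foil = symbols[:i] + symbols[i + 1 :]
    return CategoryString(foil, g.marker_slots(len(foil)))


def make_mismatched_foil(
    s: CategoryString, grammar: str | Grammar, rng: np.random.Generator
) -> CategoryString:
    """Flip exactly one symbol's category so that ``grammar`` rejects the result."""
    g = get_grammar(grammar)
    symbols = s.symbols
    if not g.accepts(s):
        raise FoilConstructionError("mismatched foil requires a grammatical base")

    def flipped(i: int) -> str:
        c = "B" if symbols[i] == "A" else "A"
        return symbols[:i] + c + symbols[i + 1 :]

    candidates = [i for i in range(len(symbols)) if not g.accepts(flipped(i))]
    if not candidates:
        raise FoilConstructionError(
            f"no single category flip of {symbols!r} is rejected by {g.name}"
        )
    i = int(rng.choice(candidates))
    return CategoryString(flipped(i), g.marker_slots(len(symbols)))


def assign_tiles(
    s: CategoryString,
    rng: np.random.Generator,
    *,
    stimulus_id: str = "",
    grammar: str = "",
    n_value: int = 0,
    condition: str = "",
    grammatical: bool = True,
) -> StimulusSpec:
    """Sample tile identities without replacement from each category's 12-shape pool."""
    counts = {c: s.symbols.count(c) for c in "AB"}
    for cat, k in counts.items():
        if k > SHAPES_PER_CATEGORY:
            raise TilePoolExhaustedError(
                f"{k} {cat} symbols exceed the {SHAPES_PER_CATEGORY}-shape pool"
            )
    pools = {
        cat: iter(rng.choice(SHAPES_PER_CATEGORY, size=counts[cat], replace=False) + 1)
        for cat in "AB"
    }
    tiles = tuple(Tile(c, int(next(pools[c]))) for c in s.symbols)
    return StimulusSpec(
        stimulus_id=stimulus_id,
        grammar=grammar,
        categories=s,
        tiles=tiles,
        n_value=n_value,
        condition=condition,
        grammatical=grammatical,
    )


def _balanced_ns(ns: Sequence[int], count: int) -> list[int]:
    # as even a split as the count allows, earlier Ns get the remainder
    return [ns[i % len(ns)] for i in range(count)]


def build_exposure_set(
    grammar: str | Grammar, cfg: BatteryConfig | None = None, rng: np.random.Generator | None = None
) -> list[StimulusSpec]:
    g = get_grammar(grammar)
    cfg = cfg or BatteryConfig()
    rng = rng if rng is not None else np.random.default_rng()
    out = []
    for k, n in enumerate(sorted(_balanced_ns(cfg.exposure_n, cfg.exposure_count))):
        s = g.generate(n, rng)
        out.append(
            assign_tiles(
                s,
                rng,
                stimulus_id=f"{g.name}-exp-{k:03d}",
                grammar=g.name,
                n_value=n,
                condition="exposure",
                grammatical=True,
            )
        )
    return out


def _missing_base_ns(g: Grammar, seen: Sequence[int]) -> list[int]:
    # ABnA trained-length deletion foils come from N=2 bases only, so that the
    # foil lengths match the printed 3/5/7 ladder (deleting an edge A from
    # A B^2 A gives length 3; N=3 bases would give length-4 foils).
    if g.name == "ABnA":
        return [min(seen)]
    return list(seen)


def build_test_battery(
    grammar: str | Grammar, cfg: BatteryConfig | None = None, rng: np.random.Generator | None = None
) -> list[StimulusSpec]:
    """Build the per-grammar test battery (87 items under the default config)."""
    g = get_grammar(grammar)
    cfg = cfg or BatteryConfig()
    rng = rng if rng is not None else np.random.default_rng()

    items: list[tuple[str, int, CategoryString, bool]] = []

    def grammatical_items(condition: str, ns: Sequence[int]) -> None:
        for n in ns:
            items.append((condition, n, g.generate(n, rng), True))

    def missing_items(condition: str, ns: Sequence[int]) -> None:
        for n in ns:
            base = g.generate(n, rng)
            items.append((condition, n, make_missing_element_foil(base, g, rng), False))

    def mismatch_items(condition: str, ns: Sequence[int]) -> None:
        for n in ns:
            base = g.generate(n, rng)
            items.append((condition, n, make_mismatched_foil(base, g, rng), False))

    c = cfg.counts
    grammatical_items("correct", _balanced_ns(cfg.test_n_seen, c.get("correct", 0)))
    grammatical_items("gen4", [4] * c.get("gen4", 0))
    grammatical_items("gen6", [6] * c.get("gen6", 0))
    missing_items("gen4_missing", [4] * c.get("gen4_missing", 0))
    missing_items("gen6_missing", [6] * c.get("gen6_missing", 0))
    mismatch_items("gen4_mismatch", [4] * c.get("gen4_mismatch", 0))
    missing_items("missing", _balanced_ns(_missing_base_ns(g, cfg.test_n_seen), c.get("missing", 0)))
    mismatch_items("mismatch", _balanced_ns(cfg.test_n_seen, c.get("mismatch", 0)))

    order = rng.permutation(len(items))
    battery = []
    for rank, idx in enumerate(order):
        condition, n, s, grammatical = items[idx]
        assert g.accepts(s) == grammatical
        battery.append(
            assign_tiles(
                s,
                rng,
                stimulus_id=f"{g.name}-test-{rank:03d}",
                grammar=g.name,
                n_value=n,
                condition=condition,
                grammatical=grammatical,
            )
        )
    return battery


def battery_index(battery: Iterable[StimulusSpec]) -> pd.DataFrame:
    """Companion index table (id, grammar, condition, n, length, grammatical)."""
    rows = [
        {
            "stimulus_id": s.stimulus_id,
            "grammar": s.grammar,
            "condition": s.condition,
            "n": s.n_value,
            "length": len(s.categories),
            "grammatical": s.grammatical,
        }
        for s in battery
    ]
    return pd.DataFrame(rows)


def write_battery(battery: Sequence[StimulusSpec], path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_record() for s in battery], indent=1))


def read_battery(path: str | Path) -> list[StimulusSpec]:
    return [StimulusSpec.from_record(r) for r in json.loads(Path(path).read_text())]
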