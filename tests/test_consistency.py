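import math

import numpy as np
import pandas as pd
import pytest

from aglkit.battery import battery_index
from aglkit.consistency import (
    EmptySelectionError,
    TrialJoinError,
    binomial_criterion,
    code_consistency,
    code_trials,
    score_individuals,
    success_counts,
)
from aglkit.grammars import accepts
from aglkit.simulate import SimConfig, simulate_cohort


def exact_upper_tail(k: int, n: int) -> float:
    """Independent oracle: sum of binomial pmf terms at p = 1/2."""
    return sum(math.comb(n, j) for j in range(k, n + 1)) / 2**n


class TestBinomialCriterion:
    def test_published_training_criterion_12_of_15(self):
        crit = binomial_criterion(15, alpha=0.05)
        assert crit.threshold == 12
        assert crit.tail_p == pytest.approx(exact_upper_tail(12, 15))
        assert round(crit.tail_p, 2) == 0.02

    def test_single_trial_unattainable(self):
        crit = binomial_criterion(1, alpha=0.05)
        assert not crit.attainable
        assert crit.threshold is None

    def test_threshold_for_20_trials(self):
        # oracle: smallest k with P(X >= k) < 0.05
        k = next(k for k in range(21) if exact_upper_tail(k, 20) < 0.05)
        assert k == 15
        assert binomial_criterion(20, alpha=0.05).threshold == 15

    @pytest.mark.parametrize("n", range(8, 60))
    def test_threshold_matches_oracle(self, n):
        crit = binomial_criterion(n, alpha=0.05)
        assert crit.threshold == next(k for k in range(n + 1) if exact_upper_tail(k, n) < 0.05)
        assert 0 < crit.tail_p < 0.05

    def test_two_sided_mode(self):
        crit = binomial_criterion(15, alpha=0.05, mode="two-sided")
        # two-sided 12/15 would be ~0.035; threshold stays 12 here
        assert crit.tail_p == pytest.approx(2 * exact_upper_tail(crit.threshold, 15))

    def test_table1_subset_sizes_give_published_p_range(self):
        # trained lengths + mismatches: 20+10+15 = 45; N=4: 10+10+10 = 30; N=6: 6+6 = 12
        for n in (45, 30, 12, 15):
            crit = binomial_criterion(n, alpha=0.05)
            assert 0.01 <= round(crit.tail_p, 3) <= 0.049

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_criterion(0)
        with pytest.raises(ValueError):
            binomial_criterion(10, alpha=1.5)
        with pytest.raises(ValueError):
            binomial_criterion(10, mode="sideways")


class TestCodeConsistency:
    def test_coding_rule(self, copy_battery):
        grammatical = next(s for s in copy_battery if s.grammatical)
        foil = next(s for s in copy_battery if not s.grammatical)
        assert code_consistency("same", grammatical, "Copy") == 1
        assert code_consistency("different", grammatical, "Copy") == 0
        assert code_consistency("different", foil, "Copy") == 1
        assert code_consistency("same", foil, "Copy") == 0

    def test_perfect_copy_follower(self, copy_battery):
        """A scripted perfect follower is 100% consistent with Copy; its BFirst
        consistency equals the battery-specific verdict-agreement rate."""
        trials = pd.DataFrame(
            {
                "participant_id": "P01",
                "session_grammar": "Copy",
                "session_order": 1,
                "trial_index": range(len(copy_battery)),
                "stimulus_id": [s.stimulus_id for s in copy_battery],
                "response": ["same" if s.grammatical else "different" for s in copy_battery],
            }
        )
        coded = code_trials(trials, {"Copy": copy_battery}, ["Copy", "BFirst"])
        by = coded.groupby("candidate")["consistent"].mean()
        assert by["Copy"] == 1.0
        # independent exhaustive evaluation of BFirst vs Copy verdicts
        agreement = np.mean(
            [accepts("BFirst", s.categories) == accepts("Copy", s.categories) for s in copy_battery]
        )
        assert by["BFirst"] == pytest.approx(agreement)

    def test_fair_coin_expected_half_for_every_candidate(self, batteries):
        cfg = SimConfig(n_participants=40, mu_logit=0.0, sigma2_id=0.0, seed=3)
        sim = simulate_cohort(cfg, batteries)
        coded = code_trials(sim.trials, batteries, ["Copy", "Mirror", "ABnA", "BFirst", "AEdgeStar"])
        by = coded.groupby("candidate")["consistent"].mean()
        # 40 x 3 x 87 trials per candidate -> SE ~ 0.005
        assert np.allclose(by.to_numpy(), 0.5, atol=0.02)

    def test_completeness(self, copy_battery, small_cohort):
        _, coded = small_cohort
        counts = coded.groupby("candidate")["consistent"].count()
        assert (counts == 20 * 87).all()
        assert set(coded["consistent"].unique()) <= {0, 1}

    def test_unresolvable_stimulus(self, copy_battery):
        trials = pd.DataFrame(
            {
                "participant_id": ["P01"],
                "session_grammar": ["Copy"],
                "session_order": [1],
                "trial_index": [0],
                "stimulus_id": ["nope-000"],
                "response": ["same"],
            }
        )
        with pytest.raises(TrialJoinError):
            code_trials(trials, {"Copy": copy_battery}, ["Copy"])


class TestScoreIndividuals:
    def _perfect_trials(self, battery, grammar):
        return pd.DataFrame(
            {
                "participant_id": "P01",
                "session_grammar": grammar,
                "session_order": 1,
                "trial_index": range(len(battery)),
                "stimulus_id": [s.stimulus_id for s in battery],
                "response": ["same" if s.grammatical else "different" for s in battery],
            }
        )

    def test_perfect_responder_passes(self, copy_battery):
        trials = self._perfect_trials(copy_battery, "Copy")
        scores = score_individuals(trials, battery_index(copy_battery))
        assert scores.loc[0, "passed"]
        assert scores.loc[0, "n_correct"] == 87

    def test_condition_subset(self, copy_battery):
        trials = self._perfect_trials(copy_battery, "Copy")
        scores = score_individuals(
            trials, battery_index(copy_battery), conditions=("correct", "missing", "mismatch")
        )
        assert scores.loc[0, "n_trials"] == 45

    def test_empty_selection(self, copy_battery):
        trials = self._perfect_trials(copy_battery, "Copy")
        with pytest.raises(EmptySelectionError):
            score_individuals(trials, battery_index(copy_battery), conditions=("exposure",))

    def test_fair_coin_cohort_rarely_passes(self, batteries):
        cfg = SimConfig(n_participants=20, mu_logit=0.0, sigma2_id=0.0, seed=9)
        sim = simulate_cohort(cfg, {"Copy": batteries["Copy"]})
        idx = battery_index(batteries["Copy"])
        scores = score_individuals(sim.trials, idx)
        # expected pass count = 20 * tail_p < 1; allow generous slack
        assert success_counts(scores).get("Copy", 0) <= 3

    def test_target_consistency_equals_correctness(self, batteries, small_cohort):
        sim, coded = small_cohort
        idx = battery_index(batteries["Copy"])
        scores = score_individuals(sim.trials, idx)
        target = coded[coded["candidate"] == "Copy"]
        by_participant = target.groupby("participant_id")["consistent"].sum()
        merged = scores.set_index("participant_id")["n_correct"]
        assert (by_participant == merged).all()
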