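"""Trial-level consistency coding and individual binomial success criteria.

A response is *consistent* with a candidate grammar when it matches the
verdict that grammar assigns the stimulus: "same" on accepted items,
"different" on rejected ones.  A response is *correct* when it matches the
grammaticality flag with respect to the session's target grammar; on the
target grammar the two codings coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .battery import StimulusSpec
from .grammars import DEFAULT_CANDIDATES, Grammar, get_grammar

RESPONSE_SAME = "same"
RESPONSE_DIFFERENT = "different"

TRIAL_COLUMNS = (
    "participant_id",
    "session_grammar",
    "session_order",
    "trial_index",
    "stimulus_id",
    "response",
)


class TrialJoinError(KeyError):
    """A trial's stimulus_id does not resolve to a battery item."""


class EmptySelectionError(ValueError):
    """A condition filter selected no trials."""


def code_consistency(response: str, stimulus: StimulusSpec, candidate: str | Grammar) -> int:
    """1 iff the response agrees with the candidate grammar's verdict."""
    g = get_grammar(candidate)
    expected = RESPONSE_SAME if g.accepts(stimulus.categories) else RESPONSE_DIFFERENT
    return int(response == expected)


def _battery_lookup(batteries: Mapping[str, Sequence[StimulusSpec]]) -> dict[str, StimulusSpec]:
    lookup: dict[str, StimulusSpec] = {}
    for items in batteries.values():
        for s in items:
            lookup[s.stimulus_id] = s
    return lookup


def code_trials(
    trials: pd.DataFrame,
    batteries: Mapping[str, Sequence[StimulusSpec]],
    candidates: Iterable[str] = DEFAULT_CANDIDATES,
) -> pd.DataFrame:
    """Long-format consistency table: one row per trial x candidate grammar.

    Columns: participant_id, session_grammar, session_order, trial_index,
    stimulus_id, candidate, consistent.
    """
    candidates = list(candidates)
    lookup = _battery_lookup(batteries)
    missing = set(trials["stimulus_id"]) - set(lookup)
    if missing:
        raise TrialJoinError(f"unresolvable stimulus ids: {sorted(missing)[:5]}")

    # verdict per (stimulus, candidate), computed once per stimulus
    verdict: dict[str, dict[str, str]] = {}
    for sid, stim in lookup.items():
        verdict[sid] = {
            c: (RESPONSE_SAME if get_grammar(c).accepts(stim.categories) else RESPONSE_DIFFERENT)
            for c in candidates
        }

    frames = []
    for cand in candidates:
        expected = trials["stimulus_id"].map(lambda sid: verdict[sid][cand])
        frame = trials.loc[:, list(TRIAL_COLUMNS[:5])].copy()
        frame["candidate"] = cand
        frame["consistent"] = (trials["response"] == expected).astype(int)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out


@dataclass(frozen=True)
class CriterionResult:
    """Exact binomial success criterion at chance p = 0.5."""

    n_trials: int
    threshold: int | None  # smallest k with tail probability < alpha; None if unattainable
    tail_p: float | None
    alpha: float
    mode: str = "one-sided"

    @property
    def attainable(self) -> bool:
        return self.threshold is not None

    def passed(self, n_correct: int) -> bool:
        return self.threshold is not None and n_correct >= self.threshold


def _tail_p(k: int, n: int, mode: str) -> float:
    p = float(stats.binom.sf(k - 1, n, 0.5))  # P(X >= k)
    if mode == "two-sided":
        return min(1.0, 2.0 * p)
    return p


def binomial_criterion(n_trials: int, alpha: float = 0.05, mode: str = "one-sided") -> CriterionResult:
    """Smallest correct-count threshold achieving tail probability < alpha.

    Under chance responding X ~ Binomial(n, 0.5); the default one-sided
    criterion reproduces the published 12-of-15 training rule (tail
    probability 0.018, printed as p = 0.02).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if mode not in ("one-sided", "two-sided"):
        raise ValueError(f"unknown mode {mode!r}")
    for k in range(n_trials + 1):
        p = _tail_p(k, n_trials, mode)
        if p < alpha:
            return CriterionResult(n_trials, k, p, alpha, mode)
    return CriterionResult(n_trials, None, None, alpha, mode)


def join_battery_index(trials: pd.DataFrame, battery_idx: pd.DataFrame) -> pd.DataFrame:
    merged = trials.merge(
        battery_idx.drop(columns=["grammar"], errors="ignore"),
        on="stimulus_id",
        how="left",
        validate="many_to_one",
    )
    if merged["grammatical"].isna().any():
        bad = merged.loc[merged["grammatical"].isna(), "stimulus_id"].unique()
        raise TrialJoinError(f"unresolvable stimulus ids: {list(bad)[:5]}")
    return merged


def score_individuals(
    trials: pd.DataFrame,
    battery_idx: pd.DataFrame,
    conditions: Sequence[str] | None = None,
    alpha: float = 0.05,
    mode: str = "one-sided",
) -> pd.DataFrame:
    """Per-participant correct counts against the exact binomial criterion.

    ``conditions`` restricts the trial subset (e.g. trained lengths plus
    their mismatch items); the criterion threshold is recomputed from each
    participant's subset size, mirroring the published per-subset criteria.
    Returns one row per (participant, session_grammar).
    """
    merged = join_battery_index(trials, battery_idx)
    if conditions is not None:
        merged = merged[merged["condition"].isin(conditions)]
    if merged.empty:
        raise EmptySelectionError(f"no trials selected by conditions {conditions!r}")
    merged = merged.copy()
    merged["correct"] = (
        (merged["response"] == RESPONSE_SAME) == merged["grammatical"]
    ).astype(int)

    rows = []
    for (pid, gram), grp in merged.groupby(["participant_id", "session_grammar"], sort=True):
        crit = binomial_criterion(len(grp), alpha=alpha, mode=mode)
        k = int(grp["correct"].sum())
        rows.append(
            {
                "participant_id": pid,
                "session_grammar": gram,
                "n_trials": len(grp),
                "n_correct": k,
                "threshold": crit.threshold,
                "tail_p": crit.tail_p,
                "passed": crit.passed(k),
            }
        )
    return pd.DataFrame(rows)


def success_counts(scores: pd.DataFrame) -> pd.Series:
    """Number of participants passing the criterion, per session grammar."""
    return scores.groupby("session_grammar")["passed"].sum().astype(int)
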