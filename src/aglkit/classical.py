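"""Frequentist endpoints: group comparisons, effect sizes, order/length effects.

The default two-group mode is the rank-sum (Mann-Whitney) convention, whose
statistic equals n1 * n2 under complete separation — matching the published
W = 400 with twenty participants per group.  A paired signed-rank mode is
also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consistency import EmptySelectionError, RESPONSE_SAME, join_battery_index


@dataclass(frozen=True)
class GroupComparison:
    statistic: float  # rank-based W
    p_value: float
    effect_size_d: float  # Cohen's d, pooled SD
    mode: str
    group_means: tuple[float, float]


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        raise ValueError("effect size undefined: zero pooled variance")
    return float((x.mean() - y.mean()) / pooled)


def compare_groups(x, y, mode: str = "rank_sum") -> GroupComparison:
    """Rank-based comparison of two sets of per-participant percentages."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "rank_sum":
        if min(x.size, y.size) < 5:
            raise ValueError("need at least 5 observations per group")
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        w = float(res.statistic)
        p = float(res.pvalue)
    elif mode == "signed_rank":
        if x.size != y.size or x.size < 5:
            raise ValueError("signed_rank needs >= 5 pairs of equal length")
        if np.all(x == y):
            w, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(x, y)
            w = float(res.statistic)
            p = float(res.pvalue)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GroupComparison(
        statistic=w,
        p_value=p,
        effect_size_d=cohens_d(x, y),
        mode=mode,
        group_means=(float(x.mean()), float(y.mean())),
    )


def percent_same(
    trials: pd.DataFrame,
    battery_idx: pd.DataFrame,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-participant percentage of "same" responses by grammaticality class.

    Returns columns: participant_id, session_grammar, grammatical, pct_same.
    """
    merged = join_battery_index(trials, battery_idx)
    if conditions is not None:
        merged = merged[merged["condition"].isin(conditions)]
    if merged.empty:
        raise EmptySelectionError(f"no trials selected by conditions {conditions!r}")
    merged = merged.copy()
    merged["is_same"] = (merged["response"] == RESPONSE_SAME).astype(float)
    out = (
        merged.groupby(["participant_id", "session_grammar", "grammatical"])["is_same"]
        .mean()
        .mul(100.0)
        .rename("pct_same")
        .reset_index()
    )
    return out


def grammaticality_comparison(
    trials: pd.DataFrame,
    battery_idx: pd.DataFrame,
    session_grammar: str,
    conditions: Sequence[str] | None = None,
    mode: str = "rank_sum",
) -> GroupComparison:
    """Grammatical-vs-ungrammatical percent-"same" comparison for one session."""
    pct = percent_same(
        trials[trials["session_grammar"] == session_grammar], battery_idx, conditions
    )
    wide = pct.pivot(index="participant_id", columns="grammatical", values="pct_same")
    if True not in wide.columns or False not in wide.columns:
        raise EmptySelectionError("need both grammatical and ungrammatical trials")
    return compare_groups(wide[True].to_numpy(), wide[False].to_numpy(), mode=mode)


@dataclass(frozen=True)
class KruskalResult:
    statistic: float  # chi-squared approximation
    df: int
    p_value: float
    groups: tuple


def _percent_correct(merged: pd.DataFrame) -> pd.Series:
    correct = ((merged["response"] == RESPONSE_SAME) == merged["grammatical"]).astype(float)
    return correct


def order_effect(trials: pd.DataFrame, battery_idx: pd.DataFrame, session_grammar: str) -> KruskalResult:
    """Kruskal-Wallis test of percent correct across session positions 1..3."""
    merged = join_battery_index(
        trials[trials["session_grammar"] == session_grammar], battery_idx
    )
    merged = merged.copy()
    merged["correct"] = _percent_correct(merged)
    per = merged.groupby(["participant_id", "session_order"])["correct"].mean().reset_index()
    groups = [g["correct"].to_numpy() for _, g in per.groupby("session_order")]
    if len(groups) < 2:
        raise ValueError("degenerate design: a single session-order group")
    stat, p = stats.kruskal(*groups)
    return KruskalResult(float(stat), len(groups) - 1, float(p), tuple(sorted(per["session_order"].unique())))


def length_effect(
    trials: pd.DataFrame,
    battery_idx: pd.DataFrame,
    session_grammar: str,
    conditions: Sequence[str] = ("missing", "gen4_missing", "gen6_missing"),
) -> dict:
    """Kruskal-Wallis across foil string lengths plus Bonferroni post-hocs.

    Returns {"kruskal": KruskalResult, "bonferroni_alpha": float,
    "pairwise": DataFrame(length_a, length_b, W, p_raw, significant)}.
    """
    merged = join_battery_index(
        trials[trials["session_grammar"] == session_grammar], battery_idx
    )
    merged = merged[merged["condition"].isin(conditions)].copy()
    if merged.empty:
        raise EmptySelectionError(f"no trials for conditions {conditions!r}")
    merged["correct"] = _percent_correct(merged)
    per = merged.groupby(["participant_id", "length"])["correct"].mean().reset_index()
    lengths = sorted(per["length"].unique())
    groups = {L: per.loc[per["length"] == L, "correct"].to_numpy() for L in lengths}
    if len(lengths) < 2:
        raise ValueError("degenerate design: a single length group")
    stat, p = stats.kruskal(*groups.values())
    kw = KruskalResult(float(stat), len(lengths) - 1, float(p), tuple(lengths))

    pairs = list(combinations(lengths, 2))
    alpha = 0.05 / len(pairs) if pairs else 0.05
    rows = []
    for a, b in pairs:
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append(
            {
                "length_a": a,
                "length_b": b,
                "W": float(res.statistic),
                "p_raw": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
        )
    return {"kruskal": kw, "bonferroni_alpha": alpha, "pairwise": pd.DataFrame(rows)}


def classical_report(trials: pd.DataFrame, battery_idx: pd.DataFrame) -> pd.DataFrame:
    """Tidy summary across sessions: test, subset, statistic, p, effect size."""
    rows = []
    for gram in sorted(trials["session_grammar"].unique()):
        cmp_all = grammaticality_comparison(trials, battery_idx, gram)
        rows.append(
            {
                "test": "rank_sum",
                "session_grammar": gram,
                "subset": "all",
                "statistic": cmp_all.statistic,
                "p": cmp_all.p_value,
                "effect_size_d": cmp_all.effect_size_d,
                "correction": "",
            }
        )
        kw = order_effect(trials, battery_idx, gram)
        rows.append(
            {
                "test": "kruskal_order",
                "session_grammar": gram,
                "subset": "session_order",
                "statistic": kw.statistic,
                "p": kw.p_value,
                "effect_size_d": np.nan,
                "correction": "",
            }
        )
        le = length_effect(trials, battery_idx, gram)
        rows.append(
            {
                "test": "kruskal_length",
                "session_grammar": gram,
                "subset": "missing_foils",
                "statistic": le["kruskal"].statistic,
                "p": le["kruskal"].p_value,
                "effect_size_d": np.nan,
                "correction": f"bonferroni_alpha={le['bonferroni_alpha']:.4f}",
            }
        )
    return pd.DataFrame(rows)
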