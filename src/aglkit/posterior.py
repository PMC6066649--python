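"""Posterior post-processing: rescaling, HPD intervals, model-selection summaries.

Fits are run with the latent residual variance fixed at 1; all reported
quantities are computed after rescaling the draws to an approximate
zero-residual-variance posterior using the standard logit latent-scale
constant c = 16*sqrt(3)/(15*pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: logit latent-scale correction constant, ~0.5880
C_LOGIT = 16.0 * math.sqrt(3.0) / (15.0 * math.pi)

#: latent logistic residual variance pi^2 / 3
LOGISTIC_VARIANCE = math.pi**2 / 3.0


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval holding ``mass`` of the draws.

    Empirical sliding-window algorithm over the sorted sample.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws for an interval")
    if not 0 < mass <= 1:
        raise ValueError("mass must lie in (0, 1]")
    m = int(math.ceil(mass * n))
    m = max(2, min(m, n))
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


@dataclass(frozen=True)
class RescaledPosterior:
    """Draws mapped to the zero-residual-variance scale."""

    beta0: np.ndarray  # (S,)
    sigma2_u: np.ndarray  # (S,)
    u: np.ndarray  # (S, n_participants)
    participants: tuple
    c_const: float = C_LOGIT
    sigma2_res: float = 1.0

    @property
    def intercepts(self) -> np.ndarray:
        """Predicted participant intercepts beta0 + u_i, shape (S, n)."""
        return self.beta0[:, None] + self.u


def rescale_to_zero_residual(draws, sigma2_res: float | None = None) -> RescaledPosterior:
    """Divide location draws by sqrt(1 + c^2 s2) and variances by (1 + c^2 s2).

    With ``sigma2_res`` = 0 this is the identity map.
    """
    s2 = draws.spec.residual_variance if sigma2_res is None else sigma2_res
    denom = 1.0 + C_LOGIT**2 * s2
    scale = math.sqrt(denom)
    return RescaledPosterior(
        beta0=np.asarray(draws.beta0) / scale,
        sigma2_u=np.asarray(draws.sigma2_u) / denom,
        u=np.asarray(draws.u) / scale,
        participants=tuple(draws.participants),
        sigma2_res=s2,
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ProbabilitySummary:
    """Posterior of the average-participant probability of a consistent response."""

    draws: np.ndarray
    m_p: float
    hpd95: tuple[float, float]
    p_mcmc: float  # share of draws <= 0.50


def summarize_probability(resc: RescaledPosterior, mass: float = 0.95) -> ProbabilitySummary:
    p = _logistic(resc.beta0)
    return ProbabilitySummary(
        draws=p,
        m_p=float(p.mean()),
        hpd95=hpd_interval(p, mass),
        p_mcmc=float((p <= 0.50).mean()),
    )


@dataclass(frozen=True)
class LogORSummary:
    draws: np.ndarray
    mean: float
    hpd95: tuple[float, float]
    p_mcmc: float  # share of draws <= 0


def log_odds_ratio(
    target: RescaledPosterior, alt: RescaledPosterior, mass: float = 0.95
) -> LogORSummary:
    """Natural-log odds ratio of target vs alternative average intercepts.

    Independent chains are paired draw-by-draw (index pairing); unequal
    lengths are truncated to the shorter chain.
    """
    a, b = np.asarray(target.beta0), np.asarray(alt.beta0)
    if a.size == 0 or b.size == 0:
        raise ValueError("missing fit: empty draw vector")
    s = min(a.size, b.size)
    d = a[:s] - b[:s]
    return LogORSummary(
        draws=d,
        mean=float(d.mean()),
        hpd95=hpd_interval(d, mass),
        p_mcmc=float((d <= 0.0).mean()),
    )


def odds_ratio(log_or: float) -> float:
    """Back-transform a logOR to the odds-ratio scale (logOR 2 -> ~7.4)."""
    return math.exp(log_or)


def participant_log_odds_ratios(
    target: RescaledPosterior, alt: RescaledPosterior, mass: float = 0.95
) -> pd.DataFrame:
    """Per-participant logOR between predicted intercepts of two fits.

    Significance means the 95% HPD excludes 0; p_mcmc is the share of draws
    at or below 0.
    """
    if tuple(target.participants) != tuple(alt.participants):
        raise ValueError("participant sets differ between fits")
    s = min(target.beta0.size, alt.beta0.size)
    d = target.intercepts[:s] - alt.intercepts[:s]  # (S, n)
    rows = []
    for j, pid in enumerate(target.participants):
        lo, hi = hpd_interval(d[:, j], mass)
        rows.append(
            {
                "participant_id": pid,
                "mean": float(d[:, j].mean()),
                "hpd_lo": lo,
                "hpd_hi": hi,
                "p_mcmc": float((d[:, j] <= 0.0).mean()),
                "significant": bool(lo > 0.0 or hi < 0.0),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ICCSummary:
    draws: np.ndarray
    mean: float
    hpd95: tuple[float, float]


def icc(sigma2_u_draws: np.ndarray | RescaledPosterior, mass: float = 0.95) -> ICCSummary:
    """Latent-logistic intraclass correlation sigma2_u / (sigma2_u + pi^2/3)."""
    if isinstance(sigma2_u_draws, RescaledPosterior):
        s2 = sigma2_u_draws.sigma2_u
    else:
        s2 = np.asarray(sigma2_u_draws, dtype=float)
    r = s2 / (s2 + LOGISTIC_VARIANCE)
    return ICCSummary(draws=r, mean=float(r.mean()), hpd95=hpd_interval(r, mass))


def model_selection_table(
    fits: dict[str, RescaledPosterior], target: str, mass: float = 0.95
) -> pd.DataFrame:
    """Per-candidate summary mirroring the published per-grammar figure.

    Columns: candidate, m_p, hpd_lo, hpd_hi, p_mcmc, logor_mean,
    logor_hpd_lo, logor_hpd_hi, logor_p_mcmc (logOR of the target vs each
    candidate; 0 for the target row itself).
    """
    if target not in fits:
        raise KeyError(f"target grammar {target!r} has no fit")
    rows = []
    for name, resc in fits.items():
        prob = summarize_probability(resc, mass)
        row = {
            "candidate": name,
            "m_p": prob.m_p,
            "hpd_lo": prob.hpd95[0],
            "hpd_hi": prob.hpd95[1],
            "p_mcmc": prob.p_mcmc,
        }
        if name == target:
            row.update(logor_mean=0.0, logor_hpd_lo=0.0, logor_hpd_hi=0.0, logor_p_mcmc=0.5)
        else:
            lor = log_odds_ratio(fits[target], resc, mass)
            row.update(
                logor_mean=lor.mean,
                logor_hpd_lo=lor.hpd95[0],
                logor_hpd_hi=lor.hpd95[1],
                logor_p_mcmc=lor.p_mcmc,
            )
        rows.append(row)
    return pd.DataFrame(rows)
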