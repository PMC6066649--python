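"""Bayesian Bernoulli multilevel model with participant random intercepts.

Model (per candidate grammar, one session)::

    y_j  ~ Bernoulli(logistic(l_j))
    l_j  = beta0 + u_{p(j)} + e_j
    e_j  ~ Normal(0, sigma2_res)        # residual variance FIXED (default 1)
    u_i  ~ Normal(0, sigma2_u)
    beta0 ~ Normal(0, sd^2)             # diffuse
    sigma_u ~ half-Cauchy(scale)        # weakly informative

The residual variance is never sampled; overdispersion cannot be estimated
for repeated binary measures, so it is fixed and the posterior is later
rescaled to an approximate zero-residual-variance scale (see
:mod:`aglkit.posterior`).

Sampling is Metropolis-within-Gibbs, fully vectorized over trials and
participants, with two interweaving moves (a joint intercept/random-effect
translation and a per-participant random-effect/residual shift) that
decorrelate the hierarchy, plus slice sampling for the variance component.
Chains auto-extend until every intercept term (fixed intercept and each
predicted participant intercept beta0 + u_i) reaches the configured
effective-sample-size floor; chains are never thinned by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import arviz as az
import numpy as np
import pandas as pd


class ConvergenceError(RuntimeError):
    """The ESS floor was not reached within the iteration budget."""


@dataclass(frozen=True)
class GLMMSpec:
    """Likelihood is Bernoulli with logit link; only priors are configurable."""

    intercept_prior_sd: float = 10.0
    sigma_u_prior_scale: float = 25.0
    residual_variance: float = 1.0  # fixed constant, never sampled

    def to_dict(self) -> dict:
        return {
            "likelihood": "bernoulli",
            "link": "logit",
            "intercept_prior_sd": self.intercept_prior_sd,
            "sigma_u_prior_scale": self.sigma_u_prior_scale,
            "residual_variance": self.residual_variance,
        }


@dataclass(frozen=True)
class MCMCConfig:
    burn_in: int = 1500
    chunk_size: int = 4000
    ess_floor: float = 1000.0
    max_draws: int = 80000
    seed: int | None = None
    thin: int = 1  # chains are not thinned by default
    adapt: bool = True


@dataclass(frozen=True)
class PosteriorDraws:
    """Raw-scale posterior draws from :func:`fit_glmm`."""

    beta0: np.ndarray  # (S,)
    sigma2_u: np.ndarray  # (S,)
    u: np.ndarray  # (S, n_participants)
    participants: tuple
    ess: dict[str, float]
    spec: GLMMSpec
    thinning: int = 1
    n_iterations: int = 0
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return int(self.beta0.size)


def _softplus(x):
    return np.logaddexp(0.0, x)


def ess_1d(draws: np.ndarray) -> float:
    """Autocorrelation-adjusted effective sample size of a single chain."""
    arr = np.asarray(draws, dtype=float).reshape(1, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(arr))


def _slice_sample(
    x0: float,
    logp: Callable[[float], float],
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 50,
) -> float:
    """Univariate slice sampler with stepping-out and shrinkage (Neal 2003)."""
    y = logp(x0) - rng.exponential()
    left = x0 - w * rng.random()
    right = left + w
    j = int(max_steps * rng.random())
    k = max_steps - 1 - j
    while j > 0 and logp(left) > y:
        left -= w
        j -= 1
    while k > 0 and logp(right) > y:
        right += w
        k -= 1
    while True:
        x1 = left + (right - left) * rng.random()
        if logp(x1) > y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


class _AdaptiveScale:
    """Robbins-Monro adaptation of a log proposal scale toward a target rate."""

    def __init__(self, scale: float, target: float = 0.44):
        self.log_scale = np.log(scale)
        self.target = target

    def update(self, rate: float, t: int) -> None:
        self.log_scale += (t + 1) ** -0.6 * (rate - self.target)

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))


def _prepare(consistent, participant_ids):
    y = np.asarray(consistent, dtype=float).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("responses must be coded 0/1")
    pids = np.asarray(participant_ids).ravel()
    if pids.size != y.size:
        raise ValueError("participant_ids and responses differ in length")
    participants, pidx = np.unique(pids, return_inverse=True)
    if participants.size < 2:
        raise ValueError("need at least 2 participants")
    counts = np.bincount(pidx)
    if counts.min() < 2:
        raise ValueError("need at least 2 trials per participant")
    order = np.argsort(pidx, kind="stable")
    y = y[order]
    pidx = pidx[order]
    starts = np.searchsorted(pidx, np.arange(participants.size))
    return y, pidx, starts, tuple(participants.tolist())


def fit_glmm(
    consistent,
    participant_ids,
    spec: GLMMSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Posterior draws of (beta0, sigma2_u, u) for one candidate grammar.

    The chain auto-extends in chunks until ``ess(beta0)`` and the ESS of
    every predicted participant intercept reach ``mcmc.ess_floor``; if the
    budget ``mcmc.max_draws`` is exhausted first a :class:`ConvergenceError`
    carrying the ESS diagnostics is raised.
    """
    spec = spec or GLMMSpec()
    mcmc = mcmc or MCMCConfig()
    y, pidx, starts, participants = _prepare(consistent, participant_ids)
    n = len(participants)
    m = y.size
    rng = np.random.default_rng(mcmc.seed)

    if y.min() == y.max():
        warnings.warn(
            "all responses identical: complete separation, posterior driven by prior",
            UserWarning,
            stacklevel=2,
        )

    s2_res = float(spec.residual_variance)
    b_var = float(spec.intercept_prior_sd) ** 2
    hc_scale2 = float(spec.sigma_u_prior_scale) ** 2

    # state
    grand = (y.sum() + 0.5) / (m + 1.0)
    beta0 = float(np.log(grand / (1.0 - grand)))
    u = np.zeros(n)
    e = np.zeros(m)
    log_sigma = np.log(0.7)

    sc_e = _AdaptiveScale(1.2)
    sc_u = _AdaptiveScale(0.5)
    sc_b = _AdaptiveScale(0.3)
    sc_t = _AdaptiveScale(0.3)
    sc_a = _AdaptiveScale(0.2)

    def step(t: int, adapt: bool) -> tuple[float, float, np.ndarray]:
        nonlocal beta0, log_sigma, u, e
        sig2_u = float(np.exp(2.0 * log_sigma))

        # residual latents, coordinate-wise random-walk Metropolis
        if s2_res > 0.0:
            de = sc_e.scale * rng.standard_normal(m)
            lin = beta0 + u[pidx] + e
            lin_p = lin + de
            dll = (
                y * de
                - _softplus(lin_p)
                + _softplus(lin)
                - 0.5 * ((e + de) ** 2 - e**2) / s2_res
            )
            acc = np.log(rng.random(m)) < dll
            e[acc] += de[acc]
            if adapt:
                sc_e.update(float(acc.mean()), t)

        # participant intercept deviations
        du = sc_u.scale * rng.standard_normal(n)
        lin = beta0 + u[pidx] + e
        lin_p = lin + du[pidx]
        per_trial = y * du[pidx] - _softplus(lin_p) + _softplus(lin)
        dll = np.add.reduceat(per_trial, starts) - 0.5 * ((u + du) ** 2 - u**2) / sig2_u
        acc = np.log(rng.random(n)) < dll
        u[acc] += du[acc]
        if adapt:
            sc_u.update(float(acc.mean()), t)

        # fixed intercept
        db = sc_b.scale * rng.standard_normal()
        lin = beta0 + u[pidx] + e
        dll = float(
            np.sum(y * db - _softplus(lin + db) + _softplus(lin))
            - 0.5 * ((beta0 + db) ** 2 - beta0**2) / b_var
        )
        acc_b = np.log(rng.random()) < dll
        if acc_b:
            beta0 += db
        if adapt:
            sc_b.update(float(acc_b), t)

        # interweave: translate beta0 against u (likelihood-invariant)
        delta = sc_t.scale * rng.standard_normal()
        dlp = (
            -0.5 * ((beta0 + delta) ** 2 - beta0**2) / b_var
            - 0.5 * (np.sum((u - delta) ** 2) - np.sum(u**2)) / sig2_u
        )
        acc_t = np.log(rng.random()) < dlp
        if acc_t:
            beta0 += delta
            u -= delta
        if adapt:
            sc_t.update(float(acc_t), t)

        # interweave: shift each u_i against its residuals (likelihood-invariant)
        if s2_res > 0.0:
            da = sc_a.scale * rng.standard_normal(n)
            d_e = da[pidx]
            dlp_i = (
                -0.5 * ((u + da) ** 2 - u**2) / sig2_u
                - 0.5 * np.add.reduceat((e - d_e) ** 2 - e**2, starts) / s2_res
            )
            acc = np.log(rng.random(n)) < dlp_i
            u[acc] += da[acc]
            e -= np.where(acc[pidx], d_e, 0.0)
            if adapt:
                sc_a.update(float(acc.mean()), t)

        # variance component: slice sample t = log sigma_u
        ssq = float(np.sum(u**2))

        def logp(ls: float) -> float:
            return (
                -n * ls
                - 0.5 * ssq * np.exp(-2.0 * ls)
                + ls
                - np.log1p(np.exp(2.0 * ls) / hc_scale2)
            )

        log_sigma = _slice_sample(log_sigma, logp, rng)
        return beta0, float(np.exp(2.0 * log_sigma)), u.copy()

    for t in range(mcmc.burn_in):
        step(t, mcmc.adapt)

    beta_draws: list[np.ndarray] = []
    sig2_draws: list[np.ndarray] = []
    u_draws: list[np.ndarray] = []
    total = 0
    n_iterations = mcmc.burn_in

    while True:
        cb = np.empty(mcmc.chunk_size)
        cs = np.empty(mcmc.chunk_size)
        cu = np.empty((mcmc.chunk_size, n))
        kept = 0
        for it in range(mcmc.chunk_size * mcmc.thin):
            b, s2, uu = step(mcmc.burn_in + total * mcmc.thin + it, False)
            n_iterations += 1
            if (it + 1) % mcmc.thin == 0:
                cb[kept] = b
                cs[kept] = s2
                cu[kept] = uu
                kept += 1
        beta_draws.append(cb)
        sig2_draws.append(cs)
        u_draws.append(cu)
        total += mcmc.chunk_size

        beta_all = np.concatenate(beta_draws)
        u_all = np.concatenate(u_draws)
        ess = {"beta0": ess_1d(beta_all), "sigma2_u": ess_1d(np.concatenate(sig2_draws))}
        theta = beta_all[:, None] + u_all
        for j, pid in enumerate(participants):
            ess[f"theta[{pid}]"] = ess_1d(theta[:, j])
        intercept_ess = [v for k, v in ess.items() if k != "sigma2_u"]
        if min(intercept_ess) >= mcmc.ess_floor:
            break
        if total >= mcmc.max_draws:
            raise ConvergenceError(
                f"ESS floor {mcmc.ess_floor} not reached after {total} draws; "
                f"min intercept ESS = {min(intercept_ess):.0f}"
            )

    return PosteriorDraws(
        beta0=np.concatenate(beta_draws),
        sigma2_u=np.concatenate(sig2_draws),
        u=np.concatenate(u_draws),
        participants=participants,
        ess=ess,
        spec=spec,
        thinning=mcmc.thin,
        n_iterations=n_iterations,
        seed=mcmc.seed,
    )


def draws_to_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """Flat draws table: beta0, sigma2_u, u[<participant>] columns."""
    data = {"beta0": draws.beta0, "sigma2_u": draws.sigma2_u}
    for j, pid in enumerate(draws.participants):
        data[f"u[{pid}]"] = draws.u[:, j]
    return pd.DataFrame(data)


def fit_sidecar(draws: PosteriorDraws) -> dict:
    """JSON-serializable fit metadata (priors, seed, ESS, chain length)."""
    return {
        "spec": draws.spec.to_dict(),
        "seed": draws.seed,
        "thinning": draws.thinning,
        "n_iterations": draws.n_iterations,
        "n_draws": draws.n_draws,
        "participants": list(draws.participants),
        "ess": {k: float(v) for k, v in draws.ess.items()},
    }
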