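"""Multi-response GLMM: grammar-specific intercepts, unstructured covariance.

Joint model over the three sessions' target-grammar consistency data::

    y_j ~ Bernoulli(logistic(beta_g(j) + u_{p(j), g(j)} + e_j))
    u_i. ~ MVN(0, Sigma)            # unstructured 3x3 covariance
    e_j ~ Normal(0, sigma2_res)     # fixed (default 1)
    Sigma ~ InvWishart(d + 1, I)    # marginally uniform correlations

The inverse-Wishart prior with d + 1 degrees of freedom is conjugate given
the random effects, keeping the covariance update an exact Gibbs draw;
with identity scale it places a uniform marginal prior on each pairwise
correlation.  Everything else mirrors the univariate sampler in
:mod:`aglkit.glmm`, including the interweaving moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import ConvergenceError, GLMMSpec, MCMCConfig, _AdaptiveScale, _softplus, ess_1d
from .posterior import C_LOGIT, ICCSummary, LOGISTIC_VARIANCE, hpd_interval


@dataclass(frozen=True)
class MultiResponseResult:
    grammars: tuple[str, ...]
    participants: tuple
    beta: np.ndarray  # (S, G)
    sigma: np.ndarray  # (S, G, G) covariance draws
    u: np.ndarray  # (S, n, G)
    ess: dict[str, float]
    spec: GLMMSpec
    seed: int | None = None
    n_iterations: int = 0

    @property
    def n_draws(self) -> int:
        return int(self.beta.shape[0])


def fit_multiresponse(
    data: pd.DataFrame,
    spec: GLMMSpec | None = None,
    mcmc: MCMCConfig | None = None,
    grammars: tuple[str, ...] | None = None,
) -> MultiResponseResult:
    """Fit the joint model to a long table (participant_id, session_grammar, consistent).

    Requires the same participants in every session.
    """
    spec = spec or GLMMSpec()
    mcmc = mcmc or MCMCConfig()
    if grammars is None:
        grammars = tuple(sorted(data["session_grammar"].unique()))
    g_count = len(grammars)
    if g_count < 2:
        raise ValueError("need at least 2 sessions for a multi-response fit")

    per_session = {
        g: set(data.loc[data["session_grammar"] == g, "participant_id"]) for g in grammars
    }
    shared = set.intersection(*per_session.values())
    if len(shared) < 2:
        raise ValueError("fewer than 2 participants shared across sessions")
    if any(per_session[g] != shared for g in grammars):
        raise ValueError("participant sets differ across sessions")

    participants = tuple(sorted(shared))
    p_map = {p: i for i, p in enumerate(participants)}
    g_map = {g: k for k, g in enumerate(grammars)}
    n = len(participants)

    sub = data[data["session_grammar"].isin(grammars)].copy()
    y = sub["consistent"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("responses must be coded 0/1")
    gidx = sub["session_grammar"].map(g_map).to_numpy()
    pidx = sub["participant_id"].map(p_map).to_numpy()

    # sort trials by (session, participant) so each (g, i) block is contiguous
    order = np.lexsort((pidx, gidx))
    y, gidx, pidx = y[order], gidx[order], pidx[order]
    m = y.size

    g_slices = [slice(*np.searchsorted(gidx, (k, k + 1))) for k in range(g_count)]
    starts = []  # per session: reduceat starts within the session block
    for k in range(g_count):
        block = pidx[g_slices[k]]
        if block.size == 0 or np.unique(block).size != n:
            raise ValueError(f"session {grammars[k]!r} missing trials for some participants")
        starts.append(np.searchsorted(block, np.arange(n)))

    rng = np.random.default_rng(mcmc.seed)
    s2_res = float(spec.residual_variance)
    b_var = float(spec.intercept_prior_sd) ** 2

    beta = np.zeros(g_count)
    for k in range(g_count):
        grand = (y[g_slices[k]].sum() + 0.5) / (y[g_slices[k]].size + 1.0)
        beta[k] = np.log(grand / (1.0 - grand))
    u = np.zeros((n, g_count))
    e = np.zeros(m)
    sigma = np.eye(g_count)

    nu0 = g_count + 1.0
    s0 = np.eye(g_count)

    sc_e = _AdaptiveScale(1.2)
    sc_u = [_AdaptiveScale(0.5) for _ in range(g_count)]
    sc_b = [_AdaptiveScale(0.3) for _ in range(g_count)]
    sc_t = [_AdaptiveScale(0.3) for _ in range(g_count)]
    sc_a = [_AdaptiveScale(0.2) for _ in range(g_count)]

    def linear() -> np.ndarray:
        return beta[gidx] + u[pidx, gidx] + e

    def step(t: int, adapt: bool) -> None:
        nonlocal beta, sigma, e, u
        sinv = np.linalg.inv(sigma)

        if s2_res > 0.0:
            de = sc_e.scale * rng.standard_normal(m)
            lin = linear()
            dll = (
                y * de
                - _softplus(lin + de)
                + _softplus(lin)
                - 0.5 * ((e + de) ** 2 - e**2) / s2_res
            )
            acc = np.log(rng.random(m)) < dll
            e[acc] += de[acc]
            if adapt:
                sc_e.update(float(acc.mean()), t)

        for k in range(g_count):
            sl = g_slices[k]
            yk = y[sl]
            pk = pidx[sl]
            lin_k = beta[k] + u[pk, k] + e[sl]

            # random-effect column k
            du = sc_u[k].scale * rng.standard_normal(n)
            per_trial = yk * du[pk] - _softplus(lin_k + du[pk]) + _softplus(lin_k)
            v = u @ sinv[k]  # (n,)
            dprior = -0.5 * (du**2 * sinv[k, k] + 2.0 * du * v)
            dll = np.add.reduceat(per_trial, starts[k]) + dprior
            acc = np.log(rng.random(n)) < dll
            u[acc, k] += du[acc]
            if adapt:
                sc_u[k].update(float(acc.mean()), t)
            lin_k = beta[k] + u[pk, k] + e[sl]

            # intercept k
            db = sc_b[k].scale * rng.standard_normal()
            dll_b = float(
                np.sum(yk * db - _softplus(lin_k + db) + _softplus(lin_k))
                - 0.5 * ((beta[k] + db) ** 2 - beta[k] ** 2) / b_var
            )
            acc_b = np.log(rng.random()) < dll_b
            if acc_b:
                beta[k] += db
            if adapt:
                sc_b[k].update(float(acc_b), t)

            # interweave: translate beta_k against u[:, k]
            delta = sc_t[k].scale * rng.standard_normal()
            v = u @ sinv[k]
            dlp = float(
                -0.5 * ((beta[k] + delta) ** 2 - beta[k] ** 2) / b_var
                - 0.5 * (n * delta**2 * sinv[k, k] - 2.0 * delta * v.sum())
            )
            acc_t = bool(np.log(rng.random()) < dlp)
            if acc_t:
                beta[k] += delta
                u[:, k] -= delta
            if adapt:
                sc_t[k].update(float(acc_t), t)

            # interweave: shift u[i, k] against that block's residuals
            if s2_res > 0.0:
                da = sc_a[k].scale * rng.standard_normal(n)
                v = u @ sinv[k]
                d_e = da[pk]
                e_k = e[sl]
                dlp_i = (
                    -0.5 * (da**2 * sinv[k, k] + 2.0 * da * v)
                    - 0.5 * np.add.reduceat((e_k - d_e) ** 2 - e_k**2, starts[k]) / s2_res
                )
                acc = np.log(rng.random(n)) < dlp_i
                u[acc, k] += da[acc]
                e[sl] -= np.where(acc[pk], d_e, 0.0)
                if adapt:
                    sc_a[k].update(float(acc.mean()), t)

        # covariance: conjugate inverse-Wishart Gibbs draw
        scale_post = s0 + u.T @ u
        sigma = stats.invwishart.rvs(df=nu0 + n, scale=scale_post, random_state=rng)

    for t in range(mcmc.burn_in):
        step(t, mcmc.adapt)

    beta_chunks, sigma_chunks, u_chunks = [], [], []
    total = 0
    n_iterations = mcmc.burn_in
    while True:
        cb = np.empty((mcmc.chunk_size, g_count))
        cs = np.empty((mcmc.chunk_size, g_count, g_count))
        cu = np.empty((mcmc.chunk_size, n, g_count))
        kept = 0
        for it in range(mcmc.chunk_size * mcmc.thin):
            step(mcmc.burn_in + n_iterations + it, False)
            if (it + 1) % mcmc.thin == 0:
                cb[kept] = beta
                cs[kept] = sigma
                cu[kept] = u
                kept += 1
        n_iterations += mcmc.chunk_size * mcmc.thin
        beta_chunks.append(cb)
        sigma_chunks.append(cs)
        u_chunks.append(cu)
        total += mcmc.chunk_size

        beta_all = np.concatenate(beta_chunks)
        u_all = np.concatenate(u_chunks)
        ess: dict[str, float] = {}
        for k, g in enumerate(grammars):
            ess[f"beta[{g}]"] = ess_1d(beta_all[:, k])
            theta = beta_all[:, k, None] + u_all[:, :, k]
            for j, pid in enumerate(participants):
                ess[f"theta[{g},{pid}]"] = ess_1d(theta[:, j])
        if min(ess.values()) >= mcmc.ess_floor:
            break
        if total >= mcmc.max_draws:
            raise ConvergenceError(
                f"ESS floor {mcmc.ess_floor} not reached after {total} draws; "
                f"min intercept ESS = {min(ess.values()):.0f}"
            )

    return MultiResponseResult(
        grammars=grammars,
        participants=participants,
        beta=np.concatenate(beta_chunks),
        sigma=np.concatenate(sigma_chunks),
        u=np.concatenate(u_chunks),
        ess=ess,
        spec=spec,
        seed=mcmc.seed,
        n_iterations=n_iterations,
    )


def correlation_draws(result: MultiResponseResult) -> dict[tuple[str, str], np.ndarray]:
    """Pairwise participant-effect correlation draws (rescale-invariant)."""
    out = {}
    s = result.sigma
    for a in range(len(result.grammars)):
        for b in range(a + 1, len(result.grammars)):
            r = s[:, a, b] / np.sqrt(s[:, a, a] * s[:, b, b])
            out[(result.grammars[a], result.grammars[b])] = r
    return out


def correlation_summaries(result: MultiResponseResult, mass: float = 0.95) -> pd.DataFrame:
    """Mean, HPD and p_mcmc (share of draws <= 0) per grammar pair."""
    rows = []
    for (ga, gb), r in correlation_draws(result).items():
        lo, hi = hpd_interval(r, mass)
        rows.append(
            {
                "grammar_a": ga,
                "grammar_b": gb,
                "mean": float(r.mean()),
                "hpd_lo": lo,
                "hpd_hi": hi,
                "p_mcmc": float((r <= 0.0).mean()),
            }
        )
    return pd.DataFrame(rows)


def icc_summaries(result: MultiResponseResult, mass: float = 0.95) -> dict[str, ICCSummary]:
    """Per-grammar latent-logistic ICC from the rescaled variance draws."""
    denom = 1.0 + C_LOGIT**2 * result.spec.residual_variance
    out = {}
    for k, g in enumerate(result.grammars):
        s2 = result.sigma[:, k, k] / denom
        r = s2 / (s2 + LOGISTIC_VARIANCE)
        out[g] = ICCSummary(draws=r, mean=float(r.mean()), hpd95=hpd_interval(r, mass))
    return out


def intercept_rescaled(result: MultiResponseResult, grammar: str) -> np.ndarray:
    """Rescaled average-intercept draws for one session grammar."""
    k = result.grammars.index(grammar)
    return result.beta[:, k] / np.sqrt(1.0 + C_LOGIT**2 * result.spec.residual_variance)
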