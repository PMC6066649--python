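"""Independent oracles shared across test modules.

Everything here is deliberately written from first principles (production
rules, exhaustive enumeration, dense numerical integration) so it shares no
code path with the package implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import special

from aglkit.posterior import C_LOGIT


def all_strings(max_len: int):
    for length in range(1, max_len + 1):
        for tup in itertools.product("AB", repeat=length):
            yield "".join(tup)


# --- production-rule enumerations (independent of the recognizers) ----------

def produce_abn(max_len: int) -> set[str]:
    return {"A" + "B" * k for k in range(1, max_len) if 1 + k <= max_len}


def produce_abna(max_len: int) -> set[str]:
    return {"A" + "B" * k + "A" for k in range(1, max_len - 1) if k + 2 <= max_len}


def produce_mirror(max_len: int) -> set[str]:
    out = set()
    for half in range(1, max_len // 2 + 1):
        for tup in itertools.product("AB", repeat=half):
            w = "".join(tup)
            out.add(w + w[::-1])
    return out


def produce_copy(max_len: int) -> set[str]:
    out = set()
    for half in range(1, max_len // 2 + 1):
        for tup in itertools.product("AB", repeat=half):
            w = "".join(tup)
            out.add(w + w)
    return out


def produce_aedgestar(max_len: int) -> set[str]:
    out = {"AA"}
    for mid in range(1, max_len - 1):
        for tup in itertools.product("AB", repeat=mid):
            out.add("A" + "".join(tup) + "A")
    return out


def produce_aedgeplus(max_len: int) -> set[str]:
    return produce_aedgestar(max_len) - {"AA"}


def produce_bfirst(max_len: int) -> set[str]:
    out = {"B"}
    for rest in range(1, max_len):
        for tup in itertools.product("AB", repeat=rest):
            out.add("B" + "".join(tup))
    return out


PRODUCTION_ORACLES = {
    "ABN": produce_abn,
    "ABnA": produce_abna,
    "Mirror": produce_mirror,
    "Copy": produce_copy,
    "AEdgeStar": produce_aedgestar,
    "AEdgePlus": produce_aedgeplus,
    "BFirst": produce_bfirst,
}


# --- dense-integration posterior oracle for the small GLMM case -------------

def grid_posterior_m_p(
    counts: list[tuple[int, int]],
    intercept_prior_sd: float = 10.0,
    sigma_u_prior_scale: float = 25.0,
    n_beta: int = 601,
    n_logsig: int = 181,
    gh_nodes: int = 48,
) -> float:
    """Posterior mean consistent-response probability by dense integration.

    ``counts`` holds (n_correct, n_trials) per participant.  The latent
    per-trial residual (variance 1) is integrated by Gauss-Hermite inside
    the trial success probability; the participant effect is integrated by
    Gauss-Hermite over its normal distribution; (beta0, log sigma_u) go on
    a dense grid.  M_p applies the same zero-residual rescaling constant
    used by the package, but everything else is independent arithmetic.
    """
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(gh_nodes)
    gh_w = gh_w / np.sqrt(2.0 * np.pi)

    def p_success(theta: np.ndarray) -> np.ndarray:
        t = theta[..., None] + gh_x
        return (special.expit(t) * gh_w).sum(-1)

    b_grid = np.linspace(-25.0, 25.0, n_beta)
    ls_grid = np.linspace(-7.0, 5.0, n_logsig)
    bb, ls = np.meshgrid(b_grid, ls_grid, indexing="ij")
    sig = np.exp(ls)
    a2 = sigma_u_prior_scale**2
    log_prior = -0.5 * bb**2 / intercept_prior_sd**2 + ls - np.log1p(np.exp(2 * ls) / a2)

    like = np.ones_like(bb)
    for k_i, n_i in counts:
        acc = np.zeros_like(bb)
        for xj, wj in zip(gh_x, gh_w):
            p = p_success(bb + sig * xj)
            acc += wj * p**k_i * (1.0 - p) ** (n_i - k_i)
        like *= acc
    post = np.exp(log_prior - log_prior.max()) * like
    post /= post.sum()
    marginal_beta = post.sum(axis=1)
    p_resc = special.expit(b_grid / np.sqrt(1.0 + C_LOGIT**2))
    return float(np.sum(p_resc * marginal_beta))


def hpd_bruteforce(draws: np.ndarray, mass: float) -> tuple[float, float]:
    """Narrowest interval by explicit search over every window."""
    x = np.sort(np.asarray(draws, float))
    n = x.size
    m = max(2, int(np.ceil(mass * n)))
    best = (x[0], x[-1])
    for j in range(n - m + 1):
        if x[j + m - 1] - x[j] < best[1] - best[0]:
            best = (x[j], x[j + m - 1])
    return best
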