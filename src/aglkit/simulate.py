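"""Synthetic participant cohorts with the GLMM's data-generating structure.

Each participant carries a latent propensity per session, drawn from a
multivariate normal across sessions (variance ``sigma2_id`` times the
``cross_grammar_corr`` matrix).  On every trial the response agrees with the
participant's strategy grammar's verdict with probability
``logistic(mu_logit + u)``; a lapse instead yields a uniform random
response.  Per-trial consistency with the strategy grammar is therefore
exactly Bernoulli on the latent logit scale, matching the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import StimulusSpec
from .consistency import RESPONSE_DIFFERENT, RESPONSE_SAME, TRIAL_COLUMNS
from .grammars import get_grammar


class NonPSDCorrelationError(ValueError):
    """The cross-session correlation matrix is not positive semi-definite."""


@dataclass(frozen=True)
class SimConfig:
    n_participants: int = 20
    #: session grammar -> strategy grammar actually "induced" (default: the target itself)
    strategies: Mapping[str, str] | None = None
    mu_logit: float = 1.386  # logistic(1.386) ~ 0.80
    sigma2_id: float = 0.5
    #: cross-session correlation of participant effects; None = identity
    cross_grammar_corr: np.ndarray | Sequence[Sequence[float]] | None = None
    lapse: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.sigma2_id < 0:
            raise ValueError("sigma2_id must be non-negative")
        if not 0 <= self.lapse <= 1:
            raise ValueError("lapse must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationResult:
    trials: pd.DataFrame
    #: ground-truth latent effects, one row per participant, one column per session grammar
    effects: pd.DataFrame
    config: SimConfig


def _corr_matrix(cfg: SimConfig, k: int) -> np.ndarray:
    if cfg.cross_grammar_corr is None:
        return np.eye(k)
    corr = np.asarray(cfg.cross_grammar_corr, dtype=float)
    if corr.shape != (k, k):
        raise ValueError(f"correlation matrix must be {k}x{k}, got {corr.shape}")
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise NonPSDCorrelationError("correlation matrix must be symmetric with unit diagonal")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        raise NonPSDCorrelationError(f"correlation matrix has negative eigenvalue {w.min():.3g}")
    return corr


def _draw_effects(cfg: SimConfig, k: int, rng: np.random.Generator) -> np.ndarray:
    corr = _corr_matrix(cfg, k)
    cov = cfg.sigma2_id * corr
    # eigen-based square root tolerates PSD matrices with zero eigenvalues
    w, v = np.linalg.eigh(cov)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((cfg.n_participants, k))
    return z @ root.T


def simulate_cohort(
    cfg: SimConfig,
    batteries: Mapping[str, Sequence[StimulusSpec]],
    strategy_overrides: Mapping[tuple[str, str], str] | None = None,
) -> SimulationResult:
    """Simulate a cohort over per-grammar batteries.

    ``strategy_overrides`` maps (participant_id, session_grammar) to an
    alternative strategy grammar, emulating participants who induced a
    different rule than the session target.
    """
    rng = np.random.default_rng(cfg.seed)
    sessions = list(batteries.keys())
    strategies = dict(cfg.strategies or {})
    for s in sessions:
        strategies.setdefault(s, s)
    overrides = dict(strategy_overrides or {})

    u = _draw_effects(cfg, len(sessions), rng)
    pids = [f"P{i + 1:02d}" for i in range(cfg.n_participants)]

    # verdicts per battery/strategy are pure, compute lazily and cache
    verdict_cache: dict[tuple[str, str], np.ndarray] = {}

    def verdicts(session: str, strategy: str) -> np.ndarray:
        key = (session, strategy)
        if key not in verdict_cache:
            g = get_grammar(strategy)
            verdict_cache[key] = np.array(
                [g.accepts(stim.categories) for stim in batteries[session]]
            )
        return verdict_cache[key]

    rows: list[dict] = []
    for i, pid in enumerate(pids):
        order = rng.permutation(len(sessions))
        for rank, si in enumerate(order):
            session = sessions[si]
            strategy = overrides.get((pid, session), strategies[session])
            stims = batteries[session]
            accept = verdicts(session, strategy)
            presentation = rng.permutation(len(stims))

            p_follow = 1.0 / (1.0 + np.exp(-(cfg.mu_logit + u[i, si])))
            agree = rng.random(len(stims)) < p_follow
            lapse = rng.random(len(stims)) < cfg.lapse
            coin = rng.random(len(stims)) < 0.5

            for t, j in enumerate(presentation):
                if lapse[j]:
                    say_same = bool(coin[j])
                elif agree[j]:
                    say_same = bool(accept[j])
                else:
                    say_same = not bool(accept[j])
                rows.append(
                    {
                        "participant_id": pid,
                        "session_grammar": session,
                        "session_order": rank + 1,
                        "trial_index": t,
                        "stimulus_id": stims[j].stimulus_id,
                        "response": RESPONSE_SAME if say_same else RESPONSE_DIFFERENT,
                    }
                )

    trials = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    effects = pd.DataFrame(u, index=pd.Index(pids, name="participant_id"), columns=sessions)
    return SimulationResult(trials=trials, effects=effects, config=cfg)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
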