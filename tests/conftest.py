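import warnings

import numpy as np
import pytest

from aglkit.battery import build_test_battery
from aglkit.consistency import code_trials
from aglkit.grammars import TARGET_GRAMMARS
from aglkit.simulate import SimConfig, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def batteries():
    """Default 87-item batteries for the three target grammars (fixed seed)."""
    rng = np.random.default_rng(7)
    return {g: build_test_battery(g, rng=rng) for g in TARGET_GRAMMARS}


@pytest.fixture(scope="session")
def copy_battery(batteries):
    return batteries["Copy"]


@pytest.fixture(scope="session")
def small_cohort(batteries):
    """20-participant Copy-session cohort with known generating parameters."""
    cfg = SimConfig(n_participants=20, mu_logit=1.5, sigma2_id=0.5, seed=11)
    sim = simulate_cohort(cfg, {"Copy": batteries["Copy"]})
    coded = code_trials(sim.trials, {"Copy": batteries["Copy"]}, ["Copy"])
    return sim, coded
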