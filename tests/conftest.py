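import numpy as np
import pytest
from hypothesis import settings

from g4twist import SimParams, TetherConfig, simulate_ensemble, simulate_ramp

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg_wt():
    return TetherConfig(construct="wt", ion="KCl")


@pytest.fixture(scope="session")
def cfg_mut():
    return TetherConfig(construct="mut", ion="KCl")


@pytest.fixture(scope="session")
def prm():
    return SimParams()


@pytest.fixture(scope="session")
def wt_ramp(cfg_wt, prm):
    """One G4-available wt ramp at n_t = -40 on the default grid."""
    return simulate_ramp(-40, cfg_wt, prm, True, seed=41)


@pytest.fixture(scope="session")
def mut_ramp(cfg_mut, prm):
    """One single-transition mut ramp at n_t = -40."""
    return simulate_ramp(-40, cfg_mut, prm, False, seed=42)


@pytest.fixture(scope="session")
def wt_ensemble(cfg_wt, prm):
    """60 wt-KCl ramps at n_t = -40 with recorded G4 ground truth."""
    return simulate_ensemble(60, -40, cfg_wt, prm, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
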