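import numpy as np
import pytest

from crossfeed import ModelParams, SystemState, integrate
from crossfeed.model import PRESETS


@pytest.fixture(scope="session")
def informed() -> ModelParams:
    return PRESETS["informed"]


@pytest.fixture(scope="session")
def neutral() -> ModelParams:
    return PRESETS["neutral"]


@pytest.fixture(scope="session")
def standard_init() -> SystemState:
    """Seeded culture at 1/5 of capacity, 20% ADE, no free metabolites."""
    return SystemState(xL=0.16, xA=0.04)


@pytest.fixture(scope="session")
def unsupplemented_traj(informed, standard_init):
    """Reference unsupplemented run shared across tests (read-only)."""
    return integrate(informed, standard_init, t_end=300)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
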