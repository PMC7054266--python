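import numpy as np
import pytest

from sessm import SEParams, EngineConfig
from sessm.simulate import simulate_dataset


@pytest.fixture(scope="session")
def m4_params() -> SEParams:
    """A typical full SE-SSM parameter set (used as generating truth)."""
    return SEParams(v=3.0, x_th=0.6, t=0.3, s_t=0.1, b=2.5, x_b=0.1)


@pytest.fixture(scope="session")
def basic_params() -> SEParams:
    """Basic SSM limit: no conflict terms."""
    return SEParams(v=1.0, x_th=0.5, t=0.3)


@pytest.fixture(scope="session")
def engine_cfg() -> EngineConfig:
    return EngineConfig()


@pytest.fixture(scope="session")
def m4_dataset(m4_params):
    """500 trials/condition simulated at the M4 truth (shared across tests)."""
    return simulate_dataset(m4_params, 500, rng=101)
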