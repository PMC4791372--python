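import numpy as np
import pytest
from hypothesis import settings

from axondbs import SimulationConfig, build_fiber

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def geom81():
    return build_fiber(5.7, 81)


@pytest.fixture(scope="session")
def geom171():
    return build_fiber(5.7, 171)


@pytest.fixture(scope="session")
def fast_config():
    """Coarse-step config for cheap engine tests."""
    return SimulationConfig(dt_ms=0.02, epoch_ms=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
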