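import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gridheat as gh

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalogue():
    """The packaged grid-threshold measurement table."""
    return gh.load_catalogue()


@pytest.fixture(scope="session")
def thermal():
    """Reference thermal conditions: 77 K stage, 136 K devitrification."""
    return gh.ThermalParams()


@pytest.fixture(scope="session")
def calibration(catalogue, thermal):
    """Per-material film parameters fitted on the measurement table."""
    return gh.fit_alpha(catalogue, thermal)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
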