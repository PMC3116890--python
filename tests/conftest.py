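import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from levmodel.neural_mass import ElectricalConstants
from levmodel.simulator import LEVParams
from levmodel.stimulus import StimulusProtocol

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def small_protocol():
    """Two-frequency protocol for fast end-to-end checks."""
    return StimulusProtocol(frequencies=(4.0, 10.0))


@pytest.fixture(scope="session")
def truth():
    return LEVParams.synthetic_truth()


@pytest.fixture(scope="session")
def consts():
    return ElectricalConstants()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
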