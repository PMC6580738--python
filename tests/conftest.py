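import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crcevo.simulate import SimulationParams, simulate_patient

settings.register_profile(
    "fast",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def clean_patient():
    """One noiseless simulated patient shared across read-only tests."""
    return simulate_patient(SimulationParams(noise=False), seed=17)


@pytest.fixture(scope="session")
def noisy_patient():
    return simulate_patient(SimulationParams(), seed=17)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
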