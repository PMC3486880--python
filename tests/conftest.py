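import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import paindyn as pdy
from paindyn.stimuli import ProtocolSpec, complex_stimulus, simple_stimulus

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def complex_stim():
    return complex_stimulus(ProtocolSpec())


@pytest.fixture(scope="session")
def simple_stim():
    return simple_stimulus(ProtocolSpec(seed=3))


@pytest.fixture(scope="session")
def default_second():
    return pdy.dynamics.DEFAULT_SECOND


@pytest.fixture(scope="session")
def default_first():
    return pdy.dynamics.DEFAULT_FIRST


@pytest.fixture
def step_stimulus():
    """Constant supra-threshold stimulus: T = T0 + 2 from t = 0 (T0 = 45)."""
    t = 0.1 * np.arange(500)
    return pdy.StimulusTrace(t, np.full(500, 47.0))
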