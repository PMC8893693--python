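import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stspotentials.muscle_moment_arms import GeometricMomentArmProvider
from stspotentials.state_space import enumerate_states
from stspotentials.synthetic_fixtures import default_muscles, default_segment_params

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_segment_params()


@pytest.fixture(scope="session")
def muscles():
    return default_muscles()


@pytest.fixture(scope="session")
def provider(params, muscles):
    return GeometricMomentArmProvider(muscles, params)


@pytest.fixture(scope="session")
def grid(params):
    """The full constrained kinematic grid with derived metrics."""
    return enumerate_states(params=params)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
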