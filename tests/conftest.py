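import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fraghop import AMWLite, generate_toy_system, toy_sequence
from fraghop._kinematics import warm_up

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session", autouse=True)
def _jit_warm_up():
    # compile the kinematics kernel once, outside any timed assertions
    warm_up()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def model():
    return AMWLite()


@pytest.fixture(scope="session")
def small_system():
    """A 12-residue toy system (sequence, fragment library, native)."""
    return generate_toy_system(12, seed=1)


@pytest.fixture(scope="session")
def sequence12():
    return toy_sequence(12)
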