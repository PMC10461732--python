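import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from snapmosaic import PhantomSpec, default_sensor, make_phantom_hypercube


@pytest.fixture(scope="session")
def sensor():
    """Default visible-range 4x4 sensor (16 measured, 13 ideal bands)."""
    return default_sensor(seed=0)


@pytest.fixture(scope="session")
def small_phantom():
    """A 32x32 phantom cube with reduced spectral sampling, for fast tests."""
    return make_phantom_hypercube(PhantomSpec(shape=(32, 32), n_bands=80, seed=3))


@pytest.fixture(scope="session")
def paired_sample(sensor, small_phantom):
    from snapmosaic import simulate_pair

    return simulate_pair(small_phantom, sensor)
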