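import pytest
from hypothesis import HealthCheck, settings

from otomsi import phantom

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_spec():
    """Quarter-scale phantom spec for fast unit tests."""
    return phantom.default_phantom_spec(width=244, height=124)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return phantom.generate_phantom(small_spec, seed=7)
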