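import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def forest_pop():
    """A filtered synthetic forest-floor population shared across tests."""
    from camoedge.colors import filter_population, synth_forest_population

    pop = synth_forest_population(10_000, np.random.default_rng(777))
    return filter_population(pop)
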