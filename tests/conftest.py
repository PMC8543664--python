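import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ids_pop():
    from normtrade import default_ids_population

    return default_ids_population()


@pytest.fixture(scope="session")
def lin_pop():
    """Most restricted population: linear, homoscedastic, normal."""
    from normtrade import build_population

    return build_population(linear_mu=True, homoscedastic=True, normal=True)


@pytest.fixture(scope="session")
def ids_sample(ids_pop):
    from normtrade import sample_norm_data

    return sample_norm_data(ids_pop, 1000, seed=424242)


@pytest.fixture
def ages_500():
    return np.linspace(5.0, 21.0, 500)
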