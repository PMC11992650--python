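import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import essga

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def beta_binomial():
    return essga.builtin_scenario("beta_binomial")


@pytest.fixture(scope="session")
def beta_binomial_draws(beta_binomial):
    """Mid-size draw set shared by regression/bootstrap unit tests."""
    return essga.simulate_drawset(beta_binomial, 10_000, seed=11)


@pytest.fixture(scope="session")
def gamma_exponential_draws():
    scn = essga.builtin_scenario("gamma_exponential")
    return essga.simulate_drawset(scn, 10_000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
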