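import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromdyn.synthetic_data import StateScenario, generate_state_scenario

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_scenario():
    """600-region noiseless scenario: the classifier fixed point."""
    return generate_state_scenario(
        StateScenario(n_regions=600, noise_sigma=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def noisy_scenario():
    """1000-region scenario at the study noise level (sigma = 0.2)."""
    return generate_state_scenario(
        StateScenario(n_regions=1000, noise_sigma=0.2, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
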