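import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest fully-featured cohort shared across tests."""
    from targetmr.simulate import SimulationConfig, simulate_cohort, default_outcome_models

    cfg = SimulationConfig(
        n_participants=6000, seed=11, outcome_models=default_outcome_models()
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
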