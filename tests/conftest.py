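import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mccrisk import SimulationConfig, default_true_params, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_true_params()


@pytest.fixture(scope="session")
def medium_sim():
    """One moderately sized heterogeneous cohort shared across tests."""
    cfg = SimulationConfig(
        n_total=3000, censor_ratio=0.2, sdcp=1.0, n_centers=17, seed=42
    )
    return simulate_cohort(cfg, np.random.default_rng(42))
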