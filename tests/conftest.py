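import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cfhl.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A compact deterministic cohort exercised by several test modules."""
    cfg = SimulationConfig(
        n_patients=12,
        seed=7,
        n_followup_patients=2,
        followup_missing_pre=0,
        n_snp_pool=40,
        n_artifact_pool=20,
    )
    truth, bundle = simulate_cohort(cfg)
    return truth, bundle


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (44 patients, 7 controls, 4 callers)."""
    truth, bundle = simulate_cohort(SimulationConfig(seed=11))
    return truth, bundle


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
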