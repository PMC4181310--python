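import pytest
from hypothesis import HealthCheck, settings

from fawnfate import SimConfig, field_filter, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def wtd_cohort():
    """A moderate white-tailed-deer-like cohort with default hazard."""
    cfg = SimConfig(n_neonates=150, horizon=120, seed=11)
    records, truth = simulate_cohort(cfg)
    return records, truth


@pytest.fixture(scope="session")
def wtd_known_age(wtd_cohort):
    records, _ = wtd_cohort
    return field_filter(records)
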