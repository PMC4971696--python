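import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def headline_null_config():
    """Headline null scenario: prehypertensive parallel trial, zero carryover."""
    from carrysim import TrialConfig

    return TrialConfig(
        design="parallel",
        rule="two_consecutive",
        treatment_years=2.0,
        followup_years=2.0,
        measurement_interval=0.25,
        inclusion_low=125.0,
        inclusion_high=140.0,
        trend=1.0,
        noise_sd=5.0,
        treatment_effect=-10.0,
        carryover_years=0.0,
        cohort_size_per_arm=100_000,
        n_per_arm_for_test=405,
        alpha=0.05,
    )
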