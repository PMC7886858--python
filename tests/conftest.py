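import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radgp import SyntheticCohortConfig, generate_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six patients, 12 features (2 informative): fast structural fixture."""
    return generate_cohort(
        SyntheticCohortConfig(
            n_patients=6,
            biopsies_per_patient_range=(2, 4),
            n_features=12,
            n_informative=2,
            noise_sd=0.2,
            seed=11,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
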