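import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nucleotyping as nt

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small two-class cohort with class-distinct texture and ploidy."""
    return nt.generate_cohort(
        nt.small_config(n_patients_per_class=3, nuclei_per_patient=120, seed=7)
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_cohort):
    return nt.run_study(tiny_cohort)
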