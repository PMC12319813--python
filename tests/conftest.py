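import numpy as np
import pytest

from qmrinorm import CohortDesign, TrajectorySpec, default_trajectory_specs, generate_cohort


@pytest.fixture(scope="session")
def default_specs():
    return default_trajectory_specs()


@pytest.fixture(scope="session")
def small_cohort(default_specs):
    """A 40-subject cohort over all default ROIs/metrics (seeded)."""
    return generate_cohort(CohortDesign(n_subjects=40, seed=7), default_specs)


@pytest.fixture()
def quadratic_spec():
    """A quadratic R1-like trajectory peaking at age 50."""
    return TrajectorySpec(
        roi="Pu", metric="R1", intercept=0.7375, beta_age=0.0045, beta_age2=-4.5e-5,
        beta_sex=0.005, beta_hemi=0.01, noise_sd0=0.03,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
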