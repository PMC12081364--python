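import warnings

import numpy as np
import pytest

from mtxppk.covariate_model import ErrorModel, FixedEffects, RandomEffects
from mtxppk.estimation import EventDataset
from mtxppk.structural_pk import PKParameters
from mtxppk.synthetic_cohort import StudyDesign, simulate_cohort

warnings.filterwarnings("ignore", category=RuntimeWarning)

#: final published fixed effects + module-default variability
TRUTH = {
    "cl": 12.88, "vc": 72.04, "q": 1.08, "vp": 94.94,
    "beta_egfr_cl": 0.23, "beta_bw_cl": 0.39, "beta_bw_vc": 0.31,
    "beta_blm_cl": 0.08, "beta_tbil_cl": -0.05, "beta_alb_cl": -0.18,
    "omega_cl": 0.30, "omega_vc": 0.32, "sigma_prop": 0.37,
}


@pytest.fixture(scope="session")
def final_params():
    return PKParameters(cl=12.88, vc=72.04, q=1.08, vp=94.94)


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject noisy cohort with 2 courses (fast fixture)."""
    sim = simulate_cohort(n=60, design=StudyDesign(n_courses=2), seed=123)
    return sim


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return EventDataset.from_dataframe(small_cohort.events)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """No IIV, no residual error: observations equal typical predictions."""
    return simulate_cohort(
        n=20, design=StudyDesign(n_courses=2), seed=5,
        omega=RandomEffects(omega_cl=0.0, omega_vc=0.0),
        error=ErrorModel(kind="proportional", sigma_prop=0.0),
    )


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_cohort):
    return EventDataset.from_dataframe(noise_free_cohort.events)
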