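import numpy as np
import pandas as pd
import pytest

import kfrisk
from kfrisk.synthetic import default_cohort_spec


@pytest.fixture(scope="session")
def kfre_model():
    return kfrisk.default_kfre_model()


@pytest.fixture(scope="session")
def small_spec():
    """Default study conditions at reduced scale for fast tests."""
    spec = default_cohort_spec()
    spec.n_white, spec.n_south_asian = 2700, 300
    return spec


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return kfrisk.generate_cohort(small_spec, seed=20240915)


def single_predictor_model(beta=0.5, scale=10.0, centre=7.0, s0=0.9, predictor="age"):
    return kfrisk.SurvivalModel(
        family="cox_cause_specific",
        coefficients={predictor: beta},
        centring={predictor: (scale, centre)},
        baseline_survival_5y=s0,
        acr_log_transform=False,
        acr_unit_factor=1.0,
    )


@pytest.fixture
def toy_patient():
    return dict(
        id=1, age=80.0, sex="male", ethnicity="white", egfr=25.0, acr=30.0,
        diabetes=1, heart_failure=0, cardiovascular_disease=0, hypertension=1,
        follow_up_time=5.0, event="censored", eligible=1,
    )


def uncensored_cohort(times, events, **cols) -> pd.DataFrame:
    """Minimal cohort frame for estimator-level tests."""
    n = len(times)
    base = dict(
        id=np.arange(n), age=70.0, sex="female", ethnicity="white",
        egfr=40.0, acr=5.0, diabetes=0, heart_failure=0,
        cardiovascular_disease=0, hypertension=0, eligible=1,
    )
    base.update(cols)
    return pd.DataFrame({**base, "follow_up_time": times, "event": events})
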