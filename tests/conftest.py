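import numpy as np
import pandas as pd
import pytest

import parasurv as ps


def make_censored_cohort(n=120, seed=0, event_rate=0.1, censor_rate=0.07,
                         beta=0.4):
    """Generic exponential cohort with one continuous covariate."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    T = rng.exponential(1.0 / (event_rate * np.exp(beta * z)))
    C = rng.exponential(1.0 / censor_rate, size=n)
    t = np.minimum(T, C)
    d = (T <= C).astype(int)
    return ps.SurvivalCohort(time=t, event=d,
                             covariates=pd.DataFrame({"z": z}))


@pytest.fixture
def censored_cohort():
    return make_censored_cohort()


@pytest.fixture(scope="session")
def study_cohort_5000():
    """One large cohort from the study-mimicking generator, on the
    generator's model scale — shared across recovery tests."""
    spec = ps.study_spec(n_subjects=5000, seed=202)
    cohort = ps.generate_cohort(spec)
    scaled, cols = ps.to_model_scale(cohort, spec)
    return spec, scaled, cols


@pytest.fixture(scope="session")
def fitted_models_5000(study_cohort_5000):
    spec, cohort, cols = study_cohort_5000
    weib = ps.fit_weibull_aft(cohort, cols)
    cox = ps.fit_cox(cohort, cols)
    return spec, cohort, cols, weib, cox
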