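"""Weibull AFT fitting, parameter transforms, and effect estimates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import parasurv as ps
from parasurv.nonparametric import nelson_aalen
from parasurv.weibull import _neg_loglik_and_grad

from conftest import make_censored_cohort


# ---------------------------------------------------------------- transforms

def test_aft_ph_identity_case():
    gamma, lam, beta = ps.aft_to_ph(0.0, 1.0, np.zeros(3))
    assert gamma == 1.0 and lam == 1.0 and np.all(beta == 0)


def test_shape_is_reciprocal_scale():
    gamma, _, _ = ps.aft_to_ph(0.3, 0.5, np.zeros(1))
    assert gamma == 2.0


@settings(deadline=None, derandomize=True, max_examples=200)
@given(mu=st.floats(-5, 5), sigma=st.floats(0.05, 5),
       alpha=st.lists(st.floats(-3, 3), min_size=1, max_size=4))
def test_aft_ph_round_trip(mu, sigma, alpha):
    gamma, lam, beta = ps.aft_to_ph(mu, sigma, np.asarray(alpha))
    mu2, sigma2, alpha2 = ps.ph_to_aft(gamma, lam, beta)
    assert abs(mu - mu2) < 1e-12 * max(1, abs(mu))
    assert abs(sigma - sigma2) < 1e-12
    assert np.allclose(alpha, alpha2, rtol=1e-12, atol=1e-12)


def test_transform_domain_errors():
    with pytest.raises(ps.DataError):
        ps.aft_to_ph(0.0, -1.0, np.zeros(1))
    with pytest.raises(ps.DataError):
        ps.ph_to_aft(-0.5, 1.0, np.zeros(1))


# ------------------------------------------------------------------- fitting

def test_exponential_closed_form_score():
    """With shape fixed at 1 the scale MLE is events/total-time: the score
    in log-lambda vanishes at lambda = 4/10 = 0.4 for times {1,2,3,4}."""
    t = np.array([1.0, 2.0, 3.0, 4.0])
    d = np.ones(4)
    z = np.empty((4, 0))
    theta = np.array([0.0, np.log(0.4)])  # log gamma = 0, log lambda
    _, grad = _neg_loglik_and_grad(theta, t, d, z)
    assert abs(grad[1]) < 1e-12


def test_fit_recovers_truth_and_is_locally_optimal(fitted_models_5000):
    spec, cohort, cols, weib, _ = fitted_models_5000
    truth = np.asarray(spec.beta_true)
    se = np.sqrt(np.diag(weib.covariance))
    assert abs(np.log(weib.gamma) - np.log(spec.gamma_true)) < 3 * se[0]
    assert abs(np.log(weib.lambda_) - np.log(spec.lambda_true)) < 3 * se[1]
    assert np.all(np.abs(weib.beta - truth) < 3 * se[2:])
    # local optimality: better than 100 nearby random perturbations
    t, d = cohort.time, cohort.event.astype(float)
    z = cohort.design_matrix(cols)
    theta_hat = np.concatenate([[np.log(weib.gamma), np.log(weib.lambda_)],
                                weib.beta])
    nll_hat, _ = _neg_loglik_and_grad(theta_hat, t, d, z)
    rng = np.random.default_rng(0)
    for _ in range(100):
        pert = theta_hat + 0.05 * rng.standard_normal(theta_hat.size)
        nll_p, _ = _neg_loglik_and_grad(pert, t, d, z)
        assert nll_p >= nll_hat


def test_parameterizations_consistent(fitted_models_5000):
    _, _, _, m, _ = fitted_models_5000
    assert abs(m.gamma - 1.0 / m.sigma) < 1e-10
    assert abs(m.lambda_ - np.exp(-m.mu / m.sigma)) < 1e-8 * m.lambda_
    assert np.allclose(m.beta, -m.alpha / m.sigma, atol=1e-10)
    eig = np.linalg.eigvalsh(m.covariance)
    assert eig.min() > -1e-10


def test_fit_matches_lifelines():
    lifelines = pytest.importorskip("lifelines")
    cohort = make_censored_cohort(n=800, seed=3)
    m = ps.fit_weibull_aft(cohort, ["z"])
    df = pd.DataFrame({"t": cohort.time, "d": cohort.event,
                       "z": cohort.covariates["z"]})
    aft = lifelines.WeibullAFTFitter().fit(df, "t", "d")
    rho = float(aft.params_[("rho_", "Intercept")])
    b0 = float(aft.params_[("lambda_", "Intercept")])
    bz = float(aft.params_[("lambda_", "z")])
    # lifelines: S = exp(-(t/exp(b0+bz z))^rho)  =>  PH scale:
    assert abs(m.gamma - np.exp(rho)) < 1e-3 * m.gamma
    assert abs(m.beta[0] - (-np.exp(rho) * bz)) < 1e-3
    assert abs(np.log(m.lambda_) - (-np.exp(rho) * b0)) < 1e-3


def test_fit_error_cases():
    t = np.array([1.0, 2.0, 3.0])
    cov = pd.DataFrame({"z": [1.0, 2.0, 3.0], "z2": [2.0, 4.0, 6.0]})
    cohort = ps.SurvivalCohort(time=t, event=[0, 0, 0], covariates=cov)
    with pytest.raises(ps.DataError, match="no events"):
        ps.fit_weibull_aft(cohort, ["z"])
    cohort2 = ps.SurvivalCohort(time=t, event=[1, 1, 0], covariates=cov)
    with pytest.raises(ps.DataError, match="z2"):
        ps.fit_weibull_aft(cohort2, ["z", "z2"])


# ------------------------------------------------------------------ effects

def _mock_model(beta, gamma=1.0, var=0.01, names=None):
    names = names or [f"x{i}" for i in range(len(beta))]
    beta = np.asarray(beta, dtype=float)
    p = len(beta) + 2
    cov = np.eye(p) * var
    mu, sigma, alpha = ps.ph_to_aft(gamma, 1e-4, beta)
    return ps.WeibullAFTModel(gamma=gamma, lambda_=1e-4, beta=beta, mu=mu,
                              sigma=sigma, alpha=alpha, covariance=cov,
                              loglik=0.0, n=10, n_events=5,
                              covariate_names=names)


def test_hazard_ratio_values():
    m = _mock_model([0.0, np.log(2.0)])
    assert ps.hazard_ratio(m, "x0").estimate == pytest.approx(1.0)
    assert ps.hazard_ratio(m, "x1").estimate == pytest.approx(2.0)
    hr = ps.hazard_ratio(m, "x1")
    assert hr.ci_low < hr.estimate < hr.ci_high
    with pytest.raises(ps.DataError):
        ps.hazard_ratio(m, "nope")


def test_event_time_ratio_values():
    m = _mock_model([0.0, 0.5], gamma=1.0)
    assert ps.event_time_ratio(m, "x0").estimate == pytest.approx(1.0)
    # gamma=1: ETR is exactly 1/HR
    etr = ps.event_time_ratio(m, "x1").estimate
    hr = ps.hazard_ratio(m, "x1").estimate
    assert etr == pytest.approx(1.0 / hr, rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(beta=st.floats(-3, 3), gamma=st.floats(0.05, 5))
def test_etr_hr_sign_linkage(beta, gamma):
    """ETR < 1 exactly when HR > 1, for any positive shape."""
    hr = ps.hr_from_coefficient(beta)
    etr = ps.etr_from_coefficient(beta, gamma)
    if abs(beta) > 1e-12:
        assert (hr > 1) == (etr < 1)


# ------------------------------------------- percentile times and survival

def test_percentile_time_unit_exponential():
    m = _mock_model([0.0])
    m.lambda_ = 1.0
    assert ps.percentile_time(m, [0.0], np.exp(-1.0)) == pytest.approx(1.0)


def test_percentile_time_closed_form_and_identity():
    lam, gamma = 3.0447e-05, 0.9929
    m = _mock_model([0.3], gamma=gamma)
    m.lambda_ = lam
    tp = ps.percentile_time(m, [0.0], 0.95)
    oracle = (-np.log(0.95) / lam) ** (1.0 / gamma)
    assert tp == pytest.approx(oracle, rel=1e-12)
    # S(t_p) = p to 1e-10
    assert ps.predict_survival(m, [0.0], [tp])[0] == pytest.approx(0.95, abs=1e-10)


def test_percentile_time_lambda_scaling():
    m1 = _mock_model([0.0], gamma=1.0)
    m1.lambda_ = 0.01
    m2 = _mock_model([0.0], gamma=1.0)
    m2.lambda_ = 0.02
    t1 = ps.percentile_time(m1, [0.0], 0.5)
    t2 = ps.percentile_time(m2, [0.0], 0.5)
    assert t1 == pytest.approx(2 * t2, rel=1e-12)
    with pytest.raises(ps.DataError):
        ps.percentile_time(m1, [0.0], 1.5)


def test_time_ratio_properties():
    m = _mock_model([0.4, -0.2], gamma=1.7)
    z1, z0 = np.array([1.0, 0.5]), np.array([0.0, 0.5])
    assert ps.time_ratio(m, z0, z0) == pytest.approx(1.0)
    # p-invariance
    r1 = ps.time_ratio(m, z1, z0, p=0.5)
    r2 = ps.time_ratio(m, z1, z0, p=0.95)
    assert r1 == pytest.approx(r2, rel=1e-12)
    # unit contrast reproduces the ETR
    assert r1 == pytest.approx(ps.event_time_ratio(m, "x0").estimate, rel=1e-12)


def test_predict_survival_basics():
    m = _mock_model([0.0])
    m.lambda_ = 1.0
    s = ps.predict_survival(m, [0.7], [0.0, 1.0])
    assert s[0] == 1.0
    m2 = _mock_model([0.0])
    m2.lambda_ = 1.0
    assert ps.predict_survival(m2, [0.0], [1.0])[0] == pytest.approx(np.exp(-1))
    times = np.linspace(0, 50, 30)
    vals = ps.predict_survival(m, [0.3], times)
    assert np.all(np.diff(vals) <= 0)
    with pytest.raises(ps.DataError):
        ps.predict_survival(m, [0.0], [-1.0])


def test_predicted_survival_matches_km(fitted_models_5000):
    """Deciles of KM on well-specified data within 0.02 of the model curve."""
    spec, cohort, cols, weib, _ = fitted_models_5000
    sub = cohort.subset(np.arange(len(cohort)))
    from parasurv.nonparametric import kaplan_meier
    km = kaplan_meier(sub.time, sub.event)
    grid = np.quantile(sub.time[sub.event == 1], np.linspace(0.1, 0.9, 9))
    z = sub.design_matrix(cols)
    surv = np.exp(-weib.lambda_ * np.exp(z @ weib.beta)[:, None]
                  * grid[None, :] ** weib.gamma).mean(axis=0)
    assert np.max(np.abs(np.asarray(km(grid)) - surv)) < 0.02


# ----------------------------------------------------- distribution check

def test_check_distribution_self_and_wellspecified(fitted_models_5000):
    spec, cohort, cols, weib, _ = fitted_models_5000
    chk = ps.check_distribution(weib, cohort)
    assert np.max(np.abs(chk.parametric - chk.parametric)) == 0.0
    assert chk.nonparametric[0] == 0.0 and chk.parametric[0] == 0.0
    assert np.all(np.diff(chk.nonparametric) >= 0)
    assert np.all(np.diff(chk.parametric) >= 0)
    assert chk.max_abs_discrepancy < 0.15


def test_nelson_aalen_increments_brute_force():
    rng = np.random.default_rng(6)
    t = rng.exponential(5.0, 25).round(1)  # force some ties
    d = (rng.uniform(size=25) < 0.7).astype(int)
    d[0] = 1
    na = nelson_aalen(t, d)
    # brute-force loop
    for tk, hk in zip(na.times, np.diff(np.concatenate([[0], na.values]))):
        at_risk = np.sum(t >= tk)
        deaths = np.sum((t == tk) & (d == 1))
        assert hk == pytest.approx(deaths / at_risk, rel=1e-12)
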