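"""IPCW Brier score, time-dependent AUC, null model, bootstrap bands."""

import numpy as np
import pandas as pd
import pytest

import parasurv as ps
from parasurv.nonparametric import kaplan_meier

from conftest import make_censored_cohort


def _cohort(t, d, **cols):
    if not cols:
        cols = {"z": np.zeros(len(t))}
    return ps.SurvivalCohort(time=np.asarray(t, dtype=float), event=d,
                             covariates=pd.DataFrame(cols))


# --------------------------------------------------------- censoring G(t)

def test_g_is_one_without_censoring():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    G = ps.censoring_weights(_cohort(t, [1, 1, 1, 1]))
    assert np.allclose(G([0.5, 1.5, 3.5]), 1.0)


def test_g_equals_km_of_censoring_times():
    rng = np.random.default_rng(3)
    t = rng.exponential(5.0, 40)
    d = np.zeros(40, dtype=int)  # all censored
    G = ps.censoring_weights(_cohort(t, d))
    km = kaplan_meier(t, 1 - d)
    grid = np.quantile(t, np.linspace(0.05, 0.9, 15))
    assert np.allclose(np.asarray(G(grid)), np.asarray(km(grid)), atol=1e-12)
    # brute force product-limit
    for tq in grid:
        prod = 1.0
        for tc in np.sort(t[t <= tq]):
            prod *= 1.0 - 1.0 / np.sum(t >= tc)
        assert float(G(tq)) == pytest.approx(prod, abs=1e-12)


def test_g_ignores_covariates():
    t = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
    d = [1, 0, 1, 0, 1]
    g1 = ps.censoring_weights(_cohort(t, d, z=np.arange(5.0)))
    g2 = ps.censoring_weights(_cohort(t, d, z=np.ones(5) * 9.0))
    assert np.array_equal(g1.values, g2.values)


# ------------------------------------------------------------------ Brier

def test_perfect_forecaster_brier_zero():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    d = np.ones(5, dtype=int)
    times = np.array([1.5, 2.5, 3.5])
    surv = (t[:, None] > times[None, :]).astype(float)
    curve = ps.brier_curve(surv, _cohort(t, d), times)
    assert np.allclose(curve.values, 0.0, atol=1e-15)


def test_antiperfect_forecaster_brier_one():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    d = np.ones(5, dtype=int)
    times = np.array([1.5, 2.5, 3.5])
    surv = 1.0 - (t[:, None] > times[None, :]).astype(float)
    curve = ps.brier_curve(surv, _cohort(t, d), times)
    assert np.allclose(curve.values, 1.0, atol=1e-15)


def test_constant_half_brier_quarter_at_median():
    t = np.linspace(1, 10, 10)
    d = np.ones(10, dtype=int)
    med = 5.5  # 5 above, 5 below
    curve = ps.brier_curve(np.full((10, 1), 0.5), _cohort(t, d), [med])
    assert curve.values[0] == pytest.approx(0.25)


def test_brier_brute_force_censored():
    rng = np.random.default_rng(21)
    n = 30
    T = rng.exponential(8.0, n)
    C = rng.exponential(10.0, n)
    t = np.minimum(T, C)
    d = (T <= C).astype(int)
    cohort = _cohort(t, d)
    times = np.quantile(t[d == 1], [0.25, 0.5, 0.75])
    surv = rng.uniform(0.1, 0.95, size=(n, 3))
    curve = ps.brier_curve(surv, cohort, times)
    G = ps.censoring_weights(cohort)
    for k, tt in enumerate(times):
        acc = 0.0
        for i in range(n):
            if t[i] <= tt and d[i] == 1:
                acc += surv[i, k] ** 2 / G.left_limit(t[i])
            elif t[i] > tt:
                acc += (1 - surv[i, k]) ** 2 / G(tt)
        assert curve.values[k] == pytest.approx(acc / n, abs=1e-12)


def test_brier_beyond_g_support_errors():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    d = [1, 1, 1, 0]  # last subject censored last => G hits 0
    cohort = _cohort(t, d)
    with pytest.raises(ps.DataError, match="truncate"):
        ps.brier_curve(np.full((4, 1), 0.5), cohort, [5.0])


# -------------------------------------------------------------------- AUC

def test_perfect_separation_auc_one():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    d = np.ones(6, dtype=int)
    risk = -t  # earlier death = higher risk
    curve = ps.auc_curve(risk, _cohort(t, d), [1.5, 3.5, 6.5])
    assert np.allclose(curve.values[:2], 1.0)
    assert curve.undefined[2]  # no controls after the last event


def test_random_scores_auc_half():
    rng = np.random.default_rng(14)
    n = 2000
    t = rng.exponential(5.0, n)
    d = np.ones(n, dtype=int)
    risk = rng.standard_normal(n)  # exchangeable
    times = np.quantile(t, [0.2, 0.4, 0.6, 0.8])
    curve = ps.auc_curve(risk, _cohort(t, d), times)
    assert np.max(np.abs(curve.values - 0.5)) < 0.03


def test_auc_brute_force_censored_with_ties():
    rng = np.random.default_rng(33)
    n = 30
    T = rng.exponential(8.0, n)
    C = rng.exponential(12.0, n)
    t = np.minimum(T, C)
    d = (T <= C).astype(int)
    cohort = _cohort(t, d)
    risk = rng.integers(0, 4, size=n).astype(float)  # ties in scores
    times = np.quantile(t[d == 1], [0.3, 0.6])
    curve = ps.auc_curve(risk, cohort, times)
    G = ps.censoring_weights(cohort)
    for k, tt in enumerate(times):
        num = den = 0.0
        for i in range(n):
            if not (t[i] <= tt and d[i] == 1):
                continue
            wi = 1.0 / G.left_limit(t[i])
            for j in range(n):
                if t[j] <= tt:
                    continue
                wj = 1.0 / float(G(tt))
                c = 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
                num += wi * wj * c
                den += wi * wj
        assert curve.values[k] == pytest.approx(num / den, abs=1e-12)


# ------------------------------------------------------------- null model

def test_null_brier_quarter_at_median():
    t = np.linspace(1, 10, 10)
    d = np.ones(10, dtype=int)
    km = kaplan_meier(t, d)
    t_star = 5.5
    assert float(km(t_star)) == pytest.approx(0.5)
    curve = ps.null_model_curve(_cohort(t, d), [t_star], metric="brier")
    assert curve.values[0] == pytest.approx(0.25)


def test_null_auc_flagged_undefined():
    cohort = make_censored_cohort(n=50, seed=2)
    curve = ps.null_model_curve(cohort, [1.0, 2.0], metric="auc")
    assert np.all(curve.undefined)


def test_null_independent_of_covariates():
    c1 = make_censored_cohort(n=80, seed=4)
    cov = c1.covariates.copy()
    cov["z"] = 99.0 - cov["z"]
    c2 = ps.SurvivalCohort(time=c1.time, event=c1.event, covariates=cov)
    times = np.quantile(c1.time[c1.event == 1], [0.3, 0.6])
    n1 = ps.null_model_curve(c1, times)
    n2 = ps.null_model_curve(c2, times)
    assert np.array_equal(n1.values, n2.values)


def test_informative_model_beats_null_on_average():
    """True-model predictions have smaller mean Brier than the null."""
    spec0 = ps.study_spec().to_dict()
    wins = 0
    for rep in range(20):
        spec = ps.CohortSpec(**{**spec0, "n_subjects": 1000, "seed": 900 + rep})
        cohort = ps.generate_cohort(spec)
        scaled, cols = ps.to_model_scale(cohort, spec)
        times = ps.default_time_grid(scaled, n_points=10)
        z = scaled.design_matrix(cols)
        lp = z @ np.asarray(spec.beta_true)
        surv = np.exp(-spec.lambda_true * np.exp(lp)[:, None]
                      * times[None, :] ** spec.gamma_true)
        model_b = ps.brier_curve(surv, scaled, times).mean_value()
        null_b = ps.null_model_curve(scaled, times).mean_value()
        wins += model_b <= null_b
    assert wins >= 16  # clear majority


# -------------------------------------------------------------- bootstrap

def _km_refitter(boot):
    km = kaplan_meier(boot.time, boot.event)
    return lambda times: np.repeat(np.asarray(km(times))[None, :],
                                   len(boot), axis=0)


def test_bootstrap_single_replicate_zero_band():
    cohort = make_censored_cohort(n=100, seed=6)
    times = np.quantile(cohort.time[cohort.event == 1], [0.3, 0.6])
    band = ps.bootstrap_curves(_km_refitter, cohort, times, B=1, seed=0)
    assert np.allclose(band.se, 0.0)


def test_bootstrap_seed_determinism():
    cohort = make_censored_cohort(n=100, seed=6)
    times = np.quantile(cohort.time[cohort.event == 1], [0.3, 0.6])
    b1 = ps.bootstrap_curves(_km_refitter, cohort, times, B=8, seed=5)
    b2 = ps.bootstrap_curves(_km_refitter, cohort, times, B=8, seed=5)
    assert np.array_equal(b1.values, b2.values)
    assert np.array_equal(b1.se, b2.se)


def test_bootstrap_band_shrinks_with_n():
    widths = []
    for n in (60, 240, 960):
        cohort = make_censored_cohort(n=n, seed=9)
        times = np.quantile(cohort.time[cohort.event == 1], [0.3, 0.5, 0.7])
        band = ps.bootstrap_curves(_km_refitter, cohort, times, B=25, seed=2)
        widths.append(np.median(band.se))
    assert widths[0] > widths[1] > widths[2]


def test_weibull_beats_cox_brier_on_correct_specification():
    """Parametric model at least matches Cox out-of-sample most of the time
    when the Weibull model is correctly specified (411/80 train/test)."""
    spec0 = ps.study_spec().to_dict()
    wins = 0
    reps = 100
    for rep in range(reps):
        spec = ps.CohortSpec(**{**spec0, "n_subjects": 491, "seed": 5000 + rep})
        cohort = ps.generate_cohort(spec)
        scaled, cols = ps.to_model_scale(cohort, spec)
        train, test = ps.split_cohort(scaled, 80 / 491, seed=rep)
        try:
            weib = ps.fit_weibull_aft(train, cols)
            cox = ps.fit_cox(train, cols)
        except ps.ParasurvError:
            continue
        times = ps.default_time_grid(test, n_points=20)
        z = test.design_matrix(cols)
        surv_w = np.exp(-weib.lambda_ * np.exp(z @ weib.beta)[:, None]
                        * times[None, :] ** weib.gamma)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            surv_c = np.vstack([ps.predict_survival_cox(cox, zi, times)
                                for zi in z])
        bw = ps.brier_curve(surv_w, test, times).mean_value()
        bc = ps.brier_curve(surv_c, test, times).mean_value()
        wins += bw <= bc
    assert wins / reps >= 0.6
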