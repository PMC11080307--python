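"""Semiparametric Cox proportional-hazards regression and diagnostics.

Implements the partial-likelihood fit (Efron or Breslow tie handling) by
Newton-Raphson with step-halving, the Breslow baseline cumulative hazard
(centered at covariate means), Schoenfeld and martingale residuals, and the
Grambsch-Therneau score test of the proportional-hazards assumption: a test
for zero slope of the scaled Schoenfeld residuals on a transform of event
time, the statistic behind R's ``cox.zph``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import SurvivalCohort
from .errors import ConvergenceError, DataError
from .nonparametric import StepFunction, kaplan_meier

__all__ = [
    "CoxModel", "PHTestResult", "fit_cox", "schoenfeld_residuals",
    "ph_test", "martingale_residuals", "predict_survival_cox",
]


@dataclass
class CoxModel:
    beta: np.ndarray
    covariance: np.ndarray
    baseline_cumhaz: StepFunction  # centered at covariate means
    loglik: float
    n: int
    n_events: int
    ties_method: str
    covariate_names: list[str]
    z_mean: np.ndarray
    # training data retained for residual computations / cohort matching
    _time: np.ndarray = field(repr=False, default=None)
    _event: np.ndarray = field(repr=False, default=None)
    _z: np.ndarray = field(repr=False, default=None)

    def matches(self, cohort: SurvivalCohort) -> bool:
        return (len(cohort) == self.n
                and np.array_equal(cohort.time, self._time)
                and np.array_equal(cohort.event, self._event))


@dataclass(frozen=True)
class PHTestResult:
    covariate_names: list[str]
    chi2: np.ndarray          # per covariate
    df: np.ndarray
    p_values: np.ndarray
    global_chi2: float
    global_df: int
    global_p: float
    transform: str

    def __post_init__(self):
        if np.any(self.p_values < 0) or np.any(self.p_values > 1):
            raise DataError("p-values outside [0, 1]")


def _grouped_event_times(t, d):
    """Unique event times with (risk-start index, tied-event indices)."""
    groups = []
    uniq = np.unique(t[d == 1])
    for tk in uniq:
        start = np.searchsorted(t, tk, side="left")
        tied = np.where((t == tk) & (d == 1))[0]
        groups.append((tk, start, tied))
    return groups


def _partial_lik_parts(beta, t, d, z, groups, ties):
    """(loglik, score, information) of the partial likelihood.

    Inputs sorted ascending by time. Suffix sums give risk-set aggregates.
    """
    n, p = z.shape
    eta = z @ beta if p else np.zeros(n)
    eta = eta - eta.max() if n else eta  # stabilize; constant shift cancels
    w = np.exp(eta)
    wz = w[:, None] * z
    wzz = wz[:, :, None] * z[:, None, :]
    # suffix (reverse cumulative) sums
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wz[::-1], axis=0)[::-1]
    s2 = np.cumsum(wzz[::-1], axis=0)[::-1]

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    for tk, start, tied in groups:
        dcount = tied.size
        S0, S1, S2 = s0[start], s1[start], s2[start]
        ll += eta[tied].sum()
        score += z[tied].sum(axis=0)
        if ties == "efron" and dcount > 1:
            c0 = w[tied].sum()
            c1 = wz[tied].sum(axis=0)
            c2 = wzz[tied].sum(axis=0)
            for l in range(dcount):
                f = l / dcount
                p0 = S0 - f * c0
                p1 = S1 - f * c1
                p2 = S2 - f * c2
                ll -= np.log(p0)
                zbar = p1 / p0
                score -= zbar
                info += p2 / p0 - np.outer(zbar, zbar)
        else:  # breslow, or no ties
            ll -= dcount * np.log(S0)
            zbar = S1 / S0
            score -= dcount * zbar
            info += dcount * (S2 / S0 - np.outer(zbar, zbar))
    return ll, score, info


def _baseline_increments(beta, t, d, z, groups, ties, z_mean):
    """Baseline cumulative-hazard jumps at event times, centered covariates.

    ``ties='efron'`` uses the Efron-adjusted denominators; ``'breslow'`` the
    plain d/S0 jumps (which make martingale residuals sum to exactly zero).
    """
    w = np.exp((z - z_mean) @ beta) if z.shape[1] else np.ones(t.size)
    s0 = np.cumsum(w[::-1])[::-1]
    times = np.empty(len(groups))
    inc = np.empty(len(groups))
    inc_breslow = np.empty(len(groups))
    for k, (tk, start, tied) in enumerate(groups):
        dcount = tied.size
        S0 = s0[start]
        c0 = w[tied].sum()
        times[k] = tk
        inc_breslow[k] = dcount / S0
        if ties == "efron" and dcount > 1:
            inc[k] = sum(1.0 / (S0 - (l / dcount) * c0) for l in range(dcount))
        else:
            inc[k] = dcount / S0
    return times, inc, inc_breslow


def fit_cox(cohort: SurvivalCohort, covariates: Sequence[str],
            ties: str = "efron") -> CoxModel:
    """Newton-Raphson partial-likelihood fit.

    Converges when the score max-norm drops below 1e-8; raises
    :class:`ConvergenceError` (carrying the last iterate) otherwise.
    """
    if ties not in ("efron", "breslow"):
        raise DataError(f"unknown ties method {ties!r}")
    covariates = list(covariates)
    if cohort.n_events < 1:
        raise DataError("no events in cohort")
    zfull = cohort.design_matrix(covariates) if covariates else np.empty((len(cohort), 0))
    if covariates:
        sds = zfull.std(axis=0)
        constant = [covariates[j] for j in np.where(sds == 0)[0]]
        if constant:
            raise DataError(f"constant covariate column(s): {constant}")
        q, r = np.linalg.qr(zfull - zfull.mean(axis=0))
        diag = np.abs(np.diag(r))
        bad = [covariates[j] for j in np.where(diag < 1e-8 * max(diag.max(), 1.0))[0]]
        if bad:
            raise DataError(f"rank-deficient design; collinear column(s): {bad}")

    order = np.argsort(cohort.time, kind="stable")
    t = cohort.time[order]
    d = cohort.event[order]
    z = zfull[order]
    z_mean = zfull.mean(axis=0) if covariates else np.zeros(0)
    groups = _grouped_event_times(t, d)

    p = z.shape[1]
    beta = np.zeros(p)
    ll, score, info = _partial_lik_parts(beta, t, d, z, groups, ties)
    if p:
        converged = False
        for _ in range(100):
            if np.max(np.abs(score)) < 1e-8:
                converged = True
                break
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError("singular information matrix",
                                       last_iterate=beta) from exc
            # step halving; slack scaled to |loglik| so rounding near the
            # optimum cannot stall the iteration
            slack = 1e-10 * (1.0 + abs(ll))
            for _ in range(40):
                cand = beta + step
                ll_new, score_new, info_new = _partial_lik_parts(
                    cand, t, d, z, groups, ties)
                if np.isfinite(ll_new) and ll_new >= ll - slack:
                    break
                step = step / 2.0
            beta, ll, score, info = cand, ll_new, score_new, info_new
        else:
            converged = np.max(np.abs(score)) < 1e-8
        if not converged and np.max(np.abs(score)) > 1e-6:
            raise ConvergenceError(
                f"Cox fit did not converge (score max-norm "
                f"{np.max(np.abs(score)):.2e})", last_iterate=beta)
        cov = np.linalg.inv(info)
        cov = 0.5 * (cov + cov.T)
    else:
        cov = np.zeros((0, 0))

    times, inc, _ = _baseline_increments(beta, t, d, z, groups, ties, z_mean)
    baseline = StepFunction(times=times, values=np.cumsum(inc), start=0.0)
    return CoxModel(
        beta=beta, covariance=cov, baseline_cumhaz=baseline, loglik=ll,
        n=len(cohort), n_events=cohort.n_events, ties_method=ties,
        covariate_names=covariates, z_mean=z_mean,
        _time=cohort.time.copy(), _event=cohort.event.copy(), _z=zfull.copy(),
    )


def _require_match(model: CoxModel, cohort: SurvivalCohort):
    if not model.matches(cohort):
        raise DataError("cohort does not match the one the model was fitted on")


def schoenfeld_residuals(model: CoxModel, cohort: SurvivalCohort):
    """(residuals, scaled, event_times): one row per event, time-ordered.

    The residual for an event at t is z_i minus the risk-set weighted
    covariate mean (Efron-adjusted within tied groups when the model used
    Efron weighting), so columns sum to zero at beta-hat. Scaled residuals
    follow the n_events * cov(beta) * r + beta convention.
    """
    _require_match(model, cohort)
    order = np.argsort(cohort.time, kind="stable")
    t = cohort.time[order]
    d = cohort.event[order]
    z = model._z[order]
    groups = _grouped_event_times(t, d)
    w = np.exp(z @ model.beta)
    wz = w[:, None] * z
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wz[::-1], axis=0)[::-1]

    rows, times = [], []
    for tk, start, tied in groups:
        dcount = tied.size
        S0, S1 = s0[start], s1[start]
        if model.ties_method == "efron" and dcount > 1:
            c0 = w[tied].sum()
            c1 = wz[tied].sum(axis=0)
            for l, i in enumerate(tied):
                f = l / dcount
                zbar = (S1 - f * c1) / (S0 - f * c0)
                rows.append(z[i] - zbar)
                times.append(tk)
        else:
            zbar = S1 / S0
            for i in tied:
                rows.append(z[i] - zbar)
                times.append(tk)
    resid = np.asarray(rows)
    scaled = model.n_events * (resid @ model.covariance) + model.beta
    return resid, scaled, np.asarray(times)


def ph_test(model: CoxModel, cohort: SurvivalCohort,
            transform: str = "km") -> PHTestResult:
    """Grambsch-Therneau proportional-hazards test (cox.zph analogue).

    Per covariate: chi2 = d * (V S)_j^2 / (V_jj * sum x^2), global:
    chi2 = d * S' V S / sum x^2, where S = sum_k x_k s_k with s_k the
    unscaled Schoenfeld residuals and x the centered time transform.
    """
    if model.n_events < 3:
        raise DataError("proportional-hazards test needs at least 3 events")
    if not model.covariate_names:
        raise DataError("model has no covariates to test")
    resid, _, etimes = schoenfeld_residuals(model, cohort)
    if transform == "identity":
        g = etimes.astype(float)
    elif transform == "rank":
        g = stats.rankdata(etimes)
    elif transform == "km":
        km = kaplan_meier(cohort.time, cohort.event)
        g = 1.0 - np.asarray(km(etimes))
    else:
        raise DataError(f"unknown transform {transform!r}")
    x = g - g.mean()
    sx2 = float(np.sum(x * x))
    if sx2 <= 0:
        raise DataError("degenerate time transform (all event times equal)")
    d = model.n_events
    V = model.covariance
    S = resid.T @ x  # p-vector
    VS = V @ S
    chi2 = d * VS ** 2 / (np.diag(V) * sx2)
    df = np.ones_like(chi2)
    p_values = stats.chi2.sf(chi2, 1)
    global_chi2 = float(d * (S @ VS) / sx2)
    global_df = len(model.covariate_names)
    global_p = float(stats.chi2.sf(global_chi2, global_df))
    return PHTestResult(
        covariate_names=list(model.covariate_names), chi2=chi2, df=df,
        p_values=p_values, global_chi2=global_chi2, global_df=global_df,
        global_p=global_p, transform=transform,
    )


def martingale_residuals(model: CoxModel, cohort: SurvivalCohort) -> np.ndarray:
    """event_i - H0(t_i) exp(beta'(z_i - z_mean)), Breslow baseline.

    The Breslow jumps make the residuals sum to exactly zero at beta-hat
    whatever tie method was used for the coefficients; residuals are
    bounded above by 1.
    """
    _require_match(model, cohort)
    order = np.argsort(cohort.time, kind="stable")
    t = cohort.time[order]
    d = cohort.event[order]
    z = model._z[order]
    groups = _grouped_event_times(t, d)
    times, _, inc_breslow = _baseline_increments(
        model.beta, t, d, z, groups, model.ties_method, model.z_mean)
    h0 = StepFunction(times=times, values=np.cumsum(inc_breslow), start=0.0)
    w = (np.exp((model._z - model.z_mean) @ model.beta)
         if model.covariate_names else np.ones(model.n))
    return cohort.event - np.asarray(h0(cohort.time)) * w


def predict_survival_cox(model: CoxModel, z, times) -> np.ndarray:
    """S(t|z) = exp(-H0(t))^exp(beta'(z - z_mean)) from the Breslow baseline.

    Beyond the last event time the curve is carried forward flat, with a
    warning (extrapolation flag).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise DataError("times must be non-negative")
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != len(model.beta):
        raise DataError("covariate vector length mismatch")
    last_event = model.baseline_cumhaz.times[-1] if model.baseline_cumhaz.times.size else 0.0
    if np.any(times > last_event):
        warnings.warn("survival requested beyond the last event time; "
                      "carrying the last value forward", stacklevel=2)
    h0 = np.asarray(model.baseline_cumhaz(times))
    rel = np.exp(float((z - model.z_mean) @ model.beta)) if len(model.beta) else 1.0
    return np.exp(-h0 * rel)
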