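"""Censoring-aware predictive accuracy: IPCW Brier score and time-dependent AUC.

Right censoring makes naive prediction-error estimates biased; both metrics
here reweight subjects by the inverse of the censoring survival G(t)
estimated with the reverse Kaplan-Meier (product-limit with censorings as
the event):

* Brier(t): Graf-style mean of w_i(t) * (1{T_i > t} - S_hat(t|z_i))^2 with
  weights 1{T_i <= t, event}/G(T_i-) + 1{T_i > t}/G(t).
* AUC(t): cumulative-cases / dynamic-controls weighted concordance —
  the probability that a subject with an event by t carries a higher risk
  score than a subject still event-free at t, ties counting 1/2.

A null model (marginal Kaplan-Meier, no predictors) provides the reference
curve, and subject-level bootstrap resampling with refitting yields
pointwise mean +/- sd bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cohort import SurvivalCohort
from .errors import DataError
from .nonparametric import StepFunction, kaplan_meier, reverse_kaplan_meier

__all__ = [
    "MetricCurve", "censoring_weights", "brier_curve", "auc_curve",
    "null_model_curve", "bootstrap_curves", "default_time_grid",
]


@dataclass
class MetricCurve:
    times: np.ndarray
    values: np.ndarray
    metric: str               # auc | brier
    model_label: str
    se: np.ndarray = None     # pointwise sd across bootstrap replicates
    undefined: np.ndarray = None  # mask: metric undefined at these times

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise DataError("metric time grid must be strictly increasing")
        if self.undefined is None:
            self.undefined = np.zeros(self.times.shape, dtype=bool)
        ok = ~self.undefined
        if self.metric == "brier" and np.any(self.values[ok] < -1e-12):
            raise DataError("Brier values must be non-negative")
        if self.metric == "auc" and (np.any(self.values[ok] < -1e-12)
                                     or np.any(self.values[ok] > 1 + 1e-12)):
            raise DataError("AUC values must lie in [0, 1]")

    def mean_value(self) -> float:
        ok = ~self.undefined
        return float(np.mean(self.values[ok]))


def censoring_weights(cohort: SurvivalCohort) -> StepFunction:
    """Reverse-KM censoring survival G(t); G(0)=1, non-increasing."""
    if len(cohort) < 2:
        raise DataError("need at least 2 subjects to estimate censoring")
    return reverse_kaplan_meier(cohort.time, cohort.event)


def default_time_grid(cohort: SurvivalCohort, n_points: int = 20,
                      g_floor: float = 0.1) -> np.ndarray:
    """Event-time quantiles 0.05-0.95, truncated where G(t) > g_floor."""
    etimes = cohort.time[cohort.event == 1]
    if etimes.size == 0:
        raise DataError("no events; cannot build an evaluation grid")
    grid = np.quantile(etimes, np.linspace(0.05, 0.95, n_points))
    g = censoring_weights(cohort)
    grid = grid[np.asarray(g(grid)) > g_floor]
    return np.unique(grid)


def _as_matrix(pred, cohort, times):
    """Per-subject predictions as an (n, len(times)) matrix."""
    if callable(pred):
        pred = pred(times)
    pred = np.asarray(pred, dtype=float)
    n, m = len(cohort), len(times)
    if pred.shape == (n,):
        pred = np.repeat(pred[:, None], m, axis=1)
    if pred.shape != (n, m):
        raise DataError(f"predictions must have shape ({n}, {m}), got {pred.shape}")
    return pred


def _check_g_positive(gvals, times):
    bad = np.asarray(gvals) <= 0
    if np.any(bad):
        t_bad = np.asarray(times)[bad][0] if np.ndim(times) else times
        raise DataError(
            f"censoring survival reaches 0 at or before t={t_bad:.6g}; "
            "truncate the evaluation grid to earlier times")


def brier_curve(predicted_survival, cohort: SurvivalCohort, times,
                model_label: str = "model") -> MetricCurve:
    """IPCW Brier score curve.

    ``predicted_survival`` is an (n, len(times)) matrix of S_hat(t|z_i), a
    length-n vector (constant over time), or a callable times -> matrix.
    """
    times = np.asarray(times, dtype=float)
    surv = _as_matrix(predicted_survival, cohort, times)
    G = censoring_weights(cohort)
    g_at_grid = np.asarray(G(times))
    g_at_T = np.asarray(G.left_limit(cohort.time))
    T = cohort.time[:, None]
    d = cohort.event[:, None]
    tgrid = times[None, :]

    case = (T <= tgrid) & (d == 1)         # event by t
    control = T > tgrid                     # still event-free past t
    _check_g_positive(g_at_grid, times)    # grid must stay inside G's support
    if np.any(case & (g_at_T[:, None] <= 0)):
        raise DataError("censoring survival is 0 at an event time; "
                        "truncate the evaluation grid")
    w = np.zeros_like(surv)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(case, 1.0 / g_at_T[:, None], w)
        w = np.where(control, 1.0 / g_at_grid[None, :], w)
    sq = np.where(case, surv ** 2, np.where(control, (1.0 - surv) ** 2, 0.0))
    values = np.mean(w * sq, axis=0)
    return MetricCurve(times=times, values=values, metric="brier",
                       model_label=model_label)


def auc_curve(risk_scores, cohort: SurvivalCohort, times,
              model_label: str = "model") -> MetricCurve:
    """IPCW cumulative/dynamic time-dependent AUC curve.

    ``risk_scores``: length-n vector (time-fixed risk) or (n, len(times))
    matrix. Grid times with no cases or no controls are flagged undefined
    (NaN), never silently dropped.
    """
    times = np.asarray(times, dtype=float)
    n, m = len(cohort), len(times)
    risk = np.asarray(risk_scores, dtype=float)
    if risk.shape == (n,):
        risk = np.repeat(risk[:, None], m, axis=1)
    if risk.shape != (n, m):
        raise DataError(f"risk scores must have shape ({n}, {m})")
    G = censoring_weights(cohort)
    g_at_grid = np.asarray(G(times))
    g_at_T = np.asarray(G.left_limit(cohort.time))

    values = np.full(m, np.nan)
    undefined = np.zeros(m, dtype=bool)
    for k, t in enumerate(times):
        cases = np.where((cohort.time <= t) & (cohort.event == 1))[0]
        controls = np.where(cohort.time > t)[0]
        if cases.size == 0 or controls.size == 0:
            undefined[k] = True
            continue
        _check_g_positive(g_at_T[cases], cohort.time[cases])
        _check_g_positive([g_at_grid[k]], [t])
        wc = 1.0 / g_at_T[cases]
        wn = np.full(controls.size, 1.0 / g_at_grid[k])
        ri = risk[cases, k][:, None]
        rj = risk[controls, k][None, :]
        conc = (ri > rj) + 0.5 * (ri == rj)
        wmat = wc[:, None] * wn[None, :]
        values[k] = float(np.sum(wmat * conc) / np.sum(wmat))
    return MetricCurve(times=times, values=values, metric="auc",
                       model_label=model_label, undefined=undefined)


def null_model_curve(cohort: SurvivalCohort, times,
                     metric: str = "brier") -> MetricCurve:
    """Reference curve from the covariate-free marginal KM predictions.

    For the AUC the constant score carries no ranking information, so the
    curve is returned fully flagged as undefined.
    """
    times = np.asarray(times, dtype=float)
    if metric == "brier":
        km = kaplan_meier(cohort.time, cohort.event)
        surv = np.repeat(np.asarray(km(times))[None, :], len(cohort), axis=0)
        curve = brier_curve(surv, cohort, times, model_label="null")
        return curve
    if metric == "auc":
        return MetricCurve(times=times, values=np.full(len(times), np.nan),
                           metric="auc", model_label="null",
                           undefined=np.ones(len(times), dtype=bool))
    raise DataError(f"unknown metric {metric!r}")


def bootstrap_curves(model_refitter: Callable, cohort: SurvivalCohort,
                     times, B: int, seed: int, metric: str = "brier",
                     model_label: str = "model") -> MetricCurve:
    """Subject-level bootstrap with refitting; bands = pointwise mean +/- sd.

    ``model_refitter(resampled_cohort)`` must return the per-subject
    prediction input for the metric on that resample: predicted survival
    (matrix/vector/callable) for the Brier score, risk scores for the AUC.
    Replicates with zero events are redrawn (capped at 10*B attempts).
    """
    if B < 1:
        raise DataError("B must be at least 1")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    reps = []
    attempts = 0
    redraws = 0
    while len(reps) < B:
        attempts += 1
        if attempts > 10 * B:
            raise DataError(f"too many zero-event bootstrap resamples "
                            f"({redraws} redraws)")
        idx = rng.integers(0, n, size=n)
        boot = cohort.subset(idx)
        if boot.n_events == 0:
            redraws += 1
            continue
        pred = model_refitter(boot)
        if metric == "brier":
            curve = brier_curve(pred, boot, times)
        elif metric == "auc":
            curve = auc_curve(pred, boot, times)
        else:
            raise DataError(f"unknown metric {metric!r}")
        reps.append(curve.values)
    stack = np.vstack(reps)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=0) if B > 1 else np.zeros(len(times))
    undefined = np.all(np.isnan(stack), axis=0)
    return MetricCurve(times=times, values=mean, se=sd, metric=metric,
                       model_label=model_label, undefined=undefined)
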