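"""Product-limit estimators: Kaplan-Meier, Nelson-Aalen, reverse-KM.

Small self-contained routines used by the diagnostics and the IPCW metrics.
All return right-continuous step functions represented as (times, values)
arrays plus an evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError


@dataclass
class StepFunction:
    """Right-continuous step function with value ``start`` before the first jump."""

    times: np.ndarray
    values: np.ndarray
    start: float = 1.0

    def _eval(self, t, side):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, float(self.start))
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side=side) - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.start)
        return out if out.ndim else float(out)

    def __call__(self, t) -> np.ndarray:
        return self._eval(t, "right")

    def left_limit(self, t) -> np.ndarray:
        """Value just before t, i.e. G(t-)."""
        return self._eval(t, "left")


def _risk_table(time, indicator):
    """Unique times with number at risk and number of flagged occurrences."""
    time = np.asarray(time, dtype=float)
    indicator = np.asarray(indicator)
    if time.size == 0:
        raise DataError("empty sample")
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = indicator[order]
    uniq, start = np.unique(t, return_index=True)
    n = time.size
    n_risk = n - start  # T >= t for sorted times
    counts = np.add.reduceat(d.astype(float), start)
    return uniq, n_risk.astype(float), counts


def kaplan_meier(time, event) -> StepFunction:
    """Kaplan-Meier estimate of the event-time survival function S(t)."""
    uniq, n_risk, d = _risk_table(time, event)
    keep = d > 0
    factors = 1.0 - d[keep] / n_risk[keep]
    surv = np.cumprod(factors)
    return StepFunction(times=uniq[keep], values=surv, start=1.0)


def nelson_aalen(time, event) -> StepFunction:
    """Nelson-Aalen estimate of the cumulative hazard H(t) = sum d_i / n_i."""
    uniq, n_risk, d = _risk_table(time, event)
    keep = d > 0
    cumhaz = np.cumsum(d[keep] / n_risk[keep])
    return StepFunction(times=uniq[keep], values=cumhaz, start=0.0)


def reverse_kaplan_meier(time, event) -> StepFunction:
    """Censoring survival G(t): product-limit with censorings as the event.

    At tied times the death is taken to precede the censoring, so subjects
    dying at t remain in the at-risk count for the censoring process at t.
    """
    censored = 1 - np.asarray(event)
    uniq, n_risk, c = _risk_table(time, censored)
    keep = c > 0
    factors = 1.0 - c[keep] / n_risk[keep]
    surv = np.cumprod(factors)
    return StepFunction(times=uniq[keep], values=surv, start=1.0)
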