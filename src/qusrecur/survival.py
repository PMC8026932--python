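"""Kaplan-Meier recurrence-free survival and log-rank comparison.

Time is measured in months from diagnosis; an event is an observed
recurrence, everything else is censored.  Curves are product-limit step
functions (censored subjects remain at risk at their own time; event/censor
ties at the same time count events first), with Greenwood 95 % confidence
intervals.  lifelines provides the estimator and the one-degree-of-freedom
log-rank statistic behind this module's surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalCurve",
    "kaplan_meier",
    "logrank_test",
    "rfs_by_predicted_group",
    "MILESTONES_MONTHS",
]

MILESTONES_MONTHS = (24.0, 36.0, 60.0)


@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray              # distinct observed times
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray           # S(t) at each time (step function)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    max_time: float

    def survival_at(self, t: float) -> tuple[float, bool]:
        """S(t); the flag marks extrapolation beyond the last observation."""
        beyond = t > self.max_time
        if beyond:
            warnings.warn(
                f"milestone {t} beyond last observed time "
                f"{self.max_time}; carrying last value", stacklevel=2)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return (1.0 if idx < 0 else float(self.survival[idx])), bool(beyond)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.group, "time": self.times,
            "at_risk": self.at_risk, "events": self.events,
            "survival": self.survival,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
        })


def kaplan_meier(times, events, group: str = "all") -> SurvivalCurve:
    """Kaplan-Meier product-limit curve: S(t) = prod(1 - d_i / n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) < 1:
        raise ValueError("need at least one sample")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e, label=group)
    tab = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index \
        else kmf.event_table
    grid = tab.index.to_numpy(dtype=float)
    sf = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    ci = kmf.confidence_interval_
    # align CI rows with the event-table grid
    lo = np.interp(grid, ci.index.to_numpy(dtype=float),
                   ci.iloc[:, 0].to_numpy(dtype=float))
    hi = np.interp(grid, ci.index.to_numpy(dtype=float),
                   ci.iloc[:, 1].to_numpy(dtype=float))
    return SurvivalCurve(
        group=group, times=grid,
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        events=tab["observed"].to_numpy(dtype=int),
        survival=sf, ci_lower=lo, ci_upper=hi,
        max_time=float(t.max()),
    )


def logrank_test(times_a, events_a, times_b, events_b
                 ) -> tuple[float, float]:
    """One-degree-of-freedom log-rank: (chi-square statistic, p-value)."""
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(np.asarray(times_a, dtype=float),
                      np.asarray(times_b, dtype=float),
                      event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def rfs_by_predicted_group(predicted_labels, times, events,
                           milestones=MILESTONES_MONTHS) -> dict:
    """KM curves per predicted group, log-rank p and milestone survival.

    ``predicted_labels`` are "recurrence"/"no_recurrence" strings aligned
    with the survival records (e.g. ensemble labels from LOO folds).
    """
    pred = np.asarray(predicted_labels)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (len(pred) == len(t) == len(e)):
        raise ValueError("predictions and survival records must align")
    out: dict = {"curves": {}, "milestones": {}}
    masks = {}
    for g in ("no_recurrence", "recurrence"):
        masks[g] = pred == g
        if masks[g].sum() == 0:
            out["curves"][g] = None
            out["milestones"][g] = {m: (np.nan, True) for m in milestones}
            continue
        curve = kaplan_meier(t[masks[g]], e[masks[g]], group=f"predicted_{g}")
        out["curves"][g] = curve
        out["milestones"][g] = {m: curve.survival_at(m) for m in milestones}
    if masks["recurrence"].any() and masks["no_recurrence"].any():
        stat, p = logrank_test(t[masks["recurrence"]], e[masks["recurrence"]],
                               t[masks["no_recurrence"]],
                               e[masks["no_recurrence"]])
    else:
        stat, p = np.nan, np.nan
    out["logrank_statistic"] = stat
    out["logrank_p"] = p
    return out
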