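"""Progression-free survival: Kaplan-Meier curves and the log-rank test.

Times are in months. The median is the first event time at which the
product-limit estimate drops to 0.5 or below; when the curve never
reaches 0.5 the median is "not reached" (returned as ``math.inf``).
Event/censor ties at the same time follow the standard KM convention
(events first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["SurvivalCurve", "km_curve", "km_median", "logrank_test"]

NOT_REACHED = math.inf


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) after each distinct event time."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each time
    at_risk: np.ndarray        # risk-set size at each time
    events: np.ndarray         # events at each time

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        ).to_csv(path, sep="\t", index=False)


def km_curve(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier estimator; censored times shrink the risk set only."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    if t.size == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tab = kmf.event_table
    mask = tab["observed"] > 0
    ev_times = tab.index[mask].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ev_times).to_numpy(dtype=float)
    return SurvivalCurve(
        times=ev_times,
        survival=surv,
        at_risk=tab.loc[mask, "at_risk"].to_numpy(dtype=int),
        events=tab.loc[mask, "observed"].to_numpy(dtype=int),
    )


def km_median(curve: SurvivalCurve) -> float:
    """First event time with S(t) <= 0.5, or ``math.inf`` (not reached)."""
    below = curve.survival <= 0.5
    if not below.any():
        return NOT_REACHED
    return float(curve.times[np.argmax(below)])


def logrank_test(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) test: (chi-square with 1 df, p)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {len(labels)}")
    m0, m1 = g == labels[0], g == labels[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    return float(res.test_statistic), float(res.p_value)
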