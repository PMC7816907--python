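"""Censored time-to-event outcomes from quarterly registration data.

Registration at a primary-care practice is observed per calendar
quarter.  Loss to follow-up is the first day of the earliest run of four
or more consecutive absent quarters, or of a trailing absent run that
reaches the end of the observation window.  Follow-up is censored at AF
diagnosis, loss to follow-up, or the administrative end of the 5-year
window — whichever comes first.

The Kaplan-Meier estimator here is implemented directly (product-limit
with Greenwood variance) rather than delegated, so that the risk-set
tie convention (events before censorings at equal times) and the
variance used in calibration confidence intervals are explicit and
testable against brute-force enumeration; `lifelines` serves as an
independent cross-check in the test-suite.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DAYS_PER_YEAR",
    "FollowupOutcome",
    "SurvivalCurve",
    "loss_to_followup_date",
    "resolve_outcome",
    "kaplan_meier",
    "incidence_rate",
]

#: Fixed conversion between day intervals and years.
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class FollowupOutcome:
    """Resolved follow-up for one patient."""

    time_years: float
    event: bool
    censor_reason: str  # "af_event" | "lost_to_followup" | "admin_end"
    loss_date: Optional[dt.date] = None


def _quarter_start(grid_start: dt.date, index: int) -> dt.date:
    month0 = (grid_start.year * 12 + (grid_start.month - 1)) + 3 * index
    return dt.date(month0 // 12, month0 % 12 + 1, 1)


def loss_to_followup_date(
    registration_quarters: Sequence[bool],
    grid_start: dt.date,
    min_run: int = 4,
) -> Optional[dt.date]:
    """First day of the earliest absent-quarter run that signals dropout.

    A run counts if it spans at least ``min_run`` consecutive absent
    quarters, or if it is a trailing run reaching the final quarter of
    the grid (any length).  Returns ``None`` when registration never
    lapses in a qualifying way.
    """
    flags = list(registration_quarters)
    if not flags:
        raise ValueError("registration grid is empty")
    n = len(flags)
    i = 0
    while i < n:
        if not flags[i]:
            j = i
            while j < n and not flags[j]:
                j += 1
            run_len = j - i
            if run_len >= min_run or j == n:
                return _quarter_start(grid_start, i)
            i = j
        else:
            i += 1
    return None


def resolve_outcome(
    af_date: Optional[dt.date],
    loss_date: Optional[dt.date],
    baseline: dt.date,
    horizon_end: dt.date,
) -> FollowupOutcome:
    """Combine AF date, loss date and the administrative window end.

    The earliest of the three determines the outcome: an AF diagnosis
    strictly before both loss and window end is an event; otherwise the
    patient is censored at loss or at the window end.  An AF diagnosis
    on or after the loss date falls inside the unregistered period and
    is unobservable through the registry, so it does not count; a
    diagnosis on the window-end date is outside the half-open window
    [baseline, end).  Time in years uses 365.25 days per year.
    """
    if af_date is not None and af_date < baseline:
        raise ValueError("AF before baseline: prevalent case should be excluded")
    candidates = [(horizon_end, "admin_end")]
    if loss_date is not None:
        if loss_date < baseline:
            raise ValueError("loss to follow-up before baseline")
        candidates.append((loss_date, "lost_to_followup"))
    if af_date is not None:
        candidates.append((af_date, "af_event"))
    # on date ties the censoring mechanisms win: AF must be strictly
    # earliest to count as an observed event
    priority = {"admin_end": 0, "lost_to_followup": 1, "af_event": 2}
    end_date, reason = min(candidates, key=lambda c: (c[0], priority[c[1]]))
    time_years = (end_date - baseline).days / DAYS_PER_YEAR
    return FollowupOutcome(
        time_years=time_years,
        event=reason == "af_event",
        censor_reason=reason,
        loss_date=loss_date,
    )


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with Greenwood variance.

    Arrays are aligned on the distinct event times (censoring-only times
    do not create steps).  ``variance`` is Greenwood's estimate of
    Var(S(t)); the failure function is 1 - S(t).
    """

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n_subjects: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def failure_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.variance[idx])

    def failure_ci_at(self, t: float, z: float = 1.959963984540054):
        """Greenwood-based normal CI for the failure probability at t."""
        f = self.failure_at(t)
        se = float(np.sqrt(self.variance_at(t)))
        return max(0.0, f - z * se), min(1.0, f + z * se)


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance.

    Ties between events and censorings at the same time follow the
    standard convention: events are counted against the risk set that
    still includes the tied censored subjects.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n = times.size

    event_times, d = np.unique(t_sorted[e_sorted], return_counts=True)
    d = d.astype(float)
    if event_times.size == 0:
        return SurvivalCurve(
            times=np.array([]),
            at_risk=np.array([]),
            n_events=np.array([]),
            survival=np.array([]),
            variance=np.array([]),
            n_subjects=n,
        )
    # at risk just before each event time: subjects with time >= t
    at_risk = n - np.searchsorted(t_sorted, event_times, side="left")
    frac = 1.0 - d / at_risk
    survival = np.cumprod(frac)
    # Greenwood: Var(S) = S^2 * sum d / (r (r - d))
    greenwood = np.cumsum(d / (at_risk * (at_risk - d + (d == at_risk))))
    greenwood = np.where(d == at_risk, np.nan, greenwood)
    # once S hits 0, variance is 0 by convention
    variance = np.where(survival > 0, survival**2 * np.nan_to_num(greenwood), 0.0)
    return SurvivalCurve(
        times=event_times,
        at_risk=at_risk.astype(int),
        n_events=d.astype(int),
        survival=survival,
        variance=variance,
        n_subjects=n,
    )


@dataclass(frozen=True)
class IncidenceResult:
    n_events: int
    person_years: float
    rate_per_1000py: float
    cumulative_incidence: float  # KM failure at the horizon


def incidence_rate(times, events, horizon: float = 5.0) -> IncidenceResult:
    """Crude incidence per 1000 person-years plus KM cumulative incidence."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    total_time = float(times.sum())
    if total_time <= 0:
        raise ValueError("total person-time is zero")
    n_events = int(events.sum())
    km = kaplan_meier(times, events)
    return IncidenceResult(
        n_events=n_events,
        person_years=total_time,
        rate_per_1000py=1000.0 * n_events / total_time,
        cumulative_incidence=km.failure_at(horizon),
    )
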