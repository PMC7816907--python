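"""Screening-triage evaluation of risk cut-offs.

Dichotomising predicted baseline risk at a cut-off splits the cohort
into the patients a screening programme would invite (high risk) and
the rest.  Per cut-off this module reports the screening yield metrics:
how many patients are flagged, what share of all observed 5-year AF
cases they capture (the triage sensitivity), the AF incidence within
the flagged group, the overlap with an anticoagulation-relevant
CHA2DS2-VASc >= 2, and the unadjusted hazard ratio of flagged vs
unflagged patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .followup import kaplan_meier
from .validation import ConvergenceError, cox_fit_single

__all__ = ["TriageRow", "triage_table", "sensitivity_curve", "DEFAULT_CUTOFFS"]

DEFAULT_CUTOFFS: tuple[float, ...] = (0.025, 0.05, 0.10)


@dataclass(frozen=True)
class TriageRow:
    cutoff: float
    n_high: int
    pct_high: float
    af_cases_high: int
    sensitivity: float
    cumulative_incidence_high: float
    rate_high_per_1000py: float
    pct_high_with_vasc_ge2: float
    pct_high_af_cases_with_vasc_ge2: float
    hr_high_vs_low: float
    hr_ci_low: float
    hr_ci_high: float
    p_vasc_diff: float


def _required(df: pd.DataFrame, cols: Sequence[str]):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"cohort frame lacks columns: {missing}")


def triage_table(
    cohort: pd.DataFrame,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    horizon: float = 5.0,
    risk_col: str = "charge_af_risk5y",
) -> pd.DataFrame:
    """Screening-yield metrics per risk cut-off.

    "High risk" means predicted risk >= cutoff (a patient exactly at the
    cut-off is screened).  AF case counts are crude observed events
    within follow-up (a screening-yield reading); the Kaplan-Meier
    cumulative incidence at the horizon is reported alongside as the
    censoring-aware estimate.  The hazard ratio compares high vs low
    risk in an unadjusted proportional-hazards fit, and ``p_vasc_diff``
    is the chi-squared p-value for the difference in CHA2DS2-VASc >= 2
    prevalence between high-risk and low-risk AF cases.
    """
    _required(cohort, [risk_col, "cha2ds2vasc_ge2", "time_years", "event"])
    risks = cohort[risk_col].to_numpy(dtype=float)
    times = cohort["time_years"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=bool)
    vasc = cohort["cha2ds2vasc_ge2"].to_numpy(dtype=bool)
    n = len(cohort)
    total_cases = int(events.sum())
    rows = []
    for cutoff in cutoffs:
        if not 0.0 <= cutoff < 1.0:
            raise ValueError(f"cutoff {cutoff} outside [0, 1)")
        high = risks >= cutoff
        n_high = int(high.sum())
        cases_high = int(events[high].sum())
        sensitivity = cases_high / total_cases if total_cases else np.nan

        if n_high:
            km = kaplan_meier(times[high], events[high])
            cuminc = km.failure_at(horizon)
            rate = 1000.0 * cases_high / times[high].sum()
            pct_vasc_high = float(vasc[high].mean())
        else:
            cuminc = rate = pct_vasc_high = np.nan

        af_high_vasc = vasc[high & events]
        pct_af_vasc = float(af_high_vasc.mean()) if af_high_vasc.size else np.nan

        hr = hr_lo = hr_hi = np.nan
        if 0 < n_high < n:
            try:
                fit = cox_fit_single(high.astype(float), times, events)
                hr, hr_lo, hr_hi = fit.hazard_ratio, fit.ci_low, fit.ci_high
            except (ConvergenceError, ValueError) as exc:
                warnings.warn(f"HR undefined at cutoff {cutoff}: {exc}")
        else:
            warnings.warn(f"degenerate split at cutoff {cutoff}: HR undefined")

        # chi2 for CHA2DS2-VASc>=2 proportions among high- vs low-risk AF cases
        af_low_vasc = vasc[~high & events]
        p_diff = np.nan
        if af_high_vasc.size and af_low_vasc.size:
            contingency = np.array(
                [
                    [af_high_vasc.sum(), af_high_vasc.size - af_high_vasc.sum()],
                    [af_low_vasc.sum(), af_low_vasc.size - af_low_vasc.sum()],
                ]
            )
            if contingency.sum(axis=0).all():
                _, p_diff, _, _ = stats.chi2_contingency(
                    contingency, correction=False
                )

        rows.append(
            TriageRow(
                cutoff=float(cutoff),
                n_high=n_high,
                pct_high=n_high / n,
                af_cases_high=cases_high,
                sensitivity=sensitivity,
                cumulative_incidence_high=cuminc,
                rate_high_per_1000py=rate,
                pct_high_with_vasc_ge2=pct_vasc_high,
                pct_high_af_cases_with_vasc_ge2=pct_af_vasc,
                hr_high_vs_low=hr,
                hr_ci_low=hr_lo,
                hr_ci_high=hr_hi,
                p_vasc_diff=float(p_diff) if p_diff == p_diff else np.nan,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def sensitivity_curve(
    cohort: pd.DataFrame,
    cutoff_grid: Sequence[float],
    risk_col: str = "charge_af_risk5y",
) -> pd.DataFrame:
    """Triage sensitivity and flagged fraction over a cut-off grid.

    Sensitivity at cut-off c is the share of all observed AF cases whose
    predicted risk is >= c; both columns are non-increasing in c.
    """
    _required(cohort, [risk_col, "event"])
    risks = cohort[risk_col].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=bool)
    total = events.sum()
    rows = []
    for c in sorted(cutoff_grid):
        high = risks >= c
        rows.append(
            {
                "cutoff": float(c),
                "pct_high": float(high.mean()),
                "sensitivity": float(events[high].sum() / total) if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
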