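"""Build an analysis cohort from raw primary-care EHR-like records.

A raw record is what a primary-care registration database holds for one
patient: diagnosis episodes (with a coding-system code and a start date),
dated measurements, dated prescriptions, and a quarterly registration
grid.  This module turns such records into one row of baseline
covariates per patient (the entry closest to baseline within a one-year
window), applies the eligibility chain (age >= 40, AF-free at baseline,
registered all four baseline-year quarters), splits complete from
incomplete cases on the four body measurements, and compares groups.

Diagnosis and prescription code sets are configuration, not constants:
the shipped :data:`DEFAULT_CODE_MAP` uses standard ICPC-1 chapter codes
and ATC prefixes as sensible defaults, but any real-data user must
supply the operational code lists of their own database.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .risk import MEASUREMENT_COLUMNS

__all__ = [
    "Episode",
    "Measurement",
    "Prescription",
    "RawPatientRecord",
    "CodeMap",
    "DEFAULT_CODE_MAP",
    "BaselineCovariates",
    "CohortFlow",
    "extract_baseline",
    "apply_eligibility",
    "split_complete_cases",
    "compare_groups",
]

MEASUREMENT_KINDS = (
    "height_cm",
    "weight_kg",
    "sbp_mmHg",
    "dbp_mmHg",
    "smoking_status",
)

SMOKING_LEVELS = ("current", "former", "never")

#: Morbidity flags derived from episode codes.
CONDITION_FLAGS = (
    "diabetes",
    "heart_failure",
    "myocardial_infarction",
    "hypertension",
    "stroke",
    "tia",
    "atherosclerosis",
    "angina",
)


@dataclass(frozen=True)
class Episode:
    code: str
    start_date: dt.date
    end_date: Optional[dt.date] = None


@dataclass(frozen=True)
class Measurement:
    kind: str
    value: object  # number, or smoking level string
    date: dt.date


@dataclass(frozen=True)
class Prescription:
    atc_code: str
    date: dt.date


@dataclass
class RawPatientRecord:
    """EHR-like record for one patient over the observation window."""

    patient_id: str
    practice_id: str
    birth_date: dt.date
    sex: str  # "male" | "female"
    episodes: list[Episode] = field(default_factory=list)
    measurements: list[Measurement] = field(default_factory=list)
    prescriptions: list[Prescription] = field(default_factory=list)
    #: one flag per calendar quarter of the observation window, starting
    #: at ``registration_start`` (a quarter boundary)
    registration_quarters: list[bool] = field(default_factory=list)
    registration_start: dt.date = dt.date(2013, 1, 1)


class CodeMap(dict):
    """Mapping: condition/medication-class name -> set of code prefixes.

    Episode codes match a condition when they start with any listed
    prefix; prescription ATC codes likewise.  Every condition used by
    the scores must have a (non-empty) entry.
    """

    REQUIRED = CONDITION_FLAGS + ("atrial_fibrillation", "antihypertensive")

    def validate(self) -> None:
        missing = [k for k in self.REQUIRED if not self.get(k)]
        if missing:
            raise ValueError(f"CodeMap lacks non-empty entries for: {missing}")

    def matches(self, name: str, code: str) -> bool:
        return any(code.startswith(prefix) for prefix in self[name])

    @classmethod
    def from_yaml(cls, path) -> "CodeMap":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        cmap = cls({k: set(v) for k, v in payload.items()})
        cmap.validate()
        return cmap


#: Default mapping using ICPC-1 rubric codes (diagnoses) and ATC
#: prefixes (medication).  These are plausible defaults for a Dutch
#: primary-care registry; the operational lists of any real database
#: must be supplied by its users.
DEFAULT_CODE_MAP = CodeMap(
    {
        "atrial_fibrillation": {"K78"},
        "diabetes": {"T90"},
        "heart_failure": {"K77"},
        "myocardial_infarction": {"K75", "K76.02"},
        "hypertension": {"K86", "K87"},
        "stroke": {"K90"},
        "tia": {"K89"},
        "atherosclerosis": {"K91", "K92.01"},
        "angina": {"K74"},
        "antihypertensive": {"C02", "C03", "C07", "C08", "C09"},
    }
)


@dataclass
class BaselineCovariates:
    """The CHARGE-AF inputs plus CHA2DS2-VASc components at baseline.

    Body measurements are ``None`` when no entry fell inside the
    baseline window; such patients are incomplete cases.
    """

    patient_id: str
    age_years: float
    sex: str
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    sbp_mmHg: Optional[float] = None
    dbp_mmHg: Optional[float] = None
    current_smoking: bool = False
    antihypertensive_use: bool = False
    diabetes: bool = False
    heart_failure: bool = False
    myocardial_infarction: bool = False
    hypertension: bool = False
    stroke: bool = False
    tia: bool = False
    atherosclerosis: bool = False
    angina: bool = False
    ethnicity_white: bool = True

    @property
    def complete(self) -> bool:
        return all(
            getattr(self, m) is not None for m in MEASUREMENT_COLUMNS
        )


@dataclass
class CohortFlow:
    """Patient counts along the eligibility / completeness chain."""

    n_input: int = 0
    n_age_40_plus: int = 0
    n_registered_full_baseline_year: int = 0
    n_af_free: int = 0
    n_complete: int = 0
    n_incomplete: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _age_completed_years(birth_date: dt.date, at: dt.date) -> int:
    years = at.year - birth_date.year
    if (at.month, at.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def _closest_entry(entries: list[Measurement], baseline: dt.date, window_start: dt.date):
    """Entry in [window_start, baseline) nearest the baseline date.

    Tie between two entries on the same (closest) date: the
    lexicographically smaller value wins, so selection is deterministic
    and independent of input order.
    """
    in_window = [e for e in entries if window_start <= e.date < baseline]
    if not in_window:
        return None
    best_date = max(e.date for e in in_window)
    candidates = sorted(
        (e for e in in_window if e.date == best_date), key=lambda e: str(e.value)
    )
    return candidates[0]


def extract_baseline(
    record: RawPatientRecord,
    baseline_date: dt.date = dt.date(2014, 1, 1),
    window_days: int = 365,
    code_map: CodeMap = DEFAULT_CODE_MAP,
) -> BaselineCovariates:
    """Derive one patient's baseline covariates from a raw record.

    Measurements: for each kind, the entry dated within
    ``[baseline - window_days, baseline)`` closest to baseline is used;
    kinds with no entry in the window stay missing.  Morbidity flags are
    true iff any mapped episode starts strictly before the baseline
    date (any lookback).  Antihypertensive use requires a mapped
    prescription within the baseline window.  Smoking is current iff the
    closest smoking-status entry in the window reads "current".
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    window_start = baseline_date - dt.timedelta(days=window_days)
    by_kind: dict[str, list[Measurement]] = {k: [] for k in MEASUREMENT_KINDS}
    for m in record.measurements:
        if m.kind in by_kind:
            by_kind[m.kind].append(m)

    values: dict[str, Optional[float]] = {}
    for kind in MEASUREMENT_COLUMNS:
        entry = _closest_entry(by_kind[kind], baseline_date, window_start)
        values[kind] = float(entry.value) if entry is not None else None

    smoking_entry = _closest_entry(by_kind["smoking_status"], baseline_date, window_start)
    current_smoking = smoking_entry is not None and smoking_entry.value == "current"

    flags = {
        cond: any(
            code_map.matches(cond, ep.code) and ep.start_date < baseline_date
            for ep in record.episodes
        )
        for cond in CONDITION_FLAGS
    }
    antihypertensive = any(
        code_map.matches("antihypertensive", p.atc_code)
        and window_start <= p.date < baseline_date
        for p in record.prescriptions
    )

    return BaselineCovariates(
        patient_id=record.patient_id,
        age_years=_age_completed_years(record.birth_date, baseline_date),
        sex=record.sex,
        current_smoking=current_smoking,
        antihypertensive_use=antihypertensive,
        **values,
        **flags,
    )


def _baseline_year_quarters_registered(
    record: RawPatientRecord, baseline_date: dt.date
) -> bool:
    """All four quarters of the calendar year before baseline present."""
    year = baseline_date.year - 1
    start = record.registration_start
    for q in range(4):
        qdate = dt.date(year, 1 + 3 * q, 1)
        idx = (qdate.year - start.year) * 4 + (qdate.month - start.month) // 3
        if idx < 0 or idx >= len(record.registration_quarters):
            raise ValueError(
                f"registration grid of {record.patient_id} does not cover the "
                f"baseline year {year}"
            )
        if not record.registration_quarters[idx]:
            return False
    return True


def apply_eligibility(
    records: Iterable[RawPatientRecord],
    baseline_date: dt.date = dt.date(2014, 1, 1),
    code_map: CodeMap = DEFAULT_CODE_MAP,
) -> tuple[list[RawPatientRecord], CohortFlow]:
    """Filter to patients aged >= 40, registered throughout the baseline
    year, and AF-free at baseline; record counts at each step."""
    records = list(records)
    flow = CohortFlow(n_input=len(records))

    aged = [
        r
        for r in records
        if _age_completed_years(r.birth_date, baseline_date) >= 40
    ]
    flow.n_age_40_plus = len(aged)

    registered = [
        r for r in aged if _baseline_year_quarters_registered(r, baseline_date)
    ]
    flow.n_registered_full_baseline_year = len(registered)

    af_free = [
        r
        for r in registered
        if not any(
            code_map.matches("atrial_fibrillation", ep.code)
            and ep.start_date < baseline_date
            for ep in r.episodes
        )
    ]
    flow.n_af_free = len(af_free)
    return af_free, flow


def cohort_frame(covariates: Iterable[BaselineCovariates]) -> pd.DataFrame:
    """Stack per-patient baseline covariates into a flat cohort table."""
    rows = []
    for cov in covariates:
        row = dict(cov.__dict__)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for m in MEASUREMENT_COLUMNS:
        df[m] = pd.to_numeric(df[m], errors="coerce")
    return df


def split_complete_cases(
    cohort: pd.DataFrame, flow: Optional[CohortFlow] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cohort on availability of all four body measurements.

    Complete cases have height, weight, SBP and DBP all recorded in the
    baseline window; the partition is exhaustive and disjoint.
    """
    present = cohort[list(MEASUREMENT_COLUMNS)].notna().all(axis=1)
    complete = cohort[present]
    incomplete = cohort[~present]
    if flow is not None:
        flow.n_complete = len(complete)
        flow.n_incomplete = len(incomplete)
    return complete, incomplete


_BINARY_HINT = ("use", "smoking", "diabetes", "failure", "infarction")


def compare_groups(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    variables: Sequence[str],
    kinds: Optional[Mapping[str, str]] = None,
    labels: tuple[str, str] = ("complete", "incomplete"),
) -> pd.DataFrame:
    """Compare baseline variables between two patient groups.

    Per variable: group summaries and a p-value from Welch's unequal
    variance t-test (continuous), the Wilcoxon rank-sum test (ordinal)
    or the chi-squared test without continuity correction (binary).
    ``kinds`` maps variable -> {"continuous", "ordinal", "binary"};
    unlisted variables are classed by dtype (bool -> binary, else
    continuous).
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be non-empty")
    kinds = dict(kinds or {})
    rows = []
    for var in variables:
        a = group_a[var].dropna()
        b = group_b[var].dropna()
        kind = kinds.get(
            var, "binary" if a.dtype == bool or set(a.unique()) <= {0, 1} else "continuous"
        )
        if kind == "binary":
            table = np.array(
                [
                    [int(a.sum()), int(len(a) - a.sum())],
                    [int(b.sum()), int(len(b) - b.sum())],
                ]
            )
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            summary_a, summary_b = a.mean(), b.mean()
            stat = chi2
        elif kind == "ordinal":
            stat, p = stats.ranksums(a, b)
            summary_a, summary_b = float(a.median()), float(b.median())
        else:
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                warnings.warn(f"{var}: zero variance in both groups, test skipped")
                stat, p = np.nan, np.nan
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=False)
            summary_a, summary_b = float(a.mean()), float(b.mean())
        rows.append(
            {
                "variable": var,
                "kind": kind,
                f"{labels[0]}_summary": summary_a,
                f"{labels[1]}_summary": summary_b,
                "statistic": float(stat),
                "p_value": float(p) if p == p else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
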