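"""CSV input/output with schema validation.

Two input routes are supported.  The *flat* route is one CSV with one
row per patient, columns named exactly as the baseline covariate fields
plus (optionally) follow-up columns.  The *raw* route is four delimited
files — episodes, measurements, prescriptions and a registration file —
keyed by patient id, from which the cohort module derives the flat
table.  All outputs are plain CSV for auditability.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import (
    Episode,
    Measurement,
    Prescription,
    RawPatientRecord,
)

__all__ = [
    "COHORT_COLUMNS",
    "FOLLOWUP_COLUMNS",
    "read_cohort",
    "write_cohort",
    "write_raw_records",
    "read_raw_records",
]

COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age_years",
    "sex",
    "height_cm",
    "weight_kg",
    "sbp_mmHg",
    "dbp_mmHg",
    "current_smoking",
    "antihypertensive_use",
    "diabetes",
    "heart_failure",
    "myocardial_infarction",
    "hypertension",
    "stroke",
    "tia",
    "atherosclerosis",
    "angina",
    "ethnicity_white",
)

FOLLOWUP_COLUMNS: tuple[str, ...] = ("time_years", "event", "censor_reason")

_BOOL_COLUMNS = (
    "current_smoking",
    "antihypertensive_use",
    "diabetes",
    "heart_failure",
    "myocardial_infarction",
    "hypertension",
    "stroke",
    "tia",
    "atherosclerosis",
    "angina",
    "ethnicity_white",
    "event",
    "complete",
)


class SchemaError(ValueError):
    pass


def read_cohort(path, require_followup: bool = False) -> pd.DataFrame:
    """Load a flat cohort CSV, validating the column schema."""
    df = pd.read_csv(path)
    required = list(COHORT_COLUMNS) + (
        list(FOLLOWUP_COLUMNS) if require_followup else []
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} lacks required columns: {missing}")
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_raw_records(records: Iterable[RawPatientRecord], outdir) -> None:
    """Write the four raw-record CSVs (episodes, measurements,
    prescriptions, registration) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    episodes, measurements, prescriptions, registration = [], [], [], []
    for r in records:
        for ep in r.episodes:
            episodes.append(
                {
                    "patient_id": r.patient_id,
                    "code": ep.code,
                    "start_date": ep.start_date.isoformat(),
                    "end_date": ep.end_date.isoformat() if ep.end_date else "",
                }
            )
        for m in r.measurements:
            measurements.append(
                {
                    "patient_id": r.patient_id,
                    "kind": m.kind,
                    "value": m.value,
                    "date": m.date.isoformat(),
                }
            )
        for p in r.prescriptions:
            prescriptions.append(
                {
                    "patient_id": r.patient_id,
                    "atc_code": p.atc_code,
                    "date": p.date.isoformat(),
                }
            )
        registration.append(
            {
                "patient_id": r.patient_id,
                "practice_id": r.practice_id,
                "birth_date": r.birth_date.isoformat(),
                "sex": r.sex,
                "registration_start": r.registration_start.isoformat(),
                "quarters": "".join("1" if q else "0" for q in r.registration_quarters),
            }
        )
    pd.DataFrame(episodes).to_csv(outdir / "episodes.csv", index=False)
    pd.DataFrame(measurements).to_csv(outdir / "measurements.csv", index=False)
    pd.DataFrame(prescriptions).to_csv(outdir / "prescriptions.csv", index=False)
    pd.DataFrame(registration).to_csv(outdir / "registration.csv", index=False)


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def read_raw_records(indir) -> list[RawPatientRecord]:
    """Load raw records from the four CSVs written by
    :func:`write_raw_records`; registration.csv is the patient index."""
    indir = Path(indir)
    reg = pd.read_csv(indir / "registration.csv", dtype=str)
    required = {"patient_id", "practice_id", "birth_date", "sex",
                "registration_start", "quarters"}
    if not required <= set(reg.columns):
        raise SchemaError(
            f"registration.csv lacks columns: {sorted(required - set(reg.columns))}"
        )

    def grouped(name, cols):
        path = indir / name
        if not path.exists():
            return {}
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} lacks columns: {missing}")
        return dict(tuple(df.groupby("patient_id", sort=False)))

    eps = grouped("episodes.csv", ("patient_id", "code", "start_date"))
    meas = grouped("measurements.csv", ("patient_id", "kind", "value", "date"))
    rx = grouped("prescriptions.csv", ("patient_id", "atc_code", "date"))

    records = []
    for row in reg.itertuples(index=False):
        pid = row.patient_id
        episodes = [
            Episode(
                code=e.code,
                start_date=_parse_date(e.start_date),
                end_date=_parse_date(e.end_date) if getattr(e, "end_date", "") else None,
            )
            for e in eps.get(pid, pd.DataFrame()).itertuples(index=False)
        ]
        measurements = [
            Measurement(
                kind=m.kind,
                value=m.value if m.kind == "smoking_status" else float(m.value),
                date=_parse_date(m.date),
            )
            for m in meas.get(pid, pd.DataFrame()).itertuples(index=False)
        ]
        prescriptions = [
            Prescription(atc_code=p.atc_code, date=_parse_date(p.date))
            for p in rx.get(pid, pd.DataFrame()).itertuples(index=False)
        ]
        records.append(
            RawPatientRecord(
                patient_id=pid,
                practice_id=row.practice_id,
                birth_date=_parse_date(row.birth_date),
                sex=row.sex,
                episodes=episodes,
                measurements=measurements,
                prescriptions=prescriptions,
                registration_quarters=[c == "1" for c in row.quarters],
                registration_start=_parse_date(row.registration_start),
            )
        )
    return records
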