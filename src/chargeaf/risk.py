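"""CHARGE-AF and CHA2DS2-VASc risk scoring.

The CHARGE-AF model predicts an individual's absolute 5-year risk of
new-onset atrial fibrillation from eleven routinely available clinical
covariates via a Cox-type survival power form::

    risk = 1 - S0 ** exp(lp - c)

where ``lp`` is a weighted sum of scaled covariates, ``S0`` the baseline
5-year AF-free survival and ``c`` a centering constant.  The published
coefficients and constants are shipped as :data:`CHARGE_AF` and can be
swapped for a recalibrated variant loaded from YAML.

All scoring functions are vectorised: they accept scalars, numpy arrays,
or a :class:`pandas.DataFrame` / mapping with the covariate field names
used throughout this package (see :data:`CHARGE_AF_INPUTS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ChargeAFModel",
    "CHARGE_AF",
    "CHARGE_AF_INPUTS",
    "IncompleteCaseError",
    "charge_af_linear_predictor",
    "charge_af_risk",
    "cha2ds2_vasc",
    "categorize_risk",
    "contribution_decomposition",
    "score_cohort",
    "RISK_CATEGORY_LABELS",
]

#: Published CHARGE-AF coefficients, keyed by covariate.  Continuous
#: covariates enter scaled: age/5, height/10, weight/15, SBP/20, DBP/10.
_CHARGE_AF_COEFFICIENTS: Mapping[str, float] = {
    "age_per5": 0.5083,
    "ethnicity_white": 0.46491,
    "height_per10": 0.2478,
    "weight_per15": 0.1155,
    "sbp_per20": 0.1972,
    "dbp_per10": -0.1013,
    "current_smoking": 0.35931,
    "antihypertensive_use": 0.34889,
    "diabetes": 0.23666,
    "heart_failure": 0.70127,
    "myocardial_infarction": 0.49659,
}

#: (covariate column, coefficient key, scale divisor) triples.  Boolean
#: covariates have divisor 1.
_TERMS: Sequence[tuple[str, str, float]] = (
    ("age_years", "age_per5", 5.0),
    ("ethnicity_white", "ethnicity_white", 1.0),
    ("height_cm", "height_per10", 10.0),
    ("weight_kg", "weight_per15", 15.0),
    ("sbp_mmHg", "sbp_per20", 20.0),
    ("dbp_mmHg", "dbp_per10", 10.0),
    ("current_smoking", "current_smoking", 1.0),
    ("antihypertensive_use", "antihypertensive_use", 1.0),
    ("diabetes", "diabetes", 1.0),
    ("heart_failure", "heart_failure", 1.0),
    ("myocardial_infarction", "myocardial_infarction", 1.0),
)

#: Cohort columns required to evaluate the CHARGE-AF linear predictor.
CHARGE_AF_INPUTS: tuple[str, ...] = tuple(t[0] for t in _TERMS)

#: The four body measurements whose joint availability defines a
#: "complete case".
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "height_cm",
    "weight_kg",
    "sbp_mmHg",
    "dbp_mmHg",
)

RISK_CATEGORY_LABELS: tuple[str, ...] = ("low", "intermediate", "high")

#: Default risk-category thresholds (5-year predicted probability).
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.025, 0.05)


class IncompleteCaseError(ValueError):
    """Raised when a CHARGE-AF input is missing.

    The model must never be evaluated with silently zero-filled body
    measurements; incomplete cases are identified upstream and excluded.
    """


@dataclass(frozen=True)
class ChargeAFModel:
    """CHARGE-AF risk equation constants.

    Parameters
    ----------
    coefficients
        Mapping from the 11 coefficient keys to log-hazard weights.
    baseline_survival
        5-year AF-free survival at the centering constant, in (0, 1).
    centering_constant
        Value subtracted from the linear predictor before exponentiation
        (the derivation-cohort mean linear predictor).
    horizon_years
        Prediction horizon of the equation.
    """

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(_CHARGE_AF_COEFFICIENTS)
    )
    baseline_survival: float = 0.9718412736
    centering_constant: float = 12.5815600
    horizon_years: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_survival < 1.0:
            raise ValueError("baseline_survival must lie in (0, 1)")
        missing = set(_CHARGE_AF_COEFFICIENTS) - set(self.coefficients)
        extra = set(self.coefficients) - set(_CHARGE_AF_COEFFICIENTS)
        if missing or extra:
            raise ValueError(
                f"coefficient set must cover exactly the 11 CHARGE-AF terms; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "ChargeAFModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            coefficients=dict(payload["coefficients"]),
            baseline_survival=float(payload["baseline_survival"]),
            centering_constant=float(payload["centering_constant"]),
            horizon_years=float(payload.get("horizon_years", 5.0)),
        )

    def to_yaml(self, path) -> None:
        payload = {
            "coefficients": dict(self.coefficients),
            "baseline_survival": self.baseline_survival,
            "centering_constant": self.centering_constant,
            "horizon_years": self.horizon_years,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    def with_coefficient(self, key: str, value: float) -> "ChargeAFModel":
        coefs = dict(self.coefficients)
        coefs[key] = value
        return replace(self, coefficients=coefs)


#: The published model instance used as default everywhere.
CHARGE_AF = ChargeAFModel()


def _as_columns(cov) -> Mapping[str, np.ndarray]:
    """Normalise covariate input to a name -> array mapping."""
    if isinstance(cov, pd.DataFrame):
        return {c: cov[c].to_numpy() for c in cov.columns}
    if isinstance(cov, Mapping):
        return {k: np.asarray(v) for k, v in cov.items()}
    # dataclass-like object (BaselineCovariates)
    return {
        name: np.asarray(getattr(cov, name))
        for name in CHARGE_AF_INPUTS
        if hasattr(cov, name)
    }


def charge_af_linear_predictor(cov, model: ChargeAFModel = CHARGE_AF):
    """Evaluate the CHARGE-AF linear predictor sum(b * X).

    ``cov`` supplies the 11 covariates by name (``age_years``,
    ``ethnicity_white``, ``height_cm``, ``weight_kg``, ``sbp_mmHg``,
    ``dbp_mmHg`` plus the five boolean flags).  Continuous covariates are
    scaled by the published divisors before multiplication.

    Raises
    ------
    IncompleteCaseError
        If a required covariate column is absent or contains NaN.  The
        model is only defined for complete cases.
    """
    cols = _as_columns(cov)
    absent = [c for c in CHARGE_AF_INPUTS if c not in cols]
    if absent:
        raise IncompleteCaseError(f"missing CHARGE-AF covariates: {absent}")
    lp = 0.0
    for col, key, divisor in _TERMS:
        x = np.asarray(cols[col], dtype=float)
        if np.any(np.isnan(x)):
            raise IncompleteCaseError(
                f"covariate {col!r} contains missing values; score complete "
                "cases only (no silent zero-fill)"
            )
        lp = lp + model.coefficients[key] * (x / divisor)
    return lp


def charge_af_risk(lp, model: ChargeAFModel = CHARGE_AF):
    """Map a linear predictor to the predicted 5-year AF probability.

    risk = 1 - S0 ** exp(lp - c), strictly increasing in ``lp`` and
    strictly inside (0, 1) for finite ``lp``.
    """
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    risk = 1.0 - model.baseline_survival ** np.exp(lp - model.centering_constant)
    return risk if risk.ndim else float(risk)


def charge_af_score(cov, model: ChargeAFModel = CHARGE_AF):
    """Convenience: linear predictor and risk in one call."""
    lp = charge_af_linear_predictor(cov, model)
    return lp, charge_af_risk(lp, model)


def cha2ds2_vasc(cov):
    """CHA2DS2-VASc stroke-risk score, an integer in [0, 9].

    Components: congestive heart failure (1), hypertension (1), age >= 75
    (2) or 65-74 (1), diabetes (1), prior stroke or TIA (2), vascular
    disease (1; here myocardial infarction, atherosclerotic arterial
    disease or angina), female sex (1).  Age uses completed years.
    """
    cols = _as_columns(cov)
    age = np.asarray(cols["age_years"], dtype=float)
    female = np.asarray(cols["sex"]) == "female" if "sex" in cols else np.asarray(
        cols["female"], dtype=bool
    )

    def flag(name):
        return np.asarray(cols.get(name, np.zeros_like(age, dtype=bool)), dtype=bool)

    vascular = flag("myocardial_infarction") | flag("atherosclerosis") | flag("angina")
    if "vascular_disease" in cols:
        vascular = vascular | flag("vascular_disease")
    score = (
        flag("heart_failure").astype(int)
        + flag("hypertension").astype(int)
        + np.where(np.floor(age) >= 75, 2, np.where(np.floor(age) >= 65, 1, 0))
        + flag("diabetes").astype(int)
        + 2 * (flag("stroke") | flag("tia")).astype(int)
        + vascular.astype(int)
        + np.asarray(female, dtype=int)
    )
    return score if score.ndim else int(score)


def categorize_risk(risk, thresholds: Sequence[float] = DEFAULT_THRESHOLDS):
    """Assign ordinal risk categories given increasing probability cut-offs.

    With the default thresholds (0.025, 0.05) the categories are
    low (< 2.5%), intermediate (2.5%-5%, both boundaries included) and
    high (> 5%): interior boundaries close the interval on the left, and
    the top boundary value still belongs to the middle band, matching the
    conventional "2.5%-5%" reading.

    Returns integer category indices (0 = lowest); for the default
    two-threshold case :data:`RISK_CATEGORY_LABELS` gives the names.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.size == 0:
        raise ValueError("threshold list must be non-empty")
    if np.any(thr <= 0) or np.any(thr >= 1) or np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly increasing within (0, 1)")
    risk = np.asarray(risk, dtype=float)
    idx = np.searchsorted(thr, risk, side="right")
    idx = np.where(risk == thr[-1], len(thr) - 1, idx)
    return idx if idx.ndim else int(idx)


def category_labels(thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> list[str]:
    """Human-readable labels for the categories of ``thresholds``."""
    if len(thresholds) == 2:
        return list(RISK_CATEGORY_LABELS)
    edges = ["0"] + [f"{t:g}" for t in thresholds] + ["1"]
    return [f"[{a}, {b})" for a, b in zip(edges[:-1], edges[1:])]


def contribution_decomposition(
    cohort: pd.DataFrame,
    model: ChargeAFModel = CHARGE_AF,
    strata_edges: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-variable contribution to the linear predictor by risk stratum.

    For each stratum of predicted baseline risk the table holds, per
    covariate, the stratum mean of the scaled covariate times its
    coefficient.  Row sums therefore reproduce the stratum mean linear
    predictor exactly — a useful identity check, and the standard way to
    show which variables drive risk upward across strata (in practice,
    age dominates).
    """
    lp = charge_af_linear_predictor(cohort, model)
    risk = charge_af_risk(lp, model)
    cat = categorize_risk(risk, strata_edges)
    rows = {}
    for stratum in range(len(strata_edges) + 1):
        mask = cat == stratum
        if not np.any(mask):
            continue
        row = {}
        for col, key, divisor in _TERMS:
            x = np.asarray(cohort[col], dtype=float)[mask]
            row[col] = model.coefficients[key] * float(np.mean(x)) / divisor
        rows[stratum] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "stratum"
    return out


def score_cohort(
    cohort: pd.DataFrame,
    model: ChargeAFModel = CHARGE_AF,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Append model scores to a flat cohort table.

    Adds columns ``charge_af_lp``, ``charge_af_risk5y``,
    ``charge_af_category``, ``cha2ds2vasc`` and ``cha2ds2vasc_ge2``.
    Rows with missing body measurements raise
    :class:`IncompleteCaseError`; split complete cases first.
    """
    out = cohort.copy()
    lp = charge_af_linear_predictor(out, model)
    risk = charge_af_risk(lp, model)
    out["charge_af_lp"] = lp
    out["charge_af_risk5y"] = risk
    out["charge_af_category"] = categorize_risk(risk, thresholds)
    out["cha2ds2vasc"] = cha2ds2_vasc(out)
    out["cha2ds2vasc_ge2"] = out["cha2ds2vasc"] >= 2
    return out
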