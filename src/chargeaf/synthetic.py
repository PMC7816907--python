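"""Synthetic primary-care cohort generator.

Emulates the statistical structure a validation of a 5-year AF risk
model in routine primary-care data has to cope with, so the whole
pipeline runs without access to any licensed database:

* baseline covariate marginals of the complete-case population
  (age 65.5 +/- 11.4 truncated at 40, 52.5% female, published body
  measurement means/SDs, realistic comorbidity prevalences rising with
  age);
* informative (MNAR) missingness of the four body measurements —
  availability increases with comorbidity burden and age, calibrated so
  that 17.2% of the AF-free cohort is a complete case;
* event times driven by the risk model itself: each patient gets a
  constant hazard that reproduces their (optionally distorted and
  recalibrated) predicted 5-year risk exactly, which makes the
  generating process exactly proportional-hazards in the linear
  predictor — so discrimination and calibration-slope recovery are
  well-posed checks;
* quarterly registration censoring: an absorbing per-quarter dropout
  process, calibrated to a mean observed follow-up of 3.5 years.

Calibration parameters (population age location, comorbidity and
missingness intercepts, hazard multiplier, dropout probability) are
solved numerically against a fixed set of random deviates drawn from
the seed, so regeneration with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr, ndtri

from .cohort import DEFAULT_CODE_MAP, CodeMap, Episode, Measurement, Prescription, RawPatientRecord
from .followup import DAYS_PER_YEAR
from .risk import CHARGE_AF, ChargeAFModel, charge_af_linear_predictor, charge_af_risk

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort", "emit_raw_records"]

#: comorbidity flag -> (target prevalence, log-odds slope per year of age)
_DEFAULT_COMORBIDITIES: Mapping[str, tuple[float, float]] = {
    "antihypertensive_use": (0.709, 0.08),
    "hypertension": (0.665, 0.08),
    "diabetes": (0.427, 0.05),
    "heart_failure": (0.042, 0.10),
    "myocardial_infarction": (0.049, 0.07),
    "current_smoking": (0.142, -0.04),
    "stroke": (0.067, 0.09),
    "tia": (0.030, 0.07),
    "atherosclerosis": (0.057, 0.08),
    "angina": (0.091, 0.06),
}

#: flags entering the "comorbidity count" that drives measurement
#: availability (cardiovascular morbidity, not behaviour or treatment)
_COUNT_FLAGS = (
    "hypertension",
    "diabetes",
    "heart_failure",
    "myocardial_infarction",
    "stroke",
    "tia",
    "atherosclerosis",
    "angina",
)


def _years_later(d: dt.date, years: int) -> dt.date:
    return d.replace(year=d.year + years)


def _quarter_start(base: dt.date, index: int) -> dt.date:
    month0 = base.year * 12 + (base.month - 1) + 3 * index
    return dt.date(month0 // 12, month0 % 12 + 1, 1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the synthetic cohort.

    Covariate targets describe the *complete-case* subpopulation (that
    is what a baseline table of a complete-case validation study
    reports); the generator solves the population-level parameters so
    the complete cases land on them under the informative-missingness
    model.  Comorbidity prevalences are population targets hit by
    bisection on logistic-in-age intercepts.
    """

    n: int = 100_000
    seed: int = 20140101
    # --- complete-case age target / population age shape
    age_mean: float = 65.5
    age_sd: float = 11.4
    age_min: float = 40.0
    female_fraction: float = 0.525
    # --- measurement marginals (population scale)
    height_mean: float = 170.0
    height_sd: float = 9.9
    weight_mean: float = 82.5
    weight_sd: float = 16.8
    sbp_mean: float = 137.3
    sbp_sd: float = 16.3
    dbp_mean: float = 80.5
    dbp_sd: float = 10.5
    height_weight_corr: float = 0.5
    sbp_dbp_corr: float = 0.5
    sex_height_offset_male: float = 7.0
    sex_weight_offset_male: float = 5.0
    # --- comorbidities: flag -> (prevalence target, age slope /year)
    comorbidities: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITIES)
    )
    # --- informative missingness of the four body measurements
    complete_fraction: float = 0.172
    missing_comorbidity_slope: float = 0.25
    missing_age_slope: float = 0.02
    # --- events
    risk_model: ChargeAFModel = CHARGE_AF
    target_cumulative_incidence: float = 0.047  # complete cases, 5 years
    hazard_multiplier: Optional[float] = None  # solved when None
    lp_slope_distortion: float = 1.0
    lp_intercept_shift: float = 0.0
    # --- censoring
    mean_followup_years: float = 3.5
    dropout_prob: Optional[float] = None  # per quarter; solved when None
    n_practices: int = 100
    practice_dropout_prob: float = 0.0
    # --- window
    baseline_date: dt.date = dt.date(2014, 1, 1)
    horizon_years: int = 5

    def provenance_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


@dataclass
class SyntheticCohort:
    """Generated flat cohort plus provenance."""

    frame: pd.DataFrame
    config: GeneratorConfig
    solved: dict
    provenance: str

    @property
    def complete(self) -> pd.DataFrame:
        return self.frame[self.frame["complete"]]


def _streams(seed: int) -> dict:
    names = ("covariates", "missingness", "mask", "events", "censoring")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}


def _draw_deviates(config: GeneratorConfig, rng: np.random.Generator) -> dict:
    """All covariate-stage deviates, drawn once in a fixed order."""
    n = config.n
    comorb = list(config.comorbidities)
    return {
        "u_age": rng.random(n),
        "u_sex": rng.random(n),
        "z_meas": rng.standard_normal((n, 4)),
        "u_comorb": {c: rng.random(n) for c in comorb},
        "u_complete": rng.random(n),
        "practice": rng.integers(0, config.n_practices, n),
    }


def _ages_from(config: GeneratorConfig, population_age_mean: float, u: np.ndarray):
    """Completed years at baseline from a truncated normal draw."""
    a = (config.age_min - population_age_mean) / config.age_sd
    base = ndtr(a)
    cont = population_age_mean + config.age_sd * ndtri(base + u * (1.0 - base))
    return np.floor(cont)


def _solve_logistic_intercept(target: float, linear: np.ndarray) -> float:
    """Intercept b such that mean(expit(b + linear)) == target."""
    f = lambda b: float(np.mean(expit(b + linear))) - target
    return brentq(f, -20.0, 20.0, xtol=1e-9)


def generate_covariates(
    config: GeneratorConfig,
    deviates: dict,
    population_age_mean: Optional[float] = None,
    solved: Optional[dict] = None,
) -> pd.DataFrame:
    """Draw baseline covariates for ``config.n`` patients.

    Continuous measurements come from correlated normals with
    sex-specific location offsets chosen to preserve the configured
    overall mean and SD; comorbidity flags come from logistic-in-age
    models whose intercepts are solved to hit the target population
    prevalences on the realized age sample.
    """
    mu = config.age_mean if population_age_mean is None else population_age_mean
    n = config.n
    age = _ages_from(config, mu, deviates["u_age"])
    female = deviates["u_sex"] < config.female_fraction
    sex = np.where(female, "female", "male")

    p_f = config.female_fraction

    def sexed_normal(mean, sd, male_offset, z):
        off_f = -male_offset * (1.0 - p_f) / p_f if p_f > 0 else 0.0
        between = p_f * (1 - p_f) * (male_offset - off_f) ** 2
        resid = np.sqrt(max(sd**2 - between, 1e-6))
        return mean + np.where(female, off_f, male_offset) + resid * z

    z = deviates["z_meas"]
    rho_hw, rho_bp = config.height_weight_corr, config.sbp_dbp_corr
    z_h = z[:, 0]
    z_w = rho_hw * z[:, 0] + np.sqrt(1 - rho_hw**2) * z[:, 1]
    z_s = z[:, 2]
    z_d = rho_bp * z[:, 2] + np.sqrt(1 - rho_bp**2) * z[:, 3]
    height = sexed_normal(config.height_mean, config.height_sd,
                          config.sex_height_offset_male, z_h)
    weight = sexed_normal(config.weight_mean, config.weight_sd,
                          config.sex_weight_offset_male, z_w)
    sbp = config.sbp_mean + config.sbp_sd * z_s
    dbp = config.dbp_mean + config.dbp_sd * z_d

    # physiological plausibility bounds, as an EHR ingest would apply;
    # they also keep extreme tail draws from saturating the risk scale
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i:07d}" for i in range(n)],
            "practice_id": [f"pr{k:03d}" for k in deviates["practice"]],
            "age_years": np.minimum(age, 105.0),
            "sex": sex,
            "height_cm": np.clip(height, 120.0, 210.0),
            "weight_kg": np.clip(weight, 35.0, 180.0),
            "sbp_mmHg": np.clip(sbp, 70.0, 230.0),
            "dbp_mmHg": np.clip(dbp, 40.0, 140.0),
            "ethnicity_white": True,
        }
    )
    intercepts = {}
    age_c = age - 65.0
    for flag, (prev, slope) in config.comorbidities.items():
        b = _solve_logistic_intercept(prev, slope * age_c)
        intercepts[flag] = b
        df[flag] = deviates["u_comorb"][flag] < expit(b + slope * age_c)
    if solved is not None:
        solved["comorbidity_intercepts"] = intercepts
        solved["population_age_mean"] = mu
    return df


def impose_missingness(
    table: pd.DataFrame, config: GeneratorConfig, deviates: dict
) -> tuple[np.ndarray, float]:
    """Complete-case flags under the informative-availability model.

    P(all four measurements recorded) is logit-linear in cardiovascular
    comorbidity count and age; the intercept is solved so the expected
    complete fraction equals the configured target.  Returns the flags
    and the solved intercept.
    """
    count = table[list(_COUNT_FLAGS)].to_numpy(dtype=float).sum(axis=1)
    age_c = table["age_years"].to_numpy(dtype=float) - 65.0
    linear = (
        config.missing_comorbidity_slope * count + config.missing_age_slope * age_c
    )
    b0 = _solve_logistic_intercept(config.complete_fraction, linear)
    complete = deviates["u_complete"] < expit(b0 + linear)
    return complete, b0


def _mask_measurements(
    frame: pd.DataFrame, complete: np.ndarray, rng: np.random.Generator
) -> None:
    """Blank 1-4 of the four measurements for each incomplete case."""
    from .risk import MEASUREMENT_COLUMNS

    idx = np.flatnonzero(~complete)
    if idx.size == 0:
        return
    k_missing = rng.integers(1, 5, idx.size)
    ranks = np.argsort(rng.random((idx.size, 4)), axis=1)
    mask = ranks < k_missing[:, None]  # (n_inc, 4) True = blank it
    for j, col in enumerate(MEASUREMENT_COLUMNS):
        col_idx = frame.columns.get_loc(col)
        rows = idx[mask[:, j]]
        frame.iloc[rows, col_idx] = np.nan


def _generating_risk(lp: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Predicted risk after the optional miscalibration distortion."""
    c = config.risk_model.centering_constant
    lp_gen = c + config.lp_slope_distortion * (lp - c) + config.lp_intercept_shift
    return charge_af_risk(lp_gen, config.risk_model)


def simulate_events(
    table: pd.DataFrame,
    config: GeneratorConfig,
    rng_or_u,
    complete: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Exponential event times matched to each patient's 5-year risk.

    The hazard is constant per patient, lambda_i = -m * ln(1 - p_i) / H,
    so the generating process is exactly proportional-hazards in the
    linear predictor.  The multiplier ``m`` acts on the hazard scale
    (5-year risk becomes 1 - (1 - p_i)^m) and by default is solved so
    the expected 5-year cumulative incidence among complete cases hits
    the configured target.  Returns (event times in years, multiplier).
    """
    lp = charge_af_linear_predictor(table, config.risk_model)
    p = _generating_risk(lp, config)
    if complete is None:
        complete = np.ones(len(table), dtype=bool)
    m = config.hazard_multiplier
    if m is None:
        target = config.target_cumulative_incidence
        pc = p[complete]
        f = lambda mm: float(np.mean(1.0 - (1.0 - pc) ** mm)) - target
        m = brentq(f, 1e-9, 200.0, xtol=1e-12)
    lam = -m * np.log1p(-p) / config.horizon_years
    u = rng_or_u.random(len(table)) if hasattr(rng_or_u, "random") else np.asarray(rng_or_u)
    times = -np.log(u) / lam
    return times, float(m)


def _loss_days(
    k_quarters: np.ndarray, quarter_day_offsets: np.ndarray, horizon_days: int
) -> np.ndarray:
    """Day offset of the loss date for a dropout starting at quarter k."""
    out = np.full(k_quarters.shape, horizon_days + 1, dtype=float)
    inside = (k_quarters >= 1) & (k_quarters < len(quarter_day_offsets))
    out[inside] = quarter_day_offsets[k_quarters[inside]]
    return out


def simulate_censoring(
    table: pd.DataFrame,
    config: GeneratorConfig,
    deviates_u: np.ndarray,
    event_days: np.ndarray,
    complete: np.ndarray,
    practice_u: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Absorbing quarterly dropout calibrated to the mean follow-up.

    Each patient's first absent quarter is geometric in the per-quarter
    dropout probability (never the baseline quarter itself, so time at
    risk stays positive); optionally a per-practice dropout quarter is
    drawn and the earlier of the two applies, emulating whole practices
    leaving the registry.  The probability is solved so that the mean
    observed time at risk among complete cases equals the target.
    Returns (dropout quarter index or -1, loss day offset, probability).
    """
    baseline = config.baseline_date
    horizon_end = _years_later(baseline, config.horizon_years)
    horizon_days = (horizon_end - baseline).days
    n_quarters = config.horizon_years * 4
    qdays = np.array(
        [(_quarter_start(baseline, k) - baseline).days for k in range(n_quarters)]
    )

    practice_ids = table["practice_id"].to_numpy()
    uniq, inv = np.unique(practice_ids, return_inverse=True)

    def dropout_quarters(q: float) -> np.ndarray:
        if q <= 0:
            return np.full(len(table), n_quarters + 1)
        k = 1 + np.floor(np.log(deviates_u) / np.log1p(-q)).astype(int)
        if config.practice_dropout_prob > 0 and practice_u is not None:
            kp = 1 + np.floor(
                np.log(practice_u[: len(uniq)])
                / np.log1p(-config.practice_dropout_prob)
            ).astype(int)
            k = np.minimum(k, kp[inv])
        return k

    def mean_followup(q: float) -> float:
        loss = _loss_days(dropout_quarters(q), qdays, horizon_days)
        t_days = np.minimum(np.minimum(event_days, loss), horizon_days)
        return float(t_days[complete].mean() / DAYS_PER_YEAR)

    q = config.dropout_prob
    if q is None:
        target = config.mean_followup_years
        if mean_followup(0.0) <= target:
            raise ValueError(
                "target mean follow-up not attainable: even without dropout "
                f"the mean is {mean_followup(0.0):.3f} y"
            )
        q = brentq(lambda qq: mean_followup(qq) - target, 1e-8, 0.9, xtol=1e-10)
    k = dropout_quarters(q)
    loss = _loss_days(k, qdays, horizon_days)
    k_out = np.where(k <= n_quarters - 1, k, -1)
    return k_out, loss, float(q)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the full flat cohort with provenance.

    Runs the calibration chain: an outer solve on the population age
    location brings the complete-case mean age onto its target under
    the informative-missingness model; then the hazard multiplier and
    the quarterly dropout probability are solved.  All solves evaluate
    against deviates fixed by the seed, so the result is deterministic.
    """
    solved: dict = {}

    def build(mu: float):
        rngs = _streams(config.seed)
        dev = _draw_deviates(config, rngs["covariates"])
        df = generate_covariates(config, dev, population_age_mean=mu, solved=solved)
        complete, b0 = impose_missingness(df, config, dev)
        return df, dev, complete, b0, rngs

    def gap(mu: float) -> float:
        df, _, complete, _, _ = build(mu)
        if not complete.any():
            return -config.age_mean
        return float(df["age_years"].to_numpy()[complete].mean()) - config.age_mean

    lo, hi = config.age_min + 2.0, config.age_mean + 15.0
    mu = brentq(gap, lo, hi, xtol=5e-3)
    df, dev, complete, b0, rngs = build(mu)
    solved["missingness_intercept"] = b0

    # true (undistorted) model risk from the pre-mask covariates
    true_lp = charge_af_linear_predictor(df, config.risk_model)
    true_risk = charge_af_risk(true_lp, config.risk_model)

    event_times_years, m = simulate_events(df, config, rngs["events"], complete)
    solved["hazard_multiplier"] = m
    event_days = np.floor(event_times_years * DAYS_PER_YEAR).astype(np.int64) + 1

    u_dropout = rngs["censoring"].random(config.n)
    practice_u = rngs["censoring"].random(config.n_practices)
    k_dropout, loss_days, q = simulate_censoring(
        df, config, u_dropout, event_days, complete, practice_u
    )
    solved["dropout_prob"] = q

    horizon_days = (_years_later(config.baseline_date, config.horizon_years)
                    - config.baseline_date).days
    bound = np.minimum(loss_days, horizon_days)
    event = event_days < bound
    time_days = np.minimum(event_days, bound)
    reason = np.where(
        event, "af_event", np.where(loss_days < horizon_days, "lost_to_followup", "admin_end")
    )

    df["complete"] = complete
    df["true_lp"] = true_lp
    df["true_risk"] = true_risk
    df["generating_risk"] = 1.0 - (1.0 - _generating_risk(true_lp, config)) ** m
    df["dropout_quarter"] = k_dropout
    df["af_day"] = np.where(event, event_days, -1)
    df["time_years"] = time_days / DAYS_PER_YEAR
    df["event"] = event
    df["censor_reason"] = reason
    _mask_measurements(df, complete, rngs["mask"])

    return SyntheticCohort(
        frame=df,
        config=config,
        solved=solved,
        provenance=config.provenance_hash(),
    )


# ---------------------------------------------------------------------------
# raw EHR-like emission


def emit_raw_records(
    cohort: SyntheticCohort,
    code_map: CodeMap = DEFAULT_CODE_MAP,
    decoy_measurements: bool = True,
) -> list[RawPatientRecord]:
    """Re-express the flat cohort as raw EHR-like records.

    Measurements become dated entries inside the baseline year (plus an
    optional earlier decoy entry that closest-to-baseline extraction
    must ignore), morbidity flags become pre-baseline episodes with
    mapped codes, antihypertensive use becomes a baseline-year
    prescription, observed AF events become dated episodes, and the
    dropout quarter becomes an absorbing gap in the registration grid.
    Round-tripping through baseline extraction and the complete-case
    split reproduces the flat cohort.
    """
    from .risk import MEASUREMENT_COLUMNS

    config = cohort.config
    baseline = config.baseline_date
    reg_start = _years_later(baseline, -1)
    n_quarters = 4 + config.horizon_years * 4  # baseline year + follow-up
    meas_date = baseline - dt.timedelta(days=17)
    decoy_date = baseline - dt.timedelta(days=290)
    episode_start = dt.date(baseline.year - 4, 6, 1)
    rx_date = baseline - dt.timedelta(days=200)
    rx_code = sorted(code_map["antihypertensive"])[0] + "A01"
    af_code = sorted(code_map["atrial_fibrillation"])[0]

    records = []
    for row in cohort.frame.itertuples(index=False):
        age = int(row.age_years)
        birth = dt.date(baseline.year - age - 1, 7, 2)
        measurements = []
        for col in MEASUREMENT_COLUMNS:
            value = getattr(row, col)
            if value == value:  # not NaN
                measurements.append(Measurement(col, float(value), meas_date))
                if decoy_measurements:
                    measurements.append(
                        Measurement(col, float(value) + 2.0, decoy_date)
                    )
        measurements.append(
            Measurement(
                "smoking_status",
                "current" if row.current_smoking else "never",
                meas_date,
            )
        )
        episodes = []
        for cond in (
            "diabetes", "heart_failure", "myocardial_infarction", "hypertension",
            "stroke", "tia", "atherosclerosis", "angina",
        ):
            if getattr(row, cond):
                episodes.append(
                    Episode(sorted(code_map[cond])[0], episode_start)
                )
        if row.af_day >= 0:
            episodes.append(
                Episode(af_code, baseline + dt.timedelta(days=int(row.af_day)))
            )
        prescriptions = (
            [Prescription(rx_code, rx_date)] if row.antihypertensive_use else []
        )
        quarters = [True] * 4  # fully registered during the baseline year
        for k in range(n_quarters - 4):
            quarters.append(row.dropout_quarter < 0 or k < row.dropout_quarter)
        records.append(
            RawPatientRecord(
                patient_id=row.patient_id,
                practice_id=row.practice_id,
                birth_date=birth,
                sex=row.sex,
                episodes=episodes,
                measurements=measurements,
                prescriptions=prescriptions,
                registration_quarters=quarters,
                registration_start=reg_start,
            )
        )
    return records
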