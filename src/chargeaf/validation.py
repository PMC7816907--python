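"""Validation statistics for a risk model against censored outcomes.

Implements the standard external-validation toolkit for a 5-year risk
equation evaluated on right-censored follow-up:

* Harrell's concordance index with a seeded patient-level bootstrap CI
  (point estimate via :func:`lifelines.utils.concordance_index`);
* single-covariate Cox proportional-hazards fits by Newton-Raphson on
  the Efron-corrected partial likelihood — used for the calibration
  slope of the linear predictor and for unadjusted hazard ratios;
* a calibration table over risk deciles (mean predicted risk vs
  Kaplan-Meier observed risk at the horizon, Greenwood CIs) and the
  Nam-D'Agostino chi-squared calibration statistic;
* categorical net reclassification improvement (NRI) under censoring,
  with Kaplan-Meier estimation of event status per reclassification
  cell and a seeded bootstrap CI;
* risk-category-stratified Kaplan-Meier curves and a Table-2 style
  stratified validation report comparing the model with simpler
  predictors (age alone, CHA2DS2-VASc).

All bootstrap randomness flows from a single integer seed
(:data:`DEFAULT_SEED`, the study baseline date by convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index as _lifelines_concordance
from scipy import stats

from .followup import SurvivalCurve, kaplan_meier
from .risk import categorize_risk

__all__ = [
    "DEFAULT_SEED",
    "CStatistic",
    "CoxFit",
    "NriResult",
    "harrell_c",
    "cox_fit_single",
    "calibration_table",
    "nam_dagostino",
    "categorical_nri",
    "marker_to_risk",
    "stratified_km",
    "stratified_validation",
]

DEFAULT_SEED = 20140101

_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# discrimination


@dataclass(frozen=True)
class CStatistic:
    c: float
    ci_low: float
    ci_high: float
    n_bootstrap: int


def _c_point(marker, times, events) -> float:
    """Harrell's C for a risk marker (higher marker = higher risk)."""
    if np.all(marker == marker[0]):
        warnings.warn("constant marker: concordance undefined, returning 0.5")
        return 0.5
    # lifelines scores concordance of *survival* predictions, so negate.
    return float(_lifelines_concordance(times, -marker, events))


def harrell_c(
    marker,
    times,
    events,
    n_bootstrap: int = 200,
    seed: int = DEFAULT_SEED,
) -> CStatistic:
    """Concordance index over usable pairs, with a bootstrap percentile CI.

    A pair is usable when the shorter observed time is an event; the pair
    is concordant when the higher marker belongs to the earlier event,
    and marker ties count one half.  The CI resamples patients with
    replacement ``n_bootstrap`` times under the given seed.
    """
    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise ValueError("no events: concordance has no usable pairs")
    c = _c_point(marker, times, events)
    if n_bootstrap <= 0:
        return CStatistic(c, np.nan, np.nan, 0)
    rng = np.random.default_rng(seed)
    n = len(times)
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        if not events[idx].any() or np.all(marker[idx] == marker[idx][0]):
            reps[b] = 0.5
            continue
        reps[b] = _c_point(marker[idx], times[idx], events[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return CStatistic(c, float(lo), float(hi), n_bootstrap)


# ---------------------------------------------------------------------------
# Cox partial likelihood (single covariate, Efron ties)


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class CoxFit:
    coefficient: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    log_likelihood: float
    n_iter: int
    converged: bool


def _efron_derivatives(beta, x, t_sorted, e_sorted):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Inputs must be sorted ascending by time.  The covariate is assumed
    centred by the caller (invariant quantities, better conditioning).
    """
    w = np.exp(beta * x)
    rev0 = np.cumsum(w[::-1])[::-1]
    rev1 = np.cumsum((x * w)[::-1])[::-1]
    rev2 = np.cumsum((x * x * w)[::-1])[::-1]

    et = t_sorted[e_sorted]
    ut, d = np.unique(et, return_counts=True)
    first = np.searchsorted(et, ut, side="left")
    we = w[e_sorted]
    xe = x[e_sorted]
    s0d = np.add.reduceat(we, first)
    s1d = np.add.reduceat(xe * we, first)
    s2d = np.add.reduceat(xe * xe * we, first)

    pos = np.searchsorted(t_sorted, ut, side="left")
    S0, S1, S2 = rev0[pos], rev1[pos], rev2[pos]

    # flatten the Efron inner sum over l = 0 .. d_k - 1
    gidx = np.repeat(np.arange(len(ut)), d)
    offsets = np.repeat(np.concatenate(([0], np.cumsum(d)[:-1])), d)
    frac = (np.arange(d.sum()) - offsets) / np.repeat(d, d)

    phi0 = S0[gidx] - frac * s0d[gidx]
    phi1 = S1[gidx] - frac * s1d[gidx]
    phi2 = S2[gidx] - frac * s2d[gidx]

    sum_x_events = float(xe.sum())
    loglik = beta * sum_x_events - float(np.log(phi0).sum())
    r1 = phi1 / phi0
    grad = sum_x_events - float(r1.sum())
    hess = -float((phi2 / phi0 - r1 * r1).sum())
    return loglik, grad, hess


def cox_fit_single(
    covariate,
    times,
    events,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a one-covariate Cox proportional-hazards model.

    Maximises the Efron-tie-corrected partial likelihood by damped
    Newton-Raphson; the standard error comes from the observed
    information and the 95% CI is Wald.  Raises
    :class:`ConvergenceError` on monotone likelihood (complete
    separation) or failure to converge.
    """
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    if not e.any():
        raise ValueError("no events")
    order = np.argsort(t, kind="stable")
    t_s, e_s = t[order], e[order]
    x_c = (x - x.mean())[order]

    beta = 0.0
    loglik, grad, hess = _efron_derivatives(beta, x_c, t_s, e_s)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if hess >= 0:
            raise ConvergenceError("non-concave partial likelihood")
        step = -grad / hess
        # damp steps that overshoot the likelihood
        new_beta = beta + step
        new = _efron_derivatives(new_beta, x_c, t_s, e_s)
        halvings = 0
        while new[0] < loglik and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new = _efron_derivatives(new_beta, x_c, t_s, e_s)
            halvings += 1
        beta, (loglik, grad, hess) = new_beta, new
        if abs(beta) > 500:
            raise ConvergenceError(
                "monotone partial likelihood (complete separation)"
            )
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")
    if hess >= 0:
        raise ConvergenceError("observed information is singular at the optimum")
    se = float(np.sqrt(-1.0 / hess))
    return CoxFit(
        coefficient=float(beta),
        se=se,
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        log_likelihood=float(loglik),
        n_iter=it,
        converged=converged,
    )


def breslow_cumulative_hazard(fit: CoxFit, covariate, times, events, horizon: float) -> float:
    """Breslow baseline cumulative hazard at ``horizon``.

    Baseline refers to the mean-centred covariate, matching the
    centring used by :func:`cox_fit_single`.
    """
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    order = np.argsort(t, kind="stable")
    t_s, e_s = t[order], e[order]
    x_c = (x - x.mean())[order]
    w = np.exp(fit.coefficient * x_c)
    rev0 = np.cumsum(w[::-1])[::-1]
    ut, d = np.unique(t_s[e_s], return_counts=True)
    pos = np.searchsorted(t_s, ut, side="left")
    keep = ut <= horizon
    return float((d[keep] / rev0[pos][keep]).sum())


def marker_to_risk(marker, times, events, horizon: float = 5.0):
    """Convert an arbitrary risk marker to absolute horizon risks.

    Fits a single-covariate proportional-hazards model for the marker on
    the validation data and applies the Breslow baseline cumulative
    hazard at the horizon: risk = 1 - exp(-H0 * exp(b * (x - mean))).
    This is how comparator predictors (age alone, an integer score) are
    placed on the probability scale before risk categorisation.
    """
    x = np.asarray(marker, dtype=float)
    fit = cox_fit_single(x, times, events)
    h0 = breslow_cumulative_hazard(fit, x, times, events, horizon)
    return 1.0 - np.exp(-h0 * np.exp(fit.coefficient * (x - x.mean())))


# ---------------------------------------------------------------------------
# calibration


def calibration_table(
    risks,
    times,
    events,
    n_groups: int = 10,
    horizon: float = 5.0,
) -> pd.DataFrame:
    """Observed-vs-predicted risk by groups of predicted risk.

    Patients are ranked by predicted risk (stable sort, so equal risks
    keep input order and grouping is reproducible) and split into
    ``n_groups`` near-equal groups.  Per group: size, mean predicted
    risk, Kaplan-Meier failure at the horizon and a Greenwood-based 95%
    CI for it.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any((risks <= 0) | (risks >= 1)):
        raise ValueError("risks must lie strictly in (0, 1)")
    order = np.argsort(risks, kind="stable")
    rows = []
    for g, idx in enumerate(np.array_split(order, n_groups)):
        if idx.size == 0:
            continue
        km = kaplan_meier(times[idx], events[idx])
        observed = km.failure_at(horizon)
        lo, hi = km.failure_ci_at(horizon)
        rows.append(
            {
                "group": g,
                "n": int(idx.size),
                "mean_predicted": float(risks[idx].mean()),
                "observed_km": observed,
                "ci_low": lo,
                "ci_high": hi,
                "greenwood_var": km.variance_at(horizon),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NamDagostino:
    chi2: float
    df: int
    p_value: float


def nam_dagostino(
    table: pd.DataFrame,
    df_reduction: int = 0,
    variance: str = "binomial",
) -> NamDagostino:
    """Nam-D'Agostino chi-squared calibration statistic.

    chi2 = sum over groups of n_g (KM_g - pbar_g)^2 / (pbar_g (1 - pbar_g)),
    compared to a chi-squared distribution.  In external validation no
    parameter is re-estimated on the validation data, so the default
    reference distribution keeps one degree of freedom per group
    (``df_reduction=0``); pass ``df_reduction=1`` for the classic G-1
    convention used when the groups derive from model development data.

    The classic binomial denominator understates the sampling variance
    of a censored KM estimate; ``variance="greenwood"`` divides each
    group term by its Greenwood variance instead (the censoring-aware
    variant), requiring a table produced by :func:`calibration_table`.
    Groups with a degenerate mean predicted risk (or zero Greenwood
    variance) are dropped with a warning.
    """
    usable = table[(table["mean_predicted"] > 0) & (table["mean_predicted"] < 1)]
    if variance == "greenwood":
        usable = usable[usable["greenwood_var"] > 0]
    if len(usable) < len(table):
        warnings.warn(
            f"dropping {len(table) - len(usable)} group(s) with degenerate "
            "predicted risk or zero variance; degrees of freedom reduced"
        )
    if len(usable) < 2:
        raise ValueError("need at least two usable groups")
    p = usable["mean_predicted"].to_numpy()
    km = usable["observed_km"].to_numpy()
    n = usable["n"].to_numpy()
    if variance == "binomial":
        chi2 = float(np.sum(n * (km - p) ** 2 / (p * (1 - p))))
    elif variance == "greenwood":
        chi2 = float(np.sum((km - p) ** 2 / usable["greenwood_var"].to_numpy()))
    else:
        raise ValueError(f"unknown variance convention {variance!r}")
    df = len(usable) - df_reduction
    return NamDagostino(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# net reclassification improvement


@dataclass(frozen=True)
class NriResult:
    nri_overall: float
    nri_events: float
    nri_nonevents: float
    ci_low: float
    ci_high: float
    ci_events: tuple
    ci_nonevents: tuple
    n_bootstrap: int
    thresholds: tuple


def _km_failure_subset(times, events, mask, horizon) -> float:
    if not np.any(mask):
        return 0.0
    return kaplan_meier(times[mask], events[mask]).failure_at(horizon)


def _nri_point(cat_new, cat_ref, times, events, horizon):
    up = cat_new > cat_ref
    down = cat_new < cat_ref
    pe_all = _km_failure_subset(times, events, np.ones_like(up, bool), horizon)
    if pe_all in (0.0, 1.0):
        raise ValueError("overall event probability degenerate at the horizon")
    p_up = float(np.mean(up))
    p_down = float(np.mean(down))
    pe_up = _km_failure_subset(times, events, up, horizon)
    pe_down = _km_failure_subset(times, events, down, horizon)
    nri_ev = (p_up * pe_up - p_down * pe_down) / pe_all
    nri_ne = (p_down * (1 - pe_down) - p_up * (1 - pe_up)) / (1 - pe_all)
    return nri_ev, nri_ne


def categorical_nri(
    risk_new,
    risk_ref,
    times,
    events,
    thresholds: Sequence[float] = (0.025, 0.05),
    horizon: float = 5.0,
    n_bootstrap: int = 200,
    seed: int = DEFAULT_SEED,
) -> NriResult:
    """Categorical NRI of ``risk_new`` over ``risk_ref`` under censoring.

    Both risk vectors must already be on the probability scale (use
    :func:`marker_to_risk` for comparators such as age).  Categories are
    cross-classified; event status at the horizon is estimated by
    Kaplan-Meier within the up- and down-reclassified sets, so censored
    patients contribute without assuming their outcome.  The event and
    non-event components sum exactly to the overall index.  CI by seeded
    percentile bootstrap over patients.
    """
    risk_new = np.asarray(risk_new, dtype=float)
    risk_ref = np.asarray(risk_ref, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    cat_new = categorize_risk(risk_new, thresholds)
    cat_ref = categorize_risk(risk_ref, thresholds)
    if not np.any(cat_new != cat_ref):
        # no patient moves: NRI is exactly zero
        nri_ev = nri_ne = 0.0
    else:
        nri_ev, nri_ne = _nri_point(cat_new, cat_ref, times, events, horizon)
    overall = nri_ev + nri_ne

    if n_bootstrap <= 0:
        return NriResult(
            overall, nri_ev, nri_ne, np.nan, np.nan, (np.nan, np.nan),
            (np.nan, np.nan), 0, tuple(thresholds),
        )
    rng = np.random.default_rng(seed)
    n = len(times)
    reps = np.empty((n_bootstrap, 2))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        try:
            ev, ne = _nri_point(
                cat_new[idx], cat_ref[idx], times[idx], events[idx], horizon
            )
        except ValueError:
            ev, ne = 0.0, 0.0
        reps[b] = (ev, ne)
    total = reps.sum(axis=1)
    lo, hi = np.percentile(total, [2.5, 97.5])
    ev_lo, ev_hi = np.percentile(reps[:, 0], [2.5, 97.5])
    ne_lo, ne_hi = np.percentile(reps[:, 1], [2.5, 97.5])
    return NriResult(
        nri_overall=overall,
        nri_events=nri_ev,
        nri_nonevents=nri_ne,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_events=(float(ev_lo), float(ev_hi)),
        ci_nonevents=(float(ne_lo), float(ne_hi)),
        n_bootstrap=n_bootstrap,
        thresholds=tuple(thresholds),
    )


# ---------------------------------------------------------------------------
# stratified views


def stratified_km(
    risks,
    thresholds,
    times,
    events,
) -> dict[int, SurvivalCurve]:
    """Kaplan-Meier curves per predicted-risk category (ordered)."""
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    cats = categorize_risk(risks, thresholds)
    curves = {}
    for c in range(len(list(thresholds)) + 1):
        mask = cats == c
        if np.any(mask):
            curves[c] = kaplan_meier(times[mask], events[mask])
    return curves


#: Stratum name -> boolean-mask builder over a scored cohort frame.
DEFAULT_STRATA = {
    "all": lambda df: np.ones(len(df), dtype=bool),
    "age_ge_65": lambda df: df["age_years"].to_numpy() >= 65,
    "age_lt_65": lambda df: df["age_years"].to_numpy() < 65,
    "men": lambda df: df["sex"].to_numpy() == "male",
    "women": lambda df: df["sex"].to_numpy() == "female",
    "cha2ds2vasc_ge_2": lambda df: df["cha2ds2vasc"].to_numpy() >= 2,
    "cha2ds2vasc_lt_2": lambda df: df["cha2ds2vasc"].to_numpy() < 2,
}

#: predictor name -> marker column of a scored cohort frame
PREDICTOR_COLUMNS = {
    "charge_af": "charge_af_risk5y",
    "cha2ds2vasc": "cha2ds2vasc",
    "age": "age_years",
}


def stratified_validation(
    cohort: pd.DataFrame,
    strata: Optional[dict] = None,
    predictors: Optional[dict] = None,
    horizon: float = 5.0,
    n_groups: int = 10,
    min_stratum_size: int = 50,
    n_bootstrap: int = 200,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Validation report stratified by clinically relevant subgroups.

    For every stratum and predictor: Harrell's C with bootstrap CI.  For
    the risk model itself additionally the Nam-D'Agostino statistic over
    risk deciles and the calibration slope of the linear predictor
    (Cox coefficient, ideal value 1).  Requires a scored cohort frame
    with ``time_years`` and ``event`` columns.
    """
    strata = strata or DEFAULT_STRATA
    predictors = predictors or PREDICTOR_COLUMNS
    times = cohort["time_years"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=bool)
    rows = []
    for sname, build in strata.items():
        mask = np.asarray(build(cohort), dtype=bool)
        n = int(mask.sum())
        if n < min_stratum_size:
            warnings.warn(f"stratum {sname!r} below minimum size ({n}), skipped")
            continue
        t_s, e_s = times[mask], events[mask]
        for pname, col in predictors.items():
            marker = cohort[col].to_numpy(dtype=float)[mask]
            try:
                cres = harrell_c(marker, t_s, e_s, n_bootstrap=n_bootstrap, seed=seed)
            except ValueError as exc:
                warnings.warn(f"stratum {sname!r} / {pname}: {exc}; skipped")
                continue
            row = {
                "stratum": sname,
                "predictor": pname,
                "n": n,
                "n_events": int(e_s.sum()),
                "c_statistic": cres.c,
                "c_ci_low": cres.ci_low,
                "c_ci_high": cres.ci_high,
                "nd_chi2": np.nan,
                "nd_p": np.nan,
                "calibration_slope": np.nan,
                "slope_ci_low": np.nan,
                "slope_ci_high": np.nan,
            }
            if pname == "charge_af":
                try:
                    table = calibration_table(
                        cohort["charge_af_risk5y"].to_numpy(dtype=float)[mask],
                        t_s,
                        e_s,
                        n_groups=n_groups,
                        horizon=horizon,
                    )
                    nd = nam_dagostino(table)
                    fit = cox_fit_single(
                        cohort["charge_af_lp"].to_numpy(dtype=float)[mask], t_s, e_s
                    )
                except (ValueError, ConvergenceError) as exc:
                    warnings.warn(
                        f"stratum {sname!r}: calibration statistics undefined "
                        f"({exc}); left blank"
                    )
                else:
                    row.update(
                        nd_chi2=nd.chi2,
                        nd_p=nd.p_value,
                        calibration_slope=fit.coefficient,
                        slope_ci_low=fit.coefficient - _Z95 * fit.se,
                        slope_ci_high=fit.coefficient + _Z95 * fit.se,
                    )
            rows.append(row)
    return pd.DataFrame(rows)
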