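"""Validation-statistic tests with independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar

from chargeaf.validation import (
    ConvergenceError,
    calibration_table,
    categorical_nri,
    cox_fit_single,
    harrell_c,
    marker_to_risk,
    nam_dagostino,
    stratified_km,
    stratified_validation,
)
from chargeaf.followup import kaplan_meier
from chargeaf.risk import categorize_risk, score_cohort
from conftest import random_survival_fixture


# ---------------------------------------------------------------------------
# concordance


def brute_force_c(marker, times, events):
    """O(n^2) pair enumeration implementing Harrell's rules.

    Usable pairs: distinct times where the earlier is an event, plus
    tied times with exactly one event (the event counts as earlier).
    Tied markers contribute one half."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j]:
                if events[i] == events[j]:
                    continue
                first, second = (i, j) if events[i] else (j, i)
            elif times[i] < times[j]:
                if not events[i]:
                    continue
                first, second = i, j
            else:
                if not events[j]:
                    continue
                first, second = j, i
            den += 1
            if marker[first] > marker[second]:
                num += 1
            elif marker[first] == marker[second]:
                num += 0.5
    return num / den


class TestHarrellC:
    def test_perfect_ordering(self):
        times = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        marker = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = harrell_c(marker, times, np.ones(5, bool), n_bootstrap=0)
        assert res.c == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equality_small_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        marker, times, events = random_survival_fixture(rng, n)
        if not events.any():
            return
        res = harrell_c(marker, times, events, n_bootstrap=0)
        assert res.c == pytest.approx(brute_force_c(marker, times, events), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        marker, times, events = random_survival_fixture(rng, 20, tie_markers=False)
        if not events.any():
            return
        c_pos = harrell_c(marker, times, events, n_bootstrap=0).c
        c_neg = harrell_c(-marker, times, events, n_bootstrap=0).c
        assert c_pos + c_neg == pytest.approx(1.0, abs=1e-12)

    def test_independent_marker_near_half(self):
        rng = np.random.default_rng(11)
        n = 2000
        times = rng.exponential(3, n) + 0.01
        events = rng.random(n) < 0.7
        marker = rng.random(n)
        res = harrell_c(marker, times, events, n_bootstrap=0)
        assert res.c == pytest.approx(0.5, abs=0.03)

    def test_constant_marker_warns_half(self):
        with pytest.warns(UserWarning):
            res = harrell_c(
                np.ones(10), np.arange(1, 11.0), np.ones(10, bool), n_bootstrap=0
            )
        assert res.c == 0.5

    def test_no_events_error(self):
        with pytest.raises(ValueError):
            harrell_c(np.arange(5.0), np.arange(1, 6.0), np.zeros(5, bool))

    def test_bootstrap_ci_reproducible_and_covers(self):
        rng = np.random.default_rng(5)
        marker, times, events = random_survival_fixture(rng, 300, tie_markers=False)
        a = harrell_c(marker, times, events, n_bootstrap=100, seed=99)
        b = harrell_c(marker, times, events, n_bootstrap=100, seed=99)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.c <= a.ci_high


# ---------------------------------------------------------------------------
# Cox single covariate


def naive_efron_loglik(beta, x, times, events):
    """Literal Efron partial log-likelihood, loops and all."""
    ll = 0.0
    for t in sorted(set(times[events])):
        dead = np.flatnonzero((times == t) & events)
        risk = np.flatnonzero(times >= t)
        d = len(dead)
        s0_risk = np.exp(beta * x[risk]).sum()
        s0_dead = np.exp(beta * x[dead]).sum()
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= np.log(s0_risk - (l / d) * s0_dead)
    return ll


class TestCoxFit:
    def test_small_fixture_matches_grid_oracle(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 0], bool)
        fit = cox_fit_single(x, times, events)
        oracle = minimize_scalar(
            lambda b: -naive_efron_loglik(b, x, times, events),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coefficient == pytest.approx(oracle.x, abs=1e-6)
        assert fit.log_likelihood == pytest.approx(-oracle.fun, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tied_data_matches_oracle_and_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        x = rng.normal(0, 1, n)
        times = rng.integers(1, 12, n).astype(float)  # heavy quarterly-style ties
        events = rng.random(n) < 0.5
        fit = cox_fit_single(x, times, events)
        oracle = minimize_scalar(
            lambda b: -naive_efron_loglik(b, x - x.mean(), times, events),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10},
        )
        assert fit.coefficient == pytest.approx(oracle.x, abs=1e-6)

        from lifelines import CoxPHFitter

        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "T": times, "E": events}), "T", "E"
        )
        # lifelines stops at a looser tolerance than our 1e-9 Newton steps
        assert fit.coefficient == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_rescaling_halves_coefficient(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 200)
        times = rng.exponential(np.exp(-0.5 * x)) + 0.001
        events = np.ones(200, bool)
        f1 = cox_fit_single(x, times, events)
        f2 = cox_fit_single(2 * x, times, events)
        assert f2.coefficient == pytest.approx(f1.coefficient / 2, rel=1e-6)

    def test_hazard_ratio_consistency(self):
        rng = np.random.default_rng(6)
        x = (rng.random(150) < 0.5).astype(float)
        times = rng.exponential(np.exp(-x)) + 0.001
        fit = cox_fit_single(x, times, np.ones(150, bool))
        assert fit.hazard_ratio == pytest.approx(np.exp(fit.coefficient))
        assert fit.ci_low < fit.hazard_ratio < fit.ci_high
        assert fit.converged and fit.n_iter <= 50

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_fit_single(np.ones(10), np.arange(1, 11.0), np.ones(10, bool))

    def test_complete_separation_raises(self):
        # the single event has the largest covariate by far -> monotone likelihood
        x = np.array([0.0, 0.0, 0.0, 0.0, 50.0])
        times = np.array([5.0, 6.0, 7.0, 8.0, 1.0])
        events = np.array([0, 0, 0, 0, 1], bool)
        with pytest.raises(ConvergenceError):
            cox_fit_single(x, times, events)


# ---------------------------------------------------------------------------
# calibration


class TestCalibration:
    def test_equal_risks_reproduce_overall_km(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(4, 600) + 0.01
        events = rng.random(600) < 0.5
        risks = np.full(600, 0.05)
        table = calibration_table(risks, times, events, n_groups=5)
        overall = kaplan_meier(times, events)
        # each fifth of the cohort is an iid sample; predicted identical
        assert table["mean_predicted"].to_numpy() == pytest.approx(0.05)
        assert table["n"].sum() == 600

    def test_groups_ordered_and_exhaustive(self, synth_complete):
        df = synth_complete
        table = calibration_table(
            df["true_risk"].to_numpy(),
            df["time_years"].to_numpy(),
            df["event"].to_numpy(),
        )
        assert table["n"].sum() == len(df)
        assert (np.diff(table["mean_predicted"]) >= 0).all()

    def test_inflated_hazard_shows_underprediction(self):
        rng = np.random.default_rng(9)
        n = 20_000
        risks = np.clip(rng.beta(2, 30, n), 1e-4, 0.5)
        lam = -np.log1p(-risks) / 5.0
        times = np.minimum(rng.exponential(1 / (2 * lam)), 5.0)  # hazard x2
        events = times < 5.0
        times = np.maximum(times, 1e-6)
        table = calibration_table(risks, times, events)
        assert (table["observed_km"] > table["mean_predicted"]).all()

    def test_rejects_out_of_range_risks(self):
        with pytest.raises(ValueError):
            calibration_table([0.0, 0.5], [1, 2], [1, 0])


class TestNamDagostino:
    def test_perfect_calibration_gives_zero(self):
        table = pd.DataFrame(
            {"n": [100, 100], "mean_predicted": [0.1, 0.2], "observed_km": [0.1, 0.2]}
        )
        nd = nam_dagostino(table)
        assert nd.chi2 == 0.0 and nd.p_value == 1.0

    def test_two_group_hand_example(self):
        # 100*(0.05)^2/0.09 + 100*(0.05)^2/0.16 = 2.7778 + 1.5625 = 4.3403
        table = pd.DataFrame(
            {
                "n": [100, 100],
                "mean_predicted": [0.1, 0.2],
                "observed_km": [0.15, 0.25],
            }
        )
        nd = nam_dagostino(table)
        assert nd.chi2 == pytest.approx(4.3403, abs=1e-4)
        assert nd.df == 2
        classic = nam_dagostino(table, df_reduction=1)
        assert classic.df == 1
        assert classic.p_value == pytest.approx(stats.chi2.sf(4.3403, 1), abs=1e-4)

    def test_group_relabelling_invariant(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame(
            {
                "n": rng.integers(50, 200, 8),
                "mean_predicted": np.sort(rng.random(8)) * 0.3 + 0.01,
                "observed_km": rng.random(8) * 0.3,
            }
        )
        shuffled = table.sample(frac=1, random_state=0)
        assert nam_dagostino(table).chi2 == pytest.approx(
            nam_dagostino(shuffled).chi2, abs=1e-12
        )

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            nam_dagostino(
                pd.DataFrame({"n": [10], "mean_predicted": [0.1], "observed_km": [0.1]})
            )


# ---------------------------------------------------------------------------
# NRI


def closed_form_nri(risk_new, risk_ref, events, thresholds):
    """Uncensored categorical NRI from the contingency table, enumerated."""
    cn = categorize_risk(risk_new, thresholds)
    cr = categorize_risk(risk_ref, thresholds)
    up, down = cn > cr, cn < cr
    p_event = events.mean()
    ev = (up & events).mean() / p_event - (down & events).mean() / p_event
    ne = (down & ~events).mean() / (1 - p_event) - (up & ~events).mean() / (1 - p_event)
    return ev, ne


class TestNri:
    def test_self_comparison_exactly_zero(self):
        rng = np.random.default_rng(12)
        risks = rng.random(200) * 0.2 + 0.001
        times = rng.exponential(4, 200) + 0.01
        events = rng.random(200) < 0.3
        res = categorical_nri(risks, risks, times, events, n_bootstrap=50, seed=1)
        assert res.nri_overall == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_uncensored_equals_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        risk_new = rng.random(n) * 0.15 + 0.001
        risk_ref = np.clip(risk_new + rng.normal(0, 0.03, n), 1e-4, 0.9)
        events = rng.random(n) < 0.3
        if events.all() or not events.any():
            return
        # no censoring: events occur inside the horizon, the rest run out
        times = np.where(events, 2.0, 5.0)
        res = categorical_nri(
            risk_new, risk_ref, times, events, horizon=5.0, n_bootstrap=0
        )
        ev, ne = closed_form_nri(risk_new, risk_ref, events, (0.025, 0.05))
        assert res.nri_events == pytest.approx(ev, abs=1e-12)
        assert res.nri_nonevents == pytest.approx(ne, abs=1e-12)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(13)
        n = 400
        risk_new = rng.random(n) * 0.2 + 0.001
        risk_ref = rng.random(n) * 0.2 + 0.001
        times = rng.exponential(4, n) + 0.01
        events = rng.random(n) < 0.4
        res = categorical_nri(risk_new, risk_ref, times, events, n_bootstrap=0)
        assert res.nri_overall == res.nri_events + res.nri_nonevents

    def test_true_risk_beats_noisy_copy(self):
        rng = np.random.default_rng(14)
        n = 8000
        risk_true = np.clip(rng.beta(2, 30, n), 1e-4, 0.6)
        risk_noisy = np.clip(
            risk_true * np.exp(rng.normal(0, 0.8, n)), 1e-4, 0.9
        )
        events = rng.random(n) < risk_true
        times = np.where(events, rng.random(n) * 5, 5.0)
        times = np.maximum(times, 1e-6)
        res = categorical_nri(
            risk_true, risk_noisy, times, events, n_bootstrap=50, seed=2
        )
        assert res.nri_overall > 0

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(15)
        n = 300
        risk_new = rng.random(n) * 0.2 + 0.001
        risk_ref = rng.random(n) * 0.2 + 0.001
        times = rng.exponential(4, n) + 0.01
        events = rng.random(n) < 0.4
        a = categorical_nri(risk_new, risk_ref, times, events, n_bootstrap=40, seed=7)
        b = categorical_nri(risk_new, risk_ref, times, events, n_bootstrap=40, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


# ---------------------------------------------------------------------------
# comparator conversion and stratified views


class TestMarkerToRisk:
    def test_risks_valid_and_monotone(self, synth_complete):
        df = synth_complete.head(4000)
        risks = marker_to_risk(
            df["age_years"].to_numpy(),
            df["time_years"].to_numpy(),
            df["event"].to_numpy(),
        )
        assert np.all((risks > 0) & (risks < 1))
        order = np.argsort(df["age_years"].to_numpy(), kind="stable")
        assert np.all(np.diff(risks[order]) >= 0)


class TestStratified:
    def test_single_category_equals_global_km(self):
        rng = np.random.default_rng(16)
        times = rng.exponential(3, 300) + 0.01
        events = rng.random(300) < 0.5
        risks = np.full(300, 0.01)  # all low
        curves = stratified_km(risks, (0.025, 0.05), times, events)
        assert list(curves) == [0]
        global_km = kaplan_meier(times, events)
        assert curves[0].survival_at(2.0) == pytest.approx(global_km.survival_at(2.0))

    def test_strata_failure_ordered_at_horizon(self, synth_complete):
        df = synth_complete
        curves = stratified_km(
            df["generating_risk"].to_numpy(),
            (0.025, 0.05),
            df["time_years"].to_numpy(),
            df["event"].to_numpy(),
        )
        failures = [curves[c].failure_at(5.0) for c in sorted(curves)]
        assert failures == sorted(failures)

    def test_stratified_validation_shape_and_sums(self, synth_complete):
        df = score_cohort(synth_complete)
        report = stratified_validation(df, n_bootstrap=0)
        assert set(report["predictor"]) == {"charge_af", "cha2ds2vasc", "age"}
        all_rows = report[report["stratum"] == "all"]
        assert (all_rows["n"] == len(df)).all()
        men = report.query("stratum == 'men' and predictor == 'charge_af'")["n"].iloc[0]
        women = report.query("stratum == 'women' and predictor == 'charge_af'")["n"].iloc[0]
        assert men + women == len(df)
        # slope/ND populated only for the risk model itself
        assert report.query("predictor == 'age'")["calibration_slope"].isna().all()
        assert np.isfinite(
            report.query("stratum == 'all' and predictor == 'charge_af'")[
                "calibration_slope"
            ].iloc[0]
        )

    def test_small_stratum_skipped_with_warning(self, synth_complete):
        df = score_cohort(synth_complete.head(300))
        strata = {"tiny": lambda d: d["age_years"].to_numpy() > 97}
        with pytest.warns(UserWarning):
            report = stratified_validation(df, strata=strata, n_bootstrap=0)
        assert report.empty

    def test_charge_af_outperforms_age_in_event_rich_strata(self, synth_complete):
        # the full model's linear predictor is the true log-hazard, so it
        # must out-discriminate age alone wherever the c estimate is not
        # dominated by small-sample noise (strata with very few events)
        df = score_cohort(synth_complete)
        report = stratified_validation(df, n_bootstrap=0)
        rich = report[report["n_events"] >= 40]
        pivot = rich.pivot_table(
            index="stratum", columns="predictor", values="c_statistic"
        )
        assert len(pivot) >= 4
        assert (pivot["charge_af"] >= pivot["age"] - 1e-9).all()
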