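"""Discrimination, calibration and overall-fit measures."""

import itertools

import numpy as np
import pandas as pd
import pytest

import kfrisk
from kfrisk.estimators import kaplan_meier, pseudo_observations
from kfrisk.metrics import (
    bootstrap_ci,
    brier_scores,
    calibration_intercept_slope,
    calibration_table,
    harrell_c,
    oe_ratio,
    point_metrics,
    validate,
)
from kfrisk.synthetic import default_cohort_spec

from conftest import uncensored_cohort


def simulate_from_model(model, spec_seed, n=20_000, distort=None):
    """Single-cause data whose true 5-year risks are the model's predictions
    (exponential event times; administrative + dropout censoring)."""
    spec = default_cohort_spec()
    spec.n_white, spec.n_south_asian = n, 0
    spec.interactions = {}
    for hz in spec.hazards.values():
        hz.death = 0.0
    cohort = kfrisk.generate_cohort(spec, spec_seed)
    true = model.copy(
        baseline_survival_5y=float(np.exp(-5 * spec.hazards["white"].krt))
    )
    return cohort, true


def brute_force_c(pred, times, flags, horizon):
    t = np.minimum(times, horizon)
    f = np.where(times <= horizon, flags, 0)
    num = den = 0.0
    for i, j in itertools.combinations(range(len(t)), 2):
        a, b = (i, j) if t[i] < t[j] else (j, i)
        if t[a] == t[b]:
            if f[a] != f[b]:  # one event, one censored at the same time
                continue
            if f[a] == 1 and f[b] == 1:
                continue  # tied event times are not comparable in Harrell's C
            continue
        if f[a] != 1:
            continue  # earlier subject censored: not comparable
        den += 1
        if pred[a] > pred[b]:
            num += 1
        elif pred[a] == pred[b]:
            num += 0.5
    return num / den


class TestHarrellC:
    def test_perfect_discrimination(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([0.9, 0.6, 0.3, 0.1])  # higher risk -> earlier event
        assert harrell_c(pred, times, [1, 1, 1, 1], 5.0) == 1.0

    def test_null_discrimination(self):
        rng = np.random.default_rng(0)
        n = 4000
        times = rng.exponential(3, n)
        pred = rng.random(n)
        c = harrell_c(pred, times, np.ones(n, int), 5.0)
        assert c == pytest.approx(0.5, abs=0.03)

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            n = int(rng.integers(4, 11))
            times = rng.exponential(3, n)  # continuous: no tied event times
            flags = rng.integers(0, 2, n)
            pred = np.round(rng.random(n), 2)
            h = float(rng.uniform(1, 6))
            if np.sum((times <= h) & (flags == 1)) == 0:
                continue
            try:
                ours = harrell_c(pred, times, flags, h)
            except ValueError:
                continue
            oracle = brute_force_c(pred, times, flags, h)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self, kfre_model, small_cohort):
        p = np.asarray(kfrisk.predict_risk_5y(kfre_model, small_cohort))
        times = small_cohort["follow_up_time"].to_numpy()
        flags = (small_cohort["event"] == "krt").astype(int).to_numpy()
        c1 = harrell_c(p, times, flags, 5.0)
        c2 = harrell_c(np.log(p / (1 - p)), times, flags, 5.0)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_c([0.1, 0.2], [1.0, 2.0], [0, 0], 5.0)


class TestOERatio:
    def test_identity_when_predictions_match_observed(self):
        times = np.array([1.0] * 3 + [9.0] * 7)
        events = ["krt"] * 3 + ["censored"] * 7
        pred = np.full(10, 0.3)
        assert oe_ratio(pred, times, events, 5.0) == pytest.approx(1.0)

    def test_doubling_predictions_halves_ratio(self):
        times = np.array([1.0] * 3 + [9.0] * 7)
        events = ["krt"] * 3 + ["censored"] * 7
        r1 = oe_ratio(np.full(10, 0.3), times, events, 5.0)
        r2 = oe_ratio(np.full(10, 0.6), times, events, 5.0)
        assert r2 == pytest.approx(r1 / 2)

    def test_uncensored_reduction_to_proportion(self):
        rng = np.random.default_rng(2)
        n = 50
        times = rng.uniform(0.1, 4.9, n)
        events = ["krt" if u < 0.4 else "censored" for u in rng.random(n)]
        # make non-events survive past the horizon (truly uncensored design)
        times = np.where(np.array(events) == "krt", times, 6.0)
        pred = rng.uniform(0.05, 0.5, n)
        expected = np.mean(np.array(events) == "krt") / pred.mean()
        assert oe_ratio(pred, times, events, 5.0) == pytest.approx(expected)


class TestCalibrationRegression:
    def test_well_calibrated_truth(self, kfre_model):
        cohort, true = simulate_from_model(kfre_model, spec_seed=50, n=30_000)
        pm = point_metrics(true, cohort, 5.0, "km")
        assert pm["calibration_slope"] == pytest.approx(1.0, abs=0.1)
        assert pm["calibration_intercept"] == pytest.approx(0.0, abs=0.08)

    def test_doubled_lp_slope_half(self, kfre_model):
        cohort, true = simulate_from_model(kfre_model, spec_seed=51, n=30_000)
        doubled = true.copy(lp_multiplier=2.0)
        pm = point_metrics(doubled, cohort, 5.0, "km")
        assert pm["calibration_slope"] == pytest.approx(0.5, abs=0.07)

    def test_cloglog_shift_recovered_in_intercept(self, kfre_model):
        cohort, true = simulate_from_model(kfre_model, spec_seed=52, n=30_000)
        shifted = true.copy(intercept_shift=0.3)
        pm = point_metrics(shifted, cohort, 5.0, "km")
        # pseudo-observation intercepts have Monte-Carlo SD ~0.06 at n=30,000
        assert pm["calibration_intercept"] == pytest.approx(-0.3, abs=0.15)

    def test_constant_predictions_rejected(self):
        po = pseudo_observations([1.0, 2.0, 3.0], ["krt", "krt", "censored"], 5.0)
        with pytest.raises(ValueError):
            calibration_intercept_slope(np.full(3, 0.2), po)


class TestBrier:
    def test_perfect_predictions(self):
        times = np.array([1.0, 2.0, 8.0, 9.0])
        codes = np.array([1, 1, 0, 0])
        pred = np.array([1.0, 1.0, 0.0, 0.0])
        b, s = brier_scores(pred, times, codes, 5.0)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(1.0)

    def test_null_model_scaled_zero(self):
        rng = np.random.default_rng(3)
        n = 500
        times = rng.exponential(4, n)
        codes = np.where(times <= 10, 1, 0)  # fully observed to the horizon
        times = np.where(codes == 1, np.minimum(times, 9.9), 10.5)
        km = kaplan_meier(times, codes)
        null_pred = np.full(n, 1 - km(5.0))
        b, s = brier_scores(null_pred, times, codes, 5.0)
        assert s == pytest.approx(0.0, abs=1e-10)

    def test_uncensored_equals_mean_squared_error(self):
        times = np.array([1.0, 3.0, 8.0, 9.0, 2.0])
        codes = np.array([1, 1, 0, 0, 1])
        times = np.where(codes == 1, times, 10.0)  # survivors observed past 5
        pred = np.array([0.8, 0.3, 0.2, 0.1, 0.6])
        o = ((codes == 1) & (times <= 5)).astype(float)
        b, _ = brier_scores(pred, times, codes, 5.0)
        assert b == pytest.approx(np.mean((pred - o) ** 2))


class TestBootstrapCI:
    def test_constant_statistic_zero_width(self, small_cohort):
        lo, hi, dropped = bootstrap_ci(lambda d: 0.42, small_cohort,
                                       n_bootstrap=100, seed=1)
        assert lo == hi == 0.42
        assert dropped == 0

    def test_sample_mean_width_matches_theory(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame({"x": rng.normal(0, 1, 10_000)})
        lo, hi, _ = bootstrap_ci(lambda d: d["x"].mean(), data,
                                 n_bootstrap=400, seed=2, stratum_col=None)
        width = hi - lo
        assert width == pytest.approx(3.92 / np.sqrt(10_000), rel=0.10)

    def test_deterministic_under_seed(self, small_cohort):
        f = lambda d: d["age"].mean()
        a = bootstrap_ci(f, small_cohort, n_bootstrap=100, seed=7)
        b = bootstrap_ci(f, small_cohort, n_bootstrap=100, seed=7)
        assert a == b


class TestCalibrationTable:
    def test_deciles_partition_equally(self):
        rng = np.random.default_rng(5)
        pred = rng.random(100)
        times = rng.exponential(3, 100)
        events = np.where(times < 5, "krt", "censored")
        tab = calibration_table(pred, times, events, 5.0, n_bootstrap=0).table
        assert (tab["n"] == 10).all()
        assert tab["n"].sum() == 100

    def test_group_observed_matches_stratified_km(self):
        rng = np.random.default_rng(6)
        n = 200
        pred = rng.random(n)
        times = rng.exponential(3, n)
        flags = rng.integers(0, 2, n)
        events = np.where(flags == 1, "krt", "censored")
        tab = calibration_table(pred, times, events, 5.0, n_bootstrap=0).table
        order = np.argsort(pred, kind="mergesort")
        ranks = np.empty(n, int)
        ranks[order] = np.arange(n)
        groups = (ranks * 10) // n + 1
        for g in range(1, 11):
            mask = groups == g
            km = kaplan_meier(times[mask], flags[mask])
            expected = 1 - km(5.0)
            row = tab[tab["group"] == g].iloc[0]
            assert row["observed"] == pytest.approx(expected, abs=1e-12)

    def test_fixed_groups_report_empty_groups(self):
        pred = np.full(30, 0.01)  # everyone in group 1
        times = np.full(30, 6.0)
        events = ["censored"] * 30
        tab = calibration_table(pred, times, events, 5.0,
                                grouping="fixed_risk_groups", n_bootstrap=0).table
        assert len(tab) == 6
        assert tab[tab["group"] == 6]["n"].iloc[0] == 0


class TestValidate:
    def test_km_view_observed_risk_dominates_aj_view(self, kfre_model, small_cohort):
        """With competing deaths, the KM-complement observed risk is never
        below the Aalen-Johansen CIF, so O/E (KM) >= O/E (AJ)."""
        p = np.asarray(kfrisk.predict_risk_5y(kfre_model, small_cohort))
        times = small_cohort["follow_up_time"].to_numpy()
        events = small_cohort["event"].to_numpy()
        oe_km = oe_ratio(p, times, events, 5.0, view="km")
        oe_aj = oe_ratio(p, times, events, 5.0, view="aj")
        assert oe_km >= oe_aj

    def test_report_complete_with_finite_cis(self, kfre_model, small_cohort):
        rep = validate(kfre_model, small_cohort, n_bootstrap=30, seed=5)
        for name, vals in rep.metrics.items():
            assert np.isfinite(vals["estimate"]), name
            assert np.isfinite(vals["ci_lower"]) and np.isfinite(vals["ci_upper"])
            assert vals["ci_lower"] <= vals["estimate"] <= vals["ci_upper"]
        assert 0 <= rep.metrics["c_index"]["estimate"] <= 1
        assert rep.metrics["brier"]["estimate"] >= 0

    def test_deterministic_under_seed(self, kfre_model, small_cohort):
        a = validate(kfre_model, small_cohort, n_bootstrap=10, seed=8)
        b = validate(kfre_model, small_cohort, n_bootstrap=10, seed=8)
        assert a.metrics == b.metrics
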