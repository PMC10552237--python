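"""Model fitting and the updating ladder (methods 1-6)."""

import numpy as np
import pandas as pd
import pytest

import kfrisk
from kfrisk.phreg import cox_newton_raphson, fine_gray_newton_raphson
from kfrisk.synthetic import StratumHazards, default_cohort_spec
from kfrisk.updating import (
    add_predictor,
    apply_shrinkage,
    fit_cox,
    fit_fine_gray,
    internal_validate,
    observed_risk,
    recalibrate_slope,
    select_interactions,
    update_baseline,
)

from conftest import uncensored_cohort


def binary_covariate_cohort(n, log_hr, seed, censor_at=8.0):
    """Exponential survival with a single binary covariate of known log-HR."""
    rng = np.random.default_rng(seed)
    sex = rng.integers(0, 2, n)
    rate = 0.1 * np.exp(log_hr * sex)
    t = rng.exponential(1.0 / rate)
    times = np.minimum(t, censor_at)
    events = np.where(t <= censor_at, "krt", "censored")
    return uncensored_cohort(times, events, sex=np.where(sex == 1, "male", "female"))


class TestCoxSolver:
    def test_parameter_recovery_known_log_hr(self):
        cohort = binary_covariate_cohort(20_000, 0.7, seed=101)
        model = fit_cox(cohort, predictors=("sex",))
        assert model.coefficients["sex"] == pytest.approx(0.7, abs=0.05)

    def test_score_zero_at_optimum(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 2))
        t = rng.exponential(1 / (0.1 * np.exp(X @ [0.4, -0.2])))
        fit = cox_newton_raphson(X, t, np.ones(500, int))
        assert np.max(np.abs(fit.score)) < 1e-6

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(2)
        X = rng.normal(size=(800, 2))
        t = np.round(rng.exponential(1 / (0.2 * np.exp(X @ [0.5, -0.3]))), 1) + 0.1
        c = rng.exponential(6, 800)
        times, flags = np.minimum(t, c), (t <= c).astype(int)
        fit = cox_newton_raphson(X, times, flags)  # Efron, as lifelines
        df = pd.DataFrame(X, columns=["a", "b"]).assign(T=times, E=flags)
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.beta, cph.params_.to_numpy(), atol=1e-5)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-5)

    def test_null_covariate_z_statistics(self):
        """A covariate unrelated to outcome has |z| < 4 in >= 95 of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.normal(size=(n, 1))
            t = rng.exponential(5.0, n)
            fit = cox_newton_raphson(x, t, np.ones(n, int))
            z = abs(fit.beta[0] / fit.se[0])
            hits += z < 4
        assert hits >= 95

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_newton_raphson(np.ones((50, 1)), np.arange(1, 51.0), np.ones(50, int))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_newton_raphson(
                np.random.default_rng(0).normal(size=(10, 1)),
                np.arange(1, 11.0),
                np.zeros(10, int),
            )


class TestUpdateBaseline:
    def test_calibrated_model_shift_near_zero(self, kfre_model):
        spec = default_cohort_spec()
        spec.n_white, spec.n_south_asian = 30_000, 0
        spec.interactions = {}
        for hz in spec.hazards.values():
            hz.death = 0.0
        cohort = kfrisk.generate_cohort(spec, 11)
        true = kfre_model.copy(
            baseline_survival_5y=float(np.exp(-5 * spec.hazards["white"].krt))
        )
        res = update_baseline(true, cohort)
        assert res.method == 2
        assert abs(res.model.intercept_shift) < 0.1

    def test_doubled_predictions_restored_to_oe_one(self, kfre_model, small_cohort):
        # construct a model predicting roughly double the observed risk
        miscal = kfre_model.copy(
            baseline_survival_5y=kfre_model.baseline_survival_5y ** 3
        )
        res = update_baseline(miscal, small_cohort)
        p = kfrisk.predict_risk_5y(res.model, small_cohort)
        obs = observed_risk(small_cohort, 5.0, "km")
        assert obs / p.mean() == pytest.approx(1.0, abs=0.02)

    def test_coefficients_untouched(self, kfre_model, small_cohort):
        res = update_baseline(kfre_model, small_cohort)
        assert res.model.coefficients == kfre_model.coefficients

    def test_stratified_updates_differ(self, kfre_model, small_cohort):
        white = small_cohort[small_cohort["ethnicity"] == "white"]
        sa = small_cohort[small_cohort["ethnicity"] == "south_asian"]
        m2a = update_baseline(kfre_model, white).model
        m2b = update_baseline(kfre_model, sa).model
        assert m2a.intercept_shift != m2b.intercept_shift


class TestRecalibrateSlope:
    def test_self_consistency_multiplier_near_one(self, kfre_model):
        spec = default_cohort_spec()
        spec.n_white, spec.n_south_asian = 30_000, 0
        spec.interactions = {}
        for hz in spec.hazards.values():
            hz.death = 0.0
        cohort = kfrisk.generate_cohort(spec, 12)
        true = kfre_model.copy(
            baseline_survival_5y=float(np.exp(-5 * spec.hazards["white"].krt))
        )
        res = recalibrate_slope(true, cohort)
        assert res.model.lp_multiplier == pytest.approx(1.0, abs=0.05)

    def test_halved_lp_recovered(self, kfre_model):
        spec = default_cohort_spec()
        spec.n_white, spec.n_south_asian = 30_000, 0
        spec.interactions = {}
        for hz in spec.hazards.values():
            hz.death = 0.0
        cohort = kfrisk.generate_cohort(spec, 13)
        halved = kfre_model.copy(lp_multiplier=2.0)  # predictions too extreme
        res = recalibrate_slope(halved, cohort)
        # the one-covariate Cox slope on a doubled LP is ~0.5
        assert res.model.meta["lp_slope"] == pytest.approx(0.5, abs=0.05)

    def test_constant_lp_rejected(self, kfre_model, small_cohort):
        flat = kfre_model.copy(coefficients={k: 0.0 for k in kfre_model.coefficients})
        with pytest.raises(ValueError):
            recalibrate_slope(flat, small_cohort)


class TestAddPredictor:
    def test_null_predictor_coefficient_near_zero(self, kfre_model):
        spec = default_cohort_spec()
        spec.n_white, spec.n_south_asian = 15_000, 15_000
        spec.interactions = {}
        # identical hazards across strata: ethnicity carries no signal
        spec.hazards["south_asian"] = StratumHazards(
            krt=spec.hazards["white"].krt, death=spec.hazards["white"].death
        )
        spec.covariates["south_asian"] = spec.covariates["white"]
        cohort = kfrisk.generate_cohort(spec, 14)
        res = add_predictor(kfre_model, cohort, "ethnicity")
        assert abs(res.model.coefficients["ethnicity"]) < 0.15

    def test_true_ethnicity_effect_recovered(self, kfre_model):
        """A true ethnicity log-HR of 0.48 baked into the KRT baseline ratio
        is recovered by the offset fit at n=30,000 (averaged over seeds; the
        per-seed Monte-Carlo SE is ~0.09)."""
        estimates = []
        for seed in range(15, 21):
            spec = default_cohort_spec()
            spec.n_white, spec.n_south_asian = 15_000, 15_000
            spec.interactions = {}
            spec.hazards["south_asian"] = StratumHazards(
                krt=spec.hazards["white"].krt * float(np.exp(0.48)),
                death=spec.hazards["white"].death,
            )
            cohort = kfrisk.generate_cohort(spec, seed)
            res = add_predictor(kfre_model, cohort, "ethnicity")
            estimates.append(res.model.coefficients["ethnicity"])
        assert np.mean(estimates) == pytest.approx(0.48, abs=0.1)

    def test_offset_coefficients_untouched(self, kfre_model, small_cohort):
        res = add_predictor(kfre_model, small_cohort, "ethnicity")
        for k, v in kfre_model.coefficients.items():
            assert res.model.coefficients[k] == v


class TestSelectInteractions:
    def test_lrt_statistic_is_twice_loglik_difference(self, small_cohort):
        res = select_interactions(small_cohort, candidates=("ethnicity:acr",))
        base = fit_cox(small_cohort)
        trial = fit_cox(small_cohort, interactions=("ethnicity:acr",))
        expected = 2 * (trial.meta["loglik"] - base.meta["loglik"])
        assert res.lrt_records[0]["statistic"] == pytest.approx(expected, abs=1e-8)

    def test_audit_records_cover_all_candidates(self, small_cohort):
        res = select_interactions(small_cohort)
        assert [r["interaction"] for r in res.lrt_records] == [
            "ethnicity:age", "ethnicity:sex", "ethnicity:egfr", "ethnicity:acr",
        ]
        for rec in res.lrt_records:
            assert 0 <= rec["p_value"] <= 1


class TestFineGray:
    def test_reduces_to_cox_single_cause_uncensored(self):
        rng = np.random.default_rng(21)
        n = 400
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1 / (0.3 * np.exp(X @ [0.5, -0.2])))
        cox = cox_newton_raphson(X, t, np.ones(n, int), ties="breslow")
        fg = fine_gray_newton_raphson(X, t, np.ones(n, int))
        np.testing.assert_allclose(fg.beta, cox.beta, atol=1e-6)

    def test_tiny_fixture_matches_independent_oracle(self):
        """Eight-subject fixture: the optimum agrees with R cmprsk::crr (to
        its tolerance) and with a brute-force grid maximisation."""
        times = np.array([0.5, 1.2, 1.7, 2.3, 2.9, 3.4, 4.1, 4.8])
        codes = np.array([1, 2, 0, 1, 2, 1, 0, 1])
        x = np.array([0.8, -0.4, 1.1, 0.2, -0.9, 1.5, -0.3, 0.6])
        fit = fine_gray_newton_raphson(x[:, None], times, codes)
        assert fit.beta[0] == pytest.approx(1.1371673819, abs=1e-4)  # crr
        assert fit.beta[0] == pytest.approx(1.137, abs=5e-4)  # grid search

    def test_fit_fine_gray_on_cohort(self, small_cohort):
        model = fit_fine_gray(small_cohort, predictors=("age", "sex", "egfr", "acr"))
        assert model.family == "fine_gray"
        assert 0 < model.baseline_survival_5y < 1
        risks = kfrisk.predict_risk_5y(model, small_cohort)
        assert np.all((risks >= 0) & (risks <= 1))


class TestShrinkage:
    def test_identity_factor(self, kfre_model):
        out = apply_shrinkage(kfre_model, 1.0)
        assert out.lp_multiplier == kfre_model.lp_multiplier
        assert not out.baseline_stale

    def test_published_factor_scales_lp(self, kfre_model, small_cohort):
        out = apply_shrinkage(kfre_model, 1.015)
        lp0 = kfrisk.linear_predictor(kfre_model, small_cohort)
        lp1 = kfrisk.linear_predictor(out, small_cohort)
        np.testing.assert_allclose(lp1, lp0 * 1.015, rtol=1e-12)

    def test_stale_baseline_blocks_prediction(self, kfre_model, small_cohort):
        out = apply_shrinkage(kfre_model, 1.1)
        with pytest.raises(kfrisk.core.InvalidModelError, match="stale"):
            kfrisk.predict_risk_5y(out, small_cohort)
        refreshed = update_baseline(out, small_cohort).model
        kfrisk.predict_risk_5y(refreshed, small_cohort)  # no raise

    def test_nonpositive_factor_rejected(self, kfre_model):
        with pytest.raises(ValueError):
            apply_shrinkage(kfre_model, 0.0)


class TestInternalValidate:
    @staticmethod
    def _simple_metric(model, data):
        p = np.asarray(kfrisk.predict_risk_5y(model, data))
        return {"mean_risk": float(p.mean())}

    def test_adjusted_equals_apparent_minus_optimism(self, kfre_model, small_cohort):
        rep = internal_validate(
            lambda d: kfre_model, self._simple_metric, small_cohort,
            n_bootstrap=20, seed=3,
        )
        m = rep.metrics["mean_risk"]
        assert m["optimism_adjusted"] == pytest.approx(
            m["apparent"] - m["optimism"], abs=1e-12
        )

    def test_reproducible_under_seed(self, kfre_model, small_cohort):
        kwargs = dict(n_bootstrap=10, seed=9)
        a = internal_validate(lambda d: kfre_model, self._simple_metric,
                              small_cohort, **kwargs)
        b = internal_validate(lambda d: kfre_model, self._simple_metric,
                              small_cohort, **kwargs)
        assert a.metrics == b.metrics

    def test_overfitted_cox_has_positive_slope_optimism(self):
        """An overparameterised Cox on few events shows calibration-slope
        optimism > 0 (predictions too extreme out of sample)."""
        from kfrisk.metrics import point_metrics

        spec = default_cohort_spec()
        spec.n_white, spec.n_south_asian = 200, 200
        spec.interactions = {}
        for hz in spec.hazards.values():
            hz.krt *= 4.0  # enough events to fit at n=400
            hz.death = 0.0
        cohort = kfrisk.generate_cohort(spec, 33)

        def fit_fn(data):
            return fit_cox(
                data,
                predictors=("age", "sex", "egfr", "acr", "ethnicity"),
                interactions=("ethnicity:age", "ethnicity:egfr", "ethnicity:acr"),
            )

        def metric_fn(model, data):
            pm = point_metrics(model, data, 5.0, "km")
            return {"calibration_slope": pm["calibration_slope"]}

        rep = internal_validate(fit_fn, metric_fn, cohort, n_bootstrap=40, seed=17)
        assert rep.metrics["calibration_slope"]["optimism"] > 0
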