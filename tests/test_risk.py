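import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from rccpsa.risk import (
    PUBLISHED_RCC_R_MODEL,
    RiskError,
    RiskGroups,
    aic,
    as_survival_frame,
    assign_risk_group,
    compare_models_cv,
    compare_nested_models,
    efron_loglik,
    efron_null_loglik,
    find_risk_cutpoints,
    fit_cox_score_model,
    hazard_ratio,
    holm_adjust,
    km_logrank,
    prognostic_index,
)
from rccpsa.synthetic import SimulationConfig, simulate_survival


class TestPrognosticIndex:
    @pytest.mark.parametrize(
        "c, expected",
        [(0.0, -1.46), (1.0, 0.00), (0.5, 1.05625)],
    )
    def test_published_coefficients(self, c, expected):
        assert prognostic_index(c) == pytest.approx(expected, abs=1e-9)

    def test_interior_maximum_marks_mixed_tumors(self):
        grid = np.linspace(0, 1, 10001)
        pi = prognostic_index(grid)
        argmax = grid[np.argmax(pi)]
        assert 0.3 < argmax < 0.5
        assert prognostic_index(1.0) > prognostic_index(0.0)

    @pytest.mark.parametrize("bad", [-0.01, 1.01, np.nan])
    def test_domain_error(self, bad):
        with pytest.raises(RiskError, match="proportion"):
            prognostic_index(bad)


class TestHazardRatio:
    @pytest.mark.parametrize(
        "pi, expected", [(0.0, 1.0), (np.log(2), 2.0), (-1.46, np.exp(-1.46))]
    )
    def test_exponentiates(self, pi, expected):
        assert hazard_ratio(pi) == pytest.approx(expected, rel=1e-12)

    def test_self_reference_is_one(self):
        for pi in (-2.0, 0.0, 3.7):
            assert hazard_ratio(pi, pi) == 1.0


class TestHolmAdjust:
    def test_hand_computed_examples(self):
        assert np.allclose(holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04])
        assert np.allclose(holm_adjust([0.5, 0.9]), [1.0, 1.0])
        assert np.allclose(holm_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_statsmodels_and_dominates_input(self, pvals):
        from statsmodels.stats.multitest import multipletests

        mine = holm_adjust(pvals)
        ref = multipletests(pvals, method="holm")[1]
        assert np.allclose(mine, ref, atol=1e-12)
        assert np.all(mine >= np.asarray(pvals) - 1e-15)
        assert np.all(mine <= 1.0)


class TestEfronLoglik:
    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 300
        x = rng.normal(0, 1, n)
        time = np.round(rng.exponential(1 / np.exp(0.5 * x)), 1)  # many ties
        event = (rng.random(n) < 0.7).astype(int)
        df = pd.DataFrame({"x": x, "time": time, "event": event})
        cph = CoxPHFitter().fit(df, "time", "event")
        mine = efron_loglik(x * cph.params_["x"], time, event)
        assert mine == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_null_loglik_closed_form(self):
        # distinct event times, no censoring: ll = -sum log(n..1) = -log(n!)
        time = np.arange(1.0, 6.0)
        event = np.ones(5, dtype=int)
        assert efron_null_loglik(time, event) == pytest.approx(-np.log(np.prod(np.arange(1, 6))))


class TestFitCoxScoreModel:
    def test_brute_force_partial_likelihood_agreement(self):
        """1-covariate toy: the fitted slope maximizes my own Efron partial
        likelihood (checked by scalar optimization, independent of lifelines)."""
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 10)
        time = rng.exponential(1 / np.exp(0.8 * x))
        surv = pd.DataFrame({"time": time, "event": 1})
        model = fit_cox_score_model((x - x.min()) / np.ptp(x), "linear", surv, min_events=1)
        z = (x - x.min()) / np.ptp(x)
        res = minimize_scalar(
            lambda b: -efron_loglik(b * z, time, np.ones(10, int)),
            bounds=(-50, 50), method="bounded",
            options={"xatol": 1e-8},
        )
        assert model.coefficients[0] == pytest.approx(res.x, abs=1e-3)

    def test_recovers_generating_cubic_single_seed(self):
        cfg = SimulationConfig(seed=3, n_samples=800, censoring_rate=0.3)
        rng = np.random.default_rng(11)
        c = rng.uniform(0, 1, 800)
        surv = simulate_survival(c, cfg)
        model = fit_cox_score_model(c, "cubic_polynomial", surv)
        for beta, truth, se in zip(
            model.coefficients, (14.71, -25.46, 12.21), model.standard_errors
        ):
            assert abs(beta - truth) <= 2 * se

    def test_null_data_gives_null_coefficients(self):
        rng = np.random.default_rng(13)
        n = 500
        c = rng.uniform(0, 1, n)
        surv = pd.DataFrame({"time": rng.exponential(5, n), "event": rng.random(n) < 0.7})
        model = fit_cox_score_model(c, "cubic_polynomial", surv.astype({"event": int}))
        for beta, se in zip(model.coefficients[:3], model.standard_errors):
            assert abs(beta) <= 2.5 * se

    def test_all_censored_rejected(self):
        surv = pd.DataFrame({"time": np.arange(1.0, 21.0), "event": 0})
        with pytest.raises(RiskError, match="no events"):
            fit_cox_score_model(np.linspace(0, 1, 20), "cubic_polynomial", surv)

    def test_fitted_pi_is_centered(self):
        cfg = SimulationConfig(seed=2, n_samples=300)
        rng = np.random.default_rng(2)
        c = rng.uniform(0, 1, 300)
        surv = simulate_survival(c, cfg)
        model = fit_cox_score_model(c, "restricted_cubic_spline", surv, knots=4)
        assert model.predict_pi(c).mean() == pytest.approx(0.0, abs=1e-9)
        assert len(model.knots) == 4
        assert np.all(np.diff(model.knots) > 0)


class TestCompareModels:
    def _sim(self, seed, n=400):
        cfg = SimulationConfig(seed=seed, n_samples=n)
        rng = np.random.default_rng([seed, 1])
        c = rng.uniform(0, 1, n)
        return c, simulate_survival(c, cfg)

    def test_true_cubic_beats_null_on_all_criteria(self):
        wins = 0
        for seed in range(5):
            c, surv = self._sim(seed)
            table = compare_models_cv(
                [{"name": "cubic", "form": "cubic_polynomial"}, {"name": "null", "form": "null"}],
                surv, folds=10, repeats=1, seed=seed, default_scores=c,
            )
            better = (
                table.loc["cubic", "cv_loglik"] > table.loc["null", "cv_loglik"]
                and table.loc["cubic", "cv_cindex"] > table.loc["null", "cv_cindex"]
                and table.loc["cubic", "aic"] < table.loc["null", "aic"]
            )
            wins += better
        assert wins >= 4

    def test_identical_specs_identical_metrics(self):
        c, surv = self._sim(7)
        table = compare_models_cv(
            [{"name": "a", "form": "cubic_polynomial"}, {"name": "b", "form": "cubic_polynomial"}],
            surv, folds=5, repeats=1, seed=3, default_scores=c,
        )
        assert table.loc["a"].drop("rank").equals(table.loc["b"].drop("rank"))

    def test_leave_one_out_boundary(self):
        rng = np.random.default_rng(1)
        n = 25
        c = rng.uniform(0, 1, n)
        surv = pd.DataFrame({"time": rng.exponential(2, n), "event": 1})
        table = compare_models_cv(
            [{"name": "linear", "form": "linear"}],
            surv, folds=n, repeats=1, seed=0, default_scores=c,
        )
        assert np.isfinite(table.loc["linear", "aic"])

    def test_nested_identical_models(self):
        c, surv = self._sim(2)
        m = fit_cox_score_model(c, "cubic_polynomial", surv)
        stat, df, p = compare_nested_models(m, m)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_nested_null_vs_cubic_df_and_power(self):
        significant = 0
        for seed in range(20):
            c, surv = self._sim(seed, n=800)
            null = fit_cox_score_model(c, "null", surv)
            cubic = fit_cox_score_model(c, "cubic_polynomial", surv)
            stat, df, p = compare_nested_models(null, cubic)
            assert df == 3  # the constant is not a partial-likelihood parameter
            significant += p < 0.01
        assert significant >= 18

    def test_non_nested_rejected(self):
        c, surv = self._sim(4)
        cubic = fit_cox_score_model(c, "cubic_polynomial", surv)
        rcs = fit_cox_score_model(c, "restricted_cubic_spline", surv)
        with pytest.raises(RiskError, match="not nested"):
            compare_nested_models(cubic, rcs)


class TestRiskCutpoints:
    @staticmethod
    def _three_strata(seed, n=600):
        rng = np.random.default_rng([seed, 7])
        pi = rng.uniform(0, 3, n)
        hr = np.where(pi <= 1, 1.0, np.where(pi <= 2, 4.0, 10.0))
        event_time = rng.exponential(1 / (0.1 * hr))
        censor = rng.uniform(0, 30, n)
        surv = pd.DataFrame(
            {"time": np.minimum(event_time, censor), "event": (event_time <= censor).astype(int)}
        )
        return pi, surv

    def test_recovers_three_strata_single_seed(self):
        pi, surv = self._three_strata(0)
        groups = find_risk_cutpoints(pi, surv)
        assert len(groups.cutpoints) == 2
        assert groups.labels == ("good", "intermediate", "poor")
        assert abs(groups.cutpoints[0] - 1.0) < 0.3
        assert abs(groups.cutpoints[1] - 2.0) < 0.3
        assert groups.hazard_ratios["poor"] > groups.hazard_ratios["intermediate"] > 1.0

    def test_independent_survival_yields_single_flagged_group(self):
        rng = np.random.default_rng(3)
        n = 300
        pi = rng.uniform(0, 3, n)
        surv = pd.DataFrame({"time": rng.exponential(5, n), "event": (rng.random(n) < 0.5).astype(int)})
        groups = find_risk_cutpoints(pi, surv)
        assert groups.flagged
        assert groups.cutpoints == ()
        assert groups.group_sizes == {"good": n}

    def test_assign_risk_group_boundaries(self):
        groups = RiskGroups(
            cutpoints=(0.0, 1.0),
            interval_labels=("good", "intermediate", "poor"),
            labels=("good", "intermediate", "poor"),
            group_sizes={"good": 1, "intermediate": 1, "poor": 1},
            hazard_ratios={"good": 1.0, "intermediate": 3.0, "poor": 9.0},
        )
        assert assign_risk_group(-0.5, groups) == "good"
        assert assign_risk_group(0.0, groups) == "good"  # boundary -> lower risk
        assert assign_risk_group(0.5, groups) == "intermediate"
        assert assign_risk_group(1.0, groups) == "intermediate"
        assert assign_risk_group(2.0, groups) == "poor"


class TestKMLogrank:
    def test_km_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(2, 80)
        surv = pd.DataFrame({"time": np.concatenate([times, times * 3]),
                             "event": 1})
        labels = ["a"] * 80 + ["b"] * 80
        result = km_logrank(labels, surv)
        curve = result.curves["a"]
        for t in [0.5, 1.0, 2.0]:
            km_at_t = curve.loc[curve.index <= t, "survival"].iloc[-1]
            assert km_at_t == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_type_one_error_calibration(self):
        """Two identical exponential arms: log-rank rejects at ~5%."""
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 400
        labels = np.array(["a"] * 100 + ["b"] * 100)
        for _ in range(reps):
            surv = pd.DataFrame({"time": rng.exponential(2, 200), "event": 1})
            if km_logrank(labels, surv).p_value < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) < 0.025

    def test_power_for_threefold_hazard(self):
        rng = np.random.default_rng(18)
        labels = np.array(["a"] * 200 + ["b"] * 200)
        hits = 0
        reps = 100
        for _ in range(reps):
            t_a = rng.exponential(3, 200)
            t_b = rng.exponential(1, 200)  # hazard 3x
            surv = pd.DataFrame({"time": np.concatenate([t_a, t_b]), "event": 1})
            hits += km_logrank(labels, surv).p_value < 0.001
        assert hits >= 95

    def test_hazard_ratios_versus_reference(self):
        rng = np.random.default_rng(19)
        labels = np.array(["a"] * 300 + ["b"] * 300)
        surv = pd.DataFrame(
            {"time": np.concatenate([rng.exponential(3, 300), rng.exponential(1, 300)]),
             "event": 1}
        )
        result = km_logrank(labels, surv, reference="a")
        assert result.hazard_ratios["a"] == 1.0
        assert result.hazard_ratios["b"] == pytest.approx(3.0, rel=0.25)

    def test_two_singleton_groups_run(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        result = km_logrank(["a", "b"], surv)
        assert np.isfinite(result.statistic)
        assert result.curves["a"]["survival"].iloc[-1] == 0.0

    def test_single_group_raises_but_returns_curves(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 0, 1]})
        with pytest.raises(RiskError, match="2 non-empty groups") as excinfo:
            km_logrank(["a", "a", "a"], surv)
        assert "a" in excinfo.value.curves


class TestSurvivalFrame:
    def test_validation(self):
        with pytest.raises(RiskError, match="non-negative"):
            as_survival_frame(pd.DataFrame({"time": [-1.0], "event": [1]}))
        with pytest.raises(RiskError, match="0 or 1"):
            as_survival_frame(pd.DataFrame({"time": [1.0], "event": [2]}))
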