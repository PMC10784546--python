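import numpy as np
import pandas as pd
import pytest

from glycophen.causal import (
    AnalysisResult,
    CausalTask,
    EffectEstimate,
    check_balance,
    estimate_effect,
    propensity_weights_categorical,
    propensity_weights_continuous,
    run_study_analyses,
    weighted_pearson,
    _weighted_smd,
)
from glycophen.synthetic_data import DailyOutcomeConfig, simulate_daily_outcome_cohort


def independent_table(n=400, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "participant_id": np.repeat([f"P{i}" for i in range(n // 10)], 10),
            "t": rng.normal(5, 2, n),
            "x1": rng.normal(0, 1, n),
            "x2": rng.normal(10, 3, n),
            "y": rng.normal(0, 1, n),
        }
    )


class TestContinuousWeights:
    task = CausalTask("t", "continuous", ["x1", "x2"], "y")

    def test_near_one_under_independence(self):
        # Monte-Carlo under independence: stabilized weights concentrate at 1
        cvs = []
        for seed in range(10):
            table = independent_table(seed=seed)
            weights, info = propensity_weights_continuous(table, self.task)
            assert not info.fallback_fixed_effects
            cvs.append(weights.std() / weights.mean())
        assert np.median(cvs) < 0.1

    def test_degenerate_treatment_handled_by_truncation(self):
        table = independent_table()
        table["t"] = 2.0 * table["x1"] + 3.0 * table["x2"]  # perfectly predicted
        weights, info = propensity_weights_continuous(table, self.task)
        assert np.all(np.isfinite(weights)) and np.all(weights > 0)
        assert info.n_truncated > 0

    def test_deterministic(self):
        table, _ = simulate_daily_outcome_cohort(DailyOutcomeConfig(rng_seed=5))
        task = CausalTask(
            "daily_steps_k", "continuous",
            ["baseline_glucose", "elevated_count", "duration"], "tir",
        )
        w1, _ = propensity_weights_continuous(table, task)
        w2, _ = propensity_weights_continuous(table, task)
        np.testing.assert_array_equal(w1, w2)


class TestCategoricalWeights:
    def test_uninformative_covariates_give_marginal_weights(self):
        rng = np.random.default_rng(3)
        n = 1200
        table = pd.DataFrame(
            {
                "participant_id": np.repeat([f"P{i}" for i in range(40)], n // 40),
                "t": rng.integers(0, 3, n),
                "x1": rng.normal(0, 1, n),
                "y": rng.normal(0, 1, n),
            }
        )
        task = CausalTask("t", "categorical", ["x1"], "y")
        # unstabilized: weight ~ 1/marginal share, same within category
        weights, _ = propensity_weights_categorical(table, task, stabilized=False, truncate=False)
        shares = table["t"].value_counts(normalize=True)
        for cat in (0, 1, 2):
            got = weights[table["t"] == cat]
            assert np.allclose(got, got.mean(), rtol=0.2)
            assert got.mean() == pytest.approx(1 / shares[cat], rel=0.1)
        # stabilized: everything near 1
        weights, _ = propensity_weights_categorical(table, task, stabilized=True, truncate=False)
        assert np.allclose(weights, 1.0, atol=0.25)

    def test_single_category_raises(self):
        table = independent_table()
        table["t"] = 1
        with pytest.raises(ValueError, match="single category"):
            propensity_weights_categorical(table, CausalTask("t", "categorical", ["x1"], "y"))

    def test_rare_category_flagged(self):
        table = independent_table(n=60)
        table["t"] = np.r_[np.zeros(59), [1]]
        weights, info = propensity_weights_categorical(
            table, CausalTask("t", "categorical", ["x1"], "y"))
        assert "1" in info.note
        assert np.all(np.isfinite(weights))


class TestBalance:
    def test_hand_computed_smd(self):
        # groups A = (1,2,3), B = (4,5,6); sd = 1 in each, pooled sd = 1
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        assert _weighted_smd(x, g, np.ones(6)) == pytest.approx(3.0)
        # weights (1,1,2) on A pull its weighted mean to 2.25
        w = np.array([1.0, 1.0, 2.0, 1.0, 1.0, 1.0])
        assert _weighted_smd(x, g, w) == pytest.approx(2.75)

    def test_weighted_pearson_equal_weights_matches_numpy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=200), rng.normal(size=200)
        assert weighted_pearson(x, y, np.ones(200)) == pytest.approx(
            np.corrcoef(x, y)[0, 1]
        )

    def test_independent_passes_unweighted(self):
        table = independent_table()
        task = CausalTask("t", "continuous", ["x1", "x2"], "y")
        report = check_balance(table, task, np.ones(len(table)))
        assert report.passed and report.passed_before

    def test_confounded_fails_before_passes_after(self):
        table, _ = simulate_daily_outcome_cohort(DailyOutcomeConfig(rng_seed=0))
        task = CausalTask(
            "daily_steps_k", "continuous",
            ["baseline_glucose", "elevated_count", "duration"], "tir",
        )
        weights, _ = propensity_weights_continuous(table, task)
        report = check_balance(table, task, weights)
        assert not report.passed_before
        assert report.passed

    def test_zero_variance_covariate_excluded(self):
        table = independent_table()
        table["x1"] = 3.0
        task = CausalTask("t", "continuous", ["x1", "x2"], "y")
        report = check_balance(table, task, np.ones(len(table)))
        assert report.excluded == ["x1"]
        assert "x1" not in report.after


class TestEstimateEffect:
    def test_unit_weights_match_no_weights_exactly(self):
        table, _ = simulate_daily_outcome_cohort(DailyOutcomeConfig(rng_seed=1))
        task = CausalTask(
            "daily_steps_k", "continuous",
            ["baseline_glucose", "elevated_count", "duration"], "tir",
        )
        a = estimate_effect(table, task, None, doubly_robust=True)
        b = estimate_effect(table, task, np.ones(len(table)), doubly_robust=True)
        assert a[0].estimate == pytest.approx(b[0].estimate, rel=1e-12)
        assert a[0].se == pytest.approx(b[0].se, rel=1e-12)

    def test_scale_equivariance(self):
        table, _ = simulate_daily_outcome_cohort(DailyOutcomeConfig(rng_seed=2))
        task = CausalTask(
            "daily_steps_k", "continuous",
            ["baseline_glucose", "elevated_count", "duration"], "tir",
        )
        w, _ = propensity_weights_continuous(table, task)
        base = estimate_effect(table, task, w, doubly_robust=True)[0]
        doubled = table.copy()
        doubled["daily_steps_k"] = doubled["daily_steps_k"] * 2
        w2, _ = propensity_weights_continuous(doubled, task)
        np.testing.assert_allclose(w, w2, rtol=1e-8)  # stabilized: scale-free
        halved = estimate_effect(doubled, task, w2, doubly_robust=True)[0]
        assert halved.estimate == pytest.approx(base.estimate / 2, rel=1e-6)

    def test_weight_positivity_enforced(self):
        table, _ = simulate_daily_outcome_cohort(DailyOutcomeConfig(rng_seed=1))
        task = CausalTask("daily_steps_k", "continuous", ["baseline_glucose"], "tir")
        with pytest.raises(ValueError, match="positive"):
            estimate_effect(table, task, np.zeros(len(table)))

    def test_binary_outcome_logistic(self):
        rng = np.random.default_rng(4)
        n = 600
        t = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(0.2 + 1.5 * t)))
        table = pd.DataFrame(
            {
                "participant_id": np.repeat([f"P{i}" for i in range(30)], 20),
                "t": t,
                "x1": rng.normal(0, 1, n),
                "y": rng.binomial(1, p),
            }
        )
        task = CausalTask("t", "continuous", ["x1"], "y", outcome_type="binary")
        est = estimate_effect(table, task, doubly_robust=True)[0]
        assert est.estimate == pytest.approx(1.5, abs=0.35)

    def test_p_value_and_se_invariants(self):
        with pytest.raises(ValueError):
            EffectEstimate("a", "t", 1.0, 0.0, 0.5, False, 10)
        with pytest.raises(ValueError):
            EffectEstimate("a", "t", 1.0, 1.0, 0.0, False, 10)
        est = EffectEstimate("a", "t", 1.0, 1.0, 0.005, False, 10)
        assert est.significant


@pytest.fixture(scope="module")
def meal_table():
    rng = np.random.default_rng(7)
    n = 300
    steps = rng.uniform(0, 2.5, n)
    calories = rng.uniform(2, 9, n)  # in 100 kcal
    mgr = 1500 + 183 * calories - 641 * steps + rng.normal(0, 150, n)
    return pd.DataFrame(
        {
            "participant_id": np.repeat([f"P{i}" for i in range(30)], 10),
            "start_time": pd.Timestamp("2022-03-01 08:00"),
            "mgr_3h": mgr,
            "post_meal_steps": steps * 1000,
            "calories": calories * 100,
            "mapped_hba1c": 4.4 + 0.00065 * mgr,
            "label": np.where(4.4 + 0.00065 * mgr >= 5.7, "elevated", "normal"),
            "high_agreement": True,
        }
    )


class TestRunPaperAnalyses:
    def test_planted_signs_recovered(self, meal_table):
        day, _ = simulate_daily_outcome_cohort(DailyOutcomeConfig(rng_seed=3))
        day = day.rename(columns={"elevated_count": "elevated_count_category"})
        day["daily_steps"] = day.pop("daily_steps_k") * 1000
        day["duration_min"] = day.pop("duration")
        results = run_study_analyses(day, meal_table)
        assert results["post_meal_steps_on_mgr_3h"].estimates[0].estimate < 0
        assert results["calories_on_mgr_3h"].estimates[0].estimate > 0
        assert results["post_meal_steps_on_elevated"].estimates[0].estimate < 0
        tir = results["elevated_count_on_tir"]
        assert [e.estimate for e in tir.estimates] == sorted(
            [e.estimate for e in tir.estimates], reverse=True
        )
        assert all(e.estimate < 0 for e in tir.estimates[1:])

    def test_meal_effect_sizes_recovered(self, meal_table):
        day, _ = simulate_daily_outcome_cohort(DailyOutcomeConfig(rng_seed=3))
        day = day.rename(columns={"elevated_count": "elevated_count_category"})
        day["daily_steps"] = day.pop("daily_steps_k") * 1000
        day["duration_min"] = day.pop("duration")
        results = run_study_analyses(day, meal_table)
        est = results["post_meal_steps_on_mgr_3h"].estimates[0]
        assert est.estimate == pytest.approx(-641, abs=40)
        est = results["calories_on_mgr_3h"].estimates[0]
        assert est.estimate == pytest.approx(183, abs=15)

    def test_zero_elevated_events_not_estimable(self, meal_table):
        day, _ = simulate_daily_outcome_cohort(DailyOutcomeConfig(rng_seed=3))
        day = day.rename(columns={"elevated_count": "elevated_count_category"})
        day["elevated_count_category"] = 0
        day["daily_steps"] = day.pop("daily_steps_k") * 1000
        day["duration_min"] = day.pop("duration")
        results = run_study_analyses(day, meal_table)
        assert not results["elevated_count_on_tir"].estimable
        assert "not estimable" in results["elevated_count_on_tir"].note

    def test_empty_inputs_degrade_gracefully(self):
        results = run_study_analyses(pd.DataFrame(), pd.DataFrame())
        assert all(not r.estimable for r in results.values())
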