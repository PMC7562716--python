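"""Survival discretization, forests, Kaplan-Meier and log-rank."""

import numpy as np
import pytest

from gastroslide.survival import (
    SURVIVAL_CLASSES,
    discretize_cohort,
    discretize_survival,
    fit_survival_rf,
    km_estimate,
    median_split_curves,
    split_importance,
)
from gastroslide.synthdata import CohortSpec, generate_cohort
from gastroslide.wsi_features import FEATURE_NAMES, ForestConfig


class TestDiscretize:
    @pytest.mark.parametrize(
        "duration,event,expected",
        [
            (6, 1, "died_lt_1y"),
            (11.9, 1, "died_lt_1y"),
            (12, 1, "died_1_5y"),
            (59.9, 1, "died_1_5y"),
            (60, 1, "survived_ge_5y"),
            (72, 0, "survived_ge_5y"),
            (60, 0, "survived_ge_5y"),
            (30, 0, None),  # alive, censored before 5 years: indeterminable
            (11, 0, None),
        ],
    )
    def test_rule_application(self, duration, event, expected):
        assert discretize_survival(duration, event) == expected

    def test_cohort_discretization_drops_indeterminable(self):
        frame = generate_cohort(CohortSpec(n_patients=200, seed=0))
        out = discretize_cohort(frame)
        assert len(out) <= 200
        assert out["survival_class"].notna().all()


class TestKaplanMeier:
    def test_product_limit_worked_example(self):
        """Deaths at t=1, 2 and a censor at 3: S(1)=2/3, S(2)=1/3."""
        curve = km_estimate([1, 2, 3], [1, 1, 0])
        assert curve.survival_at(0) == pytest.approx(1.0)
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(1 / 3)
        assert curve.survival_at(5) == pytest.approx(1 / 3)

    def test_no_censoring_equals_empirical_survivor_fraction(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 50)
        curve = km_estimate(t, np.ones(50, dtype=int))
        for q in (2.0, 5.0, 12.0):
            assert curve.survival_at(q) == pytest.approx((t > q).mean())

    def test_consistency_against_generating_exponential(self):
        """KM on censored exponential data stays within 0.08 sup-norm of
        the true survivor function."""
        rng = np.random.default_rng(2)
        lam = 0.05
        t = rng.exponential(1 / lam, 200)
        c = rng.uniform(0, 90, 200)
        dur = np.minimum(t, c)
        ev = (t <= c).astype(int)
        assert ev.mean() > 0.6
        curve = km_estimate(dur, ev)
        grid = curve.times[curve.times <= np.percentile(dur, 90)]
        sup = max(
            abs(curve.survival_at(x) - np.exp(-lam * x)) for x in grid
        )
        assert sup <= 0.08

    def test_confidence_band_contains_estimate(self):
        curve = km_estimate([2, 3, 5, 7, 11, 13], [1, 1, 0, 1, 1, 0])
        inner = slice(1, None)  # the band is defined after t=0
        assert (curve.ci_lower[inner] <= curve.survival[inner] + 1e-12).all()
        assert (curve.ci_upper[inner] >= curve.survival[inner] - 1e-12).all()


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        dur = np.r_[[5, 8, 12, 20, 30, 44.0], [5, 8, 12, 20, 30, 44.0]]
        ev = np.r_[[1, 0, 1, 1, 0, 1], [1, 0, 1, 1, 0, 1]]
        x = np.r_[np.zeros(6), np.ones(6)]
        res = median_split_curves(dur, ev, x)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_observed_minus_expected(self):
        """Six-patient worked example: chi2 = (O - E)^2 / Var from the
        standard 2-group log-rank tables."""
        # group A: deaths at 1, 2; censor at 4.  group B: deaths at 3, 4, 5
        dur = np.array([1.0, 2.0, 4.0, 3.0, 4.0, 5.0])
        ev = np.array([1, 1, 0, 1, 1, 1])
        grp = np.array([0, 0, 0, 1, 1, 1])
        o_minus_e = 0.0
        var = 0.0
        for t in sorted(set(dur[ev == 1])):
            at_risk = dur >= t
            n = at_risk.sum()
            n1 = (at_risk & (grp == 1)).sum()
            d = ((dur == t) & (ev == 1)).sum()
            d1 = ((dur == t) & (ev == 1) & (grp == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        res = median_split_curves(dur, ev, grp.astype(float))
        assert res.statistic == pytest.approx(expected_chi2, rel=1e-9)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        dur = rng.exponential(20, 40)
        ev = (rng.random(40) > 0.2).astype(int)
        x = rng.normal(size=40)
        a = median_split_curves(dur, ev, x)
        b = median_split_curves(dur, ev, -x)  # swaps the groups (ties aside)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)

    def test_median_ties_go_to_upper_group(self):
        dur = np.arange(1.0, 7.0)
        ev = np.ones(6, dtype=int)
        x = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])  # median is 3
        res = median_split_curves(dur, ev, x)
        assert res.n_high == 4 and res.n_low == 2

    def test_all_equal_values_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split_curves([1, 2, 3], [1, 1, 1], [5.0, 5.0, 5.0])

    def test_power_at_hazard_ratio_three(self):
        """Two groups with hazard ratio 3, n=200: log-rank p < 0.01 in at
        least 95 of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            lam = np.r_[np.full(100, 0.01), np.full(100, 0.03)]
            t = rng.exponential(1 / lam)
            c = rng.uniform(0, 150, 200)
            dur = np.minimum(t, c)
            ev = (t <= c).astype(int)
            x = np.r_[np.zeros(100), np.ones(100)]
            res = median_split_curves(dur, ev, x)
            hits += res.p_value < 0.01
        assert hits >= 95


@pytest.fixture(scope="module")
def cohort():
    feat = FEATURE_NAMES[35]
    return generate_cohort(
        CohortSpec(
            n_patients=600,
            seed=0,
            hazard_coefficients={"positive_lymph_nodes": 0.7, feat: 1.2},
            censoring_rate=0.1,
        )
    )


class TestSurvivalForest:
    def test_fit_reports_three_class_confusion(self, cohort):
        fit = fit_survival_rf(
            cohort, "all", config=ForestConfig(n_estimators=100), seed=0
        )
        assert fit.confusion.to_numpy().sum() == fit.n_test
        assert set(fit.classes) <= set(SURVIVAL_CLASSES)
        assert 0.0 <= fit.accuracy <= 1.0

    def test_same_seed_same_accuracy(self, cohort):
        cfg = ForestConfig(n_estimators=100)
        a = fit_survival_rf(cohort, "ai", config=cfg, seed=7)
        b = fit_survival_rf(cohort, "ai", config=cfg, seed=7)
        assert a.accuracy == b.accuracy

    def test_missing_class_error_lists_counts(self):
        frame = generate_cohort(CohortSpec(n_patients=40, seed=1))
        frame = frame[frame["duration_months"] < 59]  # removes class 3
        with pytest.raises(ValueError, match="survived_ge_5y="):
            fit_survival_rf(frame, "clinical")

    def test_null_cohort_accuracy_near_chance(self):
        frame = generate_cohort(CohortSpec(n_patients=600, seed=5))
        fit = fit_survival_rf(
            frame, "all", config=ForestConfig(n_estimators=100), seed=0
        )
        majority = (
            discretize_cohort(frame)["survival_class"].value_counts().max()
            / len(discretize_cohort(frame))
        )
        assert fit.accuracy <= majority + 0.15


class TestSplitImportance:
    def test_importances_sum_to_one_and_rank_planted_feature(self):
        feat = FEATURE_NAMES[35]
        frame = generate_cohort(
            CohortSpec(
                n_patients=500, seed=2, hazard_coefficients={feat: 2.0},
                censoring_rate=0.1,
            )
        )
        fit = fit_survival_rf(
            frame, "ai", config=ForestConfig(n_estimators=200, max_depth=6),
            seed=0,
        )
        ranking = split_importance(fit)
        assert ranking["importance"].sum() == pytest.approx(1.0)
        assert ranking.iloc[0]["feature"] == feat
        assert ranking.iloc[0]["category"] == "AI"

    def test_manual_split_count_on_small_forest(self):
        rng = np.random.default_rng(4)
        from sklearn.ensemble import RandomForestClassifier

        X = rng.normal(size=(80, 5))
        y = (X[:, 2] > 0).astype(int)
        forest = RandomForestClassifier(
            n_estimators=3, random_state=0, n_jobs=1
        ).fit(X, y)
        ranking = split_importance(forest)
        manual = np.zeros(5, dtype=int)
        for tree in forest.estimators_:
            for f in tree.tree_.feature:
                if f >= 0:
                    manual[f] += 1
        by_feature = dict(zip(ranking["feature"], ranking["n_splits"]))
        for i in range(5):
            assert by_feature[f"x{i}"] == manual[i]

    def test_single_feature_forest_has_importance_one(self):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(6)
        X = np.zeros((60, 3))
        X[:, 1] = rng.normal(size=60)  # only feature 1 is informative
        y = (X[:, 1] > 0).astype(int)
        forest = RandomForestClassifier(
            n_estimators=10, random_state=0, n_jobs=1
        ).fit(X, y)
        ranking = split_importance(forest)
        top = ranking.set_index("feature")["importance"]
        assert top["x1"] == pytest.approx(1.0)
        assert top["x0"] == 0.0 and top["x2"] == 0.0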