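"""ROC/AUC machinery, CV schemes and panel evaluation reports."""

import numpy as np
import pandas as pd
import pytest

from glycofib.evaluate import (
    SCHEMES,
    EvalConfig,
    auc_ci,
    auc_ci_bootstrap,
    cv_scores,
    evaluate_groupings,
    operating_point_metrics,
    sens_at_spec,
)
from glycofib.select import RFConfig


class TestAucCI:
    def test_perfect_ranking(self):
        auc, lo, hi = auc_ci([0, 0, 1, 1], [0, 0, 1, 1])
        assert auc == 1.0
        assert lo <= auc <= hi

    def test_antiranked(self):
        auc, _, _ = auc_ci([1, 1, 0, 0], [0, 0, 1, 1])
        assert auc == 0.0

    def test_four_point_worked_example(self):
        # concordant pairs: 3 of 4 -> AUC 0.75
        auc, lo, hi = auc_ci([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)
        assert lo <= 0.75 <= hi

    def test_matches_brute_force_pair_count(self, rng):
        for _ in range(20):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean([
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            ])
            assert auc_ci(scores, labels)[0] == pytest.approx(brute, abs=1e-12)

    def test_complement_identity(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        a1 = auc_ci(scores, labels)[0]
        a2 = auc_ci(-scores, labels)[0]
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_increasing_transform(self, rng):
        scores = rng.normal(size=30)
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        a1 = auc_ci(scores, labels)
        a2 = auc_ci(np.exp(scores), labels)
        assert a2[0] == pytest.approx(a1[0], abs=1e-12)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        widths = []
        for n in (30, 100, 300):
            labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
            scores = labels * 1.0 + rng.normal(0, 1.0, n)
            _, lo, hi = auc_ci(scores, labels)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_ci([0.1, 0.2], [1, 1])

    def test_bootstrap_agrees_roughly_with_delong(self):
        rng = np.random.default_rng(1)
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        scores = labels + rng.normal(0, 1.0, 80)
        a_d, lo_d, hi_d = auc_ci(scores, labels)
        a_b, lo_b, hi_b = auc_ci_bootstrap(scores, labels, n_boot=500, seed=2)
        assert a_b == pytest.approx(a_d)
        assert lo_b == pytest.approx(lo_d, abs=0.06)
        assert hi_b == pytest.approx(hi_d, abs=0.06)


class TestSensAtSpec:
    def test_perfect_separation_any_target(self):
        scores = [0.0, 0.1, 0.9, 1.0]
        labels = [0, 0, 1, 1]
        for target in (0.5, 0.9, 0.99):
            assert sens_at_spec(scores, labels, target) == 1.0

    def test_four_point_example_at_half_specificity(self):
        assert sens_at_spec([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 0.5) == 1.0

    def test_independent_scores_near_complement_of_target(self):
        rng = np.random.default_rng(3)
        n = 4000
        labels = rng.integers(0, 2, size=n)
        scores = rng.uniform(size=n)
        sens = sens_at_spec(scores, labels, 0.90)
        assert sens == pytest.approx(0.10, abs=0.03)

    def test_unreachable_target_warns_and_returns_zero(self):
        # scores constant: only threshold puts everyone positive -> spec 0
        with pytest.warns(UserWarning, match="no threshold"):
            out = sens_at_spec([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1], 0.9)
        assert out == 0.0


class TestOperatingPoint:
    def test_metrics_at_fixed_specificity(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        m = operating_point_metrics(scores, labels, 0.9)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 1.0
        assert m["accuracy"] == 1.0
        assert m["ppv"] == 1.0 and m["npv"] == 1.0

    def test_prevalence_override(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        m = operating_point_metrics(scores, labels, 0.9, prevalence=0.01)
        # with sens = spec = 1 the projection stays exact
        assert m["ppv"] == pytest.approx(1.0)
        assert m["npv"] == pytest.approx(1.0)


@pytest.fixture()
def separable_xy(rng):
    n = 30
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    X = pd.DataFrame(
        {"a": y * 5.0 + rng.normal(0, 0.2, n), "b": rng.normal(size=n)}
    )
    return X, y


class TestCvScores:
    def test_apparent_is_training_scores(self, separable_xy):
        X, y = separable_xy
        (scores, labels), = cv_scores(X, y, RFConfig(n_estimators=50, seed=0),
                                      scheme="apparent")
        assert len(scores) == len(y)
        assert auc_ci(scores, labels)[0] == 1.0  # optimistic by construction

    def test_loocv_perfectly_separable_auc_one(self, separable_xy):
        X, y = separable_xy
        (scores, labels), = cv_scores(X, y, RFConfig(n_estimators=50, seed=0),
                                      scheme="loocv")
        assert auc_ci(scores, labels)[0] == 1.0

    def test_deterministic_given_seed(self, separable_xy):
        X, y = separable_xy
        cfg = RFConfig(n_estimators=30, seed=4)
        s1 = cv_scores(X, y, cfg, scheme="subsample3fold", reps=5, seed=9)
        s2 = cv_scores(X, y, cfg, scheme="subsample3fold", reps=5, seed=9)
        for (a, la), (b, lb) in zip(s1, s2):
            assert np.array_equal(a, b) and np.array_equal(la, lb)

    def test_repeated_scheme_shapes(self, separable_xy):
        X, y = separable_xy
        sets = cv_scores(X, y, RFConfig(n_estimators=30, seed=0),
                         scheme="repeated3fold", reps=4, seed=1)
        assert len(sets) == 4
        for scores, labels in sets:
            assert len(scores) == len(y)
            assert np.array_equal(labels, y)

    def test_subsample_scheme_test_fraction(self, separable_xy):
        X, y = separable_xy
        sets = cv_scores(X, y, RFConfig(n_estimators=30, seed=0),
                         scheme="subsample3fold", reps=3, seed=1)
        assert len(sets) == 3
        for scores, labels in sets:
            assert len(scores) == len(y) // 3

    def test_unknown_scheme_rejected(self, separable_xy):
        X, y = separable_xy
        with pytest.raises(ValueError, match="unknown CV scheme"):
            cv_scores(X, y, scheme="bootstrap632")


class TestEvaluateGroupings:
    def test_reports_cover_all_comparisons_and_schemes(self, default_cohort):
        table, truth = default_cohort
        cfg = EvalConfig(rf=RFConfig(n_estimators=30, seed=0), reps=3,
                         schemes=("apparent", "subsample3fold"), seed=0)
        reports = evaluate_groupings(table, truth.planted_labels, cfg)
        assert [r.comparison for r in reports] == ["g1_vs_g2", "g2_vs_g3", "g1_vs_g3"]
        for r in reports:
            assert set(r.metrics) == {"apparent", "subsample3fold"}
            for m in r.metrics.values():
                assert 0 <= m["auc"] <= 1
                assert m["auc_ci_low"] <= m["auc"] <= m["auc_ci_high"]

    def test_stage_regrouping_adds_comparisons(self, default_cohort):
        table, truth = default_cohort
        cfg = EvalConfig(rf=RFConfig(n_estimators=30, seed=0),
                         schemes=("apparent",), include_stage_regrouping=True, seed=0)
        reports = evaluate_groupings(table, truth.planted_labels, cfg)
        names = [r.comparison for r in reports]
        assert "stage01_vs_stage23" in names and "stage23_vs_stage4" in names

    def test_missing_panel_feature_rejected(self, default_cohort):
        table, _ = default_cohort
        with pytest.raises(ValueError, match="absent"):
            evaluate_groupings(table, ["IgG.A4G4S4F"], EvalConfig())

    def test_repeated_scheme_reports_sd(self, default_cohort):
        table, truth = default_cohort
        cfg = EvalConfig(rf=RFConfig(n_estimators=30, seed=0), reps=4,
                         schemes=("repeated3fold",), seed=0)
        (report, *_rest) = evaluate_groupings(table, truth.planted_labels, cfg)
        assert "auc_sd" in report.metrics["repeated3fold"]
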