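"""Imbalance handling, CV protocol, metrics, ROC and importances."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from ibpforecast.classifier import (
    NEGATIVE,
    POSITIVE,
    SampleTable,
    cross_validate,
    evaluate,
    gini_importance,
    parse_class_weight,
    positive_scores,
    roc_points,
    stratified_kfold,
    train_forest,
    upsample_minority,
)


def make_table(n_pos: int, n_neg: int, shift: float, seed: int = 0) -> SampleTable:
    """36-feature table; positive rows shifted down in the first column."""
    rng = np.random.default_rng(seed)
    X = rng.normal(85, 5, size=(n_pos + n_neg, 36))
    X[:n_pos, 0] -= shift
    y = np.array([POSITIVE] * n_pos + [NEGATIVE] * n_neg)
    groups = np.arange(n_pos + n_neg) % 10
    return SampleTable(X, y, groups=groups)


class TestUpsample:
    def test_equalizes_counts(self):
        t = upsample_minority(make_table(10, 90, 0), seed=1)
        _, counts = np.unique(t.labels, return_counts=True)
        assert counts.tolist() == [90, 90]

    def test_balanced_table_unchanged(self):
        t0 = make_table(50, 50, 0)
        t1 = upsample_minority(t0, seed=1)
        assert np.array_equal(t0.features, t1.features)

    def test_originals_preserved_and_additions_are_copies(self):
        t0 = make_table(7, 43, 0, seed=3)
        t1 = upsample_minority(t0, seed=1)
        assert np.array_equal(t1.features[: t0.n], t0.features)
        added = t1.features[t0.n :]
        pool = t0.features[t0.labels == POSITIVE]
        for row in added:
            assert any(np.array_equal(row, p) for p in pool)

    def test_exact_balance_for_random_ratios(self, rng):
        for _ in range(10):
            n_pos = int(rng.integers(1, 40))
            t = upsample_minority(make_table(n_pos, 60, 0), seed=2)
            _, counts = np.unique(t.labels, return_counts=True)
            assert counts[0] == counts[1]

    def test_single_class_raises(self):
        t = SampleTable(np.ones((5, 36)), np.array([NEGATIVE] * 5))
        with pytest.raises(ValueError):
            upsample_minority(t, seed=0)


class TestStratifiedKFold:
    def test_partition_and_stratification(self):
        t = make_table(10, 90, 0)
        folds = stratified_kfold(t, k=5, seed=1)
        all_test = np.sort(np.concatenate([te for _, te in folds]))
        assert np.array_equal(all_test, np.arange(100))
        for tr, te in folds:
            assert np.intersect1d(tr, te).size == 0
            assert (t.labels[te] == POSITIVE).sum() == 2  # exact 10% per fold

    def test_deterministic_given_seed(self):
        t = make_table(10, 90, 0)
        a = stratified_kfold(t, seed=4)
        b = stratified_kfold(t, seed=4)
        assert all(np.array_equal(x[1], y[1]) for x, y in zip(a, b))

    def test_class_smaller_than_k_raises(self):
        with pytest.raises(ValueError):
            stratified_kfold(make_table(3, 90, 0), k=5)


class TestTrainForest:
    def test_memorizes_separable_data(self):
        t = make_table(30, 70, 25, seed=1)
        model = train_forest(t, seed=0)
        _, met = evaluate(model.predict(t.features), t.labels)
        assert met.recall == 1.0

    def test_deterministic_given_seed(self):
        t = make_table(20, 80, 5, seed=2)
        p1 = train_forest(t, seed=9).predict(t.features)
        p2 = train_forest(t, seed=9).predict(t.features)
        assert np.array_equal(p1, p2)

    def test_class_weight_parsing(self):
        assert parse_class_weight("none") is None
        assert parse_class_weight("balanced") == "balanced"
        assert parse_class_weight("9:1") == {POSITIVE: 9.0, NEGATIVE: 1.0}
        with pytest.raises(ValueError):
            parse_class_weight("bogus")


class TestEvaluate:
    def test_worked_example(self):
        pred = [POSITIVE] * 6 + [NEGATIVE] * 94
        truth = [POSITIVE] * 5 + [NEGATIVE] * 1 + [POSITIVE] * 5 + [NEGATIVE] * 89
        cm, met = evaluate(np.array(pred), np.array(truth))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (5, 1, 5, 89)
        assert met.accuracy == pytest.approx(0.94)
        assert met.precision == pytest.approx(5 / 6)
        assert met.recall == pytest.approx(0.5)

    def test_perfect_and_degenerate(self):
        y = np.array([POSITIVE] * 10 + [NEGATIVE] * 90)
        _, met = evaluate(y, y)
        assert (met.accuracy, met.precision, met.recall) == (1.0, 1.0, 1.0)
        _, met = evaluate(np.full(100, NEGATIVE), y)
        assert met.accuracy == pytest.approx(0.9)
        assert met.recall == 0.0 and not met.precision_defined

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            evaluate(np.array([POSITIVE]), np.array([POSITIVE, NEGATIVE]))

    def test_matches_counting_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 50))
            pred = rng.choice([POSITIVE, NEGATIVE], size=n)
            truth = rng.choice([POSITIVE, NEGATIVE], size=n)
            cm, met = evaluate(pred, truth)
            tp = sum(p == POSITIVE and t == POSITIVE for p, t in zip(pred, truth))
            fp = sum(p == POSITIVE and t == NEGATIVE for p, t in zip(pred, truth))
            fn = sum(p == NEGATIVE and t == POSITIVE for p, t in zip(pred, truth))
            tn = n - tp - fp - fn
            assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
            assert met.accuracy == pytest.approx((tp + tn) / n)


class TestRoc:
    def test_perfect_scores_area_one(self):
        truth = np.array([POSITIVE] * 5 + [NEGATIVE] * 15)
        scores = (truth == POSITIVE).astype(float)
        _, _, area = roc_points(scores, truth)
        assert area == 1.0

    def test_reversal_symmetry(self, rng):
        truth = rng.choice([POSITIVE, NEGATIVE], size=200)
        scores = rng.uniform(size=200)
        _, _, a = roc_points(scores, truth)
        _, _, b = roc_points(-scores, truth)
        assert a + b == pytest.approx(1.0)

    def test_area_equals_mann_whitney_statistic(self, rng):
        truth = np.array([POSITIVE] * 80 + [NEGATIVE] * 120)
        scores = rng.uniform(size=200)
        _, _, area = roc_points(scores, truth)
        u = mannwhitneyu(scores[:80], scores[80:], alternative="two-sided").statistic
        assert area == pytest.approx(u / (80 * 120), abs=1e-9)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_points(np.ones(5), np.full(5, NEGATIVE))


class TestGiniImportance:
    def test_informative_feature_ranked_first_and_sums_to_one(self, rng):
        n = 400
        X = rng.normal(size=(n, 36))
        y = np.where(rng.uniform(size=n) < 0.5, POSITIVE, NEGATIVE)
        X[:, 17] += 3.0 * (y == POSITIVE)
        model = train_forest(SampleTable(X, y), seed=0)
        imp = gini_importance(model)
        assert imp.sum() == pytest.approx(1.0, abs=1e-6)
        assert int(np.argmax(imp)) == 17

    def test_unfitted_model_raises(self):
        from sklearn.ensemble import RandomForestClassifier

        with pytest.raises(ValueError):
            gini_importance(RandomForestClassifier())


class TestCrossValidate:
    def test_report_shape_and_metric_ranges(self):
        t = make_table(25, 175, 15, seed=5)
        rep = cross_validate(t, seed=1)
        assert len(rep.folds) == 5
        for f in rep.folds:
            for v in (f.metrics.accuracy, f.metrics.precision, f.metrics.recall, f.auc):
                assert 0.0 <= v <= 1.0
        assert rep.pooled_confusion.total == t.n
        assert rep.mean_importances.sum() == pytest.approx(1.0, abs=1e-6)

    def test_grouped_cv_keeps_patients_on_one_side(self):
        t = make_table(40, 160, 10, seed=6)
        from sklearn.model_selection import StratifiedGroupKFold

        sgkf = StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=1)
        for tr, te in sgkf.split(t.features, t.labels, t.groups):
            assert np.intersect1d(np.unique(t.groups[tr]), np.unique(t.groups[te])).size == 0
        rep = cross_validate(t, seed=1, group_by_patient=True)
        assert rep.pooled_confusion.total == t.n

    def test_deterministic(self):
        t = make_table(25, 175, 5, seed=7)
        a = cross_validate(t, seed=3)
        b = cross_validate(t, seed=3)
        assert a.pooled == b.pooled
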