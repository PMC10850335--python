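"""Confusion counts, the five metrics, and the k-fold protocol."""

import itertools

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, precision_score, recall_score

from pmmnet import evaluation as ev


class TestConfusionCounts:
    def test_perfect_agreement(self):
        cc = ev.confusion_counts([1, 1, 0, 0], [1, 1, 0, 0], 1)
        assert (cc.TP, cc.TN, cc.FP, cc.FN) == (2, 2, 0, 0)

    def test_total_disagreement(self):
        cc = ev.confusion_counts([1, 0], [0, 1], 1)
        assert (cc.TP, cc.TN, cc.FP, cc.FN) == (0, 0, 1, 1)

    def test_exhaustive_enumeration_small_vectors(self):
        for n in (1, 2, 3):
            for y_true in itertools.product([0, 1], repeat=n):
                for y_pred in itertools.product([0, 1], repeat=n):
                    cc = ev.confusion_counts(y_true, y_pred, 1)
                    tally = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
                    for t, p in zip(y_true, y_pred):
                        key = ("T" if t == p else "F") + ("P" if p == 1 else "N")
                        tally[key] += 1
                    assert (cc.TP, cc.TN, cc.FP, cc.FN) == (
                        tally["TP"], tally["TN"], tally["FP"], tally["FN"])
                    assert cc.total == n

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_counts([0, 1], [0], 1)


class TestClassificationMetrics:
    def test_hand_derived_example(self):
        report = ev.classification_metrics(ev.ConfusionCounts(TP=40, TN=45, FP=5, FN=10))
        assert report.accuracy == pytest.approx(0.85, abs=1e-12)
        assert report.precision == pytest.approx(40 / 45, abs=1e-12)
        assert report.sensitivity == pytest.approx(0.80, abs=1e-12)
        assert report.specificity == pytest.approx(0.90, abs=1e-12)
        assert report.f1 == pytest.approx(2 * (40 / 45) * 0.8 / (40 / 45 + 0.8), abs=1e-12)
        assert report.f1 == pytest.approx(0.8421, abs=1e-4)

    def test_perfect_classifier_all_ones(self):
        report = ev.classification_metrics(ev.ConfusionCounts(TP=3, TN=4, FP=0, FN=0))
        assert all(getattr(report, m) == 1.0
                   for m in ("accuracy", "precision", "sensitivity", "specificity", "f1"))

    def test_degenerate_positive_class_flagged(self):
        report = ev.classification_metrics(ev.ConfusionCounts(TP=0, TN=5, FP=0, FN=3))
        assert report.sensitivity == 0.0 and report.f1 == 0.0
        assert "precision" in report.degenerate and "f1" in report.degenerate

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.classification_metrics(ev.ConfusionCounts(0, 0, 0, 0))

    def test_agreement_with_sklearn_on_random_labels(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 9))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            cc = ev.confusion_counts(y_true, y_pred, 1)
            report = ev.classification_metrics(cc)
            assert report.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
            assert report.precision == pytest.approx(
                precision_score(y_true, y_pred, pos_label=1, zero_division=0))
            assert report.sensitivity == pytest.approx(
                recall_score(y_true, y_pred, pos_label=1, zero_division=0))

    def test_f1_between_precision_and_sensitivity(self, rng):
        for _ in range(100):
            cc = ev.ConfusionCounts(*(int(v) for v in rng.integers(1, 20, 4)))
            report = ev.classification_metrics(cc)
            assert min(report.precision, report.sensitivity) - 1e-12 <= report.f1
            assert report.f1 <= max(report.precision, report.sensitivity) + 1e-12


class TestMacroAverage:
    def test_mean_of_identical_reports(self):
        r = ev.MetricsReport(0.9, 0.8, 0.7, 0.6, 0.75)
        out = ev.macro_average([r, r, r])
        for f in ("accuracy", "precision", "sensitivity", "specificity", "f1"):
            assert getattr(out, f) == pytest.approx(getattr(r, f), abs=1e-12)

    def test_arithmetic_mean(self):
        a = ev.MetricsReport(1, 1, 0.8, 1, 1)
        b = ev.MetricsReport(1, 1, 1.0, 1, 1)
        assert ev.macro_average([a, b]).sensitivity == pytest.approx(0.9)

    def test_equals_bruteforce_mean(self, rng):
        reports = [ev.MetricsReport(*rng.uniform(size=5)) for _ in range(5)]
        out = ev.macro_average(reports)
        for f in ("accuracy", "precision", "sensitivity", "specificity", "f1"):
            assert getattr(out, f) == pytest.approx(
                np.mean([getattr(r, f) for r in reports]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.macro_average([])


class TestKFoldSplit:
    def test_partition_of_100_into_10(self):
        labels = np.repeat([0, 1], 50)
        split = ev.kfold_split(np.arange(100), labels, k=10, seed=0)
        all_test = np.concatenate(split.test_indices)
        assert sorted(all_test) == list(range(100))
        assert all(len(f) == 10 for f in split.test_indices)

    def test_stratification_balanced_binary(self):
        labels = np.repeat([0, 1], 50)
        split = ev.kfold_split(np.arange(100), labels, k=10, seed=1)
        for fold in split.test_indices:
            assert np.sum(labels[fold] == 0) == 5
            assert np.sum(labels[fold] == 1) == 5

    def test_seed_determinism(self):
        labels = np.tile([0, 1], 30)
        a = ev.kfold_split(np.arange(60), labels, k=5, seed=7)
        b = ev.kfold_split(np.arange(60), labels, k=5, seed=7)
        for fa, fb in zip(a.test_indices, b.test_indices):
            np.testing.assert_array_equal(fa, fb)

    def test_train_test_disjoint_and_covering(self):
        labels = np.tile([0, 1, 2], 20)
        split = ev.kfold_split(np.arange(60), labels, k=6, seed=3)
        tested = np.zeros(60, dtype=int)
        for train_idx, test_idx in split:
            assert len(np.intersect1d(train_idx, test_idx)) == 0
            assert len(train_idx) + len(test_idx) == 60
            tested[test_idx] += 1
        assert np.all(tested == 1)

    def test_group_awareness_never_splits_recordings(self):
        groups = np.repeat(np.arange(20), 5)
        labels = np.repeat(np.tile([0, 1], 10), 5)
        split = ev.kfold_split(np.arange(100), labels, k=5, seed=0, group_ids=groups)
        for fold in split.test_indices:
            fold_groups = set(groups[fold])
            other = np.setdiff1d(np.arange(100), fold)
            assert fold_groups.isdisjoint(set(groups[other]))

    def test_small_class_warns(self):
        labels = np.array([0] * 18 + [1, 1])
        with pytest.warns(UserWarning):
            ev.kfold_split(np.arange(20), labels, k=5, seed=0)


class ConstantClassifier(ClassifierMixin, BaseEstimator):
    """Predicts the majority training class; closed-form CV expectations."""

    def fit(self, X, y):
        values, counts = np.unique(y, return_counts=True)
        self.constant_ = values[counts.argmax()]
        return self

    def predict(self, X):
        return np.full(len(X), self.constant_)


class MemorizingClassifier(ClassifierMixin, BaseEstimator):
    def fit(self, X, y):
        self.X_, self.y_ = np.asarray(X), np.asarray(y)
        return self

    def predict(self, X):
        X = np.asarray(X)
        out = []
        for row in X:
            matches = np.where((self.X_ == row).all(axis=1))[0]
            out.append(self.y_[matches[0]] if len(matches) else -1)
        return np.asarray(out)


class TestCrossValidate:
    def test_constant_predictor_on_imbalanced_set(self, rng):
        X = rng.normal(size=(100, 4))
        y = np.array([0] * 90 + [1] * 10)
        result = ev.cross_validate(ConstantClassifier(), X, y, k=5, seed=0)
        assert result.mean.accuracy == pytest.approx(0.9, abs=1e-12)
        assert result.mean.sensitivity == 0.0

    def test_disjoint_test_sets_with_memorizer(self, rng):
        X = rng.normal(size=(4, 3))
        y = np.array([0, 0, 1, 1])
        result = ev.cross_validate(MemorizingClassifier(), X, y, k=2, seed=0)
        assert len(result.per_fold) == 2
        assert sum(result.fold_sizes) == 4

    def test_mean_equals_mean_of_folds(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, 60)
        result = ev.cross_validate(ConstantClassifier(), X, y, k=5, seed=1)
        for f in ("accuracy", "precision", "sensitivity", "specificity", "f1"):
            assert getattr(result.mean, f) == pytest.approx(
                np.mean([getattr(r, f) for r in result.per_fold]))
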