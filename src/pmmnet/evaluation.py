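"""Confusion-count accounting, classification metrics and k-fold protocol.

Metrics follow the standard confusion-matrix definitions, with "abnormal"
(seizure) as the positive class:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Zero-denominator metrics are reported as 0 and flagged rather than NaN.
Multi-class tasks are scored one-vs-rest per class and macro-averaged.

Cross-validation is stratified 10-fold by default; when windows derive from
shared source recordings a group-aware split keeps every window of one
recording in the same fold to prevent train/test leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    degenerate: tuple[str, ...] = ()  # metrics whose denominator was zero

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "f1": self.f1}


@dataclass
class FoldSplit:
    """k disjoint test-index lists covering all samples."""

    test_indices: list[np.ndarray]
    n_samples: int

    @property
    def k(self) -> int:
        return len(self.test_indices)

    def train_indices(self, fold: int) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        mask[self.test_indices[fold]] = False
        return np.nonzero(mask)[0]

    def __iter__(self):
        for fold in range(self.k):
            yield self.train_indices(fold), self.test_indices[fold]


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    """One-vs-rest confusion counts with ``positive_class`` as abnormal."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def classification_metrics(cc: ConfusionCounts) -> MetricsReport:
    if cc.total == 0:
        raise ValueError("no evaluated samples")
    degenerate: list[str] = []
    accuracy = (cc.TP + cc.TN) / cc.total
    precision = _ratio(cc.TP, cc.TP + cc.FP, "precision", degenerate)
    sensitivity = _ratio(cc.TP, cc.TP + cc.FN, "sensitivity", degenerate)
    specificity = _ratio(cc.TN, cc.FP + cc.TN, "specificity", degenerate)
    if precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        degenerate.append("f1")
        f1 = 0.0
    return MetricsReport(accuracy, precision, sensitivity, specificity, f1,
                         tuple(degenerate))


def macro_average(reports: list[MetricsReport],
                  supports: list[int] | None = None) -> MetricsReport:
    """Unweighted mean of each metric over per-class reports."""
    if not reports:
        raise ValueError("no per-class reports to average")
    fields = ("accuracy", "precision", "sensitivity", "specificity", "f1")
    means = {f: float(np.mean([getattr(r, f) for r in reports])) for f in fields}
    degenerate = tuple(sorted({name for r in reports for name in r.degenerate}))
    return MetricsReport(degenerate=degenerate, **means)


def score_predictions(y_true, y_pred, positive_class=None) -> MetricsReport:
    """Binary report for a given positive class, or macro one-vs-rest."""
    y_true = np.asarray(y_true)
    classes = np.unique(y_true)
    if positive_class is None and len(classes) == 2:
        positive_class = classes.max()
    if positive_class is not None:
        return classification_metrics(confusion_counts(y_true, y_pred, positive_class))
    reports = [classification_metrics(confusion_counts(y_true, y_pred, c)) for c in classes]
    return macro_average(reports, [int(np.sum(y_true == c)) for c in classes])


def kfold_split(ids, labels, k: int = 10, seed: int = 0,
                group_ids=None) -> FoldSplit:
    """Deterministic stratified k-fold split over sample ids.

    With ``group_ids`` all windows of one source recording land in the same
    fold.  Classes with fewer than k members trigger a warning and a
    best-effort stratification.
    """
    ids = np.asarray(ids)
    labels = np.asarray(labels)
    n = len(ids)
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    counts = np.bincount(np.unique(labels, return_inverse=True)[1])
    if counts.min() < k:
        warnings.warn(f"a class has fewer than k={k} members; stratification is best-effort")
    dummy_X = np.zeros((n, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        if group_ids is not None:
            splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = [test for _, test in splitter.split(dummy_X, labels, np.asarray(group_ids))]
        else:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = [test for _, test in splitter.split(dummy_X, labels)]
    return FoldSplit([np.asarray(f) for f in folds], n)


@dataclass
class CVResult:
    mean: MetricsReport
    per_fold: list[MetricsReport]
    fold_sizes: list[int]

    def as_dict(self) -> dict:
        return {"mean": self.mean.as_dict(),
                "per_fold": [r.as_dict() for r in self.per_fold],
                "fold_sizes": self.fold_sizes}


def cross_validate(estimator, X, y, k: int = 10, seed: int = 0,
                   group_ids=None, positive_class=None) -> CVResult:
    """Train a fresh clone of ``estimator`` per fold and average the metrics.

    ``estimator`` is anything sklearn-compatible (fit/predict).  Metrics use
    the larger label as positive for binary tasks and macro one-vs-rest
    averaging otherwise.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    split = kfold_split(np.arange(len(X)), y, k=k, seed=seed, group_ids=group_ids)
    reports: list[MetricsReport] = []
    sizes: list[int] = []
    for train_idx, test_idx in split:
        fold_model = clone(estimator)
        fold_model.fit(X[train_idx], y[train_idx])
        y_pred = fold_model.predict(X[test_idx])
        reports.append(score_predictions(y[test_idx], y_pred, positive_class))
        sizes.append(len(test_idx))
    mean = macro_average(reports)
    return CVResult(mean, reports, sizes)
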