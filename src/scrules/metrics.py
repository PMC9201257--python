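"""Confusion-matrix performance measures and cross-validated evaluation.

Six measures are computed from a binary confusion summary: sensitivity
(recall), specificity, accuracy, Matthews correlation coefficient,
precision, and the F1-measure (the harmonic mean of recall and precision).
F1 is the pipeline's selection criterion; the rest are reported alongside.

Zero-denominator conventions (documented, bounded): SN, SP and precision
are 0 when undefined; MCC is 0 when any marginal is zero; F1 is 0 when
SN + precision = 0.

``cross_validate`` runs repeated stratified k-fold cross-validation and, by
default, pools out-of-fold confusion counts across all folds and repeats
before computing the measures; per-repeat metric sets are retained as an
alternative aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dataset import ExpressionDataset

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVResult",
    "confusion",
    "compute_metrics",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion summary must count at least one sample")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.TN + other.TN,
            self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricSet:
    SN: float
    SP: float
    ACC: float
    MCC: float
    precision: float
    F1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "SN": self.SN,
            "SP": self.SP,
            "ACC": self.ACC,
            "MCC": self.MCC,
            "precision": self.precision,
            "F1": self.F1,
        }


def confusion(
    y_true: Sequence,
    y_pred: Sequence,
    positive_class,
    negative_class=None,
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with the stated positive class.

    Labels outside the two known classes are an error, not a silent drop.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    observed = set(y_true) | set(y_pred)
    if negative_class is None:
        negatives = observed - {positive_class}
        if len(negatives) > 1:
            raise ValueError(f"ambiguous negative class among {sorted(map(str, observed))}")
        negative_class = negatives.pop() if negatives else None
    unknown = observed - {positive_class, negative_class}
    if unknown:
        raise ValueError(f"unknown label values: {sorted(map(str, unknown))}")
    t_pos = y_true == positive_class
    p_pos = y_pred == positive_class
    return ConfusionCounts(
        TP=int(np.sum(t_pos & p_pos)),
        FP=int(np.sum(~t_pos & p_pos)),
        TN=int(np.sum(~t_pos & ~p_pos)),
        FN=int(np.sum(t_pos & ~p_pos)),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Exact evaluation of the six measures from a confusion summary."""
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / c.total
    prec = tp / (tp + fp) if tp + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    f1 = 2 * sn * prec / (sn + prec) if sn + prec else 0.0
    return MetricSet(SN=sn, SP=sp, ACC=acc, MCC=mcc, precision=prec, F1=f1)


@dataclass
class CVResult:
    """Pooled cross-validation metrics plus per-fold / per-repeat detail."""

    pooled: MetricSet
    pooled_counts: ConfusionCounts
    fold_counts: list[ConfusionCounts]
    per_repeat: list[MetricSet]

    @property
    def mean_of_repeats(self) -> MetricSet:
        """Alternative aggregation: arithmetic mean of per-repeat metrics."""
        arrays = np.array([[m.SN, m.SP, m.ACC, m.MCC, m.precision, m.F1]
                           for m in self.per_repeat])
        sn, sp, acc, mcc, prec, f1 = arrays.mean(axis=0)
        return MetricSet(sn, sp, acc, mcc, prec, f1)


def cross_validate(
    dataset: ExpressionDataset,
    feature_subset: Sequence[str],
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    k: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of a fit/predict callable.

    Parameters
    ----------
    fit_predict
        ``fit_predict(X_train, y_train, X_test) -> y_pred`` with labels on
        the dataset's label scale.  Classifier construction (and any
        per-fold standardization) lives inside the callable, so nothing is
        ever fit on test cells.
    k, repeats, seed
        ``k``-fold splits are stratified and shuffled from ``seed`` (one
        derived seed per repeat), so fold assignment is reproducible.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    dataset.require_two_classes()
    sub = dataset.subset_genes(list(feature_subset))
    X = sub.values
    y = np.asarray(dataset.labels, dtype=object)
    fold_counts: list[ConfusionCounts] = []
    per_repeat: list[MetricSet] = []
    for rep in range(repeats):
        splitter = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=(seed + 1000003 * rep) % (2**31)
        )
        repeat_counts: list[ConfusionCounts] = []
        for train_idx, test_idx in splitter.split(X, y.astype(str)):
            y_train = y[train_idx]
            if len(set(y_train)) < 2:
                raise ValueError(
                    "a training fold lost one class entirely; increase the "
                    "sample size, lower k, or change the seed"
                )
            y_pred = fit_predict(X[train_idx], y_train, X[test_idx])
            repeat_counts.append(
                confusion(y[test_idx], y_pred, dataset.positive_class)
            )
        fold_counts.extend(repeat_counts)
        pooled_rep = repeat_counts[0]
        for c in repeat_counts[1:]:
            pooled_rep = pooled_rep + c
        per_repeat.append(compute_metrics(pooled_rep))
    pooled = fold_counts[0]
    for c in fold_counts[1:]:
        pooled = pooled + c
    return CVResult(
        pooled=compute_metrics(pooled),
        pooled_counts=pooled,
        fold_counts=fold_counts,
        per_repeat=per_repeat,
    )
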