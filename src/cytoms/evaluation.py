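"""Confusion-matrix metrics, ROC/AUC/Gini, and repeated k-fold CV.

Conventions: accuracy is reported on the 0-100 scale (the percentage form
of (TP+TN)/(TP+TN+FP+FN)); sensitivity, specificity, AUC and Gini on their
natural scales. Gini = 2*AUC - 1 is an identity here, never an independent
number. Sensitivity and specificity are None (not 0) when their denominator
is empty, so degenerate evaluations cannot silently corrupt a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The evaluation panel for one classifier on one test set."""

    accuracy: float              # percentage, [0, 100]
    sensitivity: Optional[float]  # TP/(TP+FN), None if no positives
    specificity: Optional[float]  # TN/(TN+FP), None if no negatives
    auc: Optional[float]
    gini: Optional[float]         # 2*auc - 1
    counts: Optional[ConfusionCounts] = None


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep ROC curve; endpoints are exactly (0,0) and (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


@dataclass
class CVReport:
    """Accuracies of a k-fold x repeats grid, with a robustness flag."""

    k: int
    repeats: int
    cell_accuracy: np.ndarray  # shape (repeats, k), percentages
    robustness_sd_threshold: float = 5.0

    @property
    def mean(self) -> float:
        return float(self.cell_accuracy.mean())

    @property
    def sd(self) -> float:
        return float(self.cell_accuracy.std(ddof=1))

    @property
    def robust(self) -> bool:
        """Low cell-to-cell accuracy variation marks the model as robust."""
        return self.sd <= self.robustness_sd_threshold


def confusion(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Cross-tabulate 0/1 predictions against 0/1 truth (1 = positive)."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape or pred.ndim != 1 or len(pred) == 0:
        raise ValueError("predicted and true labels must be equal-length, non-empty")
    for name, arr in (("predicted", pred), ("true", true)):
        if not np.isin(arr, [0, 1]).all():
            raise ValueError(f"{name} labels must be binary 0/1")
    tp = int(((pred == 1) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts, auc: Optional[float] = None) -> MetricReport:
    """Apply the standard panel formulas to confusion counts.

    accuracy = (TP+TN)/(TP+TN+FN+FP) * 100; sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP); gini = 2*AUC - 1.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    accuracy = (c.tp + c.tn) / c.total * 100.0
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    gini = 2.0 * auc - 1.0 if auc is not None else None
    return MetricReport(accuracy=accuracy, sensitivity=sensitivity,
                        specificity=specificity, auc=auc, gini=gini, counts=c)


def roc_auc(scores: Sequence[float],
            truth: Sequence[int]) -> Tuple[ROCCurve, float]:
    """ROC curve by threshold sweep and its trapezoidal area.

    Equivalent to the pair-counting statistic
    P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth)
    if len(np.unique(t)) < 2:
        raise ValueError("ROC requires both classes in the true labels")
    fpr, tpr, thr = _sk_roc_curve(t, s)
    # guarantee explicit (0,0) and (1,1) endpoints
    if fpr[0] != 0 or tpr[0] != 0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
        thr = np.concatenate([[np.inf], thr])
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr = np.concatenate([fpr, [1.0]])
        tpr = np.concatenate([tpr, [1.0]])
        thr = np.concatenate([thr, [-np.inf]])
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr), float(_trapezoid_auc(fpr, tpr))


def evaluate_predictions(labels: Sequence[int], scores: Sequence[float],
                         truth: Sequence[int]) -> Tuple[MetricReport, ROCCurve]:
    """Full panel: confusion metrics from hard labels, AUC/Gini from scores."""
    curve, auc_value = roc_auc(scores, truth)
    report = metrics(confusion(labels, truth), auc=auc_value)
    return report, curve


def repeated_kfold(
    table: pd.DataFrame,
    pipeline: Callable[[pd.DataFrame, pd.DataFrame, int], float],
    k: int = 6,
    repeats: int = 3,
    label_column: str = "status",
    seed: int = 0,
    stratified: bool = True,
    robustness_sd_threshold: float = 5.0,
) -> CVReport:
    """Repeated k-fold cross-validation of an arbitrary pipeline.

    *pipeline(train, test, fold_seed)* must return an accuracy percentage.
    Each repeat uses a fresh seeded shuffle; folds are class-stratified by
    default so every fold retains both classes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = table[label_column]
    if stratified and y.value_counts().min() < k:
        raise ValueError(
            f"smallest class has {y.value_counts().min()} records; "
            f"cannot form {k} stratified folds")

    cells = np.empty((repeats, k))
    for r in range(repeats):
        if stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=seed + r)
            split_iter = splitter.split(np.zeros(len(table)), y)
        else:
            rng = np.random.default_rng(seed + r)
            order = rng.permutation(len(table))
            folds = np.array_split(order, k)
            split_iter = ((np.setdiff1d(order, f), f) for f in folds)
        for j, (train_idx, test_idx) in enumerate(split_iter):
            train = table.iloc[train_idx].reset_index(drop=True)
            test = table.iloc[test_idx].reset_index(drop=True)
            cells[r, j] = pipeline(train, test, seed + 97 * r + j)
    return CVReport(k=k, repeats=repeats, cell_accuracy=cells,
                    robustness_sd_threshold=robustness_sd_threshold)
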