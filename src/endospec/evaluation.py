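"""Classifier evaluation: one-vs-rest confusion statistics and ROC/AUC.

Per class c the predictions are reduced to a binary problem (c vs rest)
and the usual counts TP/TN/FP/FN give

    sensitivity (TPR) = TP / (TP + FN)
    specificity (TNR) = TN / (TN + FP)
    accuracy          = (TP + TN) / (TP + TN + FP + FN)

plus precision (PPV = TP / (TP + FP)) and F1 = 2*PPV*TPR/(PPV+TPR).
Overall accuracy is the fraction of samples assigned their true class.
Rates whose denominator is zero are reported as NaN ("missing").

ROC curves are built one-vs-rest from the continuous predicted-indicator
score of each class; the AUC is trapezoidal, which on any input equals
the Mann-Whitney pair-counting statistic P(score+ > score-) + P(tie)/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ClassStats:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.sensitivity
        if np.isnan(p) or np.isnan(r) or (p + r) == 0:
            return float("nan")
        return 2 * p * r / (p + r)


@dataclass(frozen=True)
class ConfusionStats:
    classes: tuple[str, ...]
    per_class: Mapping[str, ClassStats]
    overall_accuracy: float
    n: int

    def as_percent_table(self) -> pd.DataFrame:
        """Metrics table (percentages to 1 decimal), one column per class."""
        rows = {
            "Accuracy": [self.per_class[c].accuracy for c in self.classes],
            "Sensitivity (TPR)": [self.per_class[c].sensitivity for c in self.classes],
            "Specificity (TNR)": [self.per_class[c].specificity for c in self.classes],
            "Precision (PPV)": [self.per_class[c].precision for c in self.classes],
            "F1-score": [self.per_class[c].f1 for c in self.classes],
        }
        df = pd.DataFrame(rows, index=list(self.classes)).T * 100.0
        df.loc["Overall accuracy"] = [self.overall_accuracy * 100.0] + [np.nan] * (
            len(self.classes) - 1
        )
        return df.round(1)


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionStats:
    """One-vs-rest confusion counts and derived metrics per class."""
    true = np.asarray(list(true_labels), dtype=object)
    pred = np.asarray(list(predicted_labels), dtype=object)
    if true.shape != pred.shape:
        raise ValueError("true and predicted label vectors differ in length")
    order = tuple(class_order)
    stray = (set(true) | set(pred)) - set(order)
    if stray:
        raise ValueError(f"labels outside class order {order}: {sorted(stray)}")
    n = true.size
    per_class = {}
    for c in order:
        t = true == c
        p = pred == c
        per_class[c] = ClassStats(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )
    return ConfusionStats(
        classes=order,
        per_class=per_class,
        overall_accuracy=float(np.mean(true == pred)),
        n=n,
    )


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], binary_labels: Sequence[int]) -> ROCCurve:
    """One-vs-rest ROC from continuous scores.

    Thresholds sweep the unique score values from high to low; tied scores
    cross their threshold simultaneously, producing the diagonal segment
    that makes the trapezoidal AUC equal to the pair-counting formulation.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(int)
    pos = int(np.sum(y == 1))
    neg = int(np.sum(y == 0))
    if pos == 0 or neg == 0:
        raise ValueError("ROC needs both positive and negative labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = y[order]
    # cumulative counts at each unique-score boundary
    boundary = np.where(np.diff(s))[0]
    idx = np.r_[boundary, s.size - 1]
    tps = np.cumsum(t)[idx]
    fps = np.cumsum(1 - t)[idx]
    tpr = np.r_[0.0, tps / pos]
    fpr = np.r_[0.0, fps / neg]
    thresholds = np.r_[np.inf, s[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)
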