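"""Classifier quality metrics: confusion-matrix rates, Cohen's kappa, ROC/AUC.

The recurrence class (BCR) is coded 1 and counts as "positive" throughout;
sensitivity is the recall of recurrences and specificity the recall of
recurrence-free cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionMetrics", "confusion_metrics", "ROCCurve", "roc_auc",
           "youden_threshold"]


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    kappa: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def confusion_metrics(predicted: np.ndarray, truth: np.ndarray) -> ConfusionMetrics:
    """Confusion counts and the four reported rates for binary labels.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the product
    of the marginal label frequencies. Undefined rates (zero denominators) are
    reported as NaN with a warning, never silently as 0.
    """
    predicted = np.asarray(predicted).astype(int)
    truth = np.asarray(truth).astype(int)
    if predicted.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    if not set(np.unique(predicted)) <= {0, 1} or not set(np.unique(truth)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    n = tp + fp + tn + fn
    se = _safe_ratio(tp, tp + fn, "sensitivity")
    sp = _safe_ratio(tn, tn + fp, "specificity")
    pr = _safe_ratio(tp, tp + fp, "precision")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = _safe_ratio(p_o - p_e, 1.0 - p_e, "kappa")
    return ConfusionMetrics(tp, fp, tn, fn, se, sp, pr, kappa)


@dataclass
class ROCCurve:
    """ROC coordinates over the threshold sweep, plus the trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr,
                             "tpr": self.tpr})


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> ROCCurve:
    """ROC curve by threshold sweep over unique scores; AUC by trapezoid rule.

    Tied scores move along the curve diagonally, so the trapezoid AUC equals
    the rank statistic U/(n_pos*n_neg) with ties counted one half. Requires at
    least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    # collapse tied scores into single thresholds
    distinct = np.r_[True, np.diff(s) != 0]
    idx = np.where(distinct)[0]
    tp_cum = np.cumsum(t)
    fp_cum = np.cumsum(1 - t)
    # last index of each tied block
    block_end = np.r_[idx[1:] - 1, t.size - 1]
    tpr = np.r_[0.0, tp_cum[block_end] / n_pos]
    fpr = np.r_[0.0, fp_cum[block_end] / n_neg]
    thresholds = np.r_[np.inf, s[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, thresholds, auc)


def youden_threshold(curve: ROCCurve) -> float:
    """Threshold maximizing Youden's J = TPR - FPR (reported for transparency)."""
    j = curve.tpr - curve.fpr
    return float(curve.thresholds[int(np.argmax(j))])
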