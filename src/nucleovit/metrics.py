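"""Segmentation and classification evaluation metrics.

Overlap scores (Dice, Jaccard) follow the smoothed formulation with a
``smooth = 1e-32`` additive constant; the Hausdorff distance is directed by
default with an explicit flag for the symmetric variant.  Classification
metrics are all derived from an exact 2x2 confusion matrix.  Undefined
ratios (0/0) raise :class:`UndefinedMetricError` rather than silently
returning 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "UndefinedMetricError", "ConfusionMatrix2", "dice", "jaccard", "hausdorff",
    "confusion", "confusion_from_rates", "f1", "youden", "kappa", "roc_auc",
    "classification_report", "segmentation_report",
]

SMOOTH = 1e-32


class UndefinedMetricError(ZeroDivisionError):
    """A metric whose defining ratio is 0/0 for the given inputs."""


def _check_overlap_inputs(pred, targ):
    pred = np.asarray(pred, dtype=np.float64)
    targ = np.asarray(targ, dtype=np.float64)
    if pred.shape != targ.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {targ.shape}")
    return pred, targ


def dice(pred, targ, smooth: float = SMOOTH) -> float:
    """(2*inter + smooth) / (sum_pred + sum_targ + smooth)."""
    pred, targ = _check_overlap_inputs(pred, targ)
    inter = float((pred * targ).sum())
    return (2.0 * inter + smooth) / (pred.sum() + targ.sum() + smooth)


def jaccard(pred, targ, smooth: float = SMOOTH) -> float:
    """(inter + smooth) / (sum_pred + sum_targ - inter + smooth)."""
    pred, targ = _check_overlap_inputs(pred, targ)
    inter = float((pred * targ).sum())
    return (inter + smooth) / (pred.sum() + targ.sum() - inter + smooth)


def hausdorff(points_a, points_b, symmetric: bool = False) -> float:
    """Directed Hausdorff distance max_a min_b d(a, b) in Euclidean pixels.

    With ``symmetric=True`` returns max(H(A,B), H(B,A)).
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(points_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("Hausdorff distance requires non-empty point sets")
    d_ab = float(cKDTree(b).query(a)[0].max())
    if not symmetric:
        return d_ab
    d_ba = float(cKDTree(a).query(b)[0].max())
    return max(d_ab, d_ba)


def mask_hausdorff(pred_mask, targ_mask, symmetric: bool = False) -> float:
    """Hausdorff distance between the foreground pixel sets of two masks."""
    return hausdorff(np.argwhere(np.asarray(pred_mask) > 0),
                     np.argwhere(np.asarray(targ_mask) > 0),
                     symmetric=symmetric)


@dataclass(frozen=True)
class ConfusionMatrix2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            raise UndefinedMetricError("precision undefined: no predicted positives")
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("recall undefined: no actual positives")
        return self.tp / (self.tp + self.fn)

    sensitivity = recall

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise UndefinedMetricError("specificity undefined: no actual negatives")
        return self.tn / (self.tn + self.fp)

    def swap_positive(self) -> "ConfusionMatrix2":
        return ConfusionMatrix2(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


def confusion(pred_labels, true_labels, positive_class) -> ConfusionMatrix2:
    pred_labels = list(pred_labels)
    true_labels = list(true_labels)
    if len(pred_labels) != len(true_labels):
        raise ValueError("pred and true label sequences differ in length")
    tp = fp = fn = tn = 0
    for p, t in zip(pred_labels, true_labels):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix2(tp=tp, fp=fp, fn=fn, tn=tn)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def confusion_from_rates(n_positive: int, n_negative: int,
                         recall_positive: float,
                         recall_negative: float) -> ConfusionMatrix2:
    """Rebuild an exact 2x2 matrix from class counts and per-class recalls.

    Products are rounded half-up to the nearest integer.
    """
    if n_positive < 1 or n_negative < 1:
        raise ValueError("class counts must be >= 1")
    if not (0.0 <= recall_positive <= 1.0 and 0.0 <= recall_negative <= 1.0):
        raise ValueError("recalls must lie in [0, 1]")
    tp = _round_half_up(recall_positive * n_positive)
    tn = _round_half_up(recall_negative * n_negative)
    return ConfusionMatrix2(tp=tp, fn=n_positive - tp,
                            tn=tn, fp=n_negative - tn)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean 2PR / (P + R)."""
    if precision == 0.0 and recall == 0.0:
        raise UndefinedMetricError("F1 undefined for precision = recall = 0")
    return 2.0 * precision * recall / (precision + recall)


def youden(sensitivity: float, specificity: float) -> float:
    return sensitivity + specificity - 1.0


def kappa(cm: ConfusionMatrix2) -> float:
    """Cohen's kappa (p0 - pe) / (1 - pe) from the 2x2 matrix."""
    total = cm.total
    p0 = cm.accuracy
    actual_pos, actual_neg = cm.tp + cm.fn, cm.fp + cm.tn
    pred_pos, pred_neg = cm.tp + cm.fp, cm.fn + cm.tn
    pe = (actual_pos * pred_pos + actual_neg * pred_neg) / total ** 2
    if pe == 1.0:
        raise UndefinedMetricError("kappa undefined: chance agreement pe = 1")
    return (p0 - pe) / (1.0 - pe)


def roc_auc(scores, labels, positive_class=1):
    """Trapezoidal ROC area with ties averaged (Mann-Whitney equivalent).

    Returns ``(auc, points)`` where ``points`` is the list of (FPR, TPR)
    pairs of the full threshold sweep.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray([1 if lab == positive_class else 0 for lab in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    scores, y = scores[order], y[order]
    tpr_pts, fpr_pts = [0.0], [0.0]
    tp = fp = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        tpr_pts.append(tp / n_pos)
        fpr_pts.append(fp / n_neg)
        i = j
    auc = float(np.trapezoid(tpr_pts, fpr_pts))
    return auc, list(zip(fpr_pts, tpr_pts))


def _safe(fn, *args):
    try:
        return fn(*args)
    except UndefinedMetricError:
        return None


def classification_report(pred_labels, true_labels, scores=None,
                          positive_class="malignant",
                          negative_class="benign") -> dict:
    cm_pos = confusion(pred_labels, true_labels, positive_class)
    cm_neg = cm_pos.swap_positive()
    report = {"accuracy": cm_pos.accuracy, "per_class": {}}
    for name, cm in ((positive_class, cm_pos), (negative_class, cm_neg)):
        prec = _safe(lambda: cm.precision)
        rec = _safe(lambda: cm.recall)
        report["per_class"][name] = {
            "precision": prec,
            "recall": rec,
            "f1": _safe(f1, prec, rec) if prec is not None and rec is not None else None,
        }
    report["youden"] = _safe(
        lambda: youden(cm_pos.recall, cm_pos.specificity))
    report["kappa"] = _safe(kappa, cm_pos)
    report["confusion"] = {"tp": cm_pos.tp, "fp": cm_pos.fp,
                           "fn": cm_pos.fn, "tn": cm_pos.tn,
                           "positive_class": positive_class}
    if scores is not None:
        auc, pts = roc_auc(scores, true_labels, positive_class=positive_class)
        report["auc"] = auc
        report["roc"] = [{"fpr": fpr, "tpr": tpr} for fpr, tpr in pts]
    return report


def segmentation_report(pred_mask, targ_mask, symmetric_hausdorff=False) -> dict:
    report = {"dice": dice(pred_mask, targ_mask),
              "jaccard": jaccard(pred_mask, targ_mask)}
    try:
        report["hausdorff"] = mask_hausdorff(pred_mask, targ_mask,
                                             symmetric=symmetric_hausdorff)
    except ValueError:
        report["hausdorff"] = None
    return report


def write_report(report: dict, path):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
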