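"""Evaluation statistics: binary and multi-class metrics, ROC/PR curves.

Binary metrics from a confusion table (TP, TN, FP, FN):

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Spe = TN / (TN + FP)
    Sen = TP / (TP + FN)
    F1  = 2 TP / (2 TP + FP + FN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Multi-class metrics from a K x K confusion matrix (rows = true labels,
columns = predictions) use macro averaging — the unweighted mean of the
per-class one-vs-all binary metric — for Acc, Spe, Sen and F1, plus the
multi-class Matthews correlation coefficient computed from the marginals:

    MCC_multi = (c·s − Σ_k p_k t_k)
                / sqrt((s² − Σ_k p_k²)(s² − Σ_k t_k²))

where t_k are true-class counts (row sums), p_k predicted-class counts
(column sums), c the trace (correct predictions) and s the total count.
On a 2 x 2 table MCC_multi reduces algebraically to the binary MCC.

Degenerate denominators: an MCC with a zero factor is reported as 0.0 and
flagged; a specificity/sensitivity with an empty class is reported as NaN
and flagged. ROC and PR curves are computed through scikit-learn with
trapezoidal AUC; tied scores collapse into a single threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_recall_curve as _sk_pr,
    roc_curve as _sk_roc,
)

from .errors import ValidationError

__all__ = [
    "ConfusionBinary",
    "ConfusionMulti",
    "CurvePoints",
    "binary_metrics",
    "multiclass_metrics",
    "confusion",
    "one_vs_all",
    "roc_points",
    "pr_points",
]


@dataclass(frozen=True)
class ConfusionBinary:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ConfusionMulti:
    counts: np.ndarray  # (K, K), rows = true, columns = predicted

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] < 2:
            raise ValidationError("counts must be a square K x K matrix, K >= 2")
        if (c < 0).any():
            raise ValidationError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Occurrences of each true class (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def p(self) -> np.ndarray:
        """Predictions of each class (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def c(self) -> int:
        """Correctly predicted samples (trace)."""
        return int(np.trace(self.counts))

    @property
    def s(self) -> int:
        """Total samples."""
        return int(self.counts.sum())


@dataclass(frozen=True)
class CurvePoints:
    """An ROC or PR curve: thresholds (strictly decreasing), x, y, AUC."""

    thresholds: np.ndarray
    x: np.ndarray
    y: np.ndarray
    auc: float
    kind: str  # "roc" | "pr"
    degenerate: bool = False


def binary_metrics(cm: ConfusionBinary) -> dict:
    """The five binary statistics plus degeneracy flags."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    flags = []
    acc = (tp + tn) / cm.total if cm.total else float("nan")
    if tn + fp:
        spe = tn / (tn + fp)
    else:
        spe = float("nan")
        flags.append("spe_undefined")
    if tp + fn:
        sen = tp / (tp + fn)
    else:
        sen = float("nan")
        flags.append("sen_undefined")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc = 0.0
        flags.append("mcc_degenerate")
    return {"Acc": acc, "Spe": spe, "Sen": sen, "F1": f1, "MCC": mcc,
            "flags": flags}


def one_vs_all(cm: ConfusionMulti, k: int) -> ConfusionBinary:
    """Collapse a K-class table to the binary view with class k positive."""
    tp = int(cm.counts[k, k])
    fn = int(cm.t[k]) - tp
    fp = int(cm.p[k]) - tp
    tn = cm.s - tp - fn - fp
    return ConfusionBinary(tp, tn, fp, fn)


def multiclass_metrics(cm: ConfusionMulti) -> dict:
    """Macro-averaged Acc/Spe/Sen/F1 and the multi-class MCC.

    Per-class one-vs-all metrics are returned as well under ``per_class``
    so alternative summaries can be recomputed.
    """
    per_class = [binary_metrics(one_vs_all(cm, k)) for k in range(cm.K)]
    flags = [f"class{k}:{f}" for k, m in enumerate(per_class) for f in m["flags"]]

    t, p, c, s = cm.t.astype(float), cm.p.astype(float), cm.c, cm.s
    denom = (s * s - (p * p).sum()) * (s * s - (t * t).sum())
    if denom > 0:
        mcc = (c * s - (p * t).sum()) / math.sqrt(denom)
    else:
        mcc = 0.0
        flags.append("mcc_degenerate")
    out = {
        "Acc_macro": float(np.mean([m["Acc"] for m in per_class])),
        "Spe_macro": float(np.mean([m["Spe"] for m in per_class])),
        "Sen_macro": float(np.mean([m["Sen"] for m in per_class])),
        "F1_macro": float(np.mean([m["F1"] for m in per_class])),
        "MCC_multi": float(mcc),
        "per_class": per_class,
        "flags": flags,
    }
    return out


def confusion(y_true, y_pred, K: int) -> ConfusionMulti:
    """K x K confusion matrix; rows are true labels, columns predictions."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= K):
            raise ValidationError(f"{name} contains labels outside [0, {K})")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(K))
    return ConfusionMulti(counts)


def _check_scores(y_true, scores) -> tuple[np.ndarray, np.ndarray, bool]:
    y = np.asarray(y_true, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValidationError("y_true and scores must have the same length")
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    degenerate = len(np.unique(y)) < 2
    return y, s, degenerate


def roc_points(y_true, scores) -> CurvePoints:
    """ROC curve (FPR, TPR) with trapezoidal AUC.

    With a single-class ``y_true`` the curve is undefined: an empty,
    flagged curve with NaN AUC is returned.
    """
    y, s, degenerate = _check_scores(y_true, scores)
    if degenerate:
        return CurvePoints(np.array([]), np.array([]), np.array([]),
                           float("nan"), "roc", degenerate=True)
    fpr, tpr, thr = _sk_roc(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return CurvePoints(thr, fpr, tpr, auc, "roc")


def pr_points(y_true, scores) -> CurvePoints:
    """Precision-recall curve ordered by decreasing threshold, trapezoidal AUC."""
    y, s, degenerate = _check_scores(y_true, scores)
    if degenerate:
        return CurvePoints(np.array([]), np.array([]), np.array([]),
                           float("nan"), "pr", degenerate=True)
    precision, recall, thr = _sk_pr(y, s)
    # sklearn orders by increasing threshold; flip so thresholds decrease
    # and recall increases along the curve. The final (recall=0) point has
    # no threshold; drop it to keep the triples aligned.
    precision, recall = precision[:-1][::-1], recall[:-1][::-1]
    thr = thr[::-1]
    auc = float(np.trapezoid(precision, recall))
    return CurvePoints(thr, recall, precision, auc, "pr")
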