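"""Classification evaluation metrics.

Implements the quantification formulas used throughout the evaluation:
accuracy, precision, sensitivity (recall), specificity, F1, the Matthews
correlation coefficient, Cohen's kappa and ROC/AUC, for binary confusion
matrices and their multiclass generalizations (macro one-vs-rest averaging,
covariance-form MCC, full-matrix kappa).  Zero denominators yield 0 with a
warning rather than NaN.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import InputError

__all__ = ["ConfusionMatrix", "MetricReport", "ROCCurve", "confusion_matrix",
           "binary_metrics", "multiclass_metrics", "roc_curve", "roc_auc",
           "multiclass_roc_auc", "plot_confusion_matrix", "plot_roc"]


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


@dataclass
class ConfusionMatrix:
    """K x K counts; rows index the true class, columns the predicted class."""

    counts: np.ndarray
    class_labels: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InputError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise InputError("confusion matrix counts must be non-negative")

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def binary_counts(self) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) with class 1 designated positive (K=2 only)."""
        if self.num_classes != 2:
            raise InputError("binary counts require a 2x2 matrix")
        c = self.counts
        return int(c[1, 1]), int(c[0, 1]), int(c[0, 0]), int(c[1, 0])


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    kappa: float
    auc: float | None = None
    averaging: str = "binary"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_csv(self, path) -> None:
        d = self.to_dict()
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(d.keys())
            w.writerow(d.values())


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["threshold", "fpr", "tpr"])
            for t, f, s in zip(self.thresholds, self.fpr, self.tpr):
                w.writerow([t, f, s])


def confusion_matrix(y_true, y_pred, num_classes: int,
                     class_labels: list[str] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise InputError(f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= num_classes):
            raise InputError(f"{name} contains labels outside [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    labels = class_labels or [str(i) for i in range(num_classes)]
    return ConfusionMatrix(counts=counts, class_labels=list(labels))


def binary_metrics(cm: ConfusionMatrix) -> MetricReport:
    """All scalar metrics of a 2x2 matrix (class 1 positive)."""
    if cm.total == 0:
        raise InputError("empty confusion matrix")
    tp, fp, tn, fn = cm.binary_counts()
    n = tp + fp + tn + fn
    accuracy = (tp + tn) / n
    precision = _safe_div(tp, tp + fp, "precision")
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    specificity = _safe_div(tn, tn + fp, "specificity")
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity, "F1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC")
    p0 = accuracy
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = _safe_div(p0 - pe, 1.0 - pe, "kappa")
    return MetricReport(accuracy=accuracy, precision=precision,
                        sensitivity=sensitivity, specificity=specificity,
                        f1=f1, mcc=float(mcc), kappa=kappa, averaging="binary")


def multiclass_metrics(cm: ConfusionMatrix, average: str = "macro") -> MetricReport:
    """Macro one-vs-rest precision/recall/F1/specificity; covariance-form MCC;
    full-matrix kappa.  Reduces to :func:`binary_metrics` at K=2 for MCC/kappa."""
    if cm.total == 0:
        raise InputError("empty confusion matrix")
    if average != "macro":
        raise InputError(f"unsupported averaging {average!r}")
    c = cm.counts.astype(np.float64)
    n = c.sum()
    k = cm.num_classes
    tp = np.diag(c)
    row = c.sum(axis=1)   # true-class totals
    col = c.sum(axis=0)   # predicted-class totals
    precisions, recalls, f1s, specs = [], [], [], []
    for i in range(k):
        p = _safe_div(tp[i], col[i], f"precision[{i}]")
        r = _safe_div(tp[i], row[i], f"recall[{i}]")
        tn = n - row[i] - col[i] + tp[i]
        s = _safe_div(tn, n - row[i], f"specificity[{i}]")
        precisions.append(p)
        recalls.append(r)
        specs.append(s)
        f1s.append(_safe_div(2 * p * r, p + r, f"F1[{i}]"))
    accuracy = tp.sum() / n
    # covariance form of the multiclass Matthews correlation
    cov_xy = tp.sum() * n - float(row @ col)
    cov_xx = n * n - float(col @ col)
    cov_yy = n * n - float(row @ row)
    mcc = _safe_div(cov_xy, np.sqrt(cov_xx) * np.sqrt(cov_yy), "MCC")
    p0 = accuracy
    pe = float(row @ col) / (n * n)
    kappa = _safe_div(p0 - pe, 1.0 - pe, "kappa")
    return MetricReport(accuracy=float(accuracy),
                        precision=float(np.mean(precisions)),
                        sensitivity=float(np.mean(recalls)),
                        specificity=float(np.mean(specs)),
                        f1=float(np.mean(f1s)), mcc=float(mcc),
                        kappa=float(kappa), averaging="macro")


def roc_curve(y_true, scores, positive_class: int = 1) -> ROCCurve:
    """Threshold sweep over the unique scores, ties grouped; AUC by trapezoid."""
    y = (np.asarray(y_true) == positive_class)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise InputError("y_true and scores differ in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC undefined: need at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.where(np.diff(s_sorted))[0]
    cut = np.r_[distinct, y.size - 1]
    tps = np.cumsum(y_sorted)[cut]
    fps = 1 + cut - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[cut]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def roc_auc(y_true, scores, positive_class: int = 1) -> float:
    return roc_curve(y_true, scores, positive_class).auc


def multiclass_roc_auc(y_true, score_matrix) -> float:
    """Unweighted mean of per-class one-vs-rest AUCs over (n, K) scores."""
    scores = np.asarray(score_matrix, dtype=np.float64)
    y = np.asarray(y_true)
    if scores.ndim != 2:
        raise InputError("score_matrix must be (n_samples, n_classes)")
    aucs = [roc_auc((y == k).astype(int), scores[:, k], positive_class=1)
            for k in range(scores.shape[1])]
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_confusion_matrix(cm: ConfusionMatrix, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4 + 0.3 * cm.num_classes,) * 2)
    im = ax.imshow(cm.counts, cmap="Blues")
    for i in range(cm.num_classes):
        for j in range(cm.num_classes):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
    ax.set_xticks(range(cm.num_classes), cm.class_labels, rotation=45)
    ax.set_yticks(range(cm.num_classes), cm.class_labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(curves: dict[str, ROCCurve], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC={curve.auc:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
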