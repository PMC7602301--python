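"""Binary classification metrics: confusion-based scores, ROC and PR curves.

The threshold metrics are the standard six reported by modification-site
predictors: sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP),
precision Pre = TP/(TP+FP), accuracy Acc = (TP+TN)/(TP+TN+FP+FN), Matthews
correlation coefficient, and F1 = 2TP/(2TP+FP+FN).  A ratio with a zero
denominator is reported as 0 and flagged (``degenerate``) rather than
raising, so greedy feature selection survives pathological folds.

Curves use scikit-learn's sweeps; AUROC is the trapezoidal area (with tied
scores grouped, this equals the Mann-Whitney U statistic over n+ * n-) and
AUPRC uses the step-wise (non-interpolated) sum, i.e. average precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    Sn: float
    Sp: float
    Pre: float
    Acc: float
    Mcc: float
    F1: float
    AUROC: float = float("nan")
    AUPRC: float = float("nan")
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "Sn": self.Sn, "Sp": self.Sp, "Pre": self.Pre, "Acc": self.Acc,
            "Mcc": self.Mcc, "F1": self.F1, "AUROC": self.AUROC, "AUPRC": self.AUPRC,
        }


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal-length")
    if scores.size == 0:
        raise ValueError("empty input")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    return scores, labels


def confusion_at_threshold(scores, labels, threshold: float = 0.0) -> ConfusionCounts:
    """Count TP/TN/FP/FN with 'score >= threshold' called positive."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _safe_ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from a confusion table (AUROC/AUPRC left NaN)."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    flags: list[str] = []
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    sn = _safe_ratio(tp, tp + fn, "Sn", flags)
    sp = _safe_ratio(tn, tn + fp, "Sp", flags)
    pre = _safe_ratio(tp, tp + fp, "Pre", flags)
    acc = (tp + tn) / (tp + tn + fp + fn)
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_ratio(tp * tn - fp * fn, mcc_den, "Mcc", flags)
    f1 = _safe_ratio(2 * tp, 2 * tp + fp + fn, "F1", flags)
    return MetricsReport(Sn=sn, Sp=sp, Pre=pre, Acc=acc, Mcc=mcc, F1=f1,
                         degenerate=flags)


def roc_points(scores, labels) -> np.ndarray:
    """All-thresholds ROC sweep as an array of (threshold, FPR, TPR) rows,
    tied scores grouped."""
    scores, labels = _check_scores_labels(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = roc_curve(labels, scores)
    return np.column_stack([thr, fpr, tpr])


def auroc(scores, labels) -> float:
    """Area under the ROC curve by the trapezoid rule."""
    curve = roc_points(scores, labels)
    return float(np.trapezoid(curve[:, 2], curve[:, 1]))


def prc_points(scores, labels) -> np.ndarray:
    """Precision-recall sweep as (threshold, recall, precision) rows."""
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() == 0:
        raise ValueError("PRC requires at least one positive")
    prec, rec, thr = precision_recall_curve(labels, scores)
    # sklearn appends a final (recall=0, precision=1) anchor with no threshold
    thr = np.append(thr, np.inf)
    return np.column_stack([thr, rec, prec])


def auprc(scores, labels) -> float:
    """Area under the PR curve by the step-wise (non-interpolated) rule."""
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() == 0:
        raise ValueError("PRC requires at least one positive")
    if labels.min() == labels.max():
        return 1.0  # all positives: precision 1 at every recall
    return float(average_precision_score(labels, scores))


def score_report(scores, labels, threshold: float = 0.0) -> MetricsReport:
    """Full metric suite (threshold metrics + AUROC/AUPRC) at a threshold."""
    report = compute_metrics(confusion_at_threshold(scores, labels, threshold))
    labels_arr = np.asarray(labels)
    if labels_arr.min() != labels_arr.max():
        report.AUROC = auroc(scores, labels)
        report.AUPRC = auprc(scores, labels)
    return report
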