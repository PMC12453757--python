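"""Binary-classification evaluation mathematics.

Implements the complete diagnostic metric family on a 2x2 confusion
matrix — accuracy, precision, recall/sensitivity, specificity, balanced
accuracy (the sensitivity/specificity mean) and F1 — plus the ROC curve
and its trapezoidal AUC, and a fixed-layout classification report with
per-class, macro and support-weighted rows.

Conventions: label 1 is the positive (disease) class; zero-denominator
metrics are reported as 0.0 with a ``degenerate`` flag rather than raised,
so trivial majority-class predictors remain representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "confusion_matrix",
    "scalar_metrics",
    "roc_curve",
    "roc_auc",
    "classification_report",
    "format_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts; positive class = 1."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def support_positive(self) -> int:
        return self.tp + self.fn

    @property
    def support_negative(self) -> int:
        return self.tn + self.fp


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class MetricsReport:
    """Every scalar metric of the evaluation battery.

    ``per_class`` holds precision/recall/F1/support with each class in
    turn treated as positive; macro averages are unweighted class means,
    weighted averages use class supports. ``degenerate`` flags any
    zero-denominator metric that was reported as 0.0.
    """

    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    per_class: dict[int, ClassMetrics]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion: ConfusionMatrix
    auc: float | None = None
    degenerate: bool = False


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not set(np.unique(arr).tolist()) <= {0, 1}:
            raise ValueError(f"{name} contains non-binary values")
    return ConfusionMatrix(
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
    )


def _safe_div(num: float, den: float, flags: list[bool]) -> float:
    if den == 0:
        flags.append(True)
        return 0.0
    return num / den


def scalar_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All confusion-matrix-derived metrics (AUC excluded).

    accuracy = (TP+TN)/total; precision = TP/(TP+FP);
    recall = sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    balanced accuracy = (sensitivity+specificity)/2;
    F1 = 2·precision·recall/(precision+recall).
    Class-0 rows are computed by relabelling 0 as positive.
    """
    flags: list[bool] = []
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = _safe_div(cm.tp, cm.tp + cm.fn, flags)
    specificity = _safe_div(cm.tn, cm.tn + cm.fp, flags)

    per_class: dict[int, ClassMetrics] = {}
    for cls in (0, 1):
        if cls == 1:
            tp, fp, fn, support = cm.tp, cm.fp, cm.fn, cm.support_positive
        else:
            tp, fp, fn, support = cm.tn, cm.fn, cm.fp, cm.support_negative
        precision = _safe_div(tp, tp + fp, flags)
        recall = _safe_div(tp, tp + fn, flags)
        f1 = _safe_div(2 * precision * recall, precision + recall, flags)
        per_class[cls] = ClassMetrics(precision, recall, f1, support)

    supports = np.array([per_class[0].support, per_class[1].support], dtype=float)
    weights = supports / supports.sum()

    def _avg(attr: str) -> tuple[float, float]:
        vals = np.array([getattr(per_class[0], attr), getattr(per_class[1], attr)])
        return float(vals.mean()), float(vals @ weights)

    macro_p, weighted_p = _avg("precision")
    macro_r, weighted_r = _avg("recall")
    macro_f1, weighted_f1 = _avg("f1")

    return MetricsReport(
        accuracy=accuracy,
        balanced_accuracy=(sensitivity + specificity) / 2,
        sensitivity=sensitivity,
        specificity=specificity,
        per_class=per_class,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f1,
        weighted_precision=weighted_p,
        weighted_recall=weighted_r,
        weighted_f1=weighted_f1,
        confusion=cm,
        degenerate=bool(flags),
    )


def roc_curve(y_true, scores) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points over all distinct score thresholds, ties grouped.

    Returns (fpr, tpr, thresholds) with a leading (0, 0) point at
    threshold +inf.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch between labels and scores")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_true = y_true[order]
    # indices where a new (lower) threshold begins
    distinct = np.flatnonzero(np.diff(sorted_scores)) if len(scores) > 1 else np.array([], int)
    boundaries = np.concatenate([distinct, [len(scores) - 1]])
    tps = np.cumsum(sorted_true == 1)[boundaries]
    fps = np.cumsum(sorted_true == 0)[boundaries]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], sorted_scores[boundaries]])
    return fpr, tpr, thresholds


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC.

    The trapezoid over tie-grouped thresholds equals the Mann-Whitney
    probability P(s+ > s-) + 0.5·P(s+ = s-).
    """
    fpr, tpr, _ = roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def classification_report(y_true, y_pred, scores=None) -> MetricsReport:
    """Assemble the full report (scalar metrics + AUC when scores given)."""
    report = scalar_metrics(confusion_matrix(y_true, y_pred))
    if scores is not None:
        _, report.auc = roc_auc(y_true, scores)
    return report


def format_report(report: MetricsReport) -> str:
    """Fixed-layout text table: 2-decimal class rows, 4-decimal summary."""
    cm = report.confusion
    lines = [
        f"{'':>14}{'precision':>11}{'recall':>10}{'f1-score':>10}{'support':>9}",
        "",
    ]
    for cls in (0, 1):
        m = report.per_class[cls]
        lines.append(
            f"{'class ' + str(cls):>14}{m.precision:>11.2f}{m.recall:>10.2f}"
            f"{m.f1:>10.2f}{m.support:>9d}"
        )
    lines.append("")
    lines.append(f"{'accuracy':>14}{'':>21}{report.accuracy:>10.2f}{cm.total:>9d}")
    lines.append(
        f"{'macro avg':>14}{report.macro_precision:>11.2f}{report.macro_recall:>10.2f}"
        f"{report.macro_f1:>10.2f}{cm.total:>9d}"
    )
    lines.append(
        f"{'weighted avg':>14}{report.weighted_precision:>11.2f}"
        f"{report.weighted_recall:>10.2f}{report.weighted_f1:>10.2f}{cm.total:>9d}"
    )
    lines.append("")
    lines.append("Confusion matrix (rows: true 0/1, cols: predicted 0/1)")
    lines.append(f"  [[{cm.tn:>6d} {cm.fp:>6d}]")
    lines.append(f"   [{cm.fn:>6d} {cm.tp:>6d}]]")
    lines.append("")
    summary = [
        ("Accuracy", report.accuracy),
        ("Balanced accuracy", report.balanced_accuracy),
        ("Sensitivity", report.sensitivity),
        ("Specificity", report.specificity),
        ("Macro F1", report.macro_f1),
    ]
    if report.auc is not None:
        summary.append(("AUC", report.auc))
    for name, value in summary:
        lines.append(f"{name:<19} {value:.4f}")
    if report.degenerate:
        lines.append("note: zero-denominator metric(s) reported as 0.0")
    return "\n".join(lines)
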