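"""Binary-classification metric suite in the per-class table convention.

Each class in turn is treated as the positive class and gets a row of
accuracy, precision, recall, F-score, MCC and G-measure. The per-class
"accuracy" column is the class recall (and the table's average row is
therefore macro recall) — the convention under which a single confusion
matrix reproduces a consistent two-row-plus-average table. Values are
scaled to percent; presentation rounds half-up to two decimals *after*
averaging unrounded values.

MCC is symmetric in the two classes of a binary problem, so it repeats
across rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion",
    "class_metrics",
    "macro_average",
    "round_half_up",
    "metrics_table",
]

METRIC_FIELDS = ("accuracy", "precision", "recall", "f_score", "mcc", "g_measure")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as used for presentation."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; rows = true class, cols = predicted, in ``classes`` order."""

    counts: np.ndarray
    classes: tuple[str, str] = ("mitosis", "non_mitosis")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cells(self, positive_class: str) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) with ``positive_class`` as positive."""
        i = self.classes.index(positive_class)
        j = 1 - i
        c = self.counts
        return int(c[i, i]), int(c[i, j]), int(c[j, i]), int(c[j, j])


@dataclass(frozen=True)
class ClassMetrics:
    """One table row, percent scale (MCC in [-100, 100], rest in [0, 100])."""

    accuracy: float
    precision: float
    recall: float
    f_score: float
    mcc: float
    g_measure: float
    warnings: tuple[str, ...] = field(default=())

    def rounded(self) -> dict:
        return {k: round_half_up(getattr(self, k)) for k in METRIC_FIELDS}


def confusion(y_true, y_pred, classes: tuple[str, str] = ("mitosis", "non_mitosis")) -> ConfusionMatrix:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must align")
    counts = np.zeros((2, 2), dtype=int)
    index = {c: k for k, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def _safe_ratio(num: float, den: float, name: str, warnings: list) -> float:
    if den == 0:
        warnings.append(f"{name} undefined (zero denominator); reported as 0")
        return 0.0
    return num / den


def class_metrics(cm: ConfusionMatrix, positive_class: str) -> ClassMetrics:
    """Metric row for one class: precision TP/(TP+FP), recall TP/(TP+FN),
    accuracy := recall, F = 2PR/(P+R), the four-cell MCC, G = sqrt(PR)."""
    tp, fn, fp, tn = cm.cells(positive_class)
    warnings: list[str] = []
    precision = _safe_ratio(tp, tp + fp, "precision", warnings)
    recall = _safe_ratio(tp, tp + fn, "recall", warnings)
    f_score = _safe_ratio(2 * precision * recall, precision + recall, "f_score", warnings)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_ratio(tp * tn - fp * fn, mcc_den, "mcc", warnings)
    g_measure = math.sqrt(precision * recall)
    return ClassMetrics(
        accuracy=100.0 * recall,
        precision=100.0 * precision,
        recall=100.0 * recall,
        f_score=100.0 * f_score,
        mcc=100.0 * mcc,
        g_measure=100.0 * g_measure,
        warnings=tuple(warnings),
    )


def macro_average(rows: list[ClassMetrics]) -> ClassMetrics:
    """Arithmetic mean per metric over the (unrounded) class rows."""
    if not rows:
        raise ValueError("need at least one class row")
    means = {k: float(np.mean([getattr(r, k) for r in rows])) for k in METRIC_FIELDS}
    warnings = tuple(w for r in rows for w in r.warnings)
    return ClassMetrics(**means, warnings=warnings)


def metrics_table(cm: ConfusionMatrix) -> dict:
    """Per-class rows plus the average row, rounded for presentation."""
    rows = {cls: class_metrics(cm, cls) for cls in cm.classes}
    table = {cls: row.rounded() for cls, row in rows.items()}
    table["average"] = macro_average(list(rows.values())).rounded()
    return table
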