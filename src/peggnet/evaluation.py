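"""Confusion matrices, accuracy/precision/recall/F1, and grade consolidation.

Metrics follow the one-vs-rest reading of a K x K confusion matrix
(rows = true class, columns = predicted class): for class i,
TP = counts[i,i], FN = row_i - TP, FP = col_i - TP, TN = total - TP - FN - FP.
Multiclass accuracy is trace/total (the K=2 one-vs-rest form reduces to the
same number).  A zero denominator yields 0 with a logged warning, so tiny
evaluations never crash.

``consolidate_grades`` merges the three substandard classes (PP, BYP, YYP)
into the single SP grade, turning the 5-class task into the 3-grade sorting
task.  Within-grade confusions land on the diagonal, so grading accuracy is
never below classification accuracy.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np

from .data import EggGrade, EggLabel, GRADE_OF

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "consolidate_grades",
    "report_table",
    "report_csv",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    labels: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K matching labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self):
        return int(self.counts.sum())

    def ovr(self, i):
        """(TP, FN, FP, TN) one-vs-rest reduction for class index i."""
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum()) - tp
        fp = int(self.counts[:, i].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn


def confusion(true_labels, pred_labels, labels=None):
    """Count matrix: counts[i, j] = #{true == i, predicted == j}."""
    t = np.asarray([getattr(x, "value", x) for x in true_labels], dtype=int)
    p = np.asarray([getattr(x, "value", x) for x in pred_labels], dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted label sequences differ in length")
    if labels is None:
        labels = [l.name for l in EggLabel]
    k = len(labels)
    if t.size and (t.min() < 0 or t.max() >= k or p.min() < 0 or p.max() >= k):
        raise ValueError(f"labels must lie in 0..{k - 1}")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, list(labels))


def _safe_div(num, den, what):
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", what)
        return 0.0
    return num / den


def accuracy(cm: ConfusionMatrix):
    return _safe_div(float(np.trace(cm.counts)), cm.total, "accuracy")


def precision(cm: ConfusionMatrix, class_index):
    tp, _, fp, _ = cm.ovr(class_index)
    return _safe_div(tp, tp + fp, f"precision[{cm.labels[class_index]}]")


def recall(cm: ConfusionMatrix, class_index):
    tp, fn, _, _ = cm.ovr(class_index)
    return _safe_div(tp, tp + fn, f"recall[{cm.labels[class_index]}]")


def f1(cm: ConfusionMatrix, class_index):
    p = precision(cm, class_index)
    r = recall(cm, class_index)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def consolidate_grades(cm5: ConfusionMatrix):
    """Merge the substandard classes of a 5-class matrix into the SP grade."""
    expected = [l.name for l in EggLabel]
    if list(cm5.labels) != expected:
        raise ValueError(f"expected labels {expected}, got {list(cm5.labels)}")
    grades = [g.name for g in EggGrade]
    proj = np.zeros((len(expected), len(grades)), dtype=int)
    for label in EggLabel:
        proj[label.value, GRADE_OF[label].value] = 1
    return ConfusionMatrix(proj.T @ cm5.counts @ proj, grades)


def report_table(cm: ConfusionMatrix, model_name="model", param_str=None):
    """Fixed-width report: per-class F1 (percent) columns + overall accuracy."""
    cols = [f"{l} Egg" for l in cm.labels]
    header = ["Model"] + (["Parameter"] if param_str else [])
    header += [f"F1 {c}/%" for c in cols] + ["Accuracy/%"]
    row = [model_name] + ([param_str] if param_str else [])
    row += [f"{100 * f1(cm, i):.1f}" for i in range(len(cm.labels))]
    row += [f"{100 * accuracy(cm):.1f}"]
    widths = [max(len(h), len(v)) for h, v in zip(header, row)]
    out = io.StringIO()
    out.write("  ".join(h.ljust(w) for h, w in zip(header, widths)) + "\n")
    out.write("  ".join(v.ljust(w) for v, w in zip(row, widths)) + "\n")
    return out.getvalue()


def report_csv(cm: ConfusionMatrix, model_name="model"):
    lines = ["model,class,f1_percent,accuracy_percent"]
    acc = f"{100 * accuracy(cm):.1f}"
    for i, label in enumerate(cm.labels):
        lines.append(f"{model_name},{label},{100 * f1(cm, i):.1f},{acc}")
    return "\n".join(lines) + "\n"
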