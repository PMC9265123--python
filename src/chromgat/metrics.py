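"""Evaluation metrics for multiclass classification.

Per class (one-vs-rest counts TP/FP/FN/TN from the confusion matrix):

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)   (harmonic mean of the two)
    accuracy  = trace / total

Macro averages weight classes equally; weighted averages weight by support.
Zero denominators yield 0 with a flag rather than NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    zero_division: bool = False


@dataclass
class EvalReport:
    """Confusion matrix plus per-class and averaged metrics.

    ``unit`` records what one evaluated item is (a whole sample graph or a
    single aberration), since the two evaluation scales are not comparable.
    """

    confusion: np.ndarray
    class_order: list[str]
    per_class: dict[str, ClassMetrics]
    accuracy: float
    macro: tuple[float, float, float]
    weighted: tuple[float, float, float]
    unit: str = "graphs"

    def to_dict(self, round_digits: int | None = None) -> dict:
        def r(x: float) -> float:
            return round(x, round_digits) if round_digits is not None else x

        return {
            "unit": self.unit,
            "class_order": self.class_order,
            "confusion": self.confusion.astype(int).tolist(),
            "accuracy": r(self.accuracy),
            "per_class": {
                c: {"precision": r(m.precision), "recall": r(m.recall),
                    "f1": r(m.f1), "support": m.support}
                for c, m in self.per_class.items()
            },
            "macro": {"precision": r(self.macro[0]), "recall": r(self.macro[1]),
                      "f1": r(self.macro[2])},
            "weighted": {"precision": r(self.weighted[0]), "recall": r(self.weighted[1]),
                         "f1": r(self.weighted[2])},
        }

    def save(self, path: str | Path, round_digits: int | None = None) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(round_digits), indent=2, sort_keys=True) + "\n"
        )


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    m = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label {t if t not in index else p!r} not in class_order")
        m[index[t], index[p]] += 1
    return m


def column_normalize(confusion: np.ndarray) -> np.ndarray:
    """Normalize each column to sum to 1; all-zero columns stay zero."""
    confusion = np.asarray(confusion, dtype=float)
    sums = confusion.sum(axis=0, keepdims=True)
    out = np.divide(confusion, sums, out=np.zeros_like(confusion), where=sums > 0)
    return out


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def macro_average(values: Sequence[float]) -> float:
    return float(np.mean(values))


def weighted_average(values: Sequence[float], supports: Sequence[float]) -> float:
    values = np.asarray(values, dtype=float)
    supports = np.asarray(supports, dtype=float)
    return float((values * supports).sum() / supports.sum())


def classification_report(
    confusion: np.ndarray,
    class_order: Sequence[str],
    unit: str = "graphs",
) -> EvalReport:
    """Full metric report from a square count matrix."""
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = confusion.sum()
    per_class: dict[str, ClassMetrics] = {}
    for i, c in enumerate(class_order):
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        zero = False
        if tp + fp == 0:
            precision, zero = 0.0, True
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            recall, zero = 0.0, True
        else:
            recall = tp / (tp + fn)
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        per_class[c] = ClassMetrics(
            precision=float(precision), recall=float(recall), f1=float(f1),
            support=int(confusion[i, :].sum()), zero_division=zero,
        )
    supports = [per_class[c].support for c in class_order]
    cols = {
        k: [getattr(per_class[c], k) for c in class_order]
        for k in ("precision", "recall", "f1")
    }
    return EvalReport(
        confusion=confusion,
        class_order=list(class_order),
        per_class=per_class,
        accuracy=float(np.trace(confusion) / total) if total else 0.0,
        macro=tuple(macro_average(cols[k]) for k in ("precision", "recall", "f1")),
        weighted=tuple(weighted_average(cols[k], supports) for k in ("precision", "recall", "f1")),
        unit=unit,
    )


def report_from_labels(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
    unit: str = "graphs",
) -> EvalReport:
    return classification_report(
        confusion_matrix(true_labels, predicted_labels, class_order),
        class_order,
        unit=unit,
    )


def write_confusion_tsv(confusion: np.ndarray, class_order: Sequence[str],
                        path: str | Path) -> None:
    confusion = np.asarray(confusion)
    with open(path, "w") as fh:
        fh.write("true\\pred\t" + "\t".join(class_order) + "\n")
        for c, row in zip(class_order, confusion):
            fh.write(c + "\t" + "\t".join(f"{x:g}" for x in row) + "\n")
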