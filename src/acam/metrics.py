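"""Multiclass evaluation: accuracy, balanced accuracy, macro F1, MCC.

All four metrics are computed from a single true-vs-predicted confusion
matrix with rows indexed by the true label and columns by the predicted
label. The macro F1 here is the harmonic mean of macro-averaged precision
and macro-averaged recall, which differs from the more common arithmetic
mean of per-class F1 scores; ``macro_f1_mode="per-class"`` selects the
latter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows: true label, cols: predicted label
    label_order: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        t = len(self.label_order)
        if self.counts.shape != (t, t):
            raise ValueError("confusion matrix shape must match label order")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    true_labels: dict[str, str], pred_labels: dict[str, str]
) -> ConfusionMatrix:
    """Cross-tabulate true against predicted labels over the same cells.

    Labels like "unknown"/"unassigned" are ordinary classes here: a cell
    predicted "unknown" counts as an error unless its true label is also
    "unknown". The label order is the sorted union of both label sets.
    """
    if set(true_labels) != set(pred_labels):
        raise ValueError("true and predicted labelings cover different cells")
    labels = sorted(set(true_labels.values()) | set(pred_labels.values()))
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for cell, t in true_labels.items():
        counts[idx[t], idx[pred_labels[cell]]] += 1
    return ConfusionMatrix(counts=counts, label_order=labels)


def evaluate(cm: ConfusionMatrix, macro_f1_mode: str = "macro-pr") -> dict[str, float]:
    """Compute accuracy, balanced accuracy, macro F1 and multiclass MCC.

    Zero-division conventions (logged, not silent): a class never seen in
    the truth contributes recall 0; a class never predicted contributes
    precision 0; an undefined MCC denominator yields MCC = 0.
    """
    c = cm.counts.astype(float)
    n = c.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c)
    row = c.sum(axis=1)  # true-class marginals (TP + FN)
    col = c.sum(axis=0)  # predicted-class marginals (TP + FP)

    accuracy = tp.sum() / n

    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, tp / row, 0.0)
        precision = np.where(col > 0, tp / col, 0.0)
    if (row == 0).any():
        logger.info("class(es) absent from truth: recall taken as 0")
    if (col == 0).any():
        logger.info("class(es) never predicted: precision taken as 0")

    balanced_accuracy = float(recall.mean())
    avg_p, avg_r = float(precision.mean()), float(recall.mean())
    if macro_f1_mode == "macro-pr":
        macro_f1 = (
            2 * avg_p * avg_r / (avg_p + avg_r) if (avg_p + avg_r) > 0 else 0.0
        )
    elif macro_f1_mode == "per-class":
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = np.where(
                precision + recall > 0,
                2 * precision * recall / (precision + recall),
                0.0,
            )
        macro_f1 = float(f1.mean())
    else:
        raise ValueError(f"unknown macro_f1_mode {macro_f1_mode!r}")

    # covariance-style multiclass MCC from the marginals
    cov = tp.sum() * n - float(col @ row)
    den = np.sqrt(n**2 - float(col @ col)) * np.sqrt(n**2 - float(row @ row))
    if den == 0:
        logger.info("MCC denominator is 0; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = cov / den

    return {
        "accuracy": float(accuracy),
        "balanced_accuracy": balanced_accuracy,
        "macro_f1": float(macro_f1),
        "mcc": float(mcc),
    }
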