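"""Confusion-matrix based classification metrics.

Accuracy is the fraction of correctly classified instances,
``(TP+TN)/(TP+TN+FP+FN)`` in the binary case; F1 is the harmonic mean of
precision and recall, ``2*TP/(2*TP+FP+FN)``, extended to the multi-class
setting as the unweighted (macro) or support-weighted mean of per-class
one-vs-rest F1 scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

BINARY = "binary"
MACRO = "macro"
WEIGHTED = "weighted"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, positive: int) -> Dict[str, int]:
        """TP/FP/FN/TN treating ``positive`` as the positive class."""
        c = self.counts
        tp = int(c[positive, positive])
        fn = int(c[positive].sum() - tp)
        fp = int(c[:, positive].sum() - tp)
        tn = int(c.sum() - tp - fn - fp)
        return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.n == 0:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.n)


def _f1_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0  # no support, no predictions -> 0


def f1_score(cm: ConfusionMatrix, averaging: str = MACRO,
             positive_class: int = 1) -> float:
    """Binary F1 (``2*TP/(2*TP+FP+FN)``) or a macro/weighted multi-class mean."""
    if averaging == BINARY:
        if cm.n_classes != 2:
            raise ValueError("binary averaging requires exactly two classes")
        ovr = cm.one_vs_rest(positive_class)
        return _f1_from_counts(ovr["TP"], ovr["FP"], ovr["FN"])
    if averaging not in (MACRO, WEIGHTED):
        raise ValueError(f"unknown averaging {averaging!r}")
    per_class = []
    support = cm.counts.sum(axis=1)
    for k in range(cm.n_classes):
        ovr = cm.one_vs_rest(k)
        per_class.append(_f1_from_counts(ovr["TP"], ovr["FP"], ovr["FN"]))
    per_class = np.array(per_class)
    if averaging == MACRO:
        return float(per_class.mean())
    if support.sum() == 0:
        raise ValueError("cannot weight by support on an empty matrix")
    return float((per_class * support).sum() / support.sum())
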