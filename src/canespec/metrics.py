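"""Accuracy metrics: Pearson R and RMSE for regression, confusion
matrix with producer's / user's / overall accuracy for classification.

Remote-sensing convention throughout: confusion-matrix rows are actual
classes, columns predicted; producer's accuracy (PA) is per-class
recall, user's accuracy (UA) per-class precision, overall accuracy
(OA) the trace over the total.  Percentages are computed in exact
rational arithmetic and rounded to one decimal only for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np


def rmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


def pearson_r(actual: np.ndarray, predicted: np.ndarray) -> float | None:
    """Pearson correlation between measured and predicted values.

    Returns None (with a warning) when either side is constant, where
    the correlation is undefined.
    """
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    if np.std(actual) == 0 or np.std(predicted) == 0:
        warnings.warn("constant sequence: Pearson R undefined", stacklevel=2)
        return None
    return float(np.corrcoef(actual, predicted)[0, 1])


def _pct(fr: Fraction) -> float:
    """Exact fraction -> percent, one decimal."""
    return float(round(fr * 100, 1))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows actual, columns predicted, labels ordered.

    Label order defines adjacency: classes whose positions differ by
    one (e.g. neighbouring irrigation amounts) are "adjacent", so
    misclassifications can be split into near misses and far misses.
    """

    labels: tuple
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError("counts must be K x K matching labels")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def misclassified(self) -> int:
        return self.total - int(np.trace(self.counts))

    def adjacency_split(self) -> tuple[int, int]:
        """(adjacent, non-adjacent) misclassified counts."""
        k = len(self.labels)
        adj = sum(
            int(self.counts[i, j])
            for i in range(k)
            for j in range(k)
            if abs(i - j) == 1
        )
        return adj, self.misclassified - adj

    def producers_accuracy(self) -> dict:
        """Per-class PA (%, 1 decimal); None for an empty actual class."""
        out = {}
        for i, lab in enumerate(self.labels):
            row = int(self.counts[i].sum())
            out[lab] = _pct(Fraction(int(self.counts[i, i]), row)) if row else None
        return out

    def users_accuracy(self) -> dict:
        """Per-class UA (%, 1 decimal); None for a never-predicted class."""
        out = {}
        for j, lab in enumerate(self.labels):
            col = int(self.counts[:, j].sum())
            out[lab] = _pct(Fraction(int(self.counts[j, j]), col)) if col else None
        return out

    def overall_accuracy(self) -> float:
        return _pct(Fraction(int(np.trace(self.counts)), self.total))

    def metrics(self) -> dict:
        adj, far = self.adjacency_split()
        return {
            "labels": list(self.labels),
            "counts": self.counts.tolist(),
            "PA": self.producers_accuracy(),
            "UA": self.users_accuracy(),
            "OA": self.overall_accuracy(),
            "total": self.total,
            "misclassified": self.misclassified,
            "misclassified_adjacent": adj,
            "misclassified_nonadjacent": far,
        }


def confusion_metrics(counts, labels=None) -> dict:
    """PA/UA/OA and adjacency breakdown from a raw count matrix."""
    counts = np.asarray(counts, dtype=np.int64)
    if labels is None:
        labels = tuple(range(counts.shape[0]))
    return ConfusionMatrix(tuple(labels), counts).metrics()
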