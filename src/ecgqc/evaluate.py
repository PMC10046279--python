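"""Confusion matrices and metrics for the 3-class and merged 2-class views.

Rows are truth, columns are prediction, in the fixed order acceptable /
unacceptable / uncertain.  The merged 2x2 view collapses acceptable +
uncertain into one "usable" class against unacceptable — the practical
data-selection question — by summing the corresponding 3x3 blocks.

Precision or recall with an empty denominator (a class never predicted, or
absent from the truth) is reported as NaN, never silently as 0, so
degenerate test sets cannot inflate averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .pipeline import LABELS, _as_str_labels

__all__ = ["EvalReport", "confusion_3x3", "merge_2x2", "metrics", "evaluate"]

MERGED_LABELS = ("acceptable+uncertain", "unacceptable")


def confusion_3x3(truth, pred) -> np.ndarray:
    """Count matrix: cell (i, j) counts truth class i predicted as class j."""
    truth = _as_str_labels(truth)
    pred = _as_str_labels(pred)
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(pred)} predictions")
    index = {c: i for i, c in enumerate(LABELS)}
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(truth, pred):
        cm[index[t], index[p]] += 1
    return cm


def merge_2x2(cm3: np.ndarray) -> np.ndarray:
    """Collapse acceptable + uncertain against unacceptable by block sums."""
    cm3 = np.asarray(cm3)
    if cm3.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got {cm3.shape}")
    usable = [0, 2]  # acceptable, uncertain
    bad = [1]
    cm2 = np.zeros((2, 2), dtype=cm3.dtype)
    cm2[0, 0] = cm3[np.ix_(usable, usable)].sum()
    cm2[0, 1] = cm3[np.ix_(usable, bad)].sum()
    cm2[1, 0] = cm3[np.ix_(bad, usable)].sum()
    cm2[1, 1] = cm3[np.ix_(bad, bad)].sum()
    return cm2


def metrics(cm: np.ndarray) -> Dict[str, object]:
    """Per-class precision and recall plus overall accuracy from a square matrix.

    ``precision_j = cm[j, j] / column_sum_j``, ``recall_i = cm[i, i] /
    row_sum_i``, ``accuracy = trace / total``.  Empty denominators yield NaN.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be nonnegative")
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    diag = np.diag(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, np.nan)
        recall = np.where(row > 0, diag / row, np.nan)
    total = cm.sum()
    accuracy = float(diag.sum() / total) if total > 0 else float("nan")
    return {"precision": precision, "recall": recall, "accuracy": accuracy}


@dataclass
class EvalReport:
    """3x3 and merged 2x2 confusion matrices with their metrics."""

    cm3: np.ndarray
    cm2: np.ndarray
    precision3: np.ndarray
    recall3: np.ndarray
    accuracy3: float
    precision2: np.ndarray
    recall2: np.ndarray
    accuracy2: float

    @property
    def n(self) -> int:
        return int(self.cm3.sum())

    def to_dict(self) -> dict:
        def _clean(a):
            return [None if not np.isfinite(v) else float(v) for v in np.atleast_1d(a)]

        return {
            "labels": list(LABELS),
            "merged_labels": list(MERGED_LABELS),
            "cm3": self.cm3.tolist(),
            "cm2": self.cm2.tolist(),
            "precision3": _clean(self.precision3),
            "recall3": _clean(self.recall3),
            "accuracy3": self.accuracy3,
            "precision2": _clean(self.precision2),
            "recall2": _clean(self.recall2),
            "accuracy2": self.accuracy2,
            "n": self.n,
        }


def evaluate(truth, pred) -> EvalReport:
    """Full report from parallel truth/prediction label sequences."""
    cm3 = confusion_3x3(truth, pred)
    cm2 = merge_2x2(cm3)
    m3 = metrics(cm3)
    m2 = metrics(cm2)
    return EvalReport(
        cm3=cm3,
        cm2=cm2,
        precision3=m3["precision"],
        recall3=m3["recall"],
        accuracy3=m3["accuracy"],
        precision2=m2["precision"],
        recall2=m2["recall"],
        accuracy2=m2["accuracy"],
    )
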