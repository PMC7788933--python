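"""Segmentation metrics: confusion counts, mean IoU, Dice.

The confusion matrix is (k+1) x (k+1) over background plus k foreground
categories, with ``p[i, j]`` the number of pixels whose true class is i and
predicted class is j.  Mean IoU averages per-class ``TP / (TP + FP + FN)``
over all k+1 classes; for binary masks the Dice coefficient is
``2 TP / (2 TP + FP + FN)``, identical to ``2|X∩Y| / (|X| + |Y|)`` on the
pixel sets, and relates to the foreground IoU by Dice = 2 IoU / (1 + IoU).

A class absent from both prediction and truth has an empty union; by default
it contributes IoU 1 (perfect agreement on absence), configurable via
``empty_value``.  Dataset-level ("pooled" / micro-averaged) metrics are
computed on summed confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "miou", "dice"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion matrix for k foreground categories (+ background)."""

    k: int
    p: np.ndarray            # (k+1, k+1) int64, rows = truth, cols = prediction

    def __post_init__(self):
        p = np.asarray(self.p)
        if p.shape != (self.k + 1, self.k + 1):
            raise ValueError(f"confusion matrix must be {self.k + 1}x{self.k + 1}")
        if (p < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.p.sum())

    def tp(self, i: int) -> int:
        return int(self.p[i, i])

    def fp(self, i: int) -> int:
        return int(self.p[:, i].sum() - self.p[i, i])

    def fn(self, i: int) -> int:
        return int(self.p[i, :].sum() - self.p[i, i])

    def tn(self, i: int) -> int:
        return self.total - self.tp(i) - self.fp(i) - self.fn(i)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if other.k != self.k:
            raise ValueError("cannot pool confusion counts with different k")
        return ConfusionCounts(self.k, self.p + other.p)


def confusion(pred: np.ndarray, truth: np.ndarray, k: int = 1) -> ConfusionCounts:
    """Accumulate the (k+1)-class pixel confusion matrix.

    Rows index the true class, columns the predicted class; entries sum to
    the number of evaluated pixels.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    pred = pred.astype(np.int64).ravel()
    truth = truth.astype(np.int64).ravel()
    n = k + 1
    for name, a in (("pred", pred), ("truth", truth)):
        if a.size and (a.min() < 0 or a.max() > k):
            raise ValueError(f"{name} labels must lie in 0..{k}")
    p = np.bincount(truth * n + pred, minlength=n * n).reshape(n, n)
    return ConfusionCounts(k, p)


def miou(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    """Mean intersection-over-union across the k+1 classes."""
    if c.total == 0:
        raise ValueError("confusion counts are empty")
    ious = []
    for i in range(c.k + 1):
        union = c.tp(i) + c.fp(i) + c.fn(i)
        ious.append(empty_value if union == 0 else c.tp(i) / union)
    return float(np.mean(ious))


def dice(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    """Binary Dice coefficient on the foreground class."""
    if c.k != 1:
        raise ValueError("dice is defined here for the binary case (k=1)")
    tp, fp, fn = c.tp(1), c.fp(1), c.fn(1)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return empty_value
    return 2 * tp / denom
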