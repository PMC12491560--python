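"""Pixel-confusion metrics for binary segmentation.

All metrics derive from the four confusion counts over pixels:

    Accuracy = (TP+TN) / (TP+TN+FP+FN)
    IoU      = TP / (TP+FP+FN)                    (foreground)
    Dice     = 2*TP / (2*TP+FP+FN)
    FWIoU    = sum_c (N_c / N_total) * IoU_c

The background class's IoU uses TN as its true-positive count
(IoU_bg = TN / (TN+FP+FN)) and class frequencies N_c are taken from the
ground truth.  When a class appears in neither prediction nor truth its
IoU is defined as 1, so empty masks evaluate cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DimensionError


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    def _check(self):
        if self.total == 0:
            raise DataError("confusion counts are all zero")


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/TN/FN between two binary maps of equal shape."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise DimensionError(f"shape mismatch {pred.shape} vs {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.isin(arr, (0, 1)).all():
            raise DataError(f"{name} map is not binary")
    p, t = pred.astype(bool), truth.astype(bool)
    return ConfusionCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))


def accuracy(c: ConfusionCounts) -> float:
    c._check()
    return (c.tp + c.tn) / c.total


def iou(c: ConfusionCounts) -> float:
    """Foreground intersection-over-union; 1 if foreground absent everywhere."""
    c._check()
    denom = c.tp + c.fp + c.fn
    return c.tp / denom if denom else 1.0


def iou_background(c: ConfusionCounts) -> float:
    """Background IoU: TN plays the true-positive role."""
    c._check()
    denom = c.tn + c.fp + c.fn
    return c.tn / denom if denom else 1.0


def dice(c: ConfusionCounts) -> float:
    c._check()
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else 1.0


def fwiou(per_class_iou, frequencies) -> float:
    """Frequency-weighted IoU: sum_c (N_c / N_total) * IoU_c."""
    per_class_iou = np.asarray(per_class_iou, dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    if per_class_iou.shape != frequencies.shape:
        raise DataError(
            f"{per_class_iou.size} IoU values for {frequencies.size} frequencies")
    total = frequencies.sum()
    if total <= 0:
        raise DataError("class frequencies sum to zero")
    return float((frequencies / total * per_class_iou).sum())


def metric_report(c: ConfusionCounts) -> dict:
    """All metrics from one set of pooled counts, JSON/CSV-ready."""
    iou_fg = iou(c)
    iou_bg = iou_background(c)
    n_fg = c.tp + c.fn
    n_bg = c.tn + c.fp
    return {
        "accuracy": accuracy(c),
        "iou_fg": iou_fg,
        "iou_bg": iou_bg,
        "miou": (iou_fg + iou_bg) / 2.0,
        "dice": dice(c),
        "fwiou": fwiou([iou_bg, iou_fg], [n_bg, n_fg]),
    }
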