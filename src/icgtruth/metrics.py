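"""Segmentation evaluation: confusion counts, IoU, Dice, pixel accuracy.

All metrics are computed on binary (background vs vessel) masks.  The
central object is :class:`ConfusionCounts`; every reported number derives
from it.  The mean Dice is, by default, obtained from the mean IoU through
the exact Jaccard-Dice relation ``D = 2J / (1 + J)`` — the convention that
reproduces published pooled confusion-matrix results — with the average of
per-class Dice scores available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "iou_foreground",
    "iou_background",
    "mean_iou",
    "iou_to_dice",
    "pixel_accuracy",
    "report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts (or fractions, when normalized)."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    def normalized(self) -> "ConfusionCounts":
        t = self.total
        if t <= 0:
            raise ValueError("cannot normalize empty counts")
        return ConfusionCounts(self.tp / t, self.fp / t, self.tn / t, self.fn / t)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    iou_foreground: float
    iou_background: float
    mean_iou: float
    mean_dice: float
    pixel_accuracy: float
    n_pixels: float

    def as_dict(self) -> dict[str, float]:
        return {
            "iou_foreground": self.iou_foreground,
            "iou_background": self.iou_background,
            "mean_iou": self.mean_iou,
            "mean_dice": self.mean_dice,
            "pixel_accuracy": self.pixel_accuracy,
            "n_pixels": self.n_pixels,
        }


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixel confusion counts between two binary masks."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_iou(intersection: float, union: float) -> float:
    # A class absent from both masks has an empty union; score it perfect
    # rather than undefined so all-background frames are not penalized.
    if union <= 0:
        return 1.0
    return intersection / union


def iou_foreground(counts: ConfusionCounts) -> float:
    return _safe_iou(counts.tp, counts.tp + counts.fp + counts.fn)


def iou_background(counts: ConfusionCounts) -> float:
    return _safe_iou(counts.tn, counts.tn + counts.fp + counts.fn)


def mean_iou(counts: ConfusionCounts) -> float:
    """Mean of foreground and background IoU over the two binary classes."""
    if counts.total <= 0:
        raise ValueError("empty confusion counts")
    return 0.5 * (iou_foreground(counts) + iou_background(counts))


def iou_to_dice(j: float) -> float:
    """Convert a Jaccard index to the equivalent Dice score, D = 2J/(1+J)."""
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"IoU must lie in [0, 1], got {j}")
    return 2.0 * j / (1.0 + j)


def pixel_accuracy(counts: ConfusionCounts) -> float:
    if counts.total <= 0:
        raise ValueError("empty confusion counts")
    return (counts.tp + counts.tn) / counts.total


def _report_from_counts(
    counts: ConfusionCounts, dice_mode: Literal["from_mean_iou", "per_class"]
) -> MetricsReport:
    fg = iou_foreground(counts)
    bg = iou_background(counts)
    miou = 0.5 * (fg + bg)
    if dice_mode == "from_mean_iou":
        mdice = iou_to_dice(miou)
    else:
        mdice = 0.5 * (iou_to_dice(fg) + iou_to_dice(bg))
    return MetricsReport(
        iou_foreground=fg,
        iou_background=bg,
        mean_iou=miou,
        mean_dice=mdice,
        pixel_accuracy=pixel_accuracy(counts),
        n_pixels=counts.total,
    )


def report(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]] | Sequence[tuple[np.ndarray, np.ndarray]],
    pooling: Literal["pooled", "per_image_mean"] = "pooled",
    dice_mode: Literal["from_mean_iou", "per_class"] = "from_mean_iou",
) -> MetricsReport:
    """Evaluate a set of (prediction, truth) mask pairs.

    ``pooled`` accumulates one confusion matrix over all pixels of all
    pairs and derives the metrics from it (each image weighted by its pixel
    count); ``per_image_mean`` computes the metrics per image and averages
    them, weighting every image equally.
    """
    all_counts = [confusion(pred, truth) for pred, truth in pairs]
    if not all_counts:
        raise ValueError("no mask pairs to evaluate")
    if pooling == "pooled":
        total = all_counts[0]
        for c in all_counts[1:]:
            total = total + c
        return _report_from_counts(total, dice_mode)
    if pooling == "per_image_mean":
        reports = [_report_from_counts(c, dice_mode) for c in all_counts]
        return MetricsReport(
            iou_foreground=float(np.mean([r.iou_foreground for r in reports])),
            iou_background=float(np.mean([r.iou_background for r in reports])),
            mean_iou=float(np.mean([r.mean_iou for r in reports])),
            mean_dice=float(np.mean([r.mean_dice for r in reports])),
            pixel_accuracy=float(np.mean([r.pixel_accuracy for r in reports])),
            n_pixels=float(sum(r.n_pixels for r in reports)),
        )
    raise ValueError(f"unknown pooling mode: {pooling!r}")
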