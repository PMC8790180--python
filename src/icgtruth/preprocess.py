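"""Fluorescence-frame preprocessing: CLAHE contrast enhancement and
Otsu / fixed-level binarization.

Raw indocyanine-green (ICG) videoangiography frames are grayscale with
strongly patient-dependent brightness (dye dose, dilution, illumination,
flow speed all vary), so a contrast-limited adaptive histogram
equalization step precedes thresholding.  Otsu's method is the default
threshold; when it produces an implausible vessel area — vessels occupy a
bounded minority of the surgical field — a fixed level in the 0.5-0.7
range (default 0.55) is used instead.  All frames are floats in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skimage import exposure

__all__ = [
    "ThresholdPolicy",
    "BinarizeResult",
    "equalize_contrast",
    "otsu_threshold",
    "binarize",
]

# Bounds within which a fixed threshold is considered clinically plausible.
FIXED_LEVEL_BOUNDS = (0.5, 0.7)


@dataclass(frozen=True)
class ThresholdPolicy:
    """How a grayscale fluorescence frame becomes a binary vessel mask.

    Parameters
    ----------
    method : {"otsu", "fixed"}
        Primary thresholding strategy.
    fixed_level : float
        Level used when ``method="fixed"`` and as the fallback when Otsu's
        foreground fraction leaves ``adequacy_band``.  Must lie in
        [0.5, 0.7].
    adequacy_band : (float, float)
        Acceptable foreground-pixel fraction for an Otsu result; outside
        it the fixed level is used instead.
    """

    method: Literal["otsu", "fixed"] = "otsu"
    fixed_level: float = 0.55
    adequacy_band: tuple[float, float] = (0.005, 0.40)

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        lo, hi = FIXED_LEVEL_BOUNDS
        if not lo <= self.fixed_level <= hi:
            raise ValueError(
                f"fixed_level {self.fixed_level} outside plausible bounds [{lo}, {hi}]"
            )
        blo, bhi = self.adequacy_band
        if not 0.0 <= blo < bhi <= 1.0:
            raise ValueError(f"invalid adequacy band {self.adequacy_band}")


@dataclass(frozen=True)
class BinarizeResult:
    """Binary mask plus a record of which thresholding path produced it."""

    mask: np.ndarray
    level: float
    method_used: Literal["otsu", "fixed"]
    fell_back: bool = False


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale frame, got shape {frame.shape}")
    return frame


def equalize_contrast(
    frame: np.ndarray,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    ``tile_grid`` gives the number of contextual tiles along (rows, cols);
    ``clip_limit`` is the normalized clipping limit that bounds noise
    amplification.  Output values stay in [0, 1].
    """
    frame = _check_frame(frame)
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    rows, cols = frame.shape
    gr, gc = tile_grid
    if gr < 1 or gc < 1 or gr > rows or gc > cols:
        raise ValueError(
            f"tile grid {tile_grid} degenerate for frame of shape {frame.shape}"
        )
    if np.ptp(frame) == 0:
        # CLAHE of a constant image is that image.
        return frame.copy()
    kernel = (max(1, int(np.ceil(rows / gr))), max(1, int(np.ceil(cols / gc))))
    out = exposure.equalize_adapthist(
        np.clip(frame, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit
    )
    return np.clip(out, 0.0, 1.0)


def otsu_threshold(frame: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold over a fixed ``n_bins``-bin histogram on [0, 1].

    The histogram is binned on the full [0, 1] range (8-bit video
    heritage) rather than on the observed data range, so the returned
    level is comparable across frames.
    """
    frame = _check_frame(frame)
    if np.ptp(frame) == 0:
        raise ValueError("constant frame: no separable intensity classes")
    counts, edges = np.histogram(np.clip(frame, 0.0, 1.0), bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # Between-class variance for every cut placed after bin i.  The curve
    # is flat between well-separated modes; the midpoint of the plateau is
    # returned so the level sits between the classes rather than at the
    # edge of one of them (which, under the strict ">" convention, would
    # swallow the lower class).
    w0 = np.cumsum(counts).astype(float)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    mu0 = np.divide(m, w0, out=np.zeros_like(m), where=w0 > 0)
    mu1 = np.divide(m[-1] - m, w1, out=np.zeros_like(m), where=w1 > 0)
    sigma_b = w0[:-1] * w1[:-1] * (mu0[:-1] - mu1[:-1]) ** 2
    maximizers = np.flatnonzero(sigma_b == sigma_b.max())
    lo_idx, hi_idx = maximizers[0], maximizers[-1]
    return float(0.5 * (centers[lo_idx] + centers[hi_idx + 1]))


def binarize(frame: np.ndarray, policy: ThresholdPolicy = ThresholdPolicy()) -> BinarizeResult:
    """Threshold a frame into a binary vessel mask.

    Pixels strictly above the effective level are foreground (ties go to
    background).  Under the Otsu method, a foreground fraction outside the
    policy's adequacy band triggers fallback to the fixed level; the
    result records which path was taken.
    """
    frame = _check_frame(frame)
    if policy.method == "fixed":
        mask = frame > policy.fixed_level
        return BinarizeResult(mask=mask, level=policy.fixed_level, method_used="fixed")
    level = otsu_threshold(frame)
    mask = frame > level
    lo, hi = policy.adequacy_band
    frac = float(mask.mean())
    if lo <= frac <= hi:
        return BinarizeResult(mask=mask, level=level, method_used="otsu")
    mask = frame > policy.fixed_level
    return BinarizeResult(
        mask=mask, level=policy.fixed_level, method_used="fixed", fell_back=True
    )
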