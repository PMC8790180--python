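"""Patch selection, augmentation, resizing, patient splits and dataset I/O.

From an aligned, registered, class-allocated frame this module carves the
actual training samples: a window of frames around a key frame, random
crops within each frame, a quality gate that discards dark / defocused /
vessel-poor patches, rotation augmentation at a fixed angular delta, and
a resize to the network input resolution (512x512).  Splits are strictly
patient-level: no patient contributes patches to both train and
validation.  Everything is reproducible from one seed, and every patch
carries provenance (patient, frame, crop origin, rotation, phase tag,
registration metric) into the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform as sktf

__all__ = [
    "QualityPolicy",
    "QualityResult",
    "LabeledPatchPair",
    "select_frame_window",
    "quality_filter",
    "crop_patches",
    "augment_rotations",
    "resize_pair",
    "split_by_patient",
    "write_dataset",
    "read_label",
]

TARGET_SIZE = 512

MANIFEST_COLUMNS = [
    "file_stem",
    "patient_id",
    "frame_index",
    "crop_row",
    "crop_col",
    "crop_size",
    "rotation_deg",
    "phase_tag",
    "registration_metric",
    "split",
]


@dataclass(frozen=True)
class QualityPolicy:
    """Operational stand-ins for the qualitative exclusion criteria.

    Frames with a lack of light, defocus, or no vessel content are
    excluded: focus is measured by the variance of the Laplacian of the
    luminance, brightness by mean luminance, vessel content by the
    foreground fraction of the label patch.
    """

    min_focus: float = 1e-5
    brightness_band: tuple[float, float] = (0.15, 0.95)
    min_vessel_fraction: float = 0.02

    def __post_init__(self) -> None:
        lo, hi = self.brightness_band
        if not (0 <= lo < hi):
            raise ValueError(f"invalid brightness band {self.brightness_band}")
        if self.min_focus < 0 or self.min_vessel_fraction < 0:
            raise ValueError("bounds must be non-negative")


@dataclass(frozen=True)
class QualityResult:
    passed: bool
    reasons: tuple[str, ...]
    focus: float
    brightness: float
    vessel_fraction: float


@dataclass(frozen=True)
class LabeledPatchPair:
    """One training sample: a visible patch and its ground-truth labels."""

    image: np.ndarray  # (512, 512, 3) float [0,1]
    labels: np.ndarray  # (512, 512) uint8 {0,1}
    patient_id: str
    frame_index: int
    crop_origin: tuple[int, int]
    crop_size: int
    rotation_deg: int
    phase_tag: Literal["arterial", "delayed"]
    registration_metric: float = float("nan")

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.labels.shape:
            raise ValueError("image and labels must share their spatial shape")
        if self.rotation_deg % 45 != 0 or not 0 <= self.rotation_deg < 360:
            raise ValueError(f"rotation {self.rotation_deg} not a 45-degree multiple")


def select_frame_window(
    key_frame: int, n_frames: int, half_width: int = 60
) -> tuple[int, int]:
    """Frames around a chosen key frame: ~``half_width`` front and back,
    clipped to the video bounds.  Returns a half-open interval."""
    if not 0 <= key_frame < n_frames:
        raise ValueError(f"key frame {key_frame} outside [0, {n_frames})")
    return (max(0, key_frame - half_width), min(n_frames, key_frame + half_width + 1))


def _luminance(rgb: np.ndarray) -> np.ndarray:
    return 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]


def quality_filter(
    image: np.ndarray,
    labels: np.ndarray,
    policy: QualityPolicy = QualityPolicy(),
) -> QualityResult:
    """Gate a patch on focus, brightness and vessel content."""
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.size == 0:
        raise ValueError("empty patch")
    lum = _luminance(image) if image.ndim == 3 else image
    focus = float(ndimage.laplace(lum).var())
    brightness = float(lum.mean())
    vessel_fraction = float((labels > 0).mean())
    reasons = []
    if focus < policy.min_focus:
        reasons.append("focus")
    lo, hi = policy.brightness_band
    if not lo <= brightness <= hi:
        reasons.append("brightness")
    if vessel_fraction < policy.min_vessel_fraction:
        reasons.append("vessel_fraction")
    return QualityResult(
        passed=not reasons,
        reasons=tuple(reasons),
        focus=focus,
        brightness=brightness,
        vessel_fraction=vessel_fraction,
    )


def crop_patches(
    image: np.ndarray,
    labels: np.ndarray,
    n_crops: int,
    crop_size: int,
    seed: int | np.random.Generator = 0,
) -> list[tuple[np.ndarray, np.ndarray, tuple[int, int]]]:
    """Cut ``n_crops`` random square patches with matching label crops.

    Origins are uniform over the frame interior and deterministic per
    seed; a generator may be passed to chain several calls on one stream.
    """
    image = np.asarray(image)
    labels = np.asarray(labels)
    h, w = labels.shape
    if crop_size > h or crop_size > w:
        raise ValueError(f"crop size {crop_size} exceeds frame dims {(h, w)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = rng.integers(0, h - crop_size + 1, size=n_crops)
    cols = rng.integers(0, w - crop_size + 1, size=n_crops)
    out = []
    for r, c in zip(rows, cols):
        r, c = int(r), int(c)
        out.append(
            (
                image[r : r + crop_size, c : c + crop_size].copy(),
                labels[r : r + crop_size, c : c + crop_size].copy(),
                (r, c),
            )
        )
    return out


def _inscribed_side(size: int, angle_deg: float) -> int:
    """Side of the largest axis-aligned square inside a ``size``-square
    rotated by ``angle_deg``."""
    rad = np.deg2rad(angle_deg % 90)
    return int(np.floor(size / (np.sin(rad) + np.cos(rad))))


def _center_crop(arr: np.ndarray, side: int) -> np.ndarray:
    h, w = arr.shape[:2]
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return arr[r0 : r0 + side, c0 : c0 + side]


def augment_rotations(
    image: np.ndarray,
    labels: np.ndarray,
    delta: int = 45,
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Rotate a patch pair at every multiple of ``delta`` degrees.

    Quarter-turn multiples are exact array rotations (no resampling).
    Other angles are resampled (bilinear image, nearest-neighbor labels)
    and center-cropped to the largest inscribed square, so no out-of-field
    corner pixels are fabricated.  Returns ``360 / delta`` pairs.
    """
    if delta <= 0 or 360 % delta != 0:
        raise ValueError(f"delta {delta} does not divide 360")
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    out: list[tuple[np.ndarray, np.ndarray, int]] = []
    for angle in range(0, 360, delta):
        if angle % 90 == 0:
            k = angle // 90
            out.append((np.rot90(image, k).copy(), np.rot90(labels, k).copy(), angle))
            continue
        rot_img = sktf.rotate(image, angle, resize=False, order=1, preserve_range=True)
        rot_lbl = sktf.rotate(
            labels.astype(float), angle, resize=False, order=0, preserve_range=True
        ).astype(labels.dtype)
        side = _inscribed_side(min(labels.shape), angle)
        out.append((_center_crop(rot_img, side), _center_crop(rot_lbl, side), angle))
    return out


def resize_pair(
    image: np.ndarray,
    labels: np.ndarray,
    target: int = TARGET_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Resize a patch pair to ``target`` x ``target``: bilinear for the
    image, nearest-neighbor for the labels (already-conforming labels are
    returned bit-exact)."""
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty patch")
    if labels.shape == (target, target) and image.shape[:2] == (target, target):
        return image.copy(), labels.copy()
    out_img = sktf.resize(
        image,
        (target, target) + image.shape[2:],
        order=1,
        anti_aliasing=min(image.shape[:2]) > target,
        preserve_range=True,
    )
    out_lbl = sktf.resize(
        labels.astype(float), (target, target), order=0, anti_aliasing=False,
        preserve_range=True,
    ).astype(labels.dtype)
    return np.clip(out_img, 0.0, 1.0), out_lbl


def split_by_patient(
    patient_ids: Sequence[str],
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> dict[str, str]:
    """Random patient-level partition into train / validation.

    Every patient lands in exactly one split; at least one patient goes to
    each side.  Deterministic per seed.
    """
    unique = sorted(set(patient_ids))
    if len(unique) < 2:
        raise ValueError("need at least two patients for a patient-level split")
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(unique))
    n_val = int(round(validation_fraction * len(unique)))
    n_val = min(max(n_val, 1), len(unique) - 1)
    val = set(order[:n_val])
    return {p: ("validation" if p in val else "train") for p in unique}


def write_dataset(
    pairs: Sequence[LabeledPatchPair],
    manifest: pd.DataFrame,
    out_dir: str | Path,
    run_config: dict | None = None,
) -> Path:
    """Write images, label maps, manifest CSV and a run-config snapshot.

    Images become 8-bit RGB PNGs; labels single-channel PNGs holding only
    the values {0, 1}.
    """
    out = Path(out_dir)
    img_dir = out / "images"
    lbl_dir = out / "labels"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
        lbl_dir.mkdir(parents=True, exist_ok=True)
        if len(pairs) != len(manifest):
            raise ValueError("manifest rows must match the number of pairs")
        for pair, stem in zip(pairs, manifest["file_stem"]):
            img8 = np.clip(pair.image * 255.0, 0, 255).round().astype(np.uint8)
            iio.imwrite(img_dir / f"{stem}.png", img8)
            iio.imwrite(lbl_dir / f"{stem}.png", pair.labels.astype(np.uint8))
        manifest.to_csv(out / "manifest.csv", index=False)
        if run_config is not None:
            (out / "run_config.json").write_text(
                json.dumps(run_config, indent=2, sort_keys=True)
            )
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out}: {exc}") from exc
    return out


def read_label(path: str | Path) -> np.ndarray:
    """Read a label PNG back as a {0,1} uint8 array."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)
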