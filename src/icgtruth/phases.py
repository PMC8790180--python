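"""Arterial / delayed phase discrimination and class allocation.

ICG flows from the arteries to the veins, so early in the angiogram only
arteries fluoresce (the *arterial phase*); later both arteries and veins
do (the *delayed phase*).  Ground-truth class maps built from an
arterial-phase frame therefore label arteries only, while delayed-phase
frames label all vessels — which is why delayed frames are tagged, so an
artery-only dataset can exclude them.

Phase boundaries are found automatically from per-pixel dye-arrival
times: arrivals cluster into an early (arterial) and a late (venous)
group, and the earliest late arrival starts the delayed phase.  Explicit
window specification bypasses the detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .preprocess import ThresholdPolicy, binarize

__all__ = ["ARRIVAL_NEVER", "PhaseWindows", "ClassMap", "arrival_map", "detect_phases", "allocate_classes"]

ARRIVAL_NEVER = -1


@dataclass(frozen=True)
class PhaseWindows:
    """Half-open frame intervals [start, end) of the two phases."""

    arterial: tuple[int, int]
    delayed: tuple[int, int]
    onset_frame: int

    def __post_init__(self) -> None:
        a0, a1 = self.arterial
        d0, d1 = self.delayed
        if a0 > a1 or d0 > d1:
            raise ValueError("windows must be non-decreasing intervals")
        if a1 > d0:
            raise ValueError("arterial window must end before the delayed window")
        if self.onset_frame != a0:
            raise ValueError("onset_frame must equal the arterial start")

    def phase_of(self, frame_index: int) -> Literal["arterial", "delayed"] | None:
        if self.arterial[0] <= frame_index < self.arterial[1]:
            return "arterial"
        if self.delayed[0] <= frame_index < self.delayed[1]:
            return "delayed"
        return None


@dataclass(frozen=True)
class ClassMap:
    """Binary ground-truth labels for one frame, tagged with its phase."""

    labels: np.ndarray  # uint8 {0 background, 1 vessel class}
    phase_tag: Literal["arterial", "delayed"]

    def __post_init__(self) -> None:
        values = np.unique(self.labels)
        if not np.all(np.isin(values, [0, 1])):
            raise ValueError(f"labels must be binary, found values {values}")


def arrival_map(
    ir_frames: Sequence[np.ndarray] | np.ndarray,
    policy: ThresholdPolicy = ThresholdPolicy(),
    debounce: int = 3,
) -> np.ndarray:
    """Per-pixel index of the first sustained threshold crossing.

    A pixel's arrival is the earliest frame at which its binarized value
    is foreground and stays foreground for at least ``debounce``
    consecutive frames (transient flicker is ignored); pixels that never
    qualify get :data:`ARRIVAL_NEVER`.
    """
    frames = np.asarray(ir_frames, dtype=float)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValueError("need a stack of at least two grayscale frames")
    k = min(max(1, debounce), len(frames))
    masks = np.empty(frames.shape, dtype=bool)
    for i, frame in enumerate(frames):
        if np.ptp(frame) < 1e-12:
            masks[i] = False
        else:
            masks[i] = binarize(frame, policy).mask
    # sustained[t] = all of masks[t .. t+k-1]
    csum = np.cumsum(masks.astype(np.int32), axis=0)
    padded = np.concatenate([np.zeros((1, *masks.shape[1:]), dtype=np.int32), csum])
    window = padded[k:] - padded[:-k]
    sustained = window == k  # shape (T-k+1, H, W)
    any_hit = sustained.any(axis=0)
    first = sustained.argmax(axis=0)
    arrivals = np.where(any_hit, first, ARRIVAL_NEVER)
    return arrivals.astype(np.int64)


def _two_means_1d(values: np.ndarray, max_iter: int = 100) -> tuple[float, float, np.ndarray]:
    """Deterministic 1-D 2-means, centers initialized at min and max."""
    c0, c1 = float(values.min()), float(values.max())
    labels = np.zeros(values.shape, dtype=bool)
    for _ in range(max_iter):
        new_labels = np.abs(values - c1) < np.abs(values - c0)
        if new_labels.any():
            n1 = float(values[new_labels].mean())
        else:
            n1 = c1
        if (~new_labels).any():
            n0 = float(values[~new_labels].mean())
        else:
            n0 = c0
        if np.array_equal(new_labels, labels) and n0 == c0 and n1 == c1:
            break
        labels, c0, c1 = new_labels, n0, n1
    return c0, c1, labels


def detect_phases(
    arrivals: np.ndarray,
    n_frames: int,
    min_active_fraction: float = 0.01,
    min_separation: int = 5,
) -> PhaseWindows:
    """Cluster arrival times into arterial and delayed windows.

    Finite arrivals are split by a deterministic 1-D 2-means (centers
    initialized at the earliest and latest arrival).  The delayed phase
    starts at the earliest arrival of the late cluster and runs to the end
    of the video.  If the clusters sit closer than ``min_separation``
    frames, the video contains no discernible venous wave and is labeled
    arterial throughout.
    """
    arrivals = np.asarray(arrivals)
    finite = arrivals[arrivals != ARRIVAL_NEVER]
    if finite.size < min_active_fraction * arrivals.size:
        raise ValueError(
            "too few activated pixels "
            f"({finite.size}/{arrivals.size}) to determine phases"
        )
    onset = int(finite.min())
    c0, c1, late = _two_means_1d(finite.astype(float))
    if c1 - c0 < min_separation:
        return PhaseWindows(
            arterial=(onset, n_frames), delayed=(n_frames, n_frames), onset_frame=onset
        )
    boundary = int(finite[late].min())
    return PhaseWindows(
        arterial=(onset, boundary), delayed=(boundary, n_frames), onset_frame=onset
    )


def allocate_classes(
    vessel_mask: np.ndarray,
    windows: PhaseWindows,
    frame_index: int,
) -> ClassMap:
    """Turn a binarized vessel mask into the frame's ground-truth classes.

    In the arterial window the mask is the artery class (veins are not
    yet fluorescent, so none can appear); in the delayed window it is the
    all-vessel class and the map is tagged ``delayed`` so artery-only
    dataset builds can drop it.
    """
    phase = windows.phase_of(frame_index)
    if phase is None:
        raise ValueError(
            f"frame {frame_index} lies outside both phase windows "
            f"(arterial {windows.arterial}, delayed {windows.delayed})"
        )
    labels = np.asarray(vessel_mask).astype(np.uint8)
    return ClassMap(labels=labels, phase_tag=phase)
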