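"""2-D similarity transforms in (row, col) image coordinates.

Convention used throughout the package: pixel coordinates are (row, col)
with the origin at the top-left corner, 0-based.  A similarity transform is
a uniform scale, a rotation and a translation; anisotropic scalings (the
fixed infrared-to-visible magnification) are handled separately as plain
resizes and never enter this class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktf

__all__ = ["SimilarityTransform2D", "warp_image"]


@dataclass(frozen=True)
class SimilarityTransform2D:
    """Uniform scale + rotation + translation mapping source to destination
    coordinates.

    A point ``p = (row, col)`` maps to ``scale * R(rotation) @ p +
    translation`` where ``R`` rotates by ``rotation_deg`` degrees
    (positive = from the row axis toward the column axis, i.e.
    counter-clockwise when the image is displayed with the origin top-left).
    ``translation`` is ``(dy, dx)`` in pixels.
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    # -- conversions -----------------------------------------------------

    def to_skimage(self) -> sktf.SimilarityTransform:
        """Equivalent scikit-image transform (which works in (x, y))."""
        dy, dx = self.translation
        return sktf.SimilarityTransform(
            scale=self.scale,
            rotation=math.radians(self.rotation_deg),
            translation=(dx, dy),
        )

    @classmethod
    def from_skimage(cls, t: sktf.SimilarityTransform) -> "SimilarityTransform2D":
        tx, ty = t.translation
        return cls(
            scale=float(t.scale),
            rotation_deg=float(math.degrees(t.rotation)),
            translation=(float(ty), float(tx)),
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform2D":
        return cls()

    @classmethod
    def about(
        cls,
        center: tuple[float, float],
        scale: float = 1.0,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "SimilarityTransform2D":
        """Scale/rotate about ``center`` (row, col), then translate.

        ``p -> center + scale * R (p - center) + translation``
        """
        cy, cx = center
        pivot = cls(translation=(-cy, -cx))
        core = cls(scale=scale, rotation_deg=rotation_deg)
        back = cls(translation=(cy + translation[0], cx + translation[1]))
        return back @ core @ pivot

    # -- algebra ---------------------------------------------------------

    def __matmul__(self, other: "SimilarityTransform2D") -> "SimilarityTransform2D":
        """Composition: ``(A @ B)(p) == A(B(p))``."""
        return SimilarityTransform2D.from_skimage(
            sktf.SimilarityTransform(
                matrix=self.to_skimage().params @ other.to_skimage().params
            )
        )

    def inverse(self) -> "SimilarityTransform2D":
        return SimilarityTransform2D.from_skimage(
            sktf.SimilarityTransform(matrix=np.linalg.inv(self.to_skimage().params))
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (row, col) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        xy = pts[:, ::-1]
        out = self.to_skimage()(xy)
        return out[:, ::-1]

    def is_identity(self, tol: float = 1e-6) -> bool:
        return (
            abs(self.scale - 1.0) <= tol
            and abs(self.rotation_deg) <= tol
            and abs(self.translation[0]) <= tol
            and abs(self.translation[1]) <= tol
        )


def warp_image(
    image: np.ndarray,
    transform: SimilarityTransform2D,
    out_shape: tuple[int, int] | None = None,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` so that content moves according to ``transform``.

    ``transform`` maps source (input) coordinates to destination (output)
    coordinates; out-of-field regions are filled with ``cval``.
    """
    if out_shape is None:
        out_shape = image.shape[:2]
    # skimage.warp expects the output->input mapping.
    inv = transform.inverse().to_skimage()
    return sktf.warp(
        np.asarray(image, dtype=float),
        inv,
        output_shape=out_shape,
        order=order,
        cval=cval,
        preserve_range=True,
    )
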