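"""Spatial mapping of infrared-camera coordinates onto visible-camera
coordinates.

Two stages, mirroring the microscope's optics:

1. :func:`rescale_infrared` — the fixed anisotropic magnification of the
   scope model: on HD scopes the infrared frame must be enlarged 2.28x
   horizontally and 2.43x vertically to reach the visible frame's scale;
   SD scopes record both streams at the same resolution, so no
   magnification is applied.
2. :func:`coregister` — intensity-based 2-D similarity registration
   (uniform scale, rotation, translation) that absorbs the residual
   misalignment between the two cameras.  The two streams are different
   modalities (reflected color vs fluorescence), so the optimization runs
   on gradient-magnitude images under normalized cross-correlation by
   default, with a mutual-information alternative.  The stereo relation
   between the cameras is not planar, but over small patches the
   departure from a similarity transform is negligible — which is why the
   pipeline registers patches, not whole frames.

The registered transform maps moving (infrared, post-magnification)
coordinates to fixed (visible) coordinates, so infrared-derived masks can
be carried onto visible patches with :func:`warp_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage import registration as skreg
from skimage import transform as sktf

from .geometry import SimilarityTransform2D, warp_image
from .synthetic import CameraModel, _round_half_up

__all__ = [
    "RegistrationOptions",
    "content_window",
    "RegistrationResult",
    "rescale_infrared",
    "coregister",
    "warp_mask",
]

ACCEPTED_SCALE_RANGE = (0.5, 2.0)


@dataclass(frozen=True)
class RegistrationOptions:
    """Knobs of the similarity registrar.

    The coarse stage scans a grid of (scale, rotation) candidates, solving
    translation by phase correlation at each; the fine stage refines all
    four parameters with Powell's method on the negated similarity metric.
    """

    metric: str = "gradient_ncc"  # or "mutual_information"
    scale_search: tuple[float, float, float] = (0.90, 1.10, 0.025)
    rotation_search_deg: tuple[float, float, float] = (-12.0, 12.0, 3.0)
    max_iterations: int = 200
    tol: float = 1e-5
    gradient_sigma: float = 1.0
    mi_bins: int = 32
    # minimum warped-in area fraction for a candidate to be considered
    min_overlap: float = 0.25
    # narrow re-warp refinement passes after the full search
    refine_passes: int = 2


@dataclass
class RegistrationResult:
    transform: SimilarityTransform2D
    final_metric: float  # similarity of the aligned pair over the warped-in region
    converged: bool
    iterations: int
    # similarity metric at each accepted (improving) optimizer step
    metric_trace: list[float] = field(default_factory=list)


def rescale_infrared(frame: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Bring an infrared frame to the visible camera's pixel scale.

    HD: width grows by the horizontal ratio, height by the vertical ratio
    (rounded half away from zero); SD: the frame is returned unchanged.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if camera.resolution_class == "SD":
        return frame.copy()
    h, w = frame.shape[:2]
    out_shape = (
        _round_half_up(camera.ir_to_visible_scale_y * h),
        _round_half_up(camera.ir_to_visible_scale_x * w),
    )
    return sktf.resize(frame, out_shape, order=1, anti_aliasing=False)


def content_window(mask: np.ndarray, side: int) -> tuple[int, int]:
    """Origin (row, col) of the ``side``-square window holding the most
    mask pixels.

    Registration needs vessel structure to lock onto; a window centered on
    empty field (or one lone straight tube) is ill-conditioned.
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    if side > h or side > w:
        raise ValueError(f"window side {side} exceeds mask shape {(h, w)}")
    counts = ndimage.uniform_filter(mask.astype(float), size=side, mode="constant")
    half = side // 2
    interior = counts[half : h - side + half + 1, half : w - side + half + 1]
    iy, ix = np.unravel_index(int(np.argmax(interior)), interior.shape)
    return int(iy), int(ix)


def _grad_mag(img: np.ndarray, sigma: float) -> np.ndarray:
    g = ndimage.gaussian_gradient_magnitude(np.asarray(img, dtype=float), sigma=sigma)
    span = np.ptp(g)
    return (g - g.min()) / span if span > 0 else g


def _ncc(a: np.ndarray, b: np.ndarray, valid: np.ndarray) -> float:
    a = a[valid]
    b = b[valid]
    if a.size < 16:
        return -1.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom <= 0:
        return -1.0
    return float((a * b).sum() / denom)


def _mutual_information(a: np.ndarray, b: np.ndarray, valid: np.ndarray, bins: int) -> float:
    hist, _, _ = np.histogram2d(a[valid], b[valid], bins=bins)
    pxy = hist / max(hist.sum(), 1.0)
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def _register_once(
    m_img: np.ndarray,
    f_img: np.ndarray,
    options: RegistrationOptions,
    use_mi: bool,
    scale_search: tuple[float, float, float],
    rotation_search: tuple[float, float, float],
) -> tuple[np.ndarray, float, list[float], int, bool]:
    """One coarse-grid + bounded-Powell registration pass on preprocessed
    images; returns (params, raw score, trace, iterations, success)."""
    center = ((m_img.shape[0] - 1) / 2.0, (m_img.shape[1] - 1) / 2.0)
    ones = np.ones_like(m_img)

    def build(params: np.ndarray) -> SimilarityTransform2D:
        log_s, rot, dy, dx = params
        return SimilarityTransform2D.about(
            center, scale=float(np.exp(log_s)), rotation_deg=float(rot),
            translation=(float(dy), float(dx)),
        )

    def raw_score(params: np.ndarray) -> tuple[float, float]:
        t = build(params)
        warped = warp_image(m_img, t, order=1)
        valid = warp_image(ones, t, order=0) > 0.5
        overlap = float(valid.mean())
        if overlap < options.min_overlap:
            return -1.0, overlap
        if use_mi:
            return _mutual_information(warped, f_img, valid, options.mi_bins), overlap
        return _ncc(warped, f_img, valid), overlap

    def weighted_score(params: np.ndarray) -> float:
        # candidates are scored over their warped-in (valid) region only,
        # so weight by overlap when comparing distant candidates:
        # otherwise a large spurious motion that shrinks the valid region
        # to a self-similar sliver (e.g. sliding along a straight vessel)
        # can outscore the true alignment
        raw, overlap = raw_score(params)
        return raw * np.sqrt(max(overlap, 0.0))

    # Coarse stage: grid over (scale, rotation), translation via phase
    # correlation of the de-scaled/de-rotated moving image against fixed.
    s_lo, s_hi, s_step = scale_search
    r_lo, r_hi, r_step = rotation_search
    scales = np.arange(s_lo, s_hi + 1e-9, s_step)
    rotations = np.arange(r_lo, r_hi + 1e-9, r_step)
    best_params = np.zeros(4)
    best_score = -np.inf
    for s in scales:
        for r in rotations:
            t0 = SimilarityTransform2D.about(center, scale=float(s), rotation_deg=float(r))
            warped = warp_image(m_img, t0, order=1)
            shift, _, _ = skreg.phase_cross_correlation(
                f_img, warped, upsample_factor=10, normalization=None
            )
            cand = np.array([np.log(s), r, shift[0], shift[1]])
            sc = weighted_score(cand)
            if sc > best_score:
                best_score, best_params = sc, cand
    # Identity is always a candidate so a perfect match stays exact.
    ident = np.zeros(4)
    if weighted_score(ident) >= best_score:
        best_params, best_score = ident, weighted_score(ident)

    # Fine stage: refine the raw metric inside the selected candidate's
    # basin (the coarse grid spacing bounds how far the truth can sit from
    # the selected node), so the overlap weight cannot bias the optimum
    # and no distant sliver solution is reachable.
    bounds = [
        (best_params[0] - 0.05, best_params[0] + 0.05),
        (best_params[1] - 4.5, best_params[1] + 4.5),
        (best_params[2] - 8.0, best_params[2] + 8.0),
        (best_params[3] - 8.0, best_params[3] + 8.0),
    ]
    start_raw, _ = raw_score(best_params)
    trace = [start_raw]

    def objective(params: np.ndarray) -> float:
        sc, _ = raw_score(params)
        if sc > trace[-1]:
            trace.append(sc)
        return -sc

    res = optimize.minimize(
        objective,
        best_params,
        method="Powell",
        bounds=bounds,
        options={
            "xtol": options.tol,
            "ftol": options.tol,
            "maxiter": options.max_iterations,
        },
    )
    final_params = res.x if -res.fun >= start_raw else best_params
    final_score = max(-res.fun, start_raw)
    return final_params, float(final_score), trace, int(res.nit), bool(res.success)


def _params_to_transform(params: np.ndarray, shape: tuple[int, int]) -> SimilarityTransform2D:
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    log_s, rot, dy, dx = params
    return SimilarityTransform2D.about(
        center, scale=float(np.exp(log_s)), rotation_deg=float(rot),
        translation=(float(dy), float(dx)),
    )


def coregister(
    moving: np.ndarray,
    fixed: np.ndarray,
    options: RegistrationOptions = RegistrationOptions(),
) -> RegistrationResult:
    """Estimate the similarity transform aligning ``moving`` onto ``fixed``.

    Both patches must share a shape and have nonzero variance.  The
    returned transform maps moving coordinates to fixed coordinates:
    ``warp_image(moving, result.transform)`` overlays ``fixed``.

    Two passes: a full search (coarse scale/rotation grid with
    phase-correlation translation, then bounded Powell refinement of the
    similarity metric), followed by a second narrow pass on the moving
    image re-warped by the first estimate — re-resampling linearizes away
    the residual the first pass leaves in shallow, sparse-content optima.
    Deterministic for fixed options.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(f"patch shapes differ: {moving.shape} vs {fixed.shape}")
    if np.ptp(moving) == 0 or np.ptp(fixed) == 0:
        raise ValueError("zero-variance patch cannot be registered")

    use_mi = options.metric == "mutual_information"

    def preprocess(img: np.ndarray) -> np.ndarray:
        return img if use_mi else _grad_mag(img, options.gradient_sigma)

    f_img = preprocess(fixed)

    # pass 1: full search
    params1, score1, trace1, it1, ok1 = _register_once(
        preprocess(moving), f_img, options, use_mi,
        options.scale_search, options.rotation_search_deg,
    )
    t1 = _params_to_transform(params1, moving.shape)

    # narrow passes around identity on the re-warped moving image:
    # re-resampling contracts the residual each time, which matters on
    # sparse content where the first optimum sits in a shallow valley (the
    # metric plateaus while the parameters still improve).  Each pass is
    # confined to a small neighborhood by its grid and Powell bounds.
    transform, trace, iterations, success = t1, list(trace1), it1, ok1
    for _ in range(max(options.refine_passes, 0)):
        moved = warp_image(moving, transform, order=1)
        params2, _, trace2, it2, ok2 = _register_once(
            preprocess(moved), f_img, options, use_mi,
            (0.99, 1.01, 0.01), (-1.0, 1.0, 1.0),
        )
        iterations += it2
        transform = _params_to_transform(params2, moving.shape) @ transform
        trace += [v for v in trace2 if v > trace[-1]]
        success = success and ok2

    # final similarity of the aligned pair, measured on the re-warped
    # moving image so it reflects the alignment actually delivered
    aligned = preprocess(warp_image(moving, transform, order=1))
    valid = warp_image(np.ones_like(moving), transform, order=0) > 0.5
    if use_mi:
        final_score = _mutual_information(aligned, f_img, valid, options.mi_bins)
    else:
        final_score = _ncc(aligned, f_img, valid)
    if final_score > trace[-1]:
        trace.append(final_score)
    converged = success and (
        ACCEPTED_SCALE_RANGE[0] <= transform.scale <= ACCEPTED_SCALE_RANGE[1]
    )
    return RegistrationResult(
        transform=transform,
        final_metric=float(final_score),
        converged=converged,
        iterations=iterations,
        metric_trace=trace,
    )


def warp_mask(
    mask: np.ndarray,
    transform: SimilarityTransform2D,
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Carry a binary mask through a similarity transform.

    Nearest-neighbor interpolation keeps the output strictly binary;
    regions mapped from outside the source are background.
    """
    mask = np.asarray(mask).astype(float)
    warped = warp_image(mask, transform, out_shape=out_shape, order=0, cval=0.0)
    return warped > 0.5
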