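"""Synthetic paired visible/infrared surgical-video generator.

Real operative microscope recordings pair a full-color visible-light
stream with a grayscale infrared ICG-fluorescence stream captured by a
second camera on the same scope.  No such recordings ship with this
package, so this module fabricates them with fully known ground truth:

* a vessel scene — elongated, branching artery and vein tubes over a
  smooth tissue texture;
* ICG transit kinetics — fluorescence arrives in arteries first and in
  veins later, because the dye flows from the arterial to the venous side;
* a dual-camera model — the infrared camera sees the scene at its own
  resolution (for HD scopes the infrared frame must be magnified 2.28x
  horizontally and 2.43x vertically to match the visible frame; SD scopes
  need no magnification), plus a residual similarity misalignment and a
  fixed start-time offset (the visible stream starts a few frames late).

Every downstream stage — thresholding, temporal alignment, registration,
phase detection, patch building, metrics — can therefore be verified
against exact truth.  All imagery is float in [0, 1]; 8-bit conversion
happens only at file I/O.  Coordinates are (row, col), origin top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import transform as sktf

from .geometry import SimilarityTransform2D

__all__ = [
    "SimulationConfig",
    "VesselScene",
    "ICGKinetics",
    "CameraModel",
    "VideoPair",
    "generate_vessel_scene",
    "simulate_icg_video",
    "render_visible_video",
    "make_video_pair",
    "write_fixture",
]

# Native stream geometries of the two scope classes (rows, cols).
VISIBLE_SHAPES = {"SD": (480, 720), "HD": (1080, 1920)}
HD_SCALE_X = 2.28
HD_SCALE_Y = 2.43
DEFAULT_FPS = 29.97
DEFAULT_OFFSETS = {"SD": 3, "HD": 8}


@dataclass(frozen=True)
class ICGKinetics:
    """Temporal model of dye transit through the scene.

    Fluorescence in a vessel pixel ramps linearly from its onset frame to
    ``peak_intensity`` over ``rise_frames`` frames, then decays
    geometrically by ``decay_per_frame`` per frame.  Veins light up after
    arteries: the dye reaches the venous side only after passing the
    capillary bed.
    """

    artery_onset_frame: int = 10
    vein_onset_frame: int = 40
    rise_frames: int = 5
    peak_intensity: float = 0.9
    decay_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if self.vein_onset_frame <= self.artery_onset_frame:
            raise ValueError("veins must fill after arteries")
        if not 0.0 < self.peak_intensity <= 1.0:
            raise ValueError("peak_intensity must lie in (0, 1]")
        if not 0.0 <= self.decay_per_frame < 1.0:
            raise ValueError("decay_per_frame must lie in [0, 1)")
        if self.rise_frames < 0 or self.artery_onset_frame < 0:
            raise ValueError("frame counts must be non-negative")

    def intensity(self, t: np.ndarray | int, onset: np.ndarray | float) -> np.ndarray:
        """Noise-free fluorescence at frame(s) ``t`` for pixel onset(s)
        ``onset``; both broadcast, so a scalar time against an onset map
        yields a per-pixel intensity map."""
        t = np.asarray(t, dtype=float)
        dt = t - np.asarray(onset, dtype=float)
        if self.rise_frames > 0:
            ramp = np.clip((dt + 1.0) / self.rise_frames, 0.0, 1.0)
        else:
            ramp = (dt >= 0).astype(float)
        ramp = np.where(dt < 0, 0.0, ramp)
        if self.decay_per_frame > 0:
            past_peak = np.maximum(dt - self.rise_frames + 1.0, 0.0)
            ramp = ramp * (1.0 - self.decay_per_frame) ** past_peak
        return self.peak_intensity * ramp


@dataclass(frozen=True)
class CameraModel:
    """Dual-camera geometry and timing of the operating microscope."""

    resolution_class: Literal["SD", "HD"] = "SD"
    ir_to_visible_scale_x: float = 1.0
    ir_to_visible_scale_y: float = 1.0
    residual_transform: SimilarityTransform2D = field(
        default_factory=SimilarityTransform2D.identity
    )
    frame_offset: int = 3
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        if self.resolution_class not in ("SD", "HD"):
            raise ValueError(f"unknown resolution class {self.resolution_class!r}")
        if self.resolution_class == "SD" and (
            self.ir_to_visible_scale_x != 1.0 or self.ir_to_visible_scale_y != 1.0
        ):
            raise ValueError("SD scopes record both streams at the same scale")
        if self.frame_offset < 0:
            raise ValueError("frame_offset must be non-negative")

    @classmethod
    def default(cls, resolution_class: str, **kwargs) -> "CameraModel":
        if resolution_class == "HD":
            kwargs.setdefault("ir_to_visible_scale_x", HD_SCALE_X)
            kwargs.setdefault("ir_to_visible_scale_y", HD_SCALE_Y)
        kwargs.setdefault("frame_offset", DEFAULT_OFFSETS[resolution_class])
        return cls(resolution_class=resolution_class, **kwargs)

    def ir_shape(self, visible_shape: tuple[int, int]) -> tuple[int, int]:
        """Native infrared frame shape for a given visible frame shape."""
        h, w = visible_shape
        return (
            _round_half_up(h / self.ir_to_visible_scale_y),
            _round_half_up(w / self.ir_to_visible_scale_x),
        )


@dataclass
class VesselScene:
    """Static anatomy in visible-camera coordinates.

    ``artery_delay`` / ``vein_delay`` hold the per-pixel dye transit delay
    in frames (0 at each vessel's entry point, growing downstream): the
    bolus front propagates along a vessel rather than lighting it up all
    at once.  Zero everywhere when transit is disabled.
    """

    artery_map: np.ndarray
    vein_map: np.ndarray
    background_texture: np.ndarray
    canvas_size: tuple[int, int]
    artery_delay: np.ndarray | None = None
    vein_delay: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.artery_map & self.vein_map):
            raise ValueError("artery and vein maps must be disjoint")
        if self.artery_delay is None:
            self.artery_delay = np.zeros(self.canvas_size)
        if self.vein_delay is None:
            self.vein_delay = np.zeros(self.canvas_size)

    @property
    def vessel_map(self) -> np.ndarray:
        return self.artery_map | self.vein_map

    def onset_map(self, kinetics: "ICGKinetics") -> np.ndarray:
        """Per-pixel dye arrival frame; +inf outside vessels."""
        onset = np.full(self.canvas_size, np.inf)
        onset[self.artery_map] = (
            kinetics.artery_onset_frame + self.artery_delay[self.artery_map]
        )
        onset[self.vein_map] = (
            kinetics.vein_onset_frame + self.vein_delay[self.vein_map]
        )
        return onset


@dataclass
class VideoPair:
    """A synchronized-but-offset pair of streams plus retained truth."""

    visible_frames: np.ndarray  # (n_vis, H, W, 3) float [0,1]
    ir_frames: np.ndarray  # (n_ir, h, w) float [0,1]
    camera: CameraModel
    patient_id: str = "sim-000"
    truth: dict | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the paired-video simulator.

    Defaults describe a routine SD recording: a few medium/large vessels
    occupying a small minority of the field, dye arriving in arteries
    ~10 frames in and in veins ~30 frames later, mild sensor noise.
    """

    resolution_class: Literal["SD", "HD"] = "SD"
    frame_shape: tuple[int, int] | None = None  # visible (rows, cols); None = native
    n_frames: int = 90
    # scene
    n_arteries: int = 3
    n_veins: int = 2
    artery_width_range: tuple[float, float] = (4.0, 9.0)
    vein_width_range: tuple[float, float] = (8.0, 14.0)
    artery_fraction_band: tuple[float, float] = (0.02, 0.25)
    branch_prob: float = 0.35
    # kinetics
    artery_onset_frame: int = 10
    vein_onset_frame: int = 40
    rise_frames: int = 5
    peak_intensity: float = 0.9
    decay_per_frame: float = 0.0
    # bolus transit time (frames) from a vessel's entry point to its far end
    artery_transit_frames: float = 6.0
    vein_transit_frames: float = 6.0
    # infrared sensor
    ir_noise_sd: float = 0.01
    ir_baseline: float = 0.05
    # visible rendering
    illumination: float = 1.0
    blur_sigma: float = 0.6
    occlusion_fraction: float = 0.0
    visible_noise_sd: float = 0.005
    visible_icg_darkening: float = 0.15
    # camera
    frame_offset: int | None = None  # None = class default
    residual_scale: float = 1.0
    residual_rotation_deg: float = 0.0
    residual_translation: tuple[float, float] = (0.0, 0.0)

    def visible_shape(self) -> tuple[int, int]:
        return self.frame_shape or VISIBLE_SHAPES[self.resolution_class]

    def kinetics(self) -> ICGKinetics:
        return ICGKinetics(
            artery_onset_frame=self.artery_onset_frame,
            vein_onset_frame=self.vein_onset_frame,
            rise_frames=self.rise_frames,
            peak_intensity=self.peak_intensity,
            decay_per_frame=self.decay_per_frame,
        )

    def camera(self) -> CameraModel:
        offset = self.frame_offset
        if offset is None:
            offset = DEFAULT_OFFSETS[self.resolution_class]
        return CameraModel.default(
            self.resolution_class,
            residual_transform=SimilarityTransform2D(
                scale=self.residual_scale,
                rotation_deg=self.residual_rotation_deg,
                translation=self.residual_translation,
            ),
            frame_offset=offset,
        )


def _round_half_up(v: float) -> int:
    """Round half away from zero (positive inputs only here)."""
    return int(np.floor(v + 0.5))


# ---------------------------------------------------------------------------
# scene generation


def _draw_tube(
    canvas: np.ndarray,
    rng: np.random.Generator,
    width_range: tuple[float, float],
    branch_prob: float,
    start: tuple[float, float] | None = None,
    heading: float | None = None,
    max_len: float | None = None,
    delay_canvas: np.ndarray | None = None,
    delay_scale: float = 0.0,
    delay_start: float = 0.0,
) -> float:
    """Stamp one smoothly curving tube onto ``canvas``; returns path length.

    The centerline is a random walk whose heading changes by a smoothed
    (AR(1)) angular increment, giving gently curving, elongated vessels;
    the width drifts slowly within ``width_range``.  With probability
    ``branch_prob`` a single narrower branch departs mid-course.
    """
    h, w = canvas.shape
    diag = float(np.hypot(h, w))
    if max_len is None:
        max_len = 1.4 * diag
    if start is None:
        side = rng.integers(4)
        if side == 0:
            start = (0.0, float(rng.uniform(0, w)))
        elif side == 1:
            start = (float(h - 1), float(rng.uniform(0, w)))
        elif side == 2:
            start = (float(rng.uniform(0, h)), 0.0)
        else:
            start = (float(rng.uniform(0, h)), float(w - 1))
    if heading is None:
        # aim at a random interior point so the tube crosses the field
        target = (rng.uniform(0.3 * h, 0.7 * h), rng.uniform(0.3 * w, 0.7 * w))
        heading = float(np.arctan2(target[0] - start[0], target[1] - start[1]))

    width = float(rng.uniform(*width_range))
    step = 2.0
    dtheta = 0.0
    r, c = start
    length = 0.0
    points: list[tuple[float, float, float]] = []
    while 0 <= r < h and 0 <= c < w and length < max_len:
        points.append((r, c, width))
        dtheta = 0.9 * dtheta + rng.normal(0.0, 0.06)
        dtheta = float(np.clip(dtheta, -0.25, 0.25))
        heading += dtheta
        width = float(
            np.clip(width * np.exp(rng.normal(0.0, 0.02)), *width_range)
        )
        r += step * np.sin(heading)
        c += step * np.cos(heading)
        length += step

    for j, (pr, pc, pw) in enumerate(points):
        rr, cc = skdraw.disk((pr, pc), max(pw / 2.0, 1.0), shape=canvas.shape)
        canvas[rr, cc] = True
        if delay_canvas is not None:
            # bolus-front arrival grows downstream along the centerline
            d = delay_start + delay_scale * (j / max(len(points) - 1, 1))
            delay_canvas[rr, cc] = np.minimum(delay_canvas[rr, cc], d)

    if points and rng.uniform() < branch_prob and length > 10 * width_range[1]:
        i = int(rng.uniform(0.3, 0.7) * len(points))
        br, bc, bw = points[i]
        side = 1.0 if rng.uniform() < 0.5 else -1.0
        frac = i / max(len(points) - 1, 1)
        _draw_tube(
            canvas,
            rng,
            (max(width_range[0], 0.6 * bw), bw),
            branch_prob=0.0,
            start=(br, bc),
            heading=heading + side * rng.uniform(0.5, 0.9),
            max_len=0.5 * max_len,
            delay_canvas=delay_canvas,
            delay_scale=0.5 * delay_scale,
            delay_start=delay_start + delay_scale * frac,
        )
    return length


def generate_vessel_scene(
    config: SimulationConfig = SimulationConfig(), seed: int = 0
) -> VesselScene:
    """Build a random vessel scene with disjoint artery and vein maps.

    Arteries are added until their pixel fraction reaches the configured
    band; a scene overshooting the band is regenerated from a derived
    sub-seed a bounded number of times before failing.
    """
    shape = config.visible_shape()
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError(f"canvas {shape} too small; need at least 64x64")
    lo, hi = config.artery_fraction_band
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"infeasible artery fraction band {config.artery_fraction_band}")

    for attempt in range(8):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        artery = np.zeros(shape, dtype=bool)
        a_delay = np.full(shape, np.inf)
        for _ in range(config.n_arteries):
            _draw_tube(
                artery, rng, config.artery_width_range, config.branch_prob,
                delay_canvas=a_delay, delay_scale=config.artery_transit_frames,
            )
        extra = 0
        while artery.mean() < lo and extra < 20:
            _draw_tube(
                artery, rng, config.artery_width_range, config.branch_prob,
                delay_canvas=a_delay, delay_scale=config.artery_transit_frames,
            )
            extra += 1
        frac = artery.mean()
        if not lo <= frac <= hi:
            continue
        vein = np.zeros(shape, dtype=bool)
        v_delay = np.full(shape, np.inf)
        for _ in range(config.n_veins):
            _draw_tube(
                vein, rng, config.vein_width_range, config.branch_prob,
                delay_canvas=v_delay, delay_scale=config.vein_transit_frames,
            )
        vein &= ~artery
        a_delay = np.where(artery, a_delay, 0.0)
        v_delay = np.where(vein, v_delay, 0.0)
        texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=25.0)
        span = np.ptp(texture)
        if span > 0:
            texture = (texture - texture.min()) / span
        else:
            texture = np.full(shape, 0.5)
        texture = 0.35 + 0.3 * texture
        return VesselScene(
            artery_map=artery,
            vein_map=vein,
            background_texture=texture,
            canvas_size=shape,
            artery_delay=a_delay,
            vein_delay=v_delay,
        )
    raise RuntimeError(
        f"could not realize artery fraction in {config.artery_fraction_band} "
        f"after bounded retries (last fraction {frac:.3f})"
    )


# ---------------------------------------------------------------------------
# infrared rendering


def simulate_icg_video(
    scene: VesselScene,
    kinetics: ICGKinetics,
    n_frames: int,
    noise_sd: float = 0.01,
    baseline: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the fluorescence time course in scene (visible) coordinates.

    Returns ``(frames, true_masks)``: frames are baseline + fluorescence +
    Gaussian noise clipped to [0, 1]; the true visibility mask marks
    pixels whose noise-free intensity exceeds half the peak intensity (a
    simulator convention that makes downstream properties exact).
    """
    if n_frames <= kinetics.vein_onset_frame:
        raise ValueError(
            f"n_frames={n_frames} leaves the delayed phase unreachable "
            f"(vein onset {kinetics.vein_onset_frame})"
        )
    rng = np.random.default_rng(seed)
    onset = scene.onset_map(kinetics)
    vessel = scene.vessel_map

    h, w = scene.canvas_size
    frames = np.empty((n_frames, h, w), dtype=float)
    masks = np.empty((n_frames, h, w), dtype=bool)
    half_peak = 0.5 * kinetics.peak_intensity
    for i in range(n_frames):
        value = np.where(vessel, kinetics.intensity(i, onset), 0.0)
        masks[i] = value > half_peak
        clean = baseline + value
        if noise_sd > 0:
            clean = clean + rng.normal(0.0, noise_sd, size=(h, w))
        frames[i] = np.clip(clean, 0.0, 1.0)
    return frames, masks


# ---------------------------------------------------------------------------
# visible rendering

_TISSUE = dict(r=(0.55, 0.35), g=(0.22, 0.25), b=(0.22, 0.20))  # base + texture gain
_ARTERY_RGB = (0.78, 0.12, 0.14)
_VEIN_RGB = (0.45, 0.12, 0.24)


def render_visible_video(
    scene: VesselScene,
    n_frames: int,
    illumination: float = 1.0,
    blur_sigma: float = 0.6,
    occlusion_fraction: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.005,
    kinetics: ICGKinetics | None = None,
    frame_times: np.ndarray | None = None,
    icg_darkening: float = 0.0,
) -> np.ndarray:
    """Render the full-color visible-light stream of the scene.

    Vessels appear as reddish tubes over a pinkish tissue texture.
    Degradations emulate the operative field: global illumination scaling,
    defocus blur, and dark occluding blobs (instruments, retractors,
    hands) covering roughly ``occlusion_fraction`` of the frame.  When
    ``kinetics`` is given, vessel pixels darken by up to ``icg_darkening``
    as the dye bolus transits (frame ``i`` rendered at scene time
    ``frame_times[i]``) — the visible-light trace of the green dye at
    bolus concentration.
    """
    if not 0.0 <= illumination <= 1.0:
        raise ValueError("illumination must lie in [0, 1]")
    if not 0.0 <= occlusion_fraction <= 1.0:
        raise ValueError("occlusion_fraction must lie in [0, 1]")
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = scene.canvas_size
    tex = scene.background_texture
    base = np.stack(
        [
            _TISSUE["r"][0] + _TISSUE["r"][1] * tex,
            _TISSUE["g"][0] + _TISSUE["g"][1] * tex,
            _TISSUE["b"][0] + _TISSUE["b"][1] * tex,
        ],
        axis=-1,
    )
    for mask, rgb in ((scene.artery_map, _ARTERY_RGB), (scene.vein_map, _VEIN_RGB)):
        for ch in range(3):
            base[..., ch][mask] = rgb[ch]

    shadow = np.ones((h, w))
    if occlusion_fraction > 0:
        covered = np.zeros((h, w), dtype=bool)
        for _ in range(200):
            if covered.mean() >= occlusion_fraction:
                break
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            ry = rng.uniform(0.05, 0.2) * h
            rx = rng.uniform(0.05, 0.2) * w
            rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=(h, w))
            covered[rr, cc] = True
        shadow[covered] = 0.25

    vessel = scene.vessel_map
    onset = scene.onset_map(kinetics) if kinetics is not None else None
    if frame_times is None:
        frame_times = np.arange(n_frames)
    frames = np.empty((n_frames, h, w, 3), dtype=float)
    for i in range(n_frames):
        frame = base.copy()
        if onset is not None and icg_darkening > 0:
            # the visible color change saturates within a frame of the
            # bolus front arriving, so darkening is a per-pixel step
            arrived = (frame_times[i] >= onset)[vessel]
            dark = 1.0 - icg_darkening * arrived.astype(float)
            for ch in range(3):
                frame[..., ch][vessel] *= dark
        frame *= shadow[..., None]
        if blur_sigma > 0:
            frame = ndimage.gaussian_filter(frame, sigma=(blur_sigma, blur_sigma, 0))
        frame *= illumination
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)
    return frames


# ---------------------------------------------------------------------------
# composition


def make_video_pair(
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    patient_id: str | None = None,
) -> VideoPair:
    """Build one complete paired recording with retained ground truth.

    The infrared stream is rendered in infrared-camera coordinates: the
    scene (which lives in visible coordinates) is pulled back through the
    inverse of the residual similarity misalignment and of the fixed
    anisotropic magnification.  The visible stream starts
    ``frame_offset`` frames late, so the streams differ in length by
    exactly that offset.
    """
    ss = np.random.SeedSequence(seed)
    s_scene, s_ir, s_vis = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]

    scene = generate_vessel_scene(config, seed=s_scene)
    kinetics = config.kinetics()
    camera = config.camera()
    n = config.n_frames

    scene_ir, true_masks = simulate_icg_video(
        scene, kinetics, n, noise_sd=0.0, baseline=config.ir_baseline, seed=0
    )

    # IR-native geometry: visible = residual(magnify(ir)).
    vis_shape = scene.canvas_size
    ir_shape = camera.ir_shape(vis_shape)
    sx, sy = camera.ir_to_visible_scale_x, camera.ir_to_visible_scale_y
    magnify = sktf.AffineTransform(scale=(sx, sy))
    forward = sktf.AffineTransform(
        matrix=camera.residual_transform.to_skimage().params @ magnify.params
    )

    rng_ir = np.random.default_rng(s_ir)
    ir_frames = np.empty((n, *ir_shape), dtype=float)
    for i in range(n):
        # warp(img, map) samples img at map(output coords): exactly the
        # ir-native -> scene forward mapping.
        native = sktf.warp(
            scene_ir[i], forward, output_shape=ir_shape, order=1, cval=config.ir_baseline
        )
        if config.ir_noise_sd > 0:
            native = native + rng_ir.normal(0.0, config.ir_noise_sd, size=ir_shape)
        ir_frames[i] = np.clip(native, 0.0, 1.0)

    offset = camera.frame_offset
    if offset >= n:
        raise ValueError("frame_offset leaves no visible frames")
    visible = render_visible_video(
        scene,
        n_frames=n - offset,
        illumination=config.illumination,
        blur_sigma=config.blur_sigma,
        occlusion_fraction=config.occlusion_fraction,
        seed=s_vis,
        noise_sd=config.visible_noise_sd,
        kinetics=kinetics,
        frame_times=np.arange(offset, n),
        icg_darkening=config.visible_icg_darkening,
    )

    truth = {
        "scene": scene,
        "kinetics": kinetics,
        "true_masks": true_masks,  # scene/visible coordinates, IR timebase
        "camera": camera,
        "seed": seed,
    }
    return VideoPair(
        visible_frames=visible,
        ir_frames=ir_frames,
        camera=camera,
        patient_id=patient_id or f"sim-{seed:03d}",
        truth=truth,
    )


def write_fixture(pair: VideoPair, out_dir: str | Path) -> Path:
    """Write a pair as PNG stacks plus a JSON truth file."""
    out = Path(out_dir)
    (out / "visible").mkdir(parents=True, exist_ok=True)
    (out / "ir").mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(pair.visible_frames):
        iio.imwrite(out / "visible" / f"{i:05d}.png", (frame * 255).round().astype(np.uint8))
    for i, frame in enumerate(pair.ir_frames):
        iio.imwrite(out / "ir" / f"{i:05d}.png", (frame * 255).round().astype(np.uint8))
    cam = pair.camera
    truth: dict = {
        "patient_id": pair.patient_id,
        "camera": {
            "resolution_class": cam.resolution_class,
            "ir_to_visible_scale_x": cam.ir_to_visible_scale_x,
            "ir_to_visible_scale_y": cam.ir_to_visible_scale_y,
            "frame_offset": cam.frame_offset,
            "fps": cam.fps,
            "residual_transform": {
                "scale": cam.residual_transform.scale,
                "rotation_deg": cam.residual_transform.rotation_deg,
                "translation": list(cam.residual_transform.translation),
            },
        },
    }
    if pair.truth is not None:
        k = pair.truth["kinetics"]
        truth["kinetics"] = {
            "artery_onset_frame": k.artery_onset_frame,
            "vein_onset_frame": k.vein_onset_frame,
            "rise_frames": k.rise_frames,
            "peak_intensity": k.peak_intensity,
            "decay_per_frame": k.decay_per_frame,
        }
        truth["seed"] = pair.truth["seed"]
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out
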