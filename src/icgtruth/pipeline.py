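"""End-to-end pipelines: simulate fixtures, build a dataset, evaluate masks.

``run_build`` chains the full ground-truth generation procedure on one or
more (simulated) paired recordings:

    preprocess (CLAHE + threshold) -> temporal alignment -> infrared
    magnification + similarity co-registration -> phase detection and
    class allocation -> frame-window selection -> random crops ->
    quality gate -> rotation augmentation -> resize -> patient split ->
    dataset on disk

Every stage logs frames in / passed / excluded, and the whole run is
reproducible from the serialized :class:`RunConfig` alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .geometry import SimilarityTransform2D
from .patches import (
    MANIFEST_COLUMNS,
    LabeledPatchPair,
    QualityPolicy,
    augment_rotations,
    crop_patches,
    quality_filter,
    read_label,
    resize_pair,
    select_frame_window,
    split_by_patient,
    write_dataset,
)
from .phases import allocate_classes, arrival_map, detect_phases
from .preprocess import ThresholdPolicy, binarize, equalize_contrast
from .register import (
    RegistrationOptions,
    content_window,
    coregister,
    rescale_infrared,
    warp_mask,
)
from .synthetic import SimulationConfig, VideoPair, make_video_pair, write_fixture
from .temporal import FrameOffset, apply_offset, estimate_offset

__all__ = ["RunConfig", "StageLog", "run_simulate", "run_build", "run_evaluate"]


@dataclass
class StageLog:
    """Per-stage frame/patch bookkeeping; in = passed + excluded always."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_passed: int) -> None:
        entry = self.counts.setdefault(stage, {"in": 0, "passed": 0, "excluded": 0})
        entry["in"] += n_in
        entry["passed"] += n_passed
        entry["excluded"] += n_in - n_passed
        if entry["in"] != entry["passed"] + entry["excluded"]:
            raise AssertionError(f"stage-count conservation violated at {stage}")


@dataclass
class RunConfig:
    """Everything needed to reproduce a dataset build bit-for-bit."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_patients: int = 3
    seed: int = 0
    # thresholding
    threshold_method: Literal["otsu", "fixed"] = "otsu"
    threshold_level: float = 0.55
    # temporal
    offset: int | Literal["auto"] = "auto"
    offset_search_range: int = 15
    # registration
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    registration_window: int = 256
    # phases
    phase_mode: Literal["auto", "arterial-only"] = "auto"
    include_delayed: bool = True
    # patches
    frames_per_patient: int = 4
    crops_per_frame: int = 3
    crop_size: int = 160
    rotation_delta: int = 45
    target_size: int = 512
    quality: QualityPolicy = field(default_factory=QualityPolicy)
    frame_window_half_width: int = 60
    validation_fraction: float = 0.2

    def threshold_policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(
            method=self.threshold_method, fixed_level=self.threshold_level
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            sim = dict(data["sim"])
            for key in ("frame_shape", "artery_width_range", "vein_width_range",
                        "artery_fraction_band", "residual_translation"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            data["sim"] = SimulationConfig(**sim)
        if "registration" in data and isinstance(data["registration"], dict):
            reg = dict(data["registration"])
            for key in ("scale_search", "rotation_search_deg"):
                if key in reg:
                    reg[key] = tuple(reg[key])
            data["registration"] = RegistrationOptions(**reg)
        if "quality" in data and isinstance(data["quality"], dict):
            q = dict(data["quality"])
            if "brightness_band" in q:
                q["brightness_band"] = tuple(q["brightness_band"])
            data["quality"] = QualityPolicy(**q)
        return cls(**data)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def patient_seeds(seed: int, n_patients: int) -> list[int]:
    """Per-patient simulator seeds derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_patients)]


def cohort(config: RunConfig) -> list[VideoPair]:
    """The simulated recordings a run with this config operates on."""
    return [
        make_video_pair(config.sim, seed=s, patient_id=f"patient-{i:03d}")
        for i, s in enumerate(patient_seeds(config.seed, config.n_patients))
    ]


def run_simulate(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Write one fixture recording per patient under ``out_dir``."""
    out = Path(out_dir)
    return [write_fixture(pair, out / pair.patient_id) for pair in cohort(config)]


def _luminance(rgb: np.ndarray) -> np.ndarray:
    return 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]


def _process_patient(
    pair: VideoPair,
    config: RunConfig,
    rng: np.random.Generator,
    log: StageLog,
) -> list[LabeledPatchPair]:
    policy = config.threshold_policy()

    # temporal alignment
    if config.offset == "auto":
        offset = estimate_offset(pair, search_range=config.offset_search_range, policy=policy)
    else:
        offset = FrameOffset(int(config.offset), source="configured")
    aligned = apply_offset(pair, offset)
    n = len(aligned.ir_frames)

    # per-frame enhanced masks in infrared-native coordinates
    enhanced = [equalize_contrast(f) for f in aligned.ir_frames]
    ir_masks = []
    for f in enhanced:
        if np.ptp(f) < 1e-12:
            ir_masks.append(np.zeros(f.shape, dtype=bool))
        else:
            ir_masks.append(binarize(f, policy).mask)

    # phase windows from dye-arrival clustering
    arrivals = arrival_map(enhanced, policy)
    windows = detect_phases(arrivals, n_frames=n)

    # key frame: largest vessel area inside the arterial window
    a0, a1 = windows.arterial
    areas = [m.mean() for m in ir_masks]
    key = a0 + int(np.argmax(areas[a0:a1])) if a1 > a0 else a0
    w0, w1 = select_frame_window(key, n, config.frame_window_half_width)

    # registration once per recording, at the frame with the most
    # fluorescent content (the delayed phase when present, where the
    # infrared tree matches everything tubular in the visible frame and a
    # not-yet-fluorescent vein cannot act as a decoy), on the window with
    # the most vessel structure
    reg_frame = int(np.argmax(areas))
    moving_full = rescale_infrared(enhanced[reg_frame], pair.camera)
    fixed_full = _luminance(aligned.visible_frames[reg_frame])
    common = (
        min(moving_full.shape[0], fixed_full.shape[0]),
        min(moving_full.shape[1], fixed_full.shape[1]),
    )
    side = min(config.registration_window, *common)
    reg_mask = rescale_infrared(ir_masks[reg_frame].astype(float), pair.camera) > 0.5
    origin = content_window(reg_mask[: common[0], : common[1]], side)
    r0, c0 = origin
    mv = moving_full[r0 : r0 + side, c0 : c0 + side]
    fx = fixed_full[r0 : r0 + side, c0 : c0 + side]
    reg = coregister(mv, fx, config.registration)
    # lift the crop-local transform to full-frame coordinates
    o = SimilarityTransform2D(translation=origin)
    transform = o @ reg.transform @ o.inverse()

    # frames allowed by the phase windows (and the artery-only switch),
    # then evenly sampled down to the per-patient budget
    allowed = []
    for idx in range(w0, w1):
        phase = windows.phase_of(idx)
        if phase is None:
            continue
        if phase == "delayed" and not config.include_delayed:
            continue
        allowed.append(idx)
    log.record("phase_gate", w1 - w0, len(allowed))
    if not allowed:
        return []
    picks = np.linspace(0, len(allowed) - 1, config.frames_per_patient)
    usable = sorted({allowed[int(round(p))] for p in picks})

    out: list[LabeledPatchPair] = []
    n_candidates = 0
    n_quality_pass = 0
    for idx in usable:
        mask_vis_scale = rescale_infrared(ir_masks[idx].astype(float), pair.camera) > 0.5
        vis = aligned.visible_frames[idx]
        h, w = vis.shape[:2]
        mask_aligned = warp_mask(mask_vis_scale, transform, out_shape=(h, w))
        class_map = allocate_classes(mask_aligned, windows, idx)

        crops = crop_patches(
            vis, class_map.labels, config.crops_per_frame, config.crop_size, seed=rng
        )
        for img_patch, lbl_patch, (r, c) in crops:
            n_candidates += 1
            q = quality_filter(img_patch, lbl_patch, config.quality)
            if not q.passed:
                continue
            n_quality_pass += 1
            for rot_img, rot_lbl, angle in augment_rotations(
                img_patch, lbl_patch, config.rotation_delta
            ):
                final_img, final_lbl = resize_pair(rot_img, rot_lbl, config.target_size)
                out.append(
                    LabeledPatchPair(
                        image=final_img,
                        labels=final_lbl.astype(np.uint8),
                        patient_id=pair.patient_id,
                        frame_index=idx,
                        crop_origin=(r, c),
                        crop_size=config.crop_size,
                        rotation_deg=angle,
                        phase_tag=class_map.phase_tag,
                        registration_metric=reg.final_metric,
                    )
                )
    log.record("quality_filter", n_candidates, n_quality_pass)
    return out


def run_build(
    config: RunConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, StageLog]:
    """Build a paired image/label dataset from simulated recordings."""
    out = Path(out_dir)
    log = StageLog()
    crop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    all_pairs: list[LabeledPatchPair] = []
    for pair in cohort(config):
        all_pairs.extend(_process_patient(pair, config, crop_rng, log))
    if not all_pairs:
        raise RuntimeError("no patches survived the pipeline; relax the quality policy")

    # split over the whole cohort: a patient whose patches were all
    # filtered out still belongs to exactly one side of the partition
    splits = split_by_patient(
        [f"patient-{i:03d}" for i in range(config.n_patients)],
        config.validation_fraction,
        seed=config.seed,
    )
    rows = []
    for j, p in enumerate(all_pairs):
        rows.append(
            {
                "file_stem": f"{p.patient_id}_f{p.frame_index:04d}_r{p.crop_origin[0]:04d}"
                f"c{p.crop_origin[1]:04d}_rot{p.rotation_deg:03d}",
                "patient_id": p.patient_id,
                "frame_index": p.frame_index,
                "crop_row": p.crop_origin[0],
                "crop_col": p.crop_origin[1],
                "crop_size": p.crop_size,
                "rotation_deg": p.rotation_deg,
                "phase_tag": p.phase_tag,
                "registration_metric": round(p.registration_metric, 6),
                "split": splits[p.patient_id],
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    write_dataset(all_pairs, manifest, out, run_config=config.to_dict())
    (out / "stage_log.json").write_text(json.dumps(log.counts, indent=2, sort_keys=True))
    return manifest, log


def run_evaluate(
    pred_dir: str | Path,
    truth_dir: str | Path,
    pooling: Literal["pooled", "per_image_mean"] = "pooled",
    out_path: str | Path | None = None,
) -> dict:
    """Score prediction PNGs against ground-truth PNGs matched by filename."""
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    preds = {p.name: p for p in sorted(pred_dir.glob("*.png"))}
    truths = {p.name: p for p in sorted(truth_dir.glob("*.png"))}
    unmatched = sorted(set(preds) ^ set(truths))
    if unmatched:
        raise ValueError(f"unmatched prediction/truth filenames: {unmatched}")
    if not preds:
        raise ValueError("no mask pairs found")
    pairs = [(read_label(preds[n]), read_label(truths[n])) for n in sorted(preds)]
    result = {
        "pooled": _metrics.report(pairs, pooling="pooled").as_dict(),
        "per_image_mean": _metrics.report(pairs, pooling="per_image_mean").as_dict(),
        "n_images": len(pairs),
        "requested_pooling": pooling,
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(result, indent=2, sort_keys=True))
    return result
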