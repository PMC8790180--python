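"""Shared fixtures: one small simulated cohort reused across the suite.

The simulator canvases here are deliberately smaller than a real SD frame
(192x256 rather than 480x720) so the full pipeline stays fast; every
property under test is resolution-independent.
"""

from __future__ import annotations

import numpy as np
import pytest

import icgtruth as it
from icgtruth.pipeline import cohort


SMALL_SIM = dict(
    frame_shape=(192, 256),
    n_frames=60,
    artery_onset_frame=10,
    vein_onset_frame=35,
    n_arteries=2,
    n_veins=1,
)


@pytest.fixture(scope="session")
def clean_sim_config() -> it.SimulationConfig:
    """Noise-free small recording with a known 5-frame start offset."""
    return it.SimulationConfig(
        **SMALL_SIM, ir_noise_sd=0.0, visible_noise_sd=0.0, frame_offset=5
    )


@pytest.fixture(scope="session")
def clean_pair(clean_sim_config) -> it.VideoPair:
    return it.make_video_pair(clean_sim_config, seed=3)


@pytest.fixture(scope="session")
def vessel_scene(clean_pair) -> it.VesselScene:
    return clean_pair.truth["scene"]


@pytest.fixture(scope="session")
def arterial_frame(clean_pair) -> np.ndarray:
    """Noise-free infrared frame with the arterial tree fully fluorescent
    (after onset + transit + rise, before the veins fill)."""
    return clean_pair.ir_frames[25]


@pytest.fixture(scope="session")
def wide_arterial_frame() -> np.ndarray:
    """Arterial-phase frame from a scene with wider vessels (8-14 px):
    mask-overlap checks after double nearest-neighbor warps need the
    one-pixel interpolation band to be small against the lumen width."""
    cfg = it.SimulationConfig(
        **{**SMALL_SIM, "artery_width_range": (8.0, 14.0)},
        ir_noise_sd=0.0, visible_noise_sd=0.0, frame_offset=5,
    )
    pair = it.make_video_pair(cfg, seed=21)
    return pair.ir_frames[25]


@pytest.fixture(scope="session")
def build_config() -> it.RunConfig:
    """Three-patient build with a genuine residual camera misalignment."""
    return it.RunConfig(
        sim=it.SimulationConfig(
            **SMALL_SIM,
            ir_noise_sd=0.0,
            visible_noise_sd=0.0,
            frame_offset=5,
            residual_scale=1.03,
            residual_rotation_deg=3.0,
            residual_translation=(4.0, -6.0),
        ),
        n_patients=3,
        seed=1,
        crop_size=96,
        frames_per_patient=3,
        crops_per_frame=2,
    )


@pytest.fixture(scope="session")
def built_dataset(build_config, tmp_path_factory):
    """One full dataset build shared by the pipeline and acceptance tests."""
    out = tmp_path_factory.mktemp("dataset")
    manifest, log = it.run_build(build_config, out)
    return out, manifest, log


@pytest.fixture(scope="session")
def build_cohort(build_config) -> dict[str, it.VideoPair]:
    """The exact recordings the shared build operated on, with truth."""
    return {p.patient_id: p for p in cohort(build_config)}
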