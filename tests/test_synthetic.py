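"""Paired-video simulator: determinism, anatomy, kinetics, camera model."""

import numpy as np
import pytest
from skimage import morphology

import icgtruth as it
from icgtruth import metrics
from icgtruth.geometry import SimilarityTransform2D
from icgtruth.register import warp_mask


SMALL = dict(frame_shape=(192, 256), n_frames=60, vein_onset_frame=35,
             n_arteries=2, n_veins=1)


class TestVesselScene:
    def test_same_seed_reproduces_scene_exactly(self):
        cfg = it.SimulationConfig(**SMALL)
        a = it.generate_vessel_scene(cfg, seed=1)
        b = it.generate_vessel_scene(cfg, seed=1)
        np.testing.assert_array_equal(a.artery_map, b.artery_map)
        np.testing.assert_array_equal(a.vein_map, b.vein_map)
        np.testing.assert_array_equal(a.background_texture, b.background_texture)

    def test_zero_vein_density_gives_empty_vein_map(self):
        cfg = it.SimulationConfig(**{**SMALL, "n_veins": 0})
        scene = it.generate_vessel_scene(cfg, seed=2)
        assert not scene.vein_map.any()

    def test_artery_fraction_within_configured_band(self):
        cfg = it.SimulationConfig(**SMALL)
        scene = it.generate_vessel_scene(cfg, seed=7)
        frac = scene.artery_map.mean()
        lo, hi = cfg.artery_fraction_band
        assert lo <= frac <= hi

    def test_maps_disjoint_and_vessels_elongated(self, vessel_scene):
        assert not np.any(vessel_scene.artery_map & vessel_scene.vein_map)
        # elongation: total skeleton length at least 3x the mean width
        for mask in (vessel_scene.artery_map, vessel_scene.vein_map):
            skeleton = morphology.skeletonize(mask)
            skel_len = skeleton.sum()
            mean_width = mask.sum() / max(skel_len, 1)
            assert skel_len >= 3 * mean_width

    def test_infeasible_fraction_band_fails_with_named_constraint(self):
        cfg = it.SimulationConfig(
            **{**SMALL, "artery_fraction_band": (0.80, 0.90), "n_arteries": 1}
        )
        with pytest.raises(RuntimeError, match="fraction"):
            it.generate_vessel_scene(cfg, seed=1)

    def test_tiny_canvas_rejected(self):
        with pytest.raises(ValueError):
            it.generate_vessel_scene(
                it.SimulationConfig(frame_shape=(32, 32)), seed=0
            )


@pytest.fixture(scope="module")
def scene():
    return it.generate_vessel_scene(it.SimulationConfig(**SMALL), seed=5)


class TestICGVideo:
    def test_no_vessel_visible_before_arterial_onset(self, scene):
        kin = it.ICGKinetics(artery_onset_frame=10, vein_onset_frame=40)
        frames, masks = it.simulate_icg_video(scene, kin, n_frames=50, noise_sd=0.0)
        assert not masks[:10].any()

    def test_mask_equals_artery_map_after_rise_without_transit(self):
        cfg = it.SimulationConfig(
            **{**SMALL, "artery_transit_frames": 0.0, "vein_transit_frames": 0.0}
        )
        scene = it.generate_vessel_scene(cfg, seed=5)
        kin = it.ICGKinetics(artery_onset_frame=10, vein_onset_frame=40, rise_frames=5)
        frames, masks = it.simulate_icg_video(scene, kin, n_frames=50, noise_sd=0.0)
        np.testing.assert_array_equal(masks[15], scene.artery_map)
        # after the veins fill, the mask covers the whole vessel tree
        np.testing.assert_array_equal(masks[45], scene.vessel_map)

    def test_instant_rise_arrives_exactly_at_onset(self):
        cfg = it.SimulationConfig(
            **{**SMALL, "artery_transit_frames": 0.0, "vein_transit_frames": 0.0}
        )
        scene = it.generate_vessel_scene(cfg, seed=6)
        kin = it.ICGKinetics(artery_onset_frame=10, vein_onset_frame=40, rise_frames=0)
        _, masks = it.simulate_icg_video(scene, kin, n_frames=45, noise_sd=0.0)
        assert not masks[9].any()
        np.testing.assert_array_equal(masks[10], scene.artery_map)

    def test_nonvessel_pixels_hold_baseline_only(self, scene):
        kin = it.ICGKinetics(artery_onset_frame=5, vein_onset_frame=20)
        frames, _ = it.simulate_icg_video(
            scene, kin, n_frames=30, noise_sd=0.0, baseline=0.05
        )
        background = ~scene.vessel_map
        assert np.allclose(frames[25][background], 0.05)

    def test_delayed_phase_unreachable_fails(self, scene):
        kin = it.ICGKinetics(artery_onset_frame=5, vein_onset_frame=40)
        with pytest.raises(ValueError):
            it.simulate_icg_video(scene, kin, n_frames=40, noise_sd=0.0)

    def test_vein_onset_must_follow_artery_onset(self):
        with pytest.raises(ValueError):
            it.ICGKinetics(artery_onset_frame=20, vein_onset_frame=20)


class TestVisibleVideo:
    def test_same_seed_renders_identical_frames(self, scene):
        a = it.render_visible_video(scene, n_frames=3, seed=4)
        b = it.render_visible_video(scene, n_frames=3, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_artery_pixels_contrast_against_background(self, scene):
        frames = it.render_visible_video(
            scene, n_frames=1, illumination=1.0, blur_sigma=0.0,
            occlusion_fraction=0.0, noise_sd=0.0, seed=0,
        )
        frame = frames[0]
        # green channel separates the reddish vessels from pinkish tissue
        green = frame[..., 1]
        bg_min_green = green[~scene.vessel_map].min()
        artery_green = green[scene.artery_map]
        assert np.all(bg_min_green - artery_green >= 0.1)

    def test_zero_illumination_gives_near_black_frames(self, scene):
        frames = it.render_visible_video(
            scene, n_frames=2, illumination=0.0, seed=1, noise_sd=0.005
        )
        assert frames.max() <= 0.03  # nothing above the noise ceiling

    def test_occlusion_darkens_requested_fraction(self, scene):
        lit = it.render_visible_video(scene, n_frames=1, seed=2, noise_sd=0.0)
        shadowed = it.render_visible_video(
            scene, n_frames=1, seed=2, noise_sd=0.0, occlusion_fraction=0.3
        )
        darker = (shadowed[0].mean(axis=-1) < lit[0].mean(axis=-1) - 0.05).mean()
        assert 0.2 <= darker <= 0.6

    def test_out_of_range_parameters_rejected(self, scene):
        with pytest.raises(ValueError):
            it.render_visible_video(scene, n_frames=1, illumination=1.5)
        with pytest.raises(ValueError):
            it.render_visible_video(scene, n_frames=1, occlusion_fraction=-0.1)


class TestVideoPair:
    def test_stream_lengths_differ_by_frame_offset(self, clean_pair, clean_sim_config):
        offset = clean_sim_config.frame_offset
        assert len(clean_pair.ir_frames) - len(clean_pair.visible_frames) == offset

    def test_same_seed_reproduces_pair_bytewise(self, clean_sim_config):
        a = it.make_video_pair(clean_sim_config, seed=11)
        b = it.make_video_pair(clean_sim_config, seed=11)
        np.testing.assert_array_equal(a.visible_frames, b.visible_frames)
        np.testing.assert_array_equal(a.ir_frames, b.ir_frames)

    def test_hd_pair_has_native_stream_geometries(self):
        cfg = it.SimulationConfig(
            resolution_class="HD", n_frames=12, artery_onset_frame=2,
            vein_onset_frame=4, rise_frames=1, n_arteries=2, n_veins=1,
            artery_width_range=(8.0, 16.0), vein_width_range=(14.0, 22.0),
        )
        pair = it.make_video_pair(cfg, seed=1)
        assert pair.visible_frames.shape[1:3] == (1080, 1920)
        # infrared native size: the visible frame divided by the fixed
        # anisotropic magnification (2.43 vertical, 2.28 horizontal)
        assert pair.ir_frames.shape[1:] == (444, 842)
        assert len(pair.ir_frames) - len(pair.visible_frames) == 8

    def test_identity_camera_keeps_ir_aligned_with_scene(self, clean_pair):
        """With unit scales and identity residual, the infrared stream is
        pixelwise aligned with the scene's truth masks."""
        scene = clean_pair.truth["scene"]
        t = 25  # full arterial development
        ir_mask = clean_pair.ir_frames[t] > 0.5 * 0.9
        np.testing.assert_array_equal(ir_mask, clean_pair.truth["true_masks"][t])

    def test_true_transform_chain_reproduces_visible_artery_map(self):
        """Carrying the infrared-native artery map through the known
        residual transform recovers the scene's artery map up to
        interpolation (IoU >= 0.95; vessels a couple of pixels wider than
        the default so the one-pixel resampling band stays small against
        the lumen area)."""
        cfg = it.SimulationConfig(**{**SMALL, "artery_width_range": (8.0, 14.0)})
        scene = it.generate_vessel_scene(cfg, seed=13)
        residual = SimilarityTransform2D(
            scale=1.04, rotation_deg=-4.0, translation=(-3.0, 5.0)
        )
        ir_native = warp_mask(
            scene.artery_map, residual.inverse(), out_shape=scene.canvas_size
        )
        recovered = warp_mask(ir_native, residual, out_shape=scene.canvas_size)
        c = metrics.confusion(recovered, scene.artery_map)
        assert metrics.iou_foreground(c) >= 0.95
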