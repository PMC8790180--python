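"""Infrared magnification and intensity-based similarity co-registration."""

import numpy as np
import pytest
from scipy import ndimage

import icgtruth as it
from icgtruth import metrics
from icgtruth.geometry import SimilarityTransform2D, warp_image
from icgtruth.register import (
    RegistrationOptions,
    content_window,
    coregister,
    rescale_infrared,
    warp_mask,
)


@pytest.fixture(scope="module")
def hd_camera():
    return it.CameraModel.default("HD")


@pytest.fixture(scope="module")
def vessel_window(arterial_frame):
    """A 160x160 window centered on the arterial tree's centroid, so every
    crop contains vessel structure."""
    h, w = arterial_frame.shape
    cy, cx = ndimage.center_of_mass(arterial_frame > 0.45)
    r0 = int(np.clip(round(cy) - 80, 0, h - 160))
    c0 = int(np.clip(round(cx) - 80, 0, w - 160))
    return slice(r0, r0 + 160), slice(c0, c0 + 160)


@pytest.fixture(scope="module")
def patch(arterial_frame, vessel_window):
    """A 160x160 vessel-bearing patch from the noise-free simulator."""
    return arterial_frame[vessel_window].copy()


def warped_crop(frame, window, transform):
    """Warp the full frame, then crop: content flows into the window from
    outside it, as in a real misaligned camera, with no synthetic borders."""
    return warp_image(frame, transform, order=1)[window]


def centered_params(result, shape):
    """Express a recovered transform as (scale, rotation, translation
    about the patch center) for comparison against the applied one."""
    center = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    t = result.transform
    translation = t.apply(center[None, :])[0] - center
    return t.scale, t.rotation_deg, translation


class TestRescaleInfrared:
    def test_hd_frame_magnified_by_fixed_ratios(self, hd_camera):
        out = rescale_infrared(np.zeros((100, 100)), hd_camera)
        assert out.shape == (243, 228)  # 2.43 x rows, 2.28 x cols

    def test_sd_frame_returned_unchanged(self, arterial_frame):
        sd = it.CameraModel(resolution_class="SD")
        out = rescale_infrared(arterial_frame, sd)
        np.testing.assert_array_equal(out, arterial_frame)

    def test_round_trip_preserves_smooth_content(self, hd_camera):
        rng = np.random.default_rng(0)
        frame = ndimage.gaussian_filter(rng.uniform(size=(120, 160)), sigma=4)
        up = rescale_infrared(frame, hd_camera)
        from skimage.transform import resize

        back = resize(up, frame.shape, order=1, anti_aliasing=True)
        assert np.abs(back - frame).mean() <= 0.02


class TestCoregister:
    def test_identical_patches_give_identity(self, patch):
        res = coregister(patch, patch)
        assert res.transform.is_identity(tol=1e-3)
        assert res.final_metric > 0.999

    def test_pure_translation_recovered_within_half_pixel(
        self, arterial_frame, vessel_window, patch
    ):
        shift = SimilarityTransform2D(translation=(5.0, -3.0))
        moving = warped_crop(arterial_frame, vessel_window, shift)
        res = coregister(moving, patch)
        s, r, t = centered_params(res, patch.shape)
        # aligning moving back onto fixed inverts the applied shift
        np.testing.assert_allclose(t, (-5.0, 3.0), atol=0.5)
        assert abs(s - 1.0) <= 0.02 and abs(r) <= 1.0

    def test_scale_and_rotation_recovered(self, arterial_frame, vessel_window, patch):
        rows, cols = vessel_window
        center = (rows.start + 79.5, cols.start + 79.5)
        applied = SimilarityTransform2D.about(center, scale=1.05, rotation_deg=5.0)
        moving = warped_crop(arterial_frame, vessel_window, applied)
        res = coregister(moving, patch)
        s, r, _ = centered_params(res, patch.shape)
        assert abs(s * 1.05 - 1.0) <= 0.02
        assert abs(r + 5.0) <= 1.0

    def test_zero_variance_patch_rejected(self, patch):
        with pytest.raises(ValueError):
            coregister(np.zeros_like(patch), patch)

    def test_shape_mismatch_rejected(self, patch):
        with pytest.raises(ValueError):
            coregister(patch[:-8], patch)

    def test_metric_trace_non_decreasing(self, patch):
        shift = SimilarityTransform2D(translation=(4.0, 2.0))
        res = coregister(warp_image(patch, shift, order=1), patch)
        trace = np.asarray(res.metric_trace)
        assert np.all(np.diff(trace) >= 0)  # similarity only improves
        assert res.final_metric >= trace[0]

    def test_multimodal_registration_visible_vs_infrared(
        self, clean_pair, vessel_window
    ):
        """Registering the visible luminance (fixed) against the infrared
        fluorescence (moving) — different modalities — still recovers an
        applied shift via the gradient-magnitude metric."""
        shift = SimilarityTransform2D(translation=(6.0, -4.0))
        moving = warped_crop(clean_pair.ir_frames[30], vessel_window, shift)
        vis = clean_pair.visible_frames[25]
        lum = 0.2126 * vis[..., 0] + 0.7152 * vis[..., 1] + 0.0722 * vis[..., 2]
        fixed = lum[vessel_window]
        res = coregister(moving, fixed)
        _, _, t = centered_params(res, fixed.shape)
        np.testing.assert_allclose(t, (-6.0, 4.0), atol=0.75)

    def test_mutual_information_metric_also_recovers_shift(
        self, arterial_frame, vessel_window, patch
    ):
        shift = SimilarityTransform2D(translation=(5.0, 0.0))
        moving = warped_crop(arterial_frame, vessel_window, shift)
        res = coregister(
            moving, patch, RegistrationOptions(metric="mutual_information")
        )
        _, _, t = centered_params(res, patch.shape)
        np.testing.assert_allclose(t, (-5.0, 0.0), atol=0.75)


def test_parameter_recovery_over_random_perturbations(wide_arterial_frame):
    """Random similarity perturbations (scale within [0.93, 1.08],
    rotation within 10 degrees, translation within 10 px) are recovered to
    0.02 / 1 degree / 0.5 px, and the registered artery mask overlaps the
    reference at IoU >= 0.90 (wider vessels, so the nearest-neighbor
    resampling band stays small against the lumen)."""
    frame = wide_arterial_frame
    r0, c0 = content_window(frame > 0.45, 160)
    window = (slice(r0, r0 + 160), slice(c0, c0 + 160))
    fixed = frame[window]
    rng = np.random.default_rng(17)
    center = (r0 + 79.5, c0 + 79.5)
    mask_full = frame > 0.45
    mask = mask_full[window]
    for _ in range(4):
        s = float(rng.uniform(0.93, 1.08))
        r = float(rng.uniform(-10, 10))
        ty, tx = (float(v) for v in rng.uniform(-10, 10, size=2))
        applied = SimilarityTransform2D.about(
            center, scale=s, rotation_deg=r, translation=(ty, tx)
        )
        moving = warped_crop(frame, window, applied.inverse())
        res = coregister(moving, fixed)
        est_s, est_r, est_t = centered_params(res, fixed.shape)
        assert abs(est_s - s) <= 0.02
        assert abs(est_r - r) <= 1.0
        assert np.all(np.abs(est_t - np.array([ty, tx])) <= 0.5)
        moving_mask_full = warp_mask(mask_full, applied.inverse())
        # lift the patch-local transform to full-frame coordinates, as the
        # dataset pipeline does, so mask content flows back into the window
        o = SimilarityTransform2D(translation=(r0, c0))
        lifted = o @ res.transform @ o.inverse()
        recovered = warp_mask(moving_mask_full, lifted)[window]
        # score only where the round trip stayed inside the recorded frame:
        # content pushed out of the field of view is not a registration error
        ones = np.ones_like(mask_full)
        valid = warp_mask(warp_mask(ones, applied.inverse()), lifted)[window]
        c = metrics.confusion(recovered[valid], mask[valid])
        assert metrics.iou_foreground(c) >= 0.90


def test_agreement_with_independent_itk_registration(
    arterial_frame, vessel_window, patch
):
    """Cross-check against SimpleITK's registration framework on the same
    translation problem: both should land within half a pixel of truth."""
    sitk = pytest.importorskip("SimpleITK")
    shift = SimilarityTransform2D(translation=(5.0, -3.0))
    moving = warped_crop(arterial_frame, vessel_window, shift)

    res = coregister(moving, patch)
    _, _, ours = centered_params(res, patch.shape)

    fixed_img = sitk.GetImageFromArray(patch.astype(np.float32))
    moving_img = sitk.GetImageFromArray(moving.astype(np.float32))
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200
    )
    reg.SetInitialTransform(sitk.TranslationTransform(2), inPlace=False)
    out = reg.Execute(fixed_img, moving_img)
    # ITK transform maps fixed points to moving points, in (x, y)
    ox, oy = out.GetParameters()
    theirs = np.array([-oy, -ox])
    np.testing.assert_allclose(ours, (-5.0, 3.0), atol=0.5)
    np.testing.assert_allclose(theirs, (-5.0, 3.0), atol=0.5)


def test_planar_approximation_residual_grows_with_patch_size(
    arterial_frame, vessel_window
):
    """The two cameras form a stereo pair, so a single 2-D similarity fit
    degrades as the field of view grows: with a synthetic non-planar
    disparity field, the post-registration misfit increases monotonically
    over three concentric patch sizes."""
    frame = arterial_frame
    h, w = frame.shape
    rows, cols = vessel_window
    cy, cx = rows.start + 79.5, cols.start + 79.5
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    # quadratic disparity: zero at the crop center, growing outward
    dx = 8.0 * ((cc - cx) / w) ** 2
    dy = 6.0 * ((rr - cy) / h) ** 2
    moving = ndimage.map_coordinates(frame, [rr + dy, cc + dx], order=1)

    misfits = []
    for size in (64, 112, 160):
        r0 = int(np.clip(round(cy) - size // 2, 0, h - size))
        c0 = int(np.clip(round(cx) - size // 2, 0, w - size))
        mv = moving[r0 : r0 + size, c0 : c0 + size]
        fx = frame[r0 : r0 + size, c0 : c0 + size]
        res = coregister(mv, fx)
        misfits.append(1.0 - res.final_metric)
    assert misfits[0] <= misfits[1] <= misfits[2]


class TestWarpMask:
    def test_identity_transform_preserves_mask(self, vessel_scene):
        mask = vessel_scene.artery_map
        out = warp_mask(mask, SimilarityTransform2D.identity())
        np.testing.assert_array_equal(out, mask)

    def test_quarter_turn_about_center_has_order_four(self):
        rng = np.random.default_rng(3)
        mask = rng.uniform(size=(33, 33)) > 0.7  # asymmetric
        center = (16.0, 16.0)
        r90 = SimilarityTransform2D.about(center, rotation_deg=90.0)
        out = mask
        for _ in range(4):
            out = warp_mask(out, r90)
        np.testing.assert_array_equal(out, mask)

    def test_translation_moves_centroid(self):
        # a compact interior blob, so nothing is clipped at the borders
        from skimage.draw import disk

        mask = np.zeros((96, 128), dtype=bool)
        rr, cc = disk((40, 60), 11)
        mask[rr, cc] = True
        out = warp_mask(mask, SimilarityTransform2D(translation=(3.0, 0.0)))
        c_in = np.array(ndimage.center_of_mass(mask))
        c_out = np.array(ndimage.center_of_mass(out))
        np.testing.assert_allclose(c_out - c_in, (3.0, 0.0), atol=0.5)

    def test_output_strictly_binary(self, vessel_scene):
        out = warp_mask(
            vessel_scene.artery_map,
            SimilarityTransform2D(scale=1.1, rotation_deg=7.0, translation=(2.5, 1.5)),
        )
        assert out.dtype == bool
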