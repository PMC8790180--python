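# Methods

This note records the models, conventions and numerical choices behind
`icgtruth`, and what the simulator-based tests do and do not establish.

## Scope and model of the recording

The package models a dual-camera neurosurgical operating microscope: a
full-color visible-light camera and an infrared camera imaging indocyanine
green (ICG) fluorescence, recorded simultaneously at 29.97 fps. Two scope
classes are supported: SD (720×480, both cameras at the same scale) and HD
(visible 1920×1080, infrared at a lower native resolution that must be
magnified ×2.28 horizontally and ×2.43 vertically to match the visible
frame — fixed properties of the scope model). The streams start a few
frames apart; the visible stream lags by 3 (alternatively 10) frames on SD
and 8 frames on HD by default. Beyond these fixed factors, the cameras are
related by a small residual 2-D similarity misalignment; the true relation
is a stereo pair, so the planar model is only valid over small patches —
which is why registration and dataset construction operate on patches, and
why a test asserts that the registration misfit grows with patch size
under a synthetic disparity field.

Ground-truth classes are binary (background vs vessel). During the
arterial phase only arteries fluoresce, so arterial-phase masks are artery
labels; delayed-phase masks include veins and are tagged so artery-only
dataset builds can exclude them. Vein-specific classes, capillaries and
atherosclerotic vessel modeling are out of scope.

## Synthetic paired-video generator

No clinical recordings ship with the package, so `synthetic` fabricates
them with exact truth. Its defaults are the study conditions every
simulator-based test and the acceptance script run under.

**Anatomy.** Vessels are smoothed random-walk tubes: a centerline whose
heading changes by an AR(1) angular increment (clipped at ±0.25 rad per
2-px step), stamped as disks whose radius drifts within a width band
(arteries 4–9 px, veins 8–14 px by default; veins are drawn wider and
darker). Each tube may spawn one narrower branch. Arteries are added until
their pixel fraction enters a configured band (default 2–25 % of the
canvas); a scene that overshoots is regenerated from a derived sub-seed a
bounded number of times before failing with the violated constraint named.
This construction guarantees the elongated morphology real vessels have
(skeleton length ≫ width) without pretending to be an anatomical model.

**Kinetics.** Dye fluorescence at a pixel ramps linearly from its onset
frame to a peak (default 0.9) over `rise_frames` (default 5), then decays
geometrically (default: no decay). Arteries onset at frame 10, veins at
40 by default. The bolus front also propagates *along* each vessel:
per-pixel transit delays grow downstream from the entry point (default
6 frames end-to-end). The per-frame **true visibility mask** is defined as
noise-free intensity above half the peak — a simulator convention stated
here so the recovery properties are exact.

**Rendering.** Infrared frames are baseline (0.05) + fluorescence +
Gaussian noise, clipped to [0, 1]; they are rendered in infrared-camera
coordinates by pulling the scene back through the inverse of the
magnification and residual transform, with noise added in the native
domain. Visible frames show reddish vessels over a smooth pinkish tissue
texture, with degradations (illumination scaling, defocus blur, dark
occluding blobs) and a small darkening of vessel pixels once the dye
reaches them (default 15 %, a per-pixel step at arrival — the visible
trace of the green dye at bolus concentration, assumed to saturate within
one frame). This darkening is what makes the temporal offset estimable
from the two streams, as it is from real recordings where the injection
leaves a visible trace.

**What the simulator does not emulate.** Photorealism, stereo disparity
fields (only a planar residual misalignment plus the synthetic disparity
used in one test), camera motion during recording, atherosclerotic wall
occlusion of fluorescence, and specular highlights. Tests passing on the
simulator therefore establish internal consistency of the pipeline —
geometry, timing, thresholds, bookkeeping — not clinical performance.

## Preprocessing

CLAHE uses a normalized clip limit of 0.01 and an 8×8 tile grid (common
practice; the method itself is standard contrast-limited adaptive
histogram equalization). Constant frames pass through unchanged.

Otsu's threshold is computed on a fixed 256-bin histogram over [0, 1]
(8-bit video heritage), not over the observed data range, so levels are
comparable across frames. The between-class variance curve is scanned
directly and the **midpoint of the maximizer plateau** is returned: on
well-separated bimodal histograms every cut between the modes maximizes
the variance, and taking an endpoint of that plateau would put the level
on the edge of one class — under the strict `>` binarization convention
(ties to background, matching common binarization semantics) that would
swallow the lower mode. Binarization under the Otsu method falls back to
the fixed level when the foreground fraction leaves an adequacy band
(default 0.5–40 %): vessels occupy a bounded minority of the field, so a
90 %-foreground Otsu split signals a frame the method cannot threshold.
The fixed level defaults to 0.55 and is validated to [0.5, 0.7], the range
that covers essentially all recordings in practice. Whether thresholding
is per-frame or per-recording was an open design point; it is applied
per-frame with a per-run policy.

## Temporal alignment

The offset is a constant integer per recording (both cameras share one
clock; no drift model). `apply_offset` pairs visible frame *i* with
infrared frame *i + offset* and retains the dropped head/tail so the
operation is exactly reversible. The estimator scores every candidate
offset up to a search bound (default 15, capped at 30) by the Pearson
correlation between two arrival-train
signals: the differenced infrared fluorescent area above an
arrival-sensitive threshold (per-frame background median plus a noise
margin of max(0.08, 6·MAD)) and the mean inter-frame visible luminance
change. Both signals count the pixels the bolus front reaches each frame;
a vessel-quality threshold (Otsu or fixed) would detect each pixel only
mid-rise and bias the estimate by a frame, which is why the estimator uses
its own threshold. Ties break toward the smallest offset. Flat streams
raise an error rather than returning an arbitrary offset.

## Spatial registration

`rescale_infrared` resizes HD infrared frames by the fixed ratios
(output dimensions rounded half away from zero, stated for bit-exact
dataset reproducibility); SD frames pass through.

`coregister` estimates the similarity transform mapping moving (infrared,
post-magnification) onto fixed (visible) coordinates. Because the streams
are different modalities, the default metric is normalized
cross-correlation of Gaussian gradient-magnitude images (σ = 1.0; sharper
gradients localize the optimum better on sparse vessel content);
histogram mutual information (32 bins) is a configurable alternative. The
search is deterministic and proceeds in passes:

1. a coarse grid over scale (0.90–1.10, step 0.025) and rotation (±12°,
   step 3°) with translation solved by phase correlation at each node and
   the identity always included. Candidates are compared by the metric
   **weighted by the square root of the warped-in overlap fraction**
   (hard floor 25 %): the metric alone is computed only over each
   candidate's valid region, so a large spurious motion that shrinks the
   valid region to a self-similar sliver — sliding along a straight
   vessel — could otherwise outscore the true alignment;
2. Powell refinement of (log-scale, rotation, dy, dx) about the patch
   center on the raw (unweighted) metric, bounded to the selected
   candidate's basin (±0.05 log-scale, ±4.5°, ±8 px), tolerance 1e-5, at
   most 200 iterations — bounded so the weighting cannot bias the optimum
   and no distant sliver is reachable;
3. two narrow re-warp passes (grid ±1 %, ±1°): the moving image is
   resampled through the current estimate and re-registered. On sparse
   content the first optimum sits in a shallow valley where the metric
   plateaus while the parameters still improve; each re-warp pass
   contracts that residual.

The reported metric is the similarity of the finally aligned pair over
its warped-in region; the result also records the metric at every
accepted (improving) optimizer step — non-decreasing by construction —
and a convergence flag that enforces a sanity bound of scale ∈ [0.5, 2].
Out-of-field pixels are always excluded through a warped validity mask.
Masks are transported with nearest-neighbor interpolation (preserves
binarity); images bilinearly. Registration runs infrared→visible because
the ground truth must land on visible patches. The dataset pipeline
registers once per recording, at the frame with the most fluorescent
content (the delayed phase when present — there the infrared tree matches
everything tubular in the visible frame, and a not-yet-fluorescent vein
cannot act as a decoy), on the window holding the most vessel pixels
(`content_window`); registration needs structure to lock onto, and a
window centered on empty field is ill-conditioned.

Mask-overlap checks after a double nearest-neighbor warp carry an
interpolation band of roughly one pixel per boundary; on 4–9 px vessels
that alone costs ~0.1 IoU, so overlap-based assertions use scenes with
8–14 px vessels and score only pixels whose round trip stayed inside the
recorded field of view — parameter-error assertions are width-independent
and use the defaults.

## Phase detection and class allocation

Per-pixel arrival is the first frame whose binarized value stays
foreground for at least 3 consecutive frames (debounce against flicker).
Finite arrivals are clustered by a deterministic 1-D 2-means with centers
initialized at the earliest and latest arrival; the delayed phase starts
at the earliest late-cluster arrival and runs to the end of the video
(the recordings give no better endpoint). If the cluster centers are
closer than 5 frames there is no discernible venous wave and the whole
video is labeled arterial. Both the debounce length and the separation
threshold are exposed in configuration; explicit window specification
bypasses detection entirely. Purity (no vein pixel in any arterial-phase
class map) is structural on noise-free input: the phase boundary is the
earliest vein detection by the same detector that builds the masks.

## Patch pipeline

The frame window is ±60 frames around a key frame (the arterial-phase
frame with the largest vessel area), clipped to the video and applied
before quality filtering; the per-patient frame budget is sampled evenly
from the frames the phase windows allow. Quality gates are operational
stand-ins for qualitative exclusions — variance of the Laplacian of
luminance ≥ 1e-5 (focus), mean luminance in [0.15, 0.95], vessel fraction
≥ 2 % — with defaults chosen on the simulator and exposed in
configuration. Crops are uniform over the frame interior (3 per frame by
default; the per-frame crop count is a free parameter). Rotation
augmentation uses a 45° delta giving 8 poses: quarter turns are exact
array rotations (no resampling), oblique angles are resampled (bilinear
image, nearest-neighbor labels) and center-cropped to the largest
inscribed square so no out-of-field corners are fabricated; the resize to
512×512 happens afterward in `resize_pair`, which returns
already-conforming labels bit-exactly. Splits are random at the patient
level with at least one patient per side; a single-patient cohort is an
error because strict patient-level validation is then impossible. All
randomness flows from one seeded generator recorded in the run config, so
a build is byte-reproducible from its `run_config.json` alone.

## Evaluation metrics

All metrics derive from exact pixel confusion counts. Per-class IoU is
`tp/(tp+fp+fn)` (foreground) and `tn/(tn+fp+fn)` (background); a class
with an empty union scores 1 so all-background frames are not penalized
(a convention; the alternative of skipping such classes changes nothing
in the shipped tests). Mean IoU averages the two classes. Pixel accuracy
is `(tp+tn)/total`. The default pooling accumulates one confusion matrix
over all pixels, which is what reproduces published whole-validation-set
tables; per-image averaging is available and weights every image equally.
The mean Dice is computed as `2J/(1+J)` of the mean IoU — this exact
Jaccard–Dice relation, not the average of per-class Dice scores,
reproduces every published mean-Dice/mean-IoU pair to ≤ 1e-4; the
per-class average remains available behind a flag. One documented
inconsistency: the published pooled pixel accuracies (0.746, 0.763) do not
equal tp+tn of the confusion rows they accompany (0.875, 0.861); the
package implements the standard `(tp+tn)/total` and does not attempt to
reconcile the printed values.

## Problem sizes

The test suite and the acceptance script exercise the pipeline on
192×256-pixel, 60-frame recordings with 2 arteries and 1 vein, three
patients per cohort — scaled-down stand-ins whose properties
(determinism, recovery accuracy, purity, fidelity) are
resolution-independent. The HD geometry test renders a single
full-resolution 1920×1080 pair with a short frame budget to verify native
stream shapes.

## Known limitations

- The registrar's coarse grid covers ±12° rotation and ±10 % scale;
  misalignments beyond that need wider (slower) search options.
- Offset estimation requires a visible-light trace of the dye bolus; on
  recordings where the injection leaves no visible signature the
  configured offset path must be used.
- Phase detection assumes one injection per recording; repeated
  injections would need explicit windows.
- The planar registration model is only as good as the patch is small;
  whole-frame registration of a stereo pair will leave residuals.
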