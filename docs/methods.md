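# Methods

## Problem and scope

`ergopose` assesses the sitting posture of a person facing a webcam, given only
the 2D skeleton a pose estimator extracts per frame: 18 named keypoints (the 17
COCO body landmarks plus a neck point) in pixel coordinates, origin top-left,
x rightward, y downward. Pose estimation itself is out of scope: the package
starts at the keypoint stream (a documented JSON-Lines / CSV schema acts as the
adapter contract for any upstream estimator) and ends at per-frame ergonomic
zone classifications, session alerts and evaluation reports.

## Postural parameters

Four parameters are measurable from a single frontal view, each the
orientation of a two-keypoint segment against an image axis:

| parameter | segment | reference axis | range (deg) |
|---|---|---|---|
| shoulder alignment | left_shoulder → right_shoulder | horizontal | [0, 90] |
| neck lateral bend | neck → nose | vertical | [0, 90] |
| right arm abduction | right_shoulder → right_elbow | vertical-down | [0, 180] |
| left arm abduction | left_shoulder → left_elbow | vertical-down | [0, 180] |

With dx = x₂ − x₁ and dy = y₂ − y₁, the deviation from horizontal is
|atan2(dy, dx)| and from vertical is |atan2(dx, dy)|, in degrees, folded into
the parameter's range (θ > 90 maps to 180 − θ for the two symmetric
parameters). atan2 is implemented as the explicit piecewise function of
arctan with its six sign branches; the orientation of a zero-length segment is
undefined and raises, while a segment with an absent endpoint yields an
*invalid* measurement that propagates through classification rather than an
error.

Choices worth noting:

- **Reference axes.** Shoulder alignment is deviation of the inter-shoulder
  line from image-horizontal; neck bend is deviation of neck→nose from
  image-vertical; arm abduction is deviation of shoulder→elbow from
  vertical-down. These make 0° correspond to level shoulders, an upright head
  and hanging arms — the healthiest band of each zone table row.
- **Folding.** Because |atan2| with a 90° fold is symmetric about both axis
  directions, a single vertical reference serves both the neck (conceptually
  measured from vertical-up) and the arms (vertical-down, unfolded to 180° so
  that a raised arm past horizontal stays distinguishable).
- **Anatomical sides** are as labelled by the upstream estimator; handling
  mirror-image cameras is the adapter's responsibility.
- **Confidence values** are carried but not thresholded by default; a
  `min_confidence` gate (default 0, i.e. off) can mark low-confidence
  keypoints absent.
- The neck→nose proxy conflates lateral bend with in-plane head rotation; a
  frontal 2D view cannot separate them, and no attempt is made to.

## Zone classification

Each parameter angle maps to one of four ergonomic range-of-motion zones,
0 (healthiest) to 3 (most strain). The zone table stores three inclusive upper
bounds (u0, u1, u2) per row; nine standard rows ship as defaults:

| row | u0 | u1 | u2 |
|---|---|---|---|
| back lateral bend | 5 | 10 | 20 |
| back flexion | 10 | 25 | 45 |
| back extension | 5 | 10 | 20 |
| shoulder alignment | 5 | 10 | 20 |
| arms adduction | 5 | 12 | 24 |
| arms abduction | 13 | 34 | 67 |
| neck lateral bend | 5 | 12 | 24 |
| neck flexion | 9 | 22 | 45 |
| neck extension | 6 | 15 | 30 |

Only four rows are reachable from a frontal camera; the others are exposed for
angles supplied by other instruments, and every row is overridable from a
key-value (YAML) file. Both arm parameters intentionally use the arms
*abduction* row: the measured movement — upper arm away from the body midline —
is abduction.

For real-valued angles the bands are left-open/right-closed on the stored
bounds: zone 0 = [0, u0], zone 1 = (u0, u1], zone 2 = (u1, u2],
zone 3 = (u2, ∞). This is gap-free, reproduces every printed integer band, and
puts the single safe→dangerous switch exactly at u1. The convention is
isolated in `classify_angle`; no other code reasons about boundaries.

Zones 0–1 collapse to **safe**, 2–3 to **dangerous**. A *critical error* is a
dangerous truth predicted safe — the direction that would leave a harmful
posture uncorrected; the opposite direction is a nuisance, not a hazard.

## Alerts and session reports

The per-frame classification is deliberately memoryless; all temporal policy
lives in one place with three time constants (defaults chosen so single-frame
estimator glitches can never alert):

- `window` (2 s): trailing majority vote over each parameter's zone series;
  ties break to the higher (worse) zone; invalid frames do not vote, and a
  window with no valid frame is invalid.
- `dwell` (10 s): the smoothed zone must stay at or above `trigger_zone`
  (default 2) this long before an alert opens; the alert's start is the moment
  the dwell elapses.
- `cooldown` (60 s): a new qualifying episode whose alert would open within
  this long of the previous alert's close extends that alert instead of
  raising a new one, so brief recoveries do not double-count an exposure.

Each frame covers the interval up to the next frame (the last frame covers one
nominal frame period), so per-parameter time-in-zone sums exactly to the valid
observed time. Alert messages come from a static per-parameter table.

## Evaluation

Ground truth and predictions are zone labels per parameter per frame.
Reported per parameter:

- the 4×4 confusion matrix (rows = truth, columns = prediction; frames with an
  invalid prediction are excluded and counted separately);
- overall accuracy = trace/total (the headline number) and per-class
  one-vs-rest accuracies A_c = (TP_c + TN_c)/TOTAL — both are emitted because
  a single per-parameter "accuracy" is ambiguous between them;
- the 2-class (safe/dangerous) re-scoring, which merges within-class
  confusions onto the diagonal and therefore can never lower accuracy;
- the critical-error count.

The re-sampling evaluation draws `n_subsets` (default 15) random subsets of
`fraction` (default 50%) of the frames **without replacement** — repeated
half-subsampling, which is what "each subset takes 50% of the samples"
describes; classic with-replacement bootstrap is available behind a flag.
Each subset is scored independently and each accuracy column is summarised by
MIN, MAX, MEAN, population STD (n in the denominator; with rounded inputs
neither std convention is distinguishable anyway, and a constant column is
forced to exactly 0), and Improve = 100·(mean₂ − mean₄)/mean₄. Frames are the
sampling unit. No cross-parameter correction is applied.

## Synthetic data generator

Real seated-worker recordings are rarely shareable, so the generator produces
labelled streams from a canonical neutral upper-body template in a 640×480
frame (neck at (320, 205), 55 px neck, 70 px shoulder half-width, 80 px upper
arm). Articulation is the exact inverse of the measurement geometry — the
shoulder line rotates about the neck, elbows rotate about their shoulders from
vertical-down, the nose swings about the neck carrying the face points — so a
noise-free generated frame measures back the requested angles to
floating-point precision, which pins the whole pipeline down: noise-free zone
accuracy is exactly 100%.

Corruption emulates a 2D pose estimator: isotropic Gaussian jitter per
keypoint coordinate (σ, default 3 px — a few pixels is typical localisation
error at VGA resolution) and independent keypoint dropout (p, default 0.02).
Per-frame target zones cycle through 0–3 with a per-parameter phase shift
(balanced classes; the angle within a zone is drawn uniformly over its band,
zone 3 capped at u2 + 30° to stay inside each parameter's fold range), unless
the caller fixes zones or exact angles. The default scale is 12 subjects × 13
frames = 156 frames, the size of a small lab study.

What the generator does *not* model — and hence what passing tests do not
show about real data: pose-estimator bias (its noise is zero-mean and
isotropic, real estimators fail anisotropically and systematically near
occlusions), body-shape variation, annotator disagreement in manual zone
labels, camera distortion, and any correlation of errors across frames or
keypoints. Synthetic accuracies characterise the classification geometry
under controlled noise, not field performance.

Useful derived expectation: a segment of length L px under per-endpoint jitter
σ has angular noise ≈ √2·σ/L radians, so at σ = 3 and L = 80 the arm angles
see ~3° of noise — comparable to the narrower zone bands, which is why the
default conditions misclassify a realistic minority of boundary frames, and
why in the small-σ limit confusions occur only between adjacent zones.

## Numerical and degenerate-input choices

- Constant accuracy lists report STD exactly 0 (guards one-ulp mean residue).
- Subset size is round(fraction·n); an empty subset is an error, not a skip.
- All randomness flows through a single `numpy` generator per operation,
  seeded explicitly; identical seeds give byte-identical outputs.
- Streams keep absent keypoints as explicit slots; both file formats
  round-trip coordinates at full precision (JSON shortest-repr floats; CSV
  read back with round-trip float parsing).
- CLI exit codes: 0 success, 1 usage error, 2 data error.

## Known limitations

- Back flexion/extension and neck flexion/extension need a side view or depth
  and are not measurable here, although their zone rows ship for completeness.
- No per-subject calibration of zone thresholds and no hysteresis at zone
  boundaries; a borderline posture can flicker between zones (the smoothing
  window, not the classifier, absorbs this).
- The alert policy's timing semantics are design choices, not established
  ergonomics practice; the defaults are deliberately conservative.
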