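# Methods

## Pipeline model and assumptions

`leafcal` operates strictly downstream of instance segmentation: its input
is, per frame, a set of binary leaf masks (or normalized polygons that it
rasterizes), and its contract is that every phenotypic quantity it reports
is a deterministic function of those masks and the timestamps in the frame
filenames. Three assumptions are load-bearing:

- **Fixed camera, fixed tray.** The planted grid does not move between
  frames, so identity can be carried by mask overlap alone; there is no
  motion model. Leaves grow roughly concentrically, which keeps the
  frame-to-frame IoU of a leaf with itself high (for a concentric shape
  that grows by a factor g in area, self-IoU ≈ 1/g).
- **Square pixels.** The width calibration (image width in pixels versus
  250 mm of physical bench) applies to both axes, so one scalar PixelArea
  converts counts to mm². Non-square pixels would need a second scale.
- **Projected area.** Reported leaf area is the 2-D projection seen by the
  camera. Curled or inclined leaves are under-measured; no 3-D correction
  is attempted.

## Coordinate and rasterization conventions

Pixels are 0-based, origin top-left, x rightward, y downward. Pixel (x, y)
covers the half-open unit square [x, x+1) × [y, y+1); a polygon claims a
pixel when the pixel's center (x+0.5, y+0.5) lies strictly inside it. This
center-inclusion rule makes axis-aligned integer rectangles rasterize to
exactly width×height pixels and makes the TXT round trip (normalize →
write → parse → rasterize) pixel-exact for such rectangles. Out-of-bounds
polygon vertices are clipped to the image rectangle with a warning rather
than rejected, because rotation augmentation legitimately pushes vertices
out. Instance centroids are the unweighted mean of foreground pixel *index*
coordinates (first image moments), so a 2×2 block with corner (10, 20) has
centroid (10.5, 20.5).

## Mask refinement

Refinement is per-instance and runs before merging and statistics, because
tracking consumes per-instance masks; the merged raster is an export
product. The sequence is: Canny edge extraction (defaults low=50, high=150
on the 0–255 mask intensity scale) gates the step and locates boundaries;
each closed contour is subsampled to ≤200 points and smoothed with a
periodic cubic spline whose smoothing factor is proportional to contour
length (`spline_smoothing`, default 1.0, dimensionless; 0 interpolates);
the smoothed curves are refilled; finally one morphological closing
(dilation then erosion, 3×3 element) removes pinholes. All of these are
parameters of `RefineParams` because no single setting suits every mask
source. On convex fixtures the pipeline is area-preserving to well under
2% and near-idempotent (a second pass changes area by less than the
single-pass tolerance); empty masks pass through unchanged.

## Tracking

First-frame IDs come from the grid: instances sorted by centroid Cy,
chunked into `rows` groups of `cols`, each group sorted by Cx, IDs assigned
row-major 0..rows·cols−1. Chunked sorting was chosen over fixed horizontal
bands because it tolerates vertical drift of whole rows. A first frame with
the wrong instance count raises immediately — a bad anchor frame would
poison every later assignment, so it must be reviewed manually.

Later frames match greedily: all (instance, track) pairs with IoU strictly
above the threshold (default 0.5, "exceeds") are claimed in descending IoU,
one instance per track per frame; the comparison target is the track's most
recent mask, not its first, because growth makes early masks stale.
Unmatched instances open new IDs beyond the grid range. Lost tracks stay
live indefinitely: a leaf the detector misses for a few frames resumes its
identity on reappearance, and the growth rate across the gap uses the true
elapsed hours. Box-level aggregation averages only IDs 0–15 (the planted
grid), so late spurious tracks cannot contaminate per-box means. IoU calls
are short-circuited through bounding boxes and evaluated on the union box,
which keeps a 16-track frame comparison cheap without changing the result.

## Phenotype quantities

PixelArea = (physical_width_mm / img_width_px)²; LeafArea = PixelArea ×
SumPixel; GrowthRate is the forward difference of LeafArea over elapsed
hours, with the window selectable in frames (default 1 = consecutive).
Because consecutive rates telescope, summing rate×Δt over a series
reconstructs the net area change exactly — this identity is asserted in the
tests and the acceptance run to machine precision. Negative rates are kept
by default: they are a genuine signature of segmentation jitter, and
silently clamping them (available via a flag) would bias mean rates upward.

## Evaluation metrics

Matching is confidence-ordered and greedy: each prediction claims its
highest-IoU unmatched ground truth if that IoU meets the threshold; IoU is
computed on mask pixel sets, not boxes. AP uses all-point interpolation
(the monotone non-increasing precision envelope integrated over recall from
0), the convention of modern detection toolkits; the test suite checks it
exhaustively against brute-force rectangle integration for every TP/FP
sequence of ≤6 predictions. For a single class, mAP50 is identically the
AP at threshold 0.50. The FLOPs formula keeps the bias term (+1) while the
parameter count omits bias — the formulas are implemented exactly as
conventionally printed, and the asymmetry is deliberate.

## Validation statistics

The manual-vs-algorithm regression is computed from the textbook moment
sums (a = S_xy/S_xx, b = ȳ − a·x̄, r = S_xy/√(S_xx·S_yy), R² = 1 −
SS_res/SS_tot, adjusted R² with the (n−1)/(n−k−1) correction, k = 1);
`scipy.stats.linregress` serves as an independent cross-check in the tests,
never as the implementation. Residual normality uses D'Agostino–Pearson's
K² omnibus statistic — a standard choice where only "residuals look
normal" is claimed; it needs n ≥ 8 and degenerates on exact fits, both of
which are guarded. Undefined precision/recall denominators are reported as
undefined (None), never coerced to zero.

## Dataset construction

The retention filter removes a leading window (default 24 h — leaves not
yet emerged), a trailing window (default 48 h — heavy overlap) and a
flagged quality set, with set-union semantics so multiply-excluded frames
count once. Splitting shuffles with a seed, rounds train and validation
sizes to the nearest integer and gives the remainder to test: this is the
only rounding convention under which 2,707 items at 70:20:10 yield
1,895/541/271 (floor would give 1,894). Augmentation draws all parameters
uniformly from one seeded generator per copy: rotation (±45°) applied
identically to image and polygons via the same affine map; hue (±180°),
brightness (±90%), Gaussian blur (radius ≤ 5.7 px, sigma = radius/2) and
salt-and-pepper noise (≤ 8.26% of pixels) applied to the image only. The
noise bound names a pixel fraction, not a distribution, so salt-and-pepper
was chosen as the simplest model touching exactly that fraction.
Augmentation multiplicity is a user parameter, and the default order is
split-then-augment to keep augmented siblings inside one subset.

## Synthetic scene generator

The generator emulates the incubator experiment the pipeline is built for:
a 4×4 grid of leaves in an 1800×1850 px frame calibrated at 250 mm,
photographed every 15 minutes over a half-open 36–192 h window (156 h, 624
frames), under seven NaCl levels (0 = CK control, 10–60 mmol/L).

Growth is logistic. Per leaf, area(t) = f·A_max / (1 + exp(−rate·(f·t −
midpoint))), with defaults A_max = 1200 mm², rate = 0.04 h⁻¹, midpoint =
120 h chosen so the control reaches ≈1.05×10³ mm² by day 7 — slow early
growth, acceleration mid-experiment, saturation late. The inhibition
multiplier f(c) = exp(−0.008·c) scales the asymptote and the developmental
clock (equivalently: the effective rate is scaled by f and the midpoint
delayed by 1/f), which makes the stressed curve lie strictly below the
control at *every* time; scaling the rate about a fixed midpoint instead
would paradoxically make young stressed leaves larger than control.
Per-leaf parameters get 5% relative jitter so the 16 trajectories are not
identical.

Leaves are drawn as analytic closed curves — ellipses (aspect 0.85) with a
sum of zero-mean harmonics (orders 3–6, amplitude ≤2%) perturbing the
radius — so ground-truth area is exact by construction: the polygon's
shoelace area is renormalized to the target exactly, leaving pixel
discretization as the only error source (<3% mean absolute relative error
for leaves ≥100 px, asserted). The boundary jitter gives the refinement
stage realistic ragged contours without invalidating the area oracle.
Masks within a frame are emitted in seeded random order, because real
detectors do not sort their output; the ground truth records each mask's
true identity. Non-occlusion mode checks that the largest asymptotic leaf
fits the grid pitch and raises otherwise; occlusion mode disables the
check. Rendered RGB frames use a soil-toned noisy background with a wide
color margin to the green leaves, so a classical threshold segmenter can
recover masks for detector-free end-to-end tests.

What the generator does *not* emulate: botanical leaf shape (lobing,
petioles), stems, germination, occlusion by non-leaf structures, lighting
drift, camera noise correlated across frames, and real biological
variance between replicates. Passing tests therefore demonstrate that the
*post-detection computation* is correct, not that any particular detector
is accurate on real okra imagery.

## Problem sizes

Tests and the acceptance script run the generator at 360×370 px (same
physical calibration, so mm² quantities are unchanged) with 30–100 frames,
and the concentration sweep at an 8 h cadence over the full 156 h window —
sizes chosen so the whole suite completes in well under a minute while
every quantity of interest (tracking consistency, area recovery, rate
conservation, dose ordering) is still exercised end to end. The generator
defaults themselves remain at full experimental scale.

## Known limitations

- Tracking has no recovery rule for a leaf splitting into two masks
  (under-segmentation): both fragments compete under the greedy rule and
  the loser opens a new ID. Intent is not guessed.
- Only polygon annotations are supported for ISAT-style documents; RLE
  masks are not.
- The CLI's `eval-seg` assumes one prediction TXT per ground-truth frame
  with optional trailing confidences; COCO JSON is out of scope.
- Areas are projected 2-D areas; growth rates inherit that bias.
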