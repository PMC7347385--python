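# Methods

## Data model and conventions

All analysis operates on a `FrameStack`: frames of one epoch held as floats
in [0, 1] (8-bit inputs divided by 255), with the acquisition rate (fps)
and spatial calibration (px/mm) attached. Grayscale conversion uses BT.601
luma weights (0.299, 0.587, 0.114); dark-fur animals are photometrically
complemented (v → 1 − v) so the body is bright against the background.
Downsampling is area-averaging (exact block means for integer factors,
anti-aliased resampling otherwise) and rescales the calibration so physical
units are preserved. Frames are 0-based internally; the CLI prints 1-based
frame numbers to match on-video counters.

Image coordinates are (x = column, y = row, origin top-left); orientations
are reported in degrees from horizontal with y pointing *up*, in (−90, 90].
Kinematic hand positions flip to a lower-left origin,
`y_mm = (H − 1 − row) / px_per_mm`, so "up" is positive in plots.

## Optical flow (CLG)

The combined local-global energy couples a Lucas–Kanade local data term
(structure tensor of the spatiotemporal gradient, Gaussian-smoothed with
σ = 1 px) with a Horn–Schunck quadratic smoothness term weighted by
`alpha`. Defaults: `alpha = 0.01`, pyramid ratio 0.5 down to a 20 px
minimum width, 7 outer (warping) fixed-point iterations, 1 inner iteration,
30 SOR sweeps. Choices the energy formulation leaves open: red-black
successive over-relaxation with ω = 1.8 (a standard value for this solver
class; convergence, not the fixed point, depends on it), bilinear warping,
and reflecting (Neumann) boundary conditions. A stack of N frames yields
N − 1 velocity fields; speeds are `|(u, v)| · fps / (px_per_mm · 10)` cm/s.
An iterative-Lucas–Kanade backend (scikit-image) can be substituted for
exploratory runs; the CLG solver is the reference implementation and the
one the tests pin down (zero flow on constant stacks; median recovered
displacement within ±0.25 px on a +2 px translating square; mean endpoint
error ≤ 0.5 px for sub-pixel global shifts up to 3 px).

## Per-pixel temporal statistics

Fixed conventions, chosen so tests are exact: sample (N−1) variance
wherever σ appears; skewness and kurtosis as biased population moment
ratios with kurtosis non-excess (normal → 3; both defined as 0 for a
constant series); mode on values quantized to 256 levels with ties broken
toward the smallest level (8-bit video semantics). Temporal entropy
min-max rescales each series to [0, 1] (a constant series maps to all
zeros, avoiding 0/0), histograms into 256 equal bins and applies
−Σ p log₂ p with 0·log 0 = 0 — hence it is invariant to affine rescaling
of a pixel's series. The Fano factor is sample variance over mean;
zero-mean pixels have no defined value and are set to NaN and counted on
the result rather than silently dropped. The Higuchi fractal dimension
uses normalized curve lengths L(k) averaged over k offsets for k = 1..10
(kmax = 10 throughout) and fits the slope over *all* k — no subrange
selection. The mean-position mask marks pixels strictly above the global
mean of the temporal mean frame; masked values are summarized by a
Gaussian KDE (Scott's-rule bandwidth, 512-point grid spanning the data ±3
bandwidths) whose trapezoid-integrated CDF and arithmetic sample mean are
the per-animal quantities compared across groups.

## Spatial measures

Spatial entropy applies the same 256-bin entropy to a whole frame.
Sharpness is the mean gradient magnitude with central differences
(one-sided at borders). The box-counting fractal dimension binarizes a
frame at its mean (strictly greater, matching the position-mask rule; a
constant frame degenerates to "is it above zero"), counts occupied boxes
for dyadic sizes ε = 1, 2, 4, … anchored at the top-left corner with
partial edge boxes included, and fits −slope of log N(ε) vs log ε over all
available sizes. Occupied-box counting (rather than per-box pixel sums)
was chosen because it yields the standard value ≈ 1.585 for a Sierpinski
triangle and 2 for a filled frame. A single grid anchor is used; averaging
several anchors would change values by less than the fit tolerance on the
fixtures tested but remains a known sensitivity.

## PCA / ICA

The stack is reshaped to a (H·W) × N matrix — pixels are observations,
frames are variables — and column-centered (per-frame means removed), so
component *scores* are images. PCA reports explained variance in percent
(sums to 100). fastICA uses the cubic nonlinearity with deflation on
PCA-whitened data, tolerance 5e-5, at most 1000 iterations, and K defaults
to half the number of frames, capped at the matrix rank; the seed is an
explicit argument and fixed seeds give bitwise-identical components.
Component permutation and sign are not meaningful and are never asserted —
sources are matched by absolute spatial correlation. Pixelwise max/min
projections across ICs localize transient objects; on a synthetic video in
which only the hands move, ≥ 80 % of the top-1 % pixels of the |max|
projection fall inside the ground-truth hand territory.

## Color segmentation

Object colors live in `ColorModel`s accumulated over a handful of frames
(k-means proposes clusters inside a window — defaults k = 3 for
body/ears/hands, k = 7 for nose/string — and accepted clusters are unioned,
deduplicated on the 8-bit grid). Distances are computed on the 0–255 scale
so the default range-search radius 1.5 keeps its conventional meaning.
The three mask generators (range, nearest-neighbor vs background with ties
to background, and per-grid-cell range search with a minimum match count)
agree exactly whenever pixels are either exact model colors or farther than
the radius from them. The optional MSER-style hand detector is a
threshold-sweep stability detector written for this package: components
whose area is stable across neighboring threshold levels (both polarities)
and that contain model-colored pixels form the mask.

Connected components are 8-connected. Region properties use the
equal-second-moments ellipse with the 1/12 pixel-extent correction (a
single pixel has major axis ≈ 1.15 px), so axis lengths and orientations
match the established regionprops convention. Close regions are merged by
single linkage on minimum pixel-to-pixel distance (default 10 px,
configurable — no canonical value exists). Up to eight masks per frame are
bit-packed into one byte plane (fur = bit 0 … string = bit 4, bits 5–7
zero) and archived zlib-compressed with a JSON header; the roundtrip is
lossless.

## Tracking heuristics

Body: convex hull of the fur mask (rejoining a body split by the string),
largest component, moment ellipse; length = major axis, tilt =
orientation. Ears: ear-colored regions outside the filled body ellipse;
with two candidates the image-left one is the animal's *right* ear (the
animal faces the camera); with more, the two closest to the previous ears
win; with one, the nearer previous ear claims it and the other is invalid
until re-initialized. Nose: merged candidate nearest the top vertex of the
body ellipse; the reported point is the topmost point of the candidate's
moment ellipse. Hands: initialized by the user in the first frame, then
per frame regions below 20 mm² are dropped and close regions merged; one
surviving region is treated as touching hands and split into two
equal-area halves across its major axis; two regions are assigned by the
pairing minimizing total distance to the previous hands; more than two are
shortlisted by `distance − λ·overlap` (λ = 1 px per overlap pixel,
configurable) and fed back recursively. When split halves tie, the
previous left/right ordering is preserved. Manual corrections enter as an
override table applied *during* tracking, so a corrected frame seeds the
context of all subsequent frames.

Accuracy against ground truth counts a part correct when its detected
point lies inside the true region (nose: region dilated by 2 px; ears and
hands additionally require correct side/label), with frames lacking the
part in truth excluded from that part's denominator.

## Synthetic data

The modeled mouse renders flat-colored ellipses on a uniform mid-gray
background: dark fur body (semi-axes 70 × 40 px at 480 × 480), green ears
at the top of the body, pink nose above them, blue hands — mirroring a
painted-parts protocol, with all part colors separated by far more than
twice the segmentation radius. Hands follow sinusoidal x/y oscillators
sampled at 360°/12 per frame (one reach cycle per 12 frames at 60 fps),
180° out of phase between hands, with vertical amplitude 60 px ≫
horizontal 15 px; body tilt (±3°) oscillates in phase with the reaching
hand. The default calibration is 2 px/mm, making the 140 px body a 70 mm
mouse and the ~311 px² hands ≈ 78 mm², comfortably above the 20 mm² region
filter. Geometry is chosen so parts never occlude one another: rendered
pixels of each part equal its ground-truth mask exactly, and the truth
table carries exact centroids, axes and orientations. The empirical
variant renders the same parts at per-frame geometry supplied in a table
(e.g. measured from real recordings), enabling render → track → compare
roundtrips (hand centroid RMS error ≤ 1 px).

What the generator does **not** emulate: fur texture, lighting variation,
motion blur, occlusion by the string or by other parts, color bleed, and
camera noise. Perfect benchmark scores on this input therefore validate
the *rules* (segmentation arithmetic, region selection, label assignment,
calibration bookkeeping) — not robustness to real-video degradations,
where the mask methods' relative merits and the manual-override path
matter.

## Kinematics

Reach cycles are segmented from a hand's vertical trajectory after a
3-frame moving average: troughs (releases) and peaks (grasps) are local
extrema with prominence ≥ 10 % of the series range — both values are
configuration, as no canonical extraction rule exists. Cycles partition
the detected extrema span exhaustively (Σ rise + fall = span). Dominant
frequency is the largest non-DC rFFT bin of the mean-removed series. Head
yaw uses the natural log of the nose-ear distance ratio (the log base only
scales the series; the zero crossing is invariant). Pitch is reported in
mm, signed positive when the nose is above the ear line; with a single
valid ear it degrades to the vertical nose-ear distance. "Time warping"
of cycles is linear time-normalization to a fixed number of points
followed by pointwise means, applied twice for group averages
(per-animal, then across animals); a dynamic-time-warping barycenter was
deliberately not made the default. Group comparisons use the
equal-variance two-sample t-test (Welch available by flag) and Cohen's d
as the absolute pooled-SD standardized mean difference. Isolated tracking
gaps up to 3 frames are linearly interpolated before differentiating;
longer gaps stay missing.

## Problem sizes used in the tests

The full-scale benchmark (300 frames, 480 × 480) runs once in the
acceptance suite and in `scripts/acceptance.py`; unit and property tests
use half-scale (240 × 240) and quarter-scale (120 × 120) specs with
geometry scaled proportionally, which exercise identical code paths at a
fraction of the cost. Flow oracles use 64 × 64 fixtures, where the
pyramid still has three levels.

## Known limitations

* Heuristic tracking assumes the animal faces the camera and both hands
  stay visible; sideways postures (one visible ear) require manual
  re-initialization, as in the original protocol.
* No grasp/release string-contact event detection; string masks are
  produced but phase classification is out of scope.
* Video-file input requires an ffmpeg-backed imageio plugin; directories
  of PNG/TIFF frames are the first-class input.
* The CLG solver is a dense variational method in pure numpy; it is meant
  for epoch-scale analysis, not real-time use.
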