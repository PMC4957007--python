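# Methods

This note documents the models, parameter choices and numerical conventions
behind `acqua`, and what the synthetic benchmark does and does not show.

## Preprocessing

The edge-energy image is the Euclidean recombination of two Sobel passes,
`H = √(h_v² + h_h²)`. Implementation notes:

* **True convolution** (kernel index-reversed relative to correlation) with
  **zero padding** and same-size output. `H` is identical under correlation —
  flipping either Sobel kernel only flips the sign of its response — so the
  choice matters only for the signed responses `h_v`, `h_h`; this is tested.
* Zero padding makes the frame border fire (background against the implicit
  zero exterior), so the pipeline zeroes a `border_trim_px = 3` margin of `H`
  before thresholding.
* RGB inputs collapse to gray with fixed BT.601 luminance weights
  (0.299, 0.587, 0.114); integer images are rescaled by their dtype range so
  all thresholds operate on `[0, 1]` floats.

## Segmentation

`H` marks filament *borders*, not bodies: a filament appears as a closed
double-edge ring. Thresholding (Otsu by default; a fixed threshold is
available), closing with a disk of radius 2 and hole filling turn rings into
solid objects. The closing radius sits above the 1-px minimum because the
edge ridge of a diagonal filament can carry 2-px gaps; radius 2 closes those
reliably while leaving the ≥ 6 px clearance between distinct structures
untouched.

Otsu normalizes per image, so an image with *no* real edges would promote
sensor noise to foreground. An absolute gradient floor
(`min_gradient = 0.15` intensity units across the Sobel support, about 4%
contrast — an order of magnitude above the noise response, an order below a
real filament edge) vetoes that; blank-scene behavior is tested.

Object classification is two-tier:

* *filamentous*: elongation (skeleton length / mean width) ≥ 5;
* *of interest*: filamentous, length ≥ 50 μm, mean width in [2, 12] μm.

These gates are stand-ins for a genus-aware classifier (out of scope here)
and are fully configurable. Width is measured as `2·EDT − 1` on the skeleton:
the Euclidean distance transform on the medial axis reads half-width plus
half a pixel (a 1-px line has EDT 1.0 and true width 1). `min_object_area`
defaults to 30 px (< 10 μm² at 0.32 μm/px, far below any filament of
interest). Objects touching the image border are kept but flagged.

## Tracing

Thinning uses the Lee variant of topology-preserving skeletonization: on
oblique constant-width ribbons it retracts at most about half the ribbon
width at the ends, where Zhang–Suen can retract by several widths — measured
directly in the test suite, skeleton endpoints land within 3 px of true
filament ends.

The skeleton is read as a graph: 8-neighbor count 1 → endpoint, ≥ 3 →
junction material. Adjacent junction pixels (thinning leaves 2–3 px blobs,
and shallow crossings split into two nearby 3-way junctions) merge into one
node positioned at the member pixel nearest the cluster centroid. Spur edges
shorter than `prune_px = 8` (≈ 2.5 μm of thinning whisker) are removed;
junction nodes left with exactly two through edges by the pruning are
dissolved into interior path points. Paths are reported ordered from node to
node, with junction-terminated paths snapped to the junction position so
branches share the crossing point.

## Spline parameterization

Cubic least-squares splines (`scipy` smoothing splines), parameterized by
cumulative chord length, fit each path's row and column coordinates. The
default smoothing budget `s = n · (0.5 px)²` absorbs pixel-quantization noise
without straightening real curvature; `s = 0` interpolates; paths with fewer
than four distinct points fall back to a flagged degree-1 polyline.

Arc length integrates the spline speed with 10-point Gauss–Legendre
quadrature per knot span — exact to machine precision on polynomial spans and
well below 1e-4 relative error on smooth curves (semicircle within 0.5% of
πr in the tests). Endpoint tangents come from the analytic first derivative,
oriented outward; a zero-derivative end falls back to a one-sided finite
difference. Curvature is `|x′y″ − y′x″| / ‖d‖³`.

## Reconnection

Candidate joins are endpoint pairs passing three gates, with defaults
`max_gap_um = 15`, `max_angle_deg = 30`, `width_ratio_max = 1.8`: occlusion
gaps are short relative to filament length, bends beyond 30° indicate
distinct filaments, and trichome width is conserved along one filament.
Cost = `gap/max_gap + (angle_a + angle_b)/(2·max_angle) + |log width ratio|`;
acceptance is greedy in cost order with a total deterministic tie-break, each
endpoint used at most once, and merged curves (spline refit over the union of
points) re-entering the pool. Greedy matching is near-optimal for the sparse
candidate sets these scenes produce and is documented as replaceable by
global assignment.

Angles are normally measured between each end's outward tangent and the
direction toward the partner end. Two exceptions use tangent-vs-tangent
alignment instead: coincident endpoints, and pairs of *junction-born* ends —
inside a junction zone the skeleton geometry is distorted and the short
baseline between ends points nowhere meaningful. This is what routes
straight-through pairings across crossings (a right-angle branch pair scores
90° and fails the gate; the collinear pair scores ≈ 0°).

**Event bookkeeping.** The reconstruction rate needs a denominator: how many
break/cross events were eligible. An event is one pair in a greedy matching
of endpoints gated by distance alone — angle and width gates are what can
make a join *fail*, not what makes the event exist. Junction branch ends lie
within the distance gate of each other, so a 4-branch crossing contributes
two events automatically. Interior junction-to-junction segments (the short
middle edge of a shallow crossing) are decomposition artifacts, not break
ends, and are excluded from event counting. In contrived geometries the
full-gate greedy can exceed this matching; the denominator is clamped so
`joined ≤ events` always holds.

## Measurement and calibration

Defaults follow the imaging setup being emulated: 0.32 μm/px at 10×, full
frames of 5184 × 3456 px. Note 5184 · 3456 · 0.32² = 1.8345 mm², while the
conventional figure quoted for this setup is 1.82 mm²; one of the printed
inputs is evidently rounded. The implementation always computes area from the
calibration. CSV reports round lengths to integer μm (matching validation-
table style); JSON keeps full precision. Each JSON report embeds the config
hash and package version.

## Major Axis regression

With both manual and automated counts subject to error, ordinary least
squares would bias the slope toward zero; the model II Major Axis line —
the first principal axis of the 2×2 covariance — treats the axes
symmetrically. Closed form via centered sums of squares/cross-products;
degenerate inputs (n < 3, zero variance, zero covariance) are rejected.
Automated estimates sit on the y-axis, manual means on x. Reported statistics
round to 2 decimals (slope, r²) and 1 decimal (percentages). Significance
uses a seeded permutation test of the Pearson correlation (the underlying
parametric test for model II fits is not uniquely defined); it is reported,
not gated on. The tested invariants: axis-swap reciprocity
(`slope_xy · slope_yx = 1`), scale equivariance, agreement with an explicit
eigen-decomposition oracle, and `r² ∈ [0, 1]`.

The packaged 40-FOV validation table drives the pooled summaries:
reconstruction rate 100·Σjoined/Σevents over all rows, per-station mean area
fraction, and pooled interest fraction 100·Σcount/Σobjects per station. Total
length fits use the per-FOV sums of that table (per-filament pairings are not
available in it).

## Synthetic scenes

The generator emulates settled-sample bright-field FOVs at 1/4 linear scale
(1296 × 864 px; full scale is a config change) for test-time speed. What it
reproduces: dark filaments of log-normal length (median 130 μm, clipped to
[70, 300]) and uniform width 3–6 μm on a bright background with a planar
intensity gradient (amplitude 0.15 on a 0.85 base, filament contrast 0.30);
smooth bounded curvature via sinusoidally modulated headings; crossings
routed through existing filaments at 55–90°; interruptions with 5–12 μm gaps
(inside the 15 μm join gate); compact blob distractors; Gaussian sensor noise
(sd 0.01). Filaments are placed with clearance — bodies ≥ 6 px apart,
filament *ends* at least 55 px from any other material — so the only join
events in a scene are the constructed gaps and crossings and truth is
unambiguous. All draws come from one seeded generator; scenes are
byte-reproducible.

What it does not reproduce: optics (point-spread function, depth of field),
within-filament intensity texture and cell septa, coiled or colonial
morphotypes, filamentous noise of other algae, debris with filament-like
elongation, and density regimes where filaments bundle. Passing the
end-to-end tests therefore shows the geometry chain is correct and
well-calibrated, not that the default gates separate taxa in real samples.

Benchmark sizes (chosen to exercise the full chain at desk scale): 10 clean
scenes of 8 filaments — counts recovered exactly, median total-length error
≤ 5% (observed ≈ 1%, dominated by end-cap geometry and the Sobel dilation of
the mask) — and 10 scenes of 12 filaments with 6 interruptions each, where
≥ 80% of detected break events are rejoined and final counts match truth in
≥ 90% of scenes. The measured width subtracts `edge_width_correction_px = 2`
(one pixel of Sobel support per side) before reporting; recovered widths sit
within ±0.3 μm of truth across the 3–6 μm range.

## Known limitations

* The filament-of-interest gates are morphological stand-ins; no taxonomic
  inference is attempted.
* Reconnection never spans FOVs and its greedy matcher can, in principle,
  miss a globally better pairing.
* A filament whose interruption gap closes at segmentation (very small gaps)
  is counted as unbroken — correct count, one fewer recorded event.
* Closed-loop (ring-shaped) skeletons are traced but parameterized as open
  curves anchored at an arbitrary pixel; periodic splines are not supported.
* The event-denominator convention above is one defensible reading of
  "reconstructed filaments a/b" bookkeeping; alternatives (e.g. counting
  every near-miss pair) would change reported rates on pathological scenes.
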