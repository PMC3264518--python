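# Methods

`ricescan` re-implements, in pure Python, the image-analysis and
trait-computation core of a high-throughput rice yield-trait inspection
line: two line-scan cameras photograph threshed spikelets moving on a dark
conveyor belt, one camera before and one after a wind separator, so that a
plant yields a *total-spikelet* image series (filled + unfilled spikelets)
and a *filled-spikelet* series (grains only). From those series the pipeline
derives the plant's number of total spikelets (NTS), number of filled
spikelets (NFS), seed setting rate, 1000-grain weight (TGW), and mean grain
length/width (GL/GW). Because the physical facility is not available at desk
scale, a seeded synthetic scene generator supplies images with exact ground
truth, and all accuracy statements below are statements about those
synthetic scenes.

## Counting model

Segmentation is deliberately minimal, matching an on-line system:

1. **Fixed threshold.** A pixel is background iff its 8-bit gray value falls
   below a fixed threshold (default 100). The belt is dark (default gray 20)
   and kernels bright (default 200), so the margin is many noise standard
   deviations wide; no adaptive thresholding is used.
2. **3×3 median filter**, one pass, on the binary mask (zero-padded at the
   image edge). This removes isolated noise pixels; it is applied once, and
   idempotence is not assumed.
3. **8-connected components** become candidate regions. Each region carries
   its area, ordered outer pixel-center boundary, bounding box,
   minimum-area-rotated-rectangle length/width, and frame-border flags.
   8-connectivity is chosen so diagonally abutting kernels form one
   "touching" region rather than two.

Three impurity filters run in flowchart order and only ever remove regions:

1. **Elongation rule** — length-width ratio above `3 ×` the reference
   spikelet ratio (default reference 2.2, so cutoff 6.6) ⇒ branch.
2. **Line rule** — straightness, the fraction of boundary-point variance
   along the principal axis, at or above 0.98 ⇒ thin straight branch. A
   circle scores 0.5; a one-pixel-wide segment scores ≈ 1. This replaces a
   proprietary line-detection operator; its contract is only that razor-thin
   straight objects are removed and elliptical blobs kept.
3. **Half-mean-area rule** — area strictly below `0.5 ×` the mean spikelet
   area ⇒ debris. The reference area is bootstrapped per tile as the median
   area of regions passing the isolated-ellipse test; if no region passes,
   the most recent reference from earlier tiles of the same plant is used,
   then the median of all surviving areas. The earlier-tile fallback matters
   for sparse tiles that contain debris but no kernel: without it the rule
   calibrates itself on the debris it is meant to remove.

Surviving regions are split into *isolated* and *touching*. A region is
isolated iff a direct least-squares ellipse fit to its boundary (a) has an
area ratio `region area / (π a b)` inside [0.85, 1.15], (b) has an RMS
radial residual at most `0.08 ×` the fitted semi-minor axis, and (c) the
region's length-width ratio is below the branch cutoff. The residual bound
carries most of the discriminative weight: on rendered kernels the fill
ratio of a touching pair (≈ 1.09) is indistinguishable from a single kernel
(≈ 1.10), while residuals separate cleanly (singles ≈ 0.03–0.05 × minor,
clusters ≥ 0.22 × minor). The classifier is deliberately strict because the
failure modes are asymmetric: an isolated kernel misread as touching still
counts as `round(A/Ā) = 1`, whereas a touching pair misread as isolated
undercounts and pollutes the mean-area estimate.

Counts follow the area-quotient model: with `Ā` the arithmetic mean area of
the isolated spikelets in the image, each touching region `j` contributes
`N_j = round(A_j / Ā)` (half away from zero by default, configurable to
half-even), clamped to at least 1 — a region that survived the debris filter
represents at least one spikelet. The image count is
`N = N_isolated + Σ N_j`, and the plant count sums all images of a series
(14 total-series and 20 filled-series frames by default). If an image has no
isolated region, `Ā` falls back to the most recent value from earlier tiles
of the plant; with no value anywhere the quotient is undefined and an error
is raised.

**Border merging.** A line-scan camera cuts the belt into frames
mid-object. Before filtering, every region touching the bottom row of frame
*k* is matched against regions touching the top row of frame *k+1* by
overlap of their column intervals on the shared border (the belt moves
strictly along rows, so a cut object keeps its columns). Matched groups are
merged — areas summed, boundaries concatenated, the upper fragment shifted
to negative row coordinates — and the merged object is counted once, in
frame *k+1*; this choice only affects per-frame, never per-plant, totals.
Unmatched border regions stay where they are. A merged single kernel
usually fails the ellipse test (its concatenated boundary contains the two
cut chords) and is counted as a touching region of quotient 1, which leaves
plant totals unchanged.

## Morphometry

GL is the maximum Euclidean distance between two boundary points (the
maximum Feret diameter), computed over convex-hull vertices — provably equal
to the brute-force all-pairs maximum, which the tests assert. Ties are
broken lexicographically. GW is the maximum chord of the *filled region*
perpendicular to the GL line (the literal reading of "length of straight
lines", not the hull projection breadth; the two coincide for convex
kernels): pixel centers are rotated so the GL chord is horizontal and
scanned in columns of `bin_width` (1 px for image data), each candidate
pooling its two neighbouring columns so a tilted chord is not truncated at
a column seam. Both measures are center-to-center distances; sub-pixel
refinement is out of scope, so measured axes sit about one pixel inside the
analytic ellipse axes. Conversion to millimetres uses the camera
calibration, 0.23 mm/px. Only isolated regions of the filled series are
measured, and the plant mean GL/GW averages a seeded random sample of 10
spikelets by default, mirroring how reference measurements are taken by
hand.

## Traits and statistics

`TGW = W_grain × 1000 / NFS` (undefined at NFS = 0), seed setting rate
`NFS / NTS` (the strict NFS ≤ NTS check applies to ground truth only —
measured counts come from two independent camera series and are not
cross-constrained), `MAE = mean |x_a − x_m|`,
`MAPE = mean |x_a − x_m| / x_m` (stored as a fraction, displayed as
percent). The facility's cycle time is `T = T_inspect + T_idle` — valid
because threshing and inspection run in parallel with packing-weighing and
packing (40 s) is faster than inspection (60 s) — giving
`⌊86400 / T⌋ = 1440` plants per continuous 24 h at the designed 60 s with
no idle time. Manual-reference bookkeeping sums per-outlet counts
(impurity, unfilled, filled outlets) into plant totals; the count lost at
the impurity outlet is the threshing error, since those spikelets never
reach a camera.

## Synthetic scenes

The generator renders what the cameras see, not photorealism: filled
ellipses (default full axes 31.9 × 14.4 px = 7.3 × 3.3 mm at 0.23 mm/px,
the long-grain indica scale, with ±5% per-kernel axis jitter and uniform
random orientation) on a belt of gray 20, kernels at gray 200, i.i.d.
Gaussian pixel noise (σ = 8) clipped to [0, 255]. A whole camera series is
rendered on one tall canvas and cut into frames, which is how a line camera
actually produces tiles and makes border-spanning objects natural; with
`border_spanning` off, placement avoids the cut rows, and with it on at
least one kernel is forced to straddle a cut. Touching clusters append
members at 0.92–1.05 of the directional touching distance with at most 5%
pixel overlap and mandatory adjacency, so clusters are connected but
area-additive, the regime the quotient model assumes. Branches are thin
rotated rectangles (default 3 px wide, 40–120 px long); hull fragments are
half-ellipse crescents with areas drawn from (0.20, 0.45) of the mean
kernel area — below the debris cutoff when the reference area is estimated
correctly, which is precisely what makes them a useful stress case.
Placement is rejection sampling against a 2-px dilated occupancy mask
(isolated objects never merge by accident) and raises an error when a scene
is too crowded to place.

What the generator does *not* model — awns, husk texture, specular
highlights, motion blur, brown-rice kernels, overlapping (stacked) grains,
illumination gradients — bounds what the tests can show: passing the
synthetic benchmark demonstrates that the counting logic, filters, merging
and measurement geometry are correct, not that the fixed threshold or the
classifier windows are adequate for real camera imagery.

## Benchmark and problem sizes

The accuracy benchmark simulates 30 plants per run, each with a uniform
500–2500 total spikelets, 20% of kernels in touching clusters of size 2–4,
a filled fraction of 0.8, per-tile impurity defaults (2 branches, 2
fragments), border spanning on, and a true TGW drawn from 22–28 g; grain
weight is derived from the true NFS and TGW, so measured TGW errors mirror
NFS errors. Frames are 1000 × 512 px rather than the full 5000 × 2048 of
the hardware — the composition per unit area, not the frame size, is what
exercises the algorithms — and a full 30-plant run takes a few minutes on
one CPU. MAE/MAPE are reported for NTS, NFS, TGW, GL and GW against
generator truth. Counting errors are dominated by quotient round-offs in
clusters and are typically zero at these settings; GL/GW carry a systematic
≈ 1-px (≈ 3–5%) underestimate from the pixel-center convention and the
median filter's erosion of kernel tips, which is inherent to the measurement
definition rather than a statistical error.

## Numerical choices and edge cases

- Rounding ties in the area quotient go half away from zero by default; the
  tie rule is configurable.
- Minimum-area-rectangle extents are clamped to ≥ 1 px so one-pixel-wide
  lines have a finite ratio; degenerate (collinear) boundaries fall back to
  a principal-axis extent.
- The ellipse fit can fail or degenerate on pathological outlines; such
  regions are classified as touching, which is count-neutral.
- Contours are traced with "high" (8-) connectivity to match component
  labeling; a diagonal one-pixel chain yields a single closed boundary.
- GL on fewer than two points, GW on collinear regions, `Ā` on an empty
  isolated set, TGW at NFS = 0, MAPE with a zero reference, and invalid
  scene parameters all raise `ValueError` rather than returning silent
  defaults; an overcrowded scene raises `SceneOverflowError`.

## Known limitations

- The fixed threshold, gray levels and noise are separability-driven
  defaults; no real pixel-intensity statistics were available to calibrate
  them.
- The line rule only removes very thin straight objects at its default
  (straightness ≥ 0.98); stubby curved branches are instead caught by the
  elongation or debris rules, and a branch mimicking a kernel's footprint
  would be counted.
- Near-collinear touching chains of ≥ 4 kernels can exceed the elongation
  cutoff and be discarded as branches; at random orientations this is rare
  (well under 1% of kernels at benchmark settings).
- Broken hulls at the upper end of their area range sit close to the 0.5·Ā
  debris cutoff; a downward-biased reference area can let them survive, in
  which case each survivor inflates a count by 1.
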