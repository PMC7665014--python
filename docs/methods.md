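# Methods

## The problem

Quantitative microscopy of budding yeast (*Saccharomyces cerevisiae*)
requires segmenting every cell in phase-contrast or bright-field images —
including freshly emerged buds of a few pixels, touching cells in crowded
colonies, filamentous mutants, bright halos and transparent vacuole-like
inclusions — and following each cell through a timelapse.  `yeastseg`
implements the post-processing, tracking, evaluation and shape-analysis
machinery of a CNN-based segmentation workflow, together with a pixel
classifier and a synthetic data generator that provides exact ground truth
for every stage.

## Segmentation pipeline

The pixel classifier emits a per-pixel score in [0, 1]: 1 = cell-like,
0 = border- or background-like.  Instances are produced in four steps:

1. **Threshold** — foreground iff score > 0.5 (strict).  The threshold is
   deliberately the intuitive midpoint; the pipeline is insensitive to it.
2. **Seeding** — the Euclidean distance transform (EDT) of the foreground
   is computed; pixels with no strictly greater EDT value within a
   *circular* neighborhood of radius 5 px become seeds.  8-connected
   plateaus of equal maximal value collapse to a single seed (plateau
   centroid snapped to the nearest plateau pixel), and every 8-connected
   foreground component is guaranteed at least one seed (its EDT argmax is
   used if its maximum is shadowed by a taller neighboring component).
   The radius is a first-class parameter: lowering it detects very small
   buds at the cost of more initial fragments.
3. **Watershed** — regions are grown from the seeds on the negated EDT with
   8-connectivity and *no* watershed line, so adjacent regions share a
   pixel interface whose scores the next step can read.
4. **Cell–cell boundary test** — for each pair of adjacent regions the
   interface is the two-sided set of region pixels with an 8-neighbor in
   the other region.  Its score is the mean of the top
   `ceil(0.75 · n)` (at least 1) interface-pixel scores; the bottom
   quarter is ignored because an erroneous boundary touches real
   boundaries at its two ends.  While any pair scores strictly above 0.99,
   the highest-scoring pair is merged (ties: lexicographically smallest
   (min ID, max ID) pair) and affected interfaces are recomputed, until a
   fixed point.  This repairs multi-peak oversegmentation (dumbbell-shaped
   cells) without a fluorescent marker.  Components below `min_area_px`
   (default 0 — buds of a few pixels are real cells) are then dropped and
   labels renumbered 1..n.

Numerical conventions: both thresholds are strict inequalities;
coordinates are 0-based (row, col); masks share the score map's shape.
Conservation holds throughout: labeled pixels are always a subset of the
thresholded foreground, and steps 3–4 neither create nor destroy
foreground pixels.

## Pixel classifier

The classifier is a compact U-Net-style encoder–decoder (two 3×3
convolution + ReLU layers per stage, 2× max-pooling, nearest-neighbor
upsampling with skip concatenation, 1×1 sigmoid head) implemented directly
on numpy with im2col convolutions, explicit backward passes and Adam.
Depth and base filter count are configurable (defaults: 2 down-levels,
8 filters); loss is per-pixel binary cross-entropy.  Optimizer, learning
rate (1e-3 default) and architecture scale are recorded in the model
metadata.

Training data: per annotated pair, the binary target is (mask > 0) with
cell–cell border pixels set to 0, where borders are the pixels covered by
the 8-connected dilations (1 px by default) of at least two distinct cell
IDs.  Images are normalized by mapping their 1st/99th intensity
percentiles to 0/1 with clipping (invariant to affine intensity changes —
acquisition light levels vary widely between experiments), cut into
256×256 tiles with stride ≤ half the tile (last window flush with the
edge; smaller images mirror-padded), and augmented on the fly: rotation
±90°, shear ±45°, zoom 0.5–2, horizontal/vertical flips and brightness
×0.5–1.5 by default, with nearest-neighbor interpolation for the target
(it stays binary) and bilinear for the image.  Batch size defaults to 25
and epochs to 100.  Prediction always runs on the whole image, reflect-
padded to the network's downsampling factor and cropped back.

## Tracking

Per frame, each cell yields (x, y, A): unweighted center of mass and pixel
count.  Features are mean-centered per frame and rescaled to population
variances (3, 3, 1) — position is deliberately weighted over area.
Population (divide-by-n) variance makes the invariant exact for any frame
of ≥ 2 distinct cells; a zero-variance feature is left centered without
scaling.  Consecutive frames are matched by minimum-total-cost rectangular
assignment (Hungarian algorithm) on Euclidean distances between
normalized triplets; unmatched later-frame cells are births (fresh,
never-reused IDs), unmatched earlier-frame cells are deaths.  An optional
`max_cost` gate converts too-expensive pairs into a death plus a birth; by
default no gate is applied, since the matching problem itself does not
define one.

Because the normalization is per frame, a birth shifts every normalized
coordinate slightly; two cells of near-identical size a few pixels apart
can then swap.  The tracker therefore guarantees perfect correspondence
only when per-frame displacements stay below half the minimal inter-cell
spacing *and* distinct cells are separated in feature space — the same
regime in which the underlying matching formulation is well-posed.

## Evaluation

A predicted cell is a true positive when its IoU with the corresponding
ground-truth cell is ≥ 0.5 (non-strict); correspondence is the optimal
one-to-one assignment maximizing total IoU over admissible pairs (at
IoU ≥ 0.5 against one-to-one ground truth the matching is essentially
unique, so greedy matching would agree).  Reported metrics: accuracy
TP/(TP+FP+FN) and mean IoU over TP pairs.  Conventions: two empty masks
score accuracy 1; with TP = 0 but errors present the mean IoU is reported
as 0 with an explicit `mean_iou_defined = False` flag.  Stacks report
per-frame metrics plus pooled counts.

## Shape analysis

Elongation = major/minor axis of the ellipse sharing the cell's central
second moments: the square root of the eigenvalue ratio of the 2×2
pixel-coordinate covariance (the axis-length scale factor cancels).
Moments use pixel-center coordinates without the +1/12 per-pixel
correction; the correction largely cancels in the ratio, and the 3%
tolerances used in tests absorb the residual discretization error (a
rasterized 40×10 rectangle gives 4.019 against the analytic 4.0).
Collinear pixel sets return infinity; single pixels are rejected.

The population profile scales each cell's area by the reference
(wild-type) group's mean area, discards the `floor(0.025 · n)` largest
records of the pooled population, splits the remaining scaled-area range
into 8 equal-width bins (half-open, last closed, so every retained record
falls in exactly one bin), and reports per genotype and bin: n, mean
elongation, SEM (sample STD/√n) and STD.  Empty bins carry NaN.  A generic
one-tailed two-sample t test is provided for group comparisons; no
biological effect size is asserted by the package.

## Synthetic data generator

The generator emulates the *structure* of phase-contrast yeast fields,
not their optics: cells are analytic regions (ellipses, capsules,
dumbbells, filaments, budded shapes) rasterized by a center-of-pixel test
— so closed-form moments exist for shape tests — placed by rejection
sampling with a bounded retry count (100 per cell, deterministic failure
reporting).  Rendering is stylized: dark interiors (~400), medium
background (~1000), a bright 1–2 px halo (~3000), optional bright
vacuole-like inclusions (~2000) whose edges must not become instance
boundaries, light Gaussian smoothing and additive Gaussian noise, in
16-bit range.  All outputs are pure functions of (params, seed).

The ideal score map is 1 on cell pixels and 0 elsewhere, with a 0-valued
separating band wherever the dilations of two distinct labels meet.
Because the pipeline can only label thresholded foreground, band pixels
that lie *on* cells would be unrecoverable; the generator therefore
defaults to a 1-px minimum background gap between cells (`crowding = 1`),
mirroring the annotation convention in which inter-cell borders are
0-valued in the training target.  With that convention the round trip
`segment(ideal_score_map(mask))` is pixel-exact up to relabeling whenever
each cell's interior produces seeds only within itself (elongated cells
that split are rejoined by the boundary test).  Genuinely shared borders
(`crowding = 0`) remain supported and are exercised by the boundary-test
fixtures; they are exactly the regime in which any method, human or
machine, must assign interface pixels by convention.

Timelapses are disc colonies with integer centers: radii grow
monotonically (growth suppressed rather than reversed on collision),
per-frame drift is an integer vector bounded by `drift_px` (rejected on
collision, so translation is exact on the pixel grid), and mature cells
bud with a fixed per-frame probability.  A mother carries at most one
attached bud over the simulated window — as real budding yeast does
before division, which is not simulated — and a new bud keeps ≥ 3 px
clearance from every non-mother cell, keeping cells separable in the
(x, y, area) feature space the tracker relies on.  Lineage (child →
(mother, birth frame)) is recorded.

What passing tests on synthetic data do *not* show: robustness to real
optics (partial focus, uneven illumination, camera noise statistics),
annotator ambiguity at true cell interfaces, or the full morphological
diversity of real mutants.  They do show that every algorithmic component
behaves exactly as specified on inputs whose ground truth is known
perfectly.

## Problem sizes and test design

Tests and the acceptance checks run at desk scale by choice: fields of
96–300 px and up to 30 cells, timelapses of 20 frames, and a reduced
classifier (depth 2, 8 base filters, 64-px tiles, 12 epochs, batch 10,
learning rate 3e-3, narrowed zoom/shear/brightness ranges) trained on 20
synthetic fields — enough for the loss to converge and held-out accuracy
to saturate on the stylized renders.  Brute-force oracles (exhaustive
local-maxima scans, all-permutation assignment minima, exhaustive merge
orders, closed-form moments) back every derived expectation.

## Known limitations

- The numpy classifier is CPU-only and deliberately small; it is not
  intended to reach published-scale accuracy on real micrographs.
- Watershed interfaces on ideal dumbbell fixtures depend on rasterization;
  the merge step makes the final labeling independent of where the split
  fell, but intermediate fragment shapes are not guaranteed symmetric.
- The tracker performs no gap closing, division detection or mother–bud
  lineage assignment; lineage ground truth exists only in the generator.
- `eval` metrics treat instances as sets of pixels; contour quality below
  the IoU threshold is not scored separately.
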