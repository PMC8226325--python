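# Methods

## The problem setting

Ear counting by object detection works from loose corner annotations: each
grain spike gets an axis-aligned box, a detector proposes scored boxes, and
the count is the number of boxes that survive post-processing. In dense
canopies the dominant error source is occlusion — ear-on-ear overlap, leaf
cover, and edge truncation — which depresses recall precisely where the
count matters most. This package implements the data-side counters to that
failure mode: an augmentation that manufactures realistic occlusion during
training-set preparation, an attention block reference for feature
refinement, and the evaluation machinery that quantifies counting quality.

## Coordinate conventions

All boxes are 0-based, half-open `[xmin, xmin + width) × [ymin, ymin +
height)`, x = column, y = row, origin top-left (the COCO convention; Pascal
VOC's 1-based inclusive corners are converted on read). An integer pixel
`(r, c)` belongs to a box iff `xmin <= c < xmax` and `ymin <= r < ymax`, so
adjacent boxes never share a pixel and membership is well-defined for
fractional box edges. Boxes partially outside the declared grid are clipped
on read; boxes with no remaining area are dropped with a warning rather
than silently kept. Ground-truth boxes never carry a confidence; detections
always do.

## Occlusion probability map

`build_probability_map` assigns every pixel `I_i = 0.001 + 0.003 * n_i`,
where `n_i` counts ground-truth boxes containing the pixel. The 0.001 floor
keeps sparse regions reachable — occlusion by leaves and stems happens away
from ear clusters too — while the 0.003 per-ear increment concentrates mass
where ears crowd. The map is built by integer coverage counting followed by
a single affine transform, so it is bit-identical to the printed formula
evaluated per pixel. No smoothing is applied: warm/cold rendering of such
maps is visualization, not part of the algorithm. Normalization divides by
the total mass; the floor guarantees the total is positive.

Counts use annotation boxes, not blob silhouettes, because boxes are the
only annotation the detection pipeline carries.

## Random-Cutout

Given an image with `N_total` ears the augmentation erases
`N = max(1, floor(N_total / n_rect_divisor))` rectangles (divisor default
4). The floor-then-minimum rule is a deliberate choice: a plain floor would
make the augmentation a no-op on images with fewer than four ears, yet
sparse scenes suffer leaf/stem occlusion as well, so at least one rectangle
is always placed when any ear exists. Images with zero ears are returned
unchanged with a logged notice — there is no occlusion to simulate.

Centers are drawn without replacement from the normalized probability map.
A two-stage variant (propose a large candidate pool, then subsample N) is
distributionally equivalent to direct weighted sampling and is not exposed.
Rectangle sizes are drawn per rectangle, uniform on
`[H_min/size_divisor, H_max/size_divisor]` for height and the analogous
width interval, where the bounds are the extreme box heights/widths *of that
image* — the adaptive element that prevents a size tuned to close-up ears
from wiping out the context of a wide-angle scene. "Length" is mapped to
box height and "width" to box width; with axis-aligned boxes no other
reading is available. Sizes are kept fractional and floored at one pixel;
the realized extent is the half-open window centered on the sampled pixel,
clipped at image borders (not re-sampled — real occluders are truncated by
the frame too). Fill is white (channel maximum) by default, with
`random_noise` and `mean` fills as options. One RNG stream per call, with
a fixed draw order (all centers, then sizes in center order), makes a seed
fully determine the output. Annotations are returned unchanged, by design:
the erased ear is still there, exactly as a leaf-occluded ear is.

The Cutout baseline erases fixed-size white squares at uniform positions;
Random Erasing erases noise-filled rectangles with sampled scale and aspect
ratio. Both ignore annotations, which is precisely the deficiency the
density-guided method addresses.

## CBAM reference

The attention module is implemented as a pure-numpy forward pass in axis
order (W, H, C). Channel attention pools globally over space (mean and
max), pushes both descriptors through one shared bias-free MLP
`W_1 · ReLU(W_0 · x)` with bottleneck C/r, sums and applies the logistic
sigmoid. As printed, the second-layer weight shape (C/r × C/r) cannot
produce a length-C gate; the standard CBAM convention `W_1 ∈ R^{C × C/r}`
is required for the refinement product to type-check and is used here. The
reduction ratio defaults to r = 16 (the literature default) and is carried
explicitly by the weight container; C must be divisible by r. Spatial
attention pools along the channel axis only, stacks the two W×H
descriptors, and convolves with a 7×7 kernel under zero same-padding so the
gate multiplies back onto the feature map; the larger "pool filter" sizes
sometimes quoted for this stage are read as the receptive field of that
convolution, not an extra pooling step. The numerically stable two-branch
sigmoid keeps gates strictly inside (0, 1) for finite inputs.

Weights are supplied, never trained: the module is meant as a
reference/verification target for implementations embedded in a detector
(e.g. the five insertion points between an EfficientDet-D0 backbone and its
BiFPN), and as such ships with a flat `.npz` weight archive format rather
than any framework checkpoint.

## Post-processing

Confidence filtering keeps boxes with score strictly greater than the
threshold (default 0.5, "higher than"). Greedy NMS then repeatedly accepts
the highest-confidence survivor and deletes boxes with IoU strictly above
the IoU threshold (default 0.5; the threshold itself is a configurable
choice). Confidence ties break by larger area, then input order — an
arbitrary but documented rule that makes results reproducible and testable
against an exhaustive reference.

## Metrics

Counting accuracy `P = N_cor / N_real` and false-detection rate
`O = N_err / N_num`. "Correct" is operationalized by greedy one-to-one
matching in descending confidence: a detection is correct iff its best-IoU
still-unmatched truth box reaches IoU ≥ 0.5 (inclusive, deliberately
distinct from NMS's strict >; both rules are stated at the interface).
Greedy-by-confidence is the standard benchmark convention; on synthetic
scenes with small jitter it agrees with maximum-cardinality matching, which
the tests verify with a Hungarian-algorithm oracle. Zero denominators
(no truth boxes, or no detections) report `None`, never 0 — an undefined
ratio is not a perfect score. Pooling over images (sum counts, then divide)
is the default; per-image averaging is available and surfaced in the CLI
report. Stratified missed-detection rates take caller-supplied occlusion
labels per image; the toolkit does not auto-classify occlusion types.
`FPS = 1/T` uses the mean per-image wall-clock time; being
hardware-dependent it is reported but never asserted against in tests.

## Synthetic scenes

The generator emulates the geometry of wheat-canopy images: `n_ears`
rotated-ellipse blobs with awn-like intensity striping, composited over a
plain or low-frequency-clutter background, every blob with an exact
analytic bounding box (center ± half-extent of the rotated ellipse). Boxes
come from the geometry rather than from rendered pixel support so that
scaling the canvas and all size ranges by a power of two scales every box
exactly; tests verify the rendered support is contained in, and near-tight
against, the analytic box. Defaults — 128×128 canvas, ear length 14–26 px,
width 5–9 px, overlap fraction 0.5, cluttered background — are chosen to
mimic the density and relative ear scale of field imagery at desk-test
size.

The target overlap fraction is met by placing `round(f·n/2)` ear pairs
whose boxes are forced to intersect and the remaining ears by rejection
sampling against all previous boxes (cap: 100 attempts per requested ear,
then a generation error). Realized overlap is therefore within 1/n plus
clipping effects of the target, comfortably inside the ±0.15 contract for
n ≥ 20. Geometry and texture use separate RNG streams spawned from the
seed, so box layouts are invariant to texture choices.

Simulated detections drop each truth box with probability `miss_rate`,
jitter surviving edges by up to `jitter` pixels, and add false positives at
`false_rate` per true box at locations disjoint from every truth box, all
confidences uniform on (0.5, 1] to sit above the default acceptance
threshold. What the generator does *not* model: photorealistic texture,
lighting/maturity variation, perspective, and correlated detector errors —
so passing tests demonstrate the correctness of the algorithms' mechanics
and their statistical contracts, not field-level detector performance.

## Benchmark problem sizes

The acceptance script measures pooled counting metrics on 200 scenes of 50
ears (128×128, ear length 10–18 px, width 5–8 px, jitter 0.5 px, miss rate
0.10, false rate 0.05); the test suite uses 500 such scenes. The smaller
ear sizes at 50-ear density keep disjoint placement feasible, and 0.5 px
jitter keeps every surviving detection above the 0.5 matching IoU even in
the worst case (for a 5-px box edge-jittered by 0.5 px the worst IoU is
0.545), so the expected pooled accuracy equals 1 − miss_rate exactly and
recovery can be tested at three standard errors. Sampling fidelity is
checked with chi-square over 8×8 spatial blocks (every expected count ≥ 5)
on 10,000 with-replacement draws per scene; `propose_centers` exposes a
`replace=True` mode for exactly this purpose, while the augmentation itself
always samples without replacement.

## Known limitations

* The probability map counts box coverage, not visible ear pixels; in
  scenes where boxes are much looser than the ears themselves the placement
  bias weakens.
* Greedy matching can differ from maximum-cardinality matching when
  detections are heavily displaced relative to crowded truth boxes; the
  discrepancy is zero in the tested small-jitter regime but users
  evaluating sloppy detectors should expect P to be a lower bound.
* Erase rectangles may overlap each other and may be mostly clipped away at
  borders; neither case is re-sampled.
* The CBAM reference is forward-only and CPU-bound; it is a correctness
  oracle, not a training component.
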