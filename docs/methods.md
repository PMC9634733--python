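# Methods

This note documents the models, algorithms and numerical choices behind
`arterylabel`, and what the synthetic phantom experiments do and do not
show.

## Problem

Anatomical labeling assigns each voxel of a segmented cerebral vessel tree
one of 24 named arterial classes (detailed constellation) or one of 11
clinically grouped territories (aggregated constellation), plus background
and non-annotated vessels — 26 and 13 classes in total.  Paired arteries
carry D- (dexter, right) / S- (sinister, left) laterality; AcomA and BA are
unpaired midline vessels.  Index order is a package convention (background
0, non-annotated 1, then catalog order, dexter before sinister) and is
serialized with every artifact.

The formulation is voxel-wise classification: no vascular graph, atlas
registration or a-priori bifurcation extraction is required for prediction,
which keeps the pipeline robust to the missing or disconnected segments
that are the norm in cerebrovascular disease.  Segment information is used
only for ground-truth creation, for training-patch placement, and for the
optional washing post-processor.

## Geometry

*Thinning.* The binary mask is reduced to a one-voxel centerline by
topology-preserving 3-D thinning (Lee's algorithm as implemented in
scikit-image).  Each centerline voxel stores the Euclidean distance
transform of the mask at that voxel, computed with the anisotropic voxel
spacing, as the local radius in mm.  One caveat observed in testing: for
*perfectly* symmetric synthetic tubes whose axis falls between voxels, the
thinning tie-breaks can erase the object entirely; real and phantom masks
are irregular enough that this never arises, but analytic test fixtures
must center tubes on a voxel.

*Segments.* Bifurcation nodes are maximal 26-connected clusters of
centerline voxels with ≥ 3 centerline neighbors (thinning can produce
adjacent branch voxels, hence clusters rather than single voxels).
Removing node voxels leaves runs; each run is ordered by walking from an
extremity, and spur runs shorter than 3 voxels that end free are pruned as
thinning artifacts (threshold configurable).  Node voxels are attached to
the adjacent run with the smallest id so the segments exactly partition the
centerline.  Disconnected components simply yield separate segments.

*Full-lumen maps.* Every mask voxel receives the segment id of its nearest
centerline voxel (spacing-aware Euclidean distance).  Washing and
evaluation therefore operate on the full lumen, not only the centerline;
whether the original ground truth covered lumen or centerline is ambiguous,
and the full-lumen choice is recorded per run.

*Per-segment ground truth* is the majority vote over a segment's voxels
with background excluded; a segment with no overlap falls back to
non-annotated.  Non-homogeneous segments are labeled by majority and
logged.

## Phantom cohorts

The generator emulates the statistical structure of a two-study
cerebrovascular cohort so that every stage is testable without data:

- a fixed template tree of all 24 segments with plausible Circle-of-Willis
  topology (ICA → ICA-CoW → {M1 → M2 sup/inf, A1 → {AcomA, A2}}, VA pairs →
  BA → P1 → P2, PcomA bridging ICA-CoW and the P1/P2 junction), left/right
  mirrored, in unit-cube coordinates with mm radii tapering distally;
- per-subject jitter: junction displacements are drawn once per junction
  (so connected segments stay connected), interior control points
  independently (sigma 0.8 mm), radii log-normally (sigma 0.08);
- pathological missing segments: with probability 0.8 per subject (the
  prevalence reported for cerebrovascular cohorts) a random nonempty subset
  of the droppable set {D/S-PcomA, D/S-A1, D/S-P1, AcomA} — the commonly
  hypoplastic CoW elements — is removed;
- distal non-annotated vasculature: each terminal segment (M2, A2, P2)
  continues into a thinner extension labeled non-annotated, 15 % of the
  parent's length, exercising that class;
- rasterization: a voxel is vessel if it lies within the interpolated
  radius of the nearest polyline point of any present segment; junction
  overlaps resolve to the most deeply covering segment;
- imaging: tissue level 100, flow-like vessel level 220 (arbitrary units),
  a smooth multiplicative bias field (Gaussian-filtered white noise, 15 %
  amplitude, 16-voxel correlation length — emulating raw scans without
  non-uniformity correction) and additive Gaussian noise (sigma 8).  At
  these defaults vessels exceed background by more than two background
  standard deviations, which the labeling task presumes.

The default grid is 96 × 96 × 48 voxels at 0.6 × 0.6 × 0.7 mm — anisotropic
like clinical angiography but desk-scale; the full clinical matrix
(312 × 384 × 127 at 0.52 × 0.52 × 0.65 mm) is available through
configuration only.  Cohorts derive per-subject seeds from one base seed
(SeedSequence), are tagged into two strata emulating the 72 + 170 = 242
patient inclusion arithmetic, and are bit-reproducible.

What the phantom does **not** emulate: real intensity distributions and
artifacts (the noise parameters are free settings, not estimates), skull
and tissue anatomy, flow effects, anatomical variants beyond segment
absence (M1 trifurcations, fetal PCA), and inter-rater labeling noise.
Passing desk-scale tests therefore demonstrates the pipeline's mechanics
and internal consistency, not clinical-grade accuracy.

## Patches, folds, augmentation

Stratified k-fold splitting shuffles within each cohort stratum once
(seeded) and gives every fold ⌊stratum/k⌋ test subjects per stratum; the
leftovers appear in every training set and no test set — the only reading
consistent with 4 × 60 = 240 < 242.  Patch centers are sampled uniformly
without replacement on each segment, 8 per segment by default (all voxels
of shorter segments); patches come in concentric pairs, the context patch
exactly twice the main patch per axis, zero-padded at volume borders, with
image and centerline-radius channels stacked.  Min–max scaling to [0, 1]
uses global per-channel training-fold statistics; out-of-range test values
clip.  Rotation augmentation keeps the originals and appends
independently rotated copies (axis uniform on the sphere, angle uniform in
[−60°, +60°]; image trilinear, vessel and labels nearest-neighbor), ×3 by
default.  Desk-scale patch sizes are 32 × 32 × 16 / 64 × 64 × 32 (the
clinical 128 × 128 × 64 / 256 × 256 × 128 are configuration); centers are
sampled once per dataset build, not per epoch.  Training sets are
materialized lazily batch-by-batch from the source volumes — a cohort's
dual-scale patches would otherwise not fit in memory.

## The classifier

A 3-D encoder–decoder over the main patch with a parallel context encoder:
the context patch is average-downsampled by 2 at entry, encoded by a twin
encoder, and its bottleneck features are concatenated with the main
encoder's before decoding; skip connections come from the main encoder.
Two 3 × 3 × 3 convolutions per level, max pooling by 2,
transposed-convolution up-sampling, filter counts doubling from
`base_filters` (desk default 4; 16 at clinical scale), deep-supervision
softmax heads at intermediate decoder levels with weights 1.0/0.5/0.25
finest-to-coarsest, Glorot-uniform kernel init, Adam with initial learning
rate 1e-3 and categorical cross-entropy, and a 1e-3 L2 penalty on
convolution kernels in place of dropout.  Disabling the context path
(`context_path=False`) reproduces the plain single-scale baseline.

Three choices were made where the architecture description leaves room,
each motivated by CPU-scale trainability and recorded in configuration:

- **Instance normalization** (`normalization`): "instance" normalizes
  after every convolution, "encoder" only in the encoders and bottleneck
  (leaving the decoder's absolute calibration of class scores untouched),
  "none" gives the bare variant.  Without any normalization, small-batch
  training on one CPU stalls in the background-collapse regime for many
  epochs; fully normalized models acquire all classes fastest but
  mis-calibrate near vessel boundaries when inference tiles differ from
  the vessel-centered training patches; the encoder-only hybrid is the
  default compromise.
- **Prior-initialized heads**: softmax-head biases start at the
  training-set log class frequencies, so optimization starts at the prior
  predictor instead of spending steps learning the ~95 % background skew
  (kernel init stays Glorot).
- **Depth 3** by default: at depth 2 the context path's receptive field
  covers too little of the desk volume to localize a segment within the
  tree, and class learning measurably stalls; at depth 3 the context
  bottleneck sees effectively the whole context patch.  Depth is
  configurable; main patch dims must be divisible by 2^depth, which makes
  output and ground-truth shapes equal by construction, so no last-slice
  workaround is needed at evaluation time.
- The **learning-rate schedule** (`lr_schedule`) defaults to cosine decay
  from the initial rate to a tenth of it; "none" keeps it constant.

The engine itself (`arterylabel.nn`) is a compact CPU implementation of
exactly these operations with hand-written backward passes, verified by
finite-difference tests; 3-D convolutions run through numba-jitted direct
kernels, with an im2col+BLAS fallback backend kept for cross-checking
(both produce identical outputs and gradients, which a test asserts).

The random-forest baseline classifies voxels independently from five
features — image intensity, vessel-channel radius, and the three voxel
coordinates normalized to [0, 1] — with 50 trees and an equal number of
voxels per class sampled from each training subject.  The feature set is a
minimal "image + vessel (+ location)" reading and is stated openly as a
choice.

## Inference and washing

Whole volumes are covered by a regular grid of main-size tiles (default
stride = tile size; halving the stride averages overlapping softmax
contributions), each with its concentric context patch, zero-padded at
borders.  Washing sums the per-voxel class probabilities over each
segment's full lumen and assigns the argmax of the sums — identical to
assigning the class of highest average likelihood, since segment size is a
constant factor — to all of the segment's voxels; ties break to the lowest
class index, voxels outside all segments keep their per-voxel argmax.
Washing is idempotent and its output segment-homogeneous by construction;
both properties are asserted against a brute-force oracle.

## Evaluation

Background and non-annotated classes are excluded from all scores; a
prediction of an excluded class on an artery voxel still counts against
that artery class as a false negative.  Per-class F1 uses 2TP/(2TP+FP+FN)
with 0 when the denominator vanishes.  Classes without ground-truth
support in an evaluation set are excluded from the macro means — with 80 %
of subjects missing segments this is unavoidable — and their count is
reported.  Category boundaries are made half-open and exhaustive:
excellent F1 > 0.9, good 0.75 < F1 ≤ 0.9, moderate 0.6 < F1 ≤ 0.75, poor
F1 ≤ 0.6 (the printed thresholds leave exactly 0.6 ambiguous).  Cross-fold
summaries report mean ± sample standard deviation.  Segment-wise scores
require washed (segment-homogeneous) input and count each segment once,
removing the segment-size skew of voxel-wise scores.

## Desk-scale experiment

The end-to-end check trains on a 20-subject phantom cohort (16 train /
4 test, the 96 × 96 × 48 grid, base_filters 4, patches 32 × 32 × 16 /
64 × 64 × 32) and measures held-out aggregated-constellation macro-F1
after washing, plus the orderings between input configurations
(image+vessel ≥ vessel-only ≥ image-only), washing on/off, and
augmentation on/off at matched training length.  Problem sizes (patches
per segment, epochs) are chosen for single-CPU runs and stated in the test
and script headers.  Because a single seed is used per run, the orderings
are checked on one realization, not averaged over many.

## Known limitations

- Desk-scale absolute scores are not comparable to clinical results; the
  phantom is easier in geometry and harder in training budget.  On one CPU
  the classifier remains compute-limited well before convergence, while
  the coordinate-featured random forest solves the phantom almost
  immediately — headline deep-model scores at desk scale therefore say
  more about the training budget than about the architecture.
- The phantom's image channel contains the complete vessel geometry at
  high contrast with no surrounding anatomy, so intensity-only models are
  *relatively* stronger on phantoms than on clinical angiography, where
  tissue clutter is what makes intensity-only labeling hard.  Orderings
  between input configurations that hinge on image-channel difficulty
  (e.g. vessel-only versus image-only) need not transfer from clinical
  data to the phantom, and in our experiments they do not.
- The desk context patch covers only about a third of the desk volume,
  whereas the clinical-scale context patch covers essentially the whole
  brain; localization-dependent classes (midline and ACA territory) are
  therefore disproportionately hard at desk scale, and a background halo
  of one to two voxels around vessels dominates the voxel-wise false
  positives of undertrained models.
- The M2-level distal classes are the hardest at any scale (smallest,
  most mobile); the detailed constellation inherits this.
- Exact thinning behavior differs from the original radius-encoding
  skeletonization it stands in for; radii agree to within a voxel on
  analytic tubes.
- Anatomical variants (trifurcations, fetal PCA) are out of scope of both
  the taxonomy and the phantom.
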