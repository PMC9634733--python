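# arterylabel

Anatomical labeling of intracranial arteries from 3-D angiographic volumes.

Given an angiographic image (bright-blood contrast, e.g. time-of-flight MRA)
and a binary vessel segmentation, the pipeline assigns every vessel voxel —
and every vessel *segment* between bifurcations — one of 24 named arterial
classes (ICA, ICA CoW, M1, M2 sup/inf, A1, AcomA, A2, VA, BA, PcomA, P1, P2,
with dexter/sinister laterality for the paired ones), or one of 11
clinically grouped territories in the *aggregated* constellation.  Everything
is exercisable end to end with no external data through a bundled synthetic
Circle-of-Willis phantom generator.

It is aimed at researchers working on cerebrovascular image analysis who
need a fully scripted, CPU-runnable reference implementation of this
labeling approach: voxel-wise classification by a multi-scale 3-D
encoder–decoder, made anatomically consistent by *segment washing*.

## Method

1. **Geometry.** The vessel mask is thinned to a one-voxel centerline whose
   voxels carry the local radius *r* (mm, Euclidean distance transform);
   the centerline is decomposed into segments — maximal runs between
   bifurcation nodes (centerline voxels with ≥ 3 neighbors,
   26-connectivity) and free ends.  A full-lumen segment-id map assigns
   every mask voxel its nearest centerline voxel's segment.
2. **Classifier.** Around voxel coordinates sampled on each segment (8 per
   segment), concentric patches are cut at two scales; image and
   centerline-radius volumes form two channels, min–max scaled with
   training-set statistics.  A U-Net-style encoder–decoder over the main
   patch is joined by a parallel *context* encoder fed the twice-larger
   patch down-sampled by two; features fuse at the bottleneck, and deep
   supervision adds auxiliary softmax heads in the decoder.  Training:
   Adam (initial LR 1e-3), categorical cross-entropy, Glorot-uniform init,
   1e-3 L2 on convolution kernels, optional ×3 inflation by random
   rotations in [−60°, +60°].
3. **Washing.** Whole-volume softmax fields are reconstructed by patch
   tiling; for each segment the per-class softmax scores are summed over
   its voxels and the argmax of the sums is written to every voxel of the
   segment, enforcing one label per anatomical segment.
4. **Evaluation.** Per-class F1 and the macro means

   mF1 = (1/|C|) Σ_c F1_c,  bAcc = (1/|C|) Σ_c recall_c

   over artery classes (background and non-annotated excluded), at voxel
   level and — after washing — at segment level, where each segment counts
   as a single prediction.  Per-class F1 is categorized excellent (> 0.9),
   good (> 0.75), moderate (> 0.6) or poor.

A voxel-wise random forest (50 trees; intensity, radius and normalized
coordinates as features) serves as the classical baseline.

## Worked example

```bash
python examples/02_centerline_segments.py
```

prints, for a complete-tree phantom subject:

```
centerline: 315 voxels, radii 0.60-2.16 mm
24 segments, 12 bifurcations

 segment_id  n_voxels          endpoint_types  gt_label    artery
          1        12         end/bifurcation         8  D-M2-sup
          2        11         end/bifurcation        10  D-M2-inf
          3        21         end/bifurcation        24      D-P2
          4        21 bifurcation/bifurcation         6      D-M1
          ...
```

Each row is one bifurcation-bounded run of centerline voxels with its
majority ground-truth artery.  `examples/04_segment_washing.py` shows
washing turn the heterogeneous per-voxel labels `[1 2 1 2 2]` of one
segment into the homogeneous `[2 2 2 2 2]` (class 2 has the highest summed
softmax, 2.65 vs 1.85), and `examples/05_train_and_evaluate.py` runs the
whole loop on a small cohort.  The `arterylabel` command
(`simulate | prepare | train | evaluate | all`) drives the same pipeline
from YAML configs.

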