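"""End-to-end orchestration: phantom cohort -> geometry -> patches ->
training -> whole-volume prediction -> washing -> evaluation.

This is the library face of the pipeline; the command-line interface and the
example scripts are thin wrappers around these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (CenterlineMap, SegmentTable, extract_segments,
                       segment_gt_labels, segment_id_volume, skeletonize)
from .grid import VolumeGrid
from .inference import argmax_labels, predict_volume, segment_wash
from .metrics import MetricsReport, scores, voxel_confusion
from .network import (ModelConfig, MultiScaleUNet, TrainConfig, build_network,
                      rf_baseline, train)
from .patches import (CONTEXT_SIZE, MAIN_SIZE, PatchPair, ScalingStats,
                      _crop_padded, extract_dual_patch, fit_scaling,
                      sample_patch_centers)
from .phantom import PhantomSubject, generate_cohort
from .taxonomy import (aggregate_labels, build_aggregated_taxonomy,
                       build_detailed_taxonomy)

__all__ = [
    "PreparedSubject", "ExperimentResult", "prepare_subject",
    "build_training_patches", "evaluate_model", "run_experiment",
    "INPUT_MODES",
]

logger = logging.getLogger(__name__)

#: Channel subsets by input configuration (0 = image, 1 = vessel radius).
INPUT_MODES = {"image+vessel": [0, 1], "vessel": [1], "image": [0]}


@dataclass
class PreparedSubject:
    """A phantom subject with its derived vessel-specific inputs."""

    subject: PhantomSubject
    centerline: CenterlineMap
    vessel: VolumeGrid          # dense centerline-radius volume (mm)
    table: SegmentTable         # gt-labeled segments
    seg_ids: VolumeGrid         # full-lumen segment-id map
    gt: VolumeGrid              # labels in the chosen constellation

    @property
    def subject_id(self) -> str:
        return self.subject.subject_id


def prepare_subject(subject: PhantomSubject,
                    constellation: str = "aggregated") -> PreparedSubject:
    """Run the geometry stage for one subject: thinning, radius encoding,
    segment decomposition, full-lumen segment-id map and per-segment
    ground-truth labels in the requested constellation."""
    if constellation == "aggregated":
        gt = aggregate_labels(subject.gt_labels, build_detailed_taxonomy())
    elif constellation == "detailed":
        gt = subject.gt_labels
    else:
        raise ValueError(f"unknown constellation '{constellation}'")
    cl = skeletonize(subject.vessel_mask)
    table = extract_segments(cl)
    table = segment_gt_labels(table, gt)
    seg_ids = segment_id_volume(table, subject.vessel_mask)
    return PreparedSubject(subject, cl, cl.dense(), table, seg_ids, gt)


class LazyPatchDataset:
    """Training patches materialized batch by batch.

    Stores only the scaled source volumes plus one (subject, center,
    rotation) triple per sample, so cohorts of thousands of dual-scale
    patches fit in memory; augmented copies carry their rotation parameters
    and are rotated on extraction.  Semantically equivalent to the eager
    list produced by :func:`patches.augment_rotations` (originals first,
    then the rotated copies).
    """

    def __init__(self, volumes: list[tuple[VolumeGrid, VolumeGrid, VolumeGrid]],
                 samples: list[tuple[int, np.ndarray, tuple | None]],
                 main_size=MAIN_SIZE, context_size=CONTEXT_SIZE):
        self.volumes = volumes
        self.samples = samples
        self.main_size = tuple(main_size)
        self.context_size = tuple(context_size)

    def __len__(self) -> int:
        return len(self.samples)

    def get(self, i: int) -> PatchPair:
        from .patches import rotate_patch

        vol_idx, center, rot = self.samples[i]
        img, ves, gt = self.volumes[vol_idx]
        p = extract_dual_patch(img, ves, gt, center, self.main_size, self.context_size)
        if rot is not None:
            p = rotate_patch(p, np.asarray(rot[0]), float(rot[1]))
        return p

    def batch(self, indices, channel_idx: list[int] | None = None):
        from .network import stack_patches

        return stack_patches([self.get(int(i)) for i in indices], channel_idx)

    def label_counts(self, n_classes: int) -> np.ndarray:
        """Class histogram over the unrotated samples' label crops (cheap:
        no image/context extraction)."""
        counts = np.zeros(n_classes, dtype=np.int64)
        for vol_idx, center, rot in self.samples:
            if rot is not None:
                continue
            gt = self.volumes[vol_idx][2]
            crop = _crop_padded(np.asarray(gt.data, dtype=np.int64), center, self.main_size)
            counts += np.bincount(crop.ravel(), minlength=n_classes)[:n_classes]
        return counts


def build_training_patches(preps: list[PreparedSubject], stats: ScalingStats,
                           per_segment: int = 8, seed: int = 0,
                           main_size=MAIN_SIZE, context_size=CONTEXT_SIZE,
                           augment: bool = False, inflation: int = 3) -> LazyPatchDataset:
    """Sample patch centers on every segment and assemble the (lazily
    materialized) training set of scaled dual-scale patches; optionally
    inflated by rotation augmentation, originals kept."""
    from .patches import scale_array

    volumes = []
    samples: list[tuple[int, np.ndarray, tuple | None]] = []
    for i, prep in enumerate(preps):
        img = prep.subject.image.with_data(
            scale_array(np.asarray(prep.subject.image.data, np.float32), stats, 0))
        ves = prep.vessel.with_data(
            scale_array(np.asarray(prep.vessel.data, np.float32), stats, 1))
        volumes.append((img, ves, prep.gt))
        centers = sample_patch_centers(prep.table, per_segment, seed=seed + 7 * i)
        samples.extend((i, c, None) for c in centers)
    if augment and inflation > 1:
        rng = np.random.default_rng(seed + 99)
        lo, hi = np.deg2rad(-60.0), np.deg2rad(60.0)
        extra = []
        for _ in range(inflation - 1):
            for vol_idx, c, _rot in samples[:len(samples)]:
                if _rot is not None:
                    continue
                axis = rng.normal(size=3)
                while np.linalg.norm(axis) < 1e-9:
                    axis = rng.normal(size=3)
                extra.append((vol_idx, c, (axis, rng.uniform(lo, hi))))
        samples = samples + extra
    return LazyPatchDataset(volumes, samples, main_size, context_size)


@dataclass
class ExperimentResult:
    model: MultiScaleUNet
    history: pd.DataFrame
    stats: ScalingStats
    voxel_plain: MetricsReport
    voxel_washed: MetricsReport | None
    segment: MetricsReport | None
    per_subject: pd.DataFrame
    n_train_patches: int = 0
    extras: dict = field(default_factory=dict)


def evaluate_model(model: MultiScaleUNet, test_preps: list[PreparedSubject],
                   stats: ScalingStats, channel_idx: list[int],
                   washing: bool = True, n_classes: int | None = None,
                   overlap: bool = True, vessel_tiles: bool = True):
    """Whole-volume prediction + optional washing over held-out subjects.

    Voxel-wise scores pool voxels over all test subjects; segment-wise
    scores pool one (gt, prediction) pair per segment.  By default tiles
    overlap at half stride and extra tiles centered on the vessel tree are
    averaged in (matching the vessel-centered training distribution);
    both refinements can be disabled for plain non-overlapping tiling.
    """
    from .inference import vessel_tile_centers

    gts, plains, washeds = [], [], []
    seg_gt, seg_pred = [], []
    rows = []
    stride = tuple(s // 2 for s in model.cfg.main_input) if overlap else None
    for prep in test_preps:
        centers = (vessel_tile_centers(prep.centerline.coords, model.cfg.main_input,
                                       prep.subject.image.shape)
                   if vessel_tiles else None)
        probs = predict_volume(model, prep.subject.image, prep.vessel, stats,
                               stride=stride, channel_idx=channel_idx,
                               extra_centers=centers)
        plain = argmax_labels(probs)
        gts.append(np.asarray(prep.gt.data))
        plains.append(np.asarray(plain.data))
        row = {"subject_id": prep.subject_id}
        if washing:
            washed = segment_wash(probs, prep.seg_ids)
            washeds.append(np.asarray(washed.data))
            wdata = np.asarray(washed.data)
            for seg in prep.table.segments:
                seg_gt.append(seg.gt_label)
                seg_pred.append(int(wdata[tuple(seg.voxels[0])]))
            row["washed_acc_vessel"] = float(
                (wdata == gts[-1])[np.asarray(prep.subject.vessel_mask.data) > 0].mean())
        rows.append(row)

    gt_all = np.concatenate([g.ravel() for g in gts])
    plain_all = np.concatenate([p.ravel() for p in plains])
    voxel_plain = scores(voxel_confusion(gt_all, plain_all, n_classes=n_classes))
    voxel_washed = segment = None
    if washing:
        washed_all = np.concatenate([w.ravel() for w in washeds])
        voxel_washed = scores(voxel_confusion(gt_all, washed_all, n_classes=n_classes))
        segment = scores(voxel_confusion(np.asarray(seg_gt), np.asarray(seg_pred),
                                         n_classes=n_classes), level="segment")
    return voxel_plain, voxel_washed, segment, pd.DataFrame(rows)


def run_experiment(subjects: list[PhantomSubject] | None = None, *,
                   n_subjects: int = 20, n_test: int = 4,
                   tag_counts: dict[str, int] | None = None,
                   constellation: str = "aggregated",
                   input_mode: str = "image+vessel",
                   washing: bool = True, augment: bool = False,
                   per_segment: int = 8, inflation: int = 3,
                   epochs: int = 2, batch_size: int = 8, lr: float = 1e-3,
                   base_filters: int = 4, depth: int = 3,
                   main_size=MAIN_SIZE, seed: int = 0,
                   preps: list[PreparedSubject] | None = None,
                   verbose: bool = False) -> ExperimentResult:
    """Train and evaluate one model configuration on a phantom cohort.

    The last ``n_test`` subjects are held out.  ``preps`` may carry
    pre-computed geometry (e.g. to share it across input-mode ablations).
    """
    channel_idx = INPUT_MODES[input_mode]
    if preps is None:
        if subjects is None:
            tag_counts = tag_counts or {"A": 8, "B": n_subjects - 8}
            subjects = generate_cohort(n_subjects, tag_counts, base_seed=seed)
        preps = [prepare_subject(s, constellation) for s in subjects]
    train_preps, test_preps = preps[:-n_test], preps[-n_test:]

    stats = fit_scaling([(p.subject.image, p.vessel) for p in train_preps])
    patches = build_training_patches(train_preps, stats, per_segment, seed,
                                     main_size, tuple(2 * s for s in main_size),
                                     augment=augment, inflation=inflation)
    n_classes = (build_aggregated_taxonomy() if constellation == "aggregated"
                 else build_detailed_taxonomy()).n_classes
    cfg = ModelConfig(main_input=main_size,
                      context_input=tuple(2 * s for s in main_size),
                      channels=len(channel_idx), classes=n_classes,
                      base_filters=base_filters, depth=depth)
    model = build_network(cfg, seed=seed)
    tcfg = TrainConfig(learning_rate=lr, epochs=epochs, batch_size=batch_size,
                       seed=seed)
    model, history = train(model, patches, None, tcfg, channel_idx, verbose=verbose)

    voxel_plain, voxel_washed, segment, per_subject = evaluate_model(
        model, test_preps, stats, channel_idx, washing, n_classes)
    return ExperimentResult(model, history, stats, voxel_plain, voxel_washed,
                            segment, per_subject, n_train_patches=len(patches))
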