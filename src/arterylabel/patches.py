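"""Fold splitting, patch-center sampling, dual-scale patch extraction,
intensity scaling, and rotation augmentation.

Training is patch-wise: around voxel coordinates sampled on arterial
segments, concentric patches are cut at two scales — a *main* patch at the
working resolution and a *context* patch twice as large per axis, feeding
the classifier's context path.  Image and vessel-radius volumes are stacked
as two channels; both come from the same grid, so the patches are naturally
aligned and centered on the same coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import SegmentTable
from .grid import VolumeGrid

__all__ = [
    "FoldSplit",
    "PatchPair",
    "ScalingStats",
    "make_folds",
    "sample_patch_centers",
    "extract_dual_patch",
    "fit_scaling",
    "apply_scaling",
    "scale_array",
    "augment_rotations",
    "MAIN_SIZE",
    "CONTEXT_SIZE",
]

#: Desk-scale default patch sizes (2:1 context:main ratio preserved).
MAIN_SIZE = (32, 32, 16)
CONTEXT_SIZE = (64, 64, 32)


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """Stratified k-fold split with disjoint test sets.

    Within each stratum (cohort tag) subjects are shuffled once; every fold
    takes ``floor(stratum/k)`` of them as test subjects, so test sets are
    pairwise disjoint and equally stratified.  The ``stratum mod k``
    leftovers appear in every training set and in no test set.
    """

    k: int
    folds: list[tuple[list[str], list[str]]]   # (train_ids, test_ids)
    strata: dict[str, str]                      # subject id -> tag

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"k": self.k, "strata": self.strata,
                       "folds": [{"train": tr, "test": te} for tr, te in self.folds]},
                      fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FoldSplit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["k"], [(f["train"], f["test"]) for f in d["folds"]], d["strata"])


def make_folds(subjects: list[tuple[str, str]], k: int, seed: int) -> FoldSplit:
    """Stratified k-fold split of ``(subject_id, tag)`` pairs."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    strata: dict[str, list[str]] = {}
    for sid, tag in subjects:
        strata.setdefault(tag, []).append(sid)
    for tag, members in strata.items():
        if len(members) < k:
            raise ValueError(f"stratum '{tag}' has {len(members)} subjects, fewer than k={k}")

    rng = np.random.default_rng(seed)
    shuffled = {tag: list(rng.permutation(members)) for tag, members in strata.items()}
    all_ids = [sid for sid, _tag in subjects]

    folds = []
    for f in range(k):
        test: list[str] = []
        for tag, members in shuffled.items():
            m = len(members) // k
            test.extend(members[f * m:(f + 1) * m])
        test_set = set(test)
        train = [sid for sid in all_ids if sid not in test_set]
        folds.append((train, test))
    return FoldSplit(k, folds, dict(subjects))


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

@dataclass
class PatchPair:
    """Concentric dual-scale patch: 2-channel main and context crops plus
    the ground-truth label patch at main size."""

    center: np.ndarray        # (3,) voxel index
    main: np.ndarray          # (2, *main_size) channels: image, vessel radius
    context: np.ndarray       # (2, *context_size)
    gt: np.ndarray            # (*main_size,) int
    subject_id: str = ""


def sample_patch_centers(table: SegmentTable, per_segment: int = 8,
                         seed: int = 0) -> list[np.ndarray]:
    """Sample up to ``per_segment`` distinct voxel coordinates uniformly
    without replacement on every segment (all voxels when a segment is
    shorter than ``per_segment``)."""
    if per_segment < 1:
        raise ValueError(f"per_segment must be >= 1, got {per_segment}")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    for seg in table.segments:
        n = min(per_segment, len(seg.voxels))
        pick = rng.choice(len(seg.voxels), size=n, replace=False)
        centers.extend(seg.voxels[i] for i in sorted(pick))
    return centers


def _crop_padded(arr: np.ndarray, center: np.ndarray, size: tuple[int, int, int]) -> np.ndarray:
    """Crop ``size`` around ``center`` with zero padding past the borders.
    The patch covers ``[c - s//2, c + s - s//2)`` per axis."""
    out = np.zeros(size, dtype=arr.dtype)
    src_lo, src_hi, dst_lo, dst_hi = [], [], [], []
    for ax in range(3):
        lo = int(center[ax]) - size[ax] // 2
        hi = lo + size[ax]
        s_lo, s_hi = max(lo, 0), min(hi, arr.shape[ax])
        src_lo.append(s_lo)
        src_hi.append(s_hi)
        dst_lo.append(s_lo - lo)
        dst_hi.append(s_lo - lo + max(s_hi - s_lo, 0))
        if s_hi <= s_lo:
            return out
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
        arr[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    return out


def extract_dual_patch(image: VolumeGrid, vessel: VolumeGrid, gt: VolumeGrid | None,
                       center, main_size=MAIN_SIZE, context_size=CONTEXT_SIZE,
                       subject_id: str = "") -> PatchPair:
    """Cut the concentric main/context crops around ``center``.

    ``context_size`` must be exactly twice ``main_size`` per axis; crops are
    zero-padded where they extend past the volume border."""
    main_size = tuple(int(s) for s in main_size)
    context_size = tuple(int(s) for s in context_size)
    if tuple(2 * s for s in main_size) != context_size:
        raise ValueError(f"context size {context_size} must be 2 x main size {main_size}")
    if any(s % 2 for s in main_size):
        raise ValueError(f"main size must be even per axis, got {main_size}")
    center = np.asarray(center, dtype=int)
    if np.any(center < 0) or np.any(center >= np.asarray(image.shape)):
        raise ValueError(f"center {center.tolist()} outside grid {image.shape}")

    img = np.asarray(image.data, dtype=np.float32)
    ves = np.asarray(vessel.data, dtype=np.float32)
    main = np.stack([_crop_padded(img, center, main_size),
                     _crop_padded(ves, center, main_size)])
    context = np.stack([_crop_padded(img, center, context_size),
                        _crop_padded(ves, center, context_size)])
    gtp = (np.zeros(main_size, dtype=np.int16) if gt is None
           else _crop_padded(np.asarray(gt.data, dtype=np.int16), center, main_size))
    return PatchPair(center, main, context, gtp, subject_id)


# ---------------------------------------------------------------------------
# intensity scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingStats:
    """Per-channel min/max over the training set (image, vessel)."""

    minimum: np.ndarray   # (2,)
    maximum: np.ndarray   # (2,)

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=np.float32)
        self.maximum = np.asarray(self.maximum, dtype=np.float32)
        if np.any(self.maximum <= self.minimum):
            raise ValueError(
                f"degenerate channel: max {self.maximum.tolist()} must exceed "
                f"min {self.minimum.tolist()}")


def fit_scaling(train_volumes: list[tuple[VolumeGrid, VolumeGrid]]) -> ScalingStats:
    """Fit global per-channel min/max over training-set (image, vessel)
    volume pairs."""
    if not train_volumes:
        raise ValueError("no training volumes to fit scaling on")
    mins = np.full(2, np.inf)
    maxs = np.full(2, -np.inf)
    for img, ves in train_volumes:
        for ch, vol in enumerate((img, ves)):
            mins[ch] = min(mins[ch], float(np.min(vol.data)))
            maxs[ch] = max(maxs[ch], float(np.max(vol.data)))
    return ScalingStats(mins, maxs)


def scale_array(arr: np.ndarray, stats: ScalingStats, channel: int) -> np.ndarray:
    """Min-max scale one channel to [0, 1], clipping out-of-range values."""
    lo, hi = stats.minimum[channel], stats.maximum[channel]
    return np.clip((arr.astype(np.float32) - lo) / (hi - lo), 0.0, 1.0)


def apply_scaling(patch: PatchPair, stats: ScalingStats) -> PatchPair:
    """Scale both channels of a patch pair to [0, 1] with training-set
    statistics (test values beyond the training range clip)."""
    main = np.stack([scale_array(patch.main[c], stats, c) for c in range(2)])
    context = np.stack([scale_array(patch.context[c], stats, c) for c in range(2)])
    return PatchPair(patch.center, main, context, patch.gt, patch.subject_id)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = axis / np.linalg.norm(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _rotate_block(block: np.ndarray, rot: np.ndarray, order: int) -> np.ndarray:
    center = (np.asarray(block.shape) - 1) / 2.0
    offset = center - rot @ center
    return ndimage.affine_transform(block, rot, offset=offset, order=order,
                                    mode="constant", cval=0.0,
                                    prefilter=(order > 1))


def rotate_patch(patch: PatchPair, axis: np.ndarray, angle_rad: float) -> PatchPair:
    """Rotate all components of a patch about its center: image channel
    linearly interpolated, vessel and label channels nearest-neighbor."""
    rot = _rotation_matrix(axis, angle_rad)
    # affine_transform maps output coords through the matrix; pass inverse
    inv = rot.T
    main = np.stack([_rotate_block(patch.main[0], inv, 1),
                     _rotate_block(patch.main[1], inv, 0)])
    context = np.stack([_rotate_block(patch.context[0], inv, 1),
                        _rotate_block(patch.context[1], inv, 0)])
    gt = _rotate_block(patch.gt, inv, 0)
    return PatchPair(patch.center, main, context, gt, patch.subject_id)


def augment_rotations(patches: list[PatchPair], inflation: int = 3,
                      angle_range_deg: tuple[float, float] = (-60.0, 60.0),
                      seed: int = 0) -> list[PatchPair]:
    """Inflate the training set by random rotations.

    The originals are kept and each patch is independently rotated
    ``inflation - 1`` additional times about a uniformly random axis by an
    angle uniform in ``angle_range_deg``.
    """
    if inflation < 1:
        raise ValueError(f"inflation must be >= 1, got {inflation}")
    if inflation == 1:
        return list(patches)
    rng = np.random.default_rng(seed)
    out = list(patches)
    lo, hi = np.deg2rad(angle_range_deg[0]), np.deg2rad(angle_range_deg[1])
    for _ in range(inflation - 1):
        for p in patches:
            axis = rng.normal(size=3)
            while np.linalg.norm(axis) < 1e-9:
                axis = rng.normal(size=3)
            angle = rng.uniform(lo, hi)
            out.append(rotate_patch(p, axis, angle))
    return out
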