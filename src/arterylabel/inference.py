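"""Whole-volume prediction by patch tiling, and segment washing.

A trained patch classifier is applied across a regular grid of main-size
tiles (stride configurable; overlapping softmax contributions are averaged),
yielding a per-voxel class-probability field for the whole volume.  Segment
washing then sums the softmax scores over each segment of the vessel tree
and assigns the class with the highest total to every voxel of that segment,
enforcing label homogeneity along the tree; voxels outside every segment
keep their plain per-voxel argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid
from .network import MultiScaleUNet
from .patches import ScalingStats, _crop_padded, scale_array

__all__ = ["SoftmaxVolume", "predict_volume", "argmax_labels", "segment_wash",
           "vessel_tile_centers"]


@dataclass
class SoftmaxVolume:
    """Per-voxel class-probability field, channels first: (classes, nx, ny, nz)."""

    probs: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs)
        if self.probs.ndim != 4:
            raise ValueError(f"expected (classes, nx, ny, nz), got {self.probs.shape}")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.probs.shape[1:]

    def validate(self, atol: float = 1e-5) -> None:
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        s = self.probs.sum(axis=0)
        if not np.allclose(s, 1.0, atol=atol):
            raise ValueError("per-voxel probabilities must sum to 1")


def _tile_origins(dim: int, size: int, stride: int) -> list[int]:
    """Origins covering [0, dim): regular stride, plus a final tile flush
    with the border when the stride does not divide evenly."""
    out = list(range(0, max(dim - size, 0) + 1, stride))
    if not out:
        out = [0]
    if out[-1] + size < dim:
        out.append(dim - size)
    return out


def vessel_tile_centers(centerline_coords: np.ndarray, size, shape,
                        margin: int = 4) -> list[tuple[int, int, int]]:
    """Greedy cover of the centerline with main-size tiles.

    Picks centerline voxels as tile centers until every centerline voxel is
    at least ``margin`` voxels inside some tile.  Used to supplement grid
    tiling with patches whose content distribution matches the
    vessel-centered training patches.
    """
    half = np.asarray(size) // 2
    inner = np.maximum(half - margin, 1)
    centers: list[tuple[int, int, int]] = []
    todo = np.ones(len(centerline_coords), dtype=bool)
    coords = np.asarray(centerline_coords)
    while todo.any():
        c = coords[np.flatnonzero(todo)[0]]
        centers.append(tuple(int(v) for v in c))
        covered = np.all(np.abs(coords - c) < inner, axis=1)
        todo &= ~covered
    return centers


def predict_volume(model: MultiScaleUNet, image: VolumeGrid, vessel: VolumeGrid,
                   stats: ScalingStats, stride: tuple[int, int, int] | None = None,
                   channel_idx: list[int] | None = None,
                   extra_centers: list | None = None,
                   batch_size: int = 8) -> SoftmaxVolume:
    """Reconstruct a whole-volume softmax field from patch-wise predictions.

    The volume is covered by a regular grid of main-size tiles (default
    stride = tile size, i.e. non-overlapping); for each tile the concentric
    context patch is extracted with zero padding at borders.  Overlapping
    contributions are averaged.  ``extra_centers`` adds tiles centered on
    the given voxels (e.g. from :func:`vessel_tile_centers`) into the same
    averaging, so vessel regions are predicted from patches that match the
    vessel-centered training distribution.
    """
    if not image.same_grid(vessel):
        raise ValueError("image and vessel volumes must share shape and spacing")
    cfg = model.cfg
    size = cfg.main_input
    stride = tuple(int(s) for s in (stride or size))
    sel = channel_idx if channel_idx is not None else [0, 1]

    img = scale_array(np.asarray(image.data, np.float32), stats, 0)
    ves = scale_array(np.asarray(vessel.data, np.float32), stats, 1)
    chans = [img, ves]
    shape = image.shape

    origins = [(ox, oy, oz)
               for ox in _tile_origins(shape[0], size[0], stride[0])
               for oy in _tile_origins(shape[1], size[1], stride[1])
               for oz in _tile_origins(shape[2], size[2], stride[2])]
    for c in extra_centers or []:
        origins.append(tuple(int(c[i]) - size[i] // 2 for i in range(3)))

    acc = np.zeros((cfg.classes, *shape), dtype=np.float32)
    cnt = np.zeros(shape, dtype=np.float32)
    csize = tuple(2 * s for s in size)

    for start in range(0, len(origins), batch_size):
        batch = origins[start:start + batch_size]
        mains, ctxs = [], []
        for o in batch:
            center = np.asarray(o) + np.asarray(size) // 2
            mains.append(np.stack([_crop_padded(chans[c], center, size) for c in sel], axis=-1))
            if cfg.context_path:
                ctxs.append(np.stack([_crop_padded(chans[c], center, csize) for c in sel], axis=-1))
        probs = model.predict_proba(np.stack(mains),
                                    np.stack(ctxs) if cfg.context_path else None)
        for o, p in zip(batch, probs):
            # clip tiles that poke past the volume (possible for extra centers)
            lo = [max(o[i], 0) for i in range(3)]
            hi = [min(o[i] + size[i], shape[i]) for i in range(3)]
            if any(l >= h for l, h in zip(lo, hi)):
                continue
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            psl = tuple(slice(l - o[i], h - o[i]) for i, (l, h) in enumerate(zip(lo, hi)))
            acc[(slice(None), *sl)] += np.moveaxis(p[psl], -1, 0)
            cnt[sl] += 1.0
    acc /= np.maximum(cnt, 1.0)[None]
    acc /= acc.sum(axis=0, keepdims=True)  # renormalize against float error
    return SoftmaxVolume(acc, image.spacing)


def argmax_labels(probs: SoftmaxVolume) -> VolumeGrid:
    """Per-voxel class with the highest probability; ties break to the
    lowest class index."""
    return VolumeGrid(np.argmax(probs.probs, axis=0).astype(np.int16), probs.spacing)


def segment_wash(probs: SoftmaxVolume, seg_ids: VolumeGrid) -> VolumeGrid:
    """Wash each segment with its highest-total-softmax label.

    For every segment id > 0 the per-class probabilities are summed over the
    segment's voxels and the argmax of the sums (ties to the lowest index)
    is assigned to all of its voxels; voxels with segment id 0 keep their
    plain per-voxel argmax.
    """
    ids = np.asarray(seg_ids.data)
    if ids.shape != probs.grid_shape:
        raise ValueError(f"segment map shape {ids.shape} != probability grid "
                         f"{probs.grid_shape}")
    out = np.argmax(probs.probs, axis=0).astype(np.int16)
    if ids.max(initial=0) > 0:
        K = probs.n_classes
        flat_ids = ids.ravel()
        flat_p = probs.probs.reshape(K, -1)
        n_ids = int(flat_ids.max()) + 1
        sums = np.zeros((n_ids, K))
        for k in range(K):
            sums[:, k] = np.bincount(flat_ids, weights=flat_p[k], minlength=n_ids)
        winner = np.argmax(sums, axis=1).astype(np.int16)
        inside = ids > 0
        out[inside] = winner[ids[inside]]
    return VolumeGrid(out, probs.spacing)
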