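"""Synthetic cerebrovascular phantoms.

Generates labeled Circle-of-Willis-like subjects: a template tree of the 24
named arterial segments (left/right mirrored across the mid-sagittal plane),
per-subject geometric jitter, pathologically missing segments in a
configurable fraction of subjects, tube rasterization into a vessel mask and
ground-truth label volume, and a bright-vessel angiography-like image with a
smooth multiplicative bias field and additive Gaussian noise (emulating raw
scans with no non-uniformity correction or brain extraction).

The default grid is a desk-scale 96 x 96 x 48 at 0.6 x 0.6 x 0.7 mm
(anisotropic, like clinical angiography); a full-scale grid is available
through configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .grid import VolumeGrid
from .taxonomy import NON_ANNOTATED, build_detailed_taxonomy

__all__ = [
    "TreeSegment",
    "VesselTreeSpec",
    "PhantomSubject",
    "GridSpec",
    "DESK_GRID",
    "FULL_GRID",
    "DEFAULT_DROPPABLE",
    "build_template_tree",
    "sample_subject",
    "generate_cohort",
    "study_inclusion",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


#: Desk-scale grid used by default: CPU-friendly, anisotropic voxels.
DESK_GRID = GridSpec((96, 96, 48), (0.6, 0.6, 0.7))
#: Full clinical-resolution grid (config only; not exercised by the tests).
FULL_GRID = GridSpec((312, 384, 127), (0.52, 0.52, 0.65))


# ---------------------------------------------------------------------------
# vessel tree
# ---------------------------------------------------------------------------

@dataclass
class TreeSegment:
    """One arterial segment: a polyline in unit-cube coordinates with a
    per-control-point radius profile in mm."""

    code: str
    class_index: int
    points: np.ndarray        # (n, 3) unit-cube coordinates
    radii_mm: np.ndarray      # (n,) positive

    def copy(self) -> "TreeSegment":
        return TreeSegment(self.code, self.class_index, self.points.copy(), self.radii_mm.copy())


@dataclass
class VesselTreeSpec:
    """A full tree: segments, per-segment presence, and the shared-endpoint
    connectivity implied by exactly coincident polyline endpoints."""

    segments: list[TreeSegment]
    present: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.present:
            self.present = {s.code: True for s in self.segments}

    def segment(self, code: str) -> TreeSegment:
        for s in self.segments:
            if s.code == code:
                return s
        raise KeyError(code)

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self.segments]

    def present_segments(self) -> list[TreeSegment]:
        return [s for s in self.segments if self.present[s.code]]

    def missing_codes(self) -> list[str]:
        return [c for c, p in self.present.items() if not p]

    def connectivity(self) -> list[tuple[str, str]]:
        """Pairs of segment codes that share an endpoint coordinate exactly."""
        out = []
        segs = self.segments
        for i, a in enumerate(segs):
            for b in segs[i + 1:]:
                ea = [a.points[0], a.points[-1]]
                eb = [b.points[0], b.points[-1]]
                if any(np.array_equal(p, q) for p in ea for q in eb):
                    out.append((a.code, b.code))
        return out

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "code": s.code,
                    "class_index": s.class_index,
                    "points": s.points.tolist(),
                    "radii_mm": s.radii_mm.tolist(),
                    "present": bool(self.present[s.code]),
                }
                for s in self.segments
            ]
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


# Template geometry.  Unit-cube coordinates: x left-right (midline x=0.5,
# dexter/right side x<0.5), y posterior-anterior, z inferior-superior.
# Radii in mm, tapering distally.  Shared junction coordinates are written
# once below so connected segments coincide exactly.
_J_ICA_TOP_D = (0.35, 0.45, 0.46)     # ICA / ICA-CoW / PcomA junction
_J_COW_D = (0.40, 0.48, 0.60)         # ICA-CoW / M1 / A1 junction
_J_M1_END_D = (0.16, 0.52, 0.63)      # M1 / M2 sup / M2 inf junction
_J_ACA_D = (0.46, 0.60, 0.65)         # A1 / A2 / AcomA junction
_J_P1_END_D = (0.36, 0.32, 0.55)      # P1 / P2 / PcomA junction
_J_BA_BOT = (0.50, 0.25, 0.26)        # VA confluence / BA origin
_J_BA_TOP = (0.50, 0.28, 0.52)        # basilar tip: BA / P1s


def _mirror(pt: tuple[float, float, float]) -> tuple[float, float, float]:
    return (1.0 - pt[0], pt[1], pt[2])


def _dexter_template() -> list[tuple[str, list[tuple[float, float, float]], list[float]]]:
    return [
        ("ICA", [(0.33, 0.42, 0.06), (0.35, 0.40, 0.22), (0.33, 0.43, 0.35), _J_ICA_TOP_D],
         [2.2, 2.2, 2.1, 2.1]),
        ("ICA-CoW", [_J_ICA_TOP_D, (0.38, 0.47, 0.54), _J_COW_D], [2.0, 2.0, 1.9]),
        ("M1", [_J_COW_D, (0.28, 0.50, 0.62), _J_M1_END_D], [1.7, 1.6, 1.5]),
        ("M2-sup", [_J_M1_END_D, (0.11, 0.55, 0.76), (0.08, 0.60, 0.88)], [1.1, 1.0, 0.9]),
        ("M2-inf", [_J_M1_END_D, (0.09, 0.58, 0.54), (0.05, 0.65, 0.46)], [1.1, 1.0, 0.9]),
        ("A1", [_J_COW_D, (0.43, 0.55, 0.63), _J_ACA_D], [1.3, 1.3, 1.2]),
        ("A2", [_J_ACA_D, (0.45, 0.68, 0.76), (0.45, 0.72, 0.90)], [1.1, 1.0, 0.9]),
        ("VA", [(0.41, 0.26, 0.04), (0.44, 0.25, 0.14), _J_BA_BOT], [1.7, 1.6, 1.6]),
        ("PCOM", [_J_ICA_TOP_D, (0.36, 0.38, 0.50), _J_P1_END_D], [0.8, 0.8, 0.8]),
        ("P1", [_J_BA_TOP, (0.43, 0.30, 0.54), _J_P1_END_D], [1.3, 1.3, 1.2]),
        ("P2", [_J_P1_END_D, (0.27, 0.36, 0.57), (0.19, 0.43, 0.61)], [1.1, 1.0, 0.9]),
    ]


def build_template_tree() -> VesselTreeSpec:
    """The fixed 24-segment template tree in unit-cube coordinates.

    Topology: ICA rises to the ICA-CoW segment which splits into M1 (lateral,
    continuing into M2 sup/inf) and A1 (medial, joined across the midline by
    the AcomA, continuing into A2); both VAs merge into the BA whose tip
    splits into the P1s, each continuing into P2; the PcomA bridges the ICA
    top to the P1/P2 junction.  Left (S-) segments mirror right (D-) ones
    across the mid-sagittal plane.
    """
    tax = build_detailed_taxonomy()
    segments: list[TreeSegment] = []

    def add(code: str, pts, radii) -> None:
        segments.append(TreeSegment(code, tax.index_of(code),
                                    np.asarray(pts, dtype=float),
                                    np.asarray(radii, dtype=float)))

    for code, pts, radii in _dexter_template():
        add(f"D-{code}", pts, radii)
        add(f"S-{code}", [_mirror(p) for p in pts], radii)
    add("ACOM", [_J_ACA_D, (0.50, 0.60, 0.65), _mirror(_J_ACA_D)], [0.8, 0.8, 0.8])
    add("BA", [_J_BA_BOT, (0.50, 0.26, 0.40), _J_BA_TOP], [2.0, 2.0, 1.9])

    order = {c.code: c.index for c in tax.classes}
    segments.sort(key=lambda s: order[s.code])
    return VesselTreeSpec(segments)


#: Common hypoplastic / absent Circle-of-Willis elements.
DEFAULT_DROPPABLE = ("D-PCOM", "S-PCOM", "D-A1", "S-A1", "D-P1", "S-P1", "ACOM")

#: Terminal segments that may carry a distal non-annotated extension.
_TERMINAL = ("D-M2-sup", "S-M2-sup", "D-M2-inf", "S-M2-inf",
             "D-A2", "S-A2", "D-P2", "S-P2")


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

@dataclass
class PhantomSubject:
    subject_id: str
    cohort_tag: str
    seed: int
    image: VolumeGrid
    vessel_mask: VolumeGrid
    gt_labels: VolumeGrid
    tree: VesselTreeSpec

    def missing_codes(self) -> list[str]:
        return self.tree.missing_codes()


def _jitter_tree(tree: VesselTreeSpec, rng: np.random.Generator,
                 extent_mm: np.ndarray, point_sigma_mm: float,
                 radius_sigma: float) -> VesselTreeSpec:
    """Jitter control points (junctions coherently, interiors independently)
    and radii.  Junction coordinates shared between segments stay shared."""
    # one displacement per distinct template coordinate => junctions move as one
    disp: dict[tuple, np.ndarray] = {}

    def displacement(pt: np.ndarray) -> np.ndarray:
        key = tuple(np.round(pt, 10))
        if key not in disp:
            disp[key] = rng.normal(0.0, point_sigma_mm, 3) / extent_mm
        return disp[key]

    out = []
    for seg in tree.segments:
        pts = np.array([p + displacement(p) for p in seg.points])
        radii = seg.radii_mm * np.exp(rng.normal(0.0, radius_sigma, len(seg.radii_mm)))
        out.append(TreeSegment(seg.code, seg.class_index, pts, radii))
    return VesselTreeSpec(out, dict(tree.present))


def _densify(points_mm: np.ndarray, radii: np.ndarray, step_mm: float):
    """Resample a polyline (with linearly interpolated radii) at ~step_mm."""
    pts, rad = [points_mm[0]], [radii[0]]
    for a, b, ra, rb in zip(points_mm[:-1], points_mm[1:], radii[:-1], radii[1:]):
        n = max(int(np.ceil(np.linalg.norm(b - a) / step_mm)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        pts.extend(a + t[:, None] * (b - a))
        rad.extend(ra + t * (rb - ra))
    return np.asarray(pts), np.asarray(rad)


def _nonannotated_extension(seg: TreeSegment, frac: float) -> TreeSegment | None:
    """A short distal continuation of a terminal segment, labeled
    non-annotated, emulating vasculature beyond the labeled territory."""
    if frac <= 0:
        return None
    a, b = seg.points[-2], seg.points[-1]
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        return None
    # straight continuation, frac of the full polyline length, thinner
    length = frac * np.sum(np.linalg.norm(np.diff(seg.points, axis=0), axis=1))
    tip = b + d / n * length
    r = seg.radii_mm[-1]
    return TreeSegment(f"{seg.code}+dist", NON_ANNOTATED,
                       np.array([b, tip]), np.array([r * 0.8, r * 0.5]))


def rasterize_tree(tree: VesselTreeSpec, grid: GridSpec,
                   nonannotated_tail_frac: float = 0.15):
    """Rasterize present segments into a vessel mask and label volume.

    A voxel is vessel if its center lies within the (interpolated) radius of
    the nearest polyline point of any present segment; overlaps at junctions
    resolve to the segment covering the voxel most deeply (largest
    radius - distance).
    """
    extent = grid.extent_mm
    spacing = np.asarray(grid.spacing)
    step = 0.25 * float(spacing.min())

    mask = np.zeros(grid.shape, dtype=np.uint8)
    labels = np.zeros(grid.shape, dtype=np.int16)
    depth = np.full(grid.shape, -np.inf, dtype=np.float32)

    segs = list(tree.present_segments())
    for seg in list(segs):
        if seg.code in _TERMINAL and tree.present.get(seg.code, False):
            ext = _nonannotated_extension(seg, nonannotated_tail_frac)
            if ext is not None:
                segs.append(ext)

    for seg in segs:
        pts_mm, rad = _densify(seg.points * extent, seg.radii_mm, step)
        rmax = float(rad.max())
        lo = np.maximum(np.floor((pts_mm.min(axis=0) - rmax) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((pts_mm.max(axis=0) + rmax) / spacing).astype(int) + 1,
                        grid.shape)
        if np.any(lo >= hi):
            continue
        ax = [np.arange(lo[i], hi[i]) * spacing[i] for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        vox = np.c_[gx.ravel(), gy.ravel(), gz.ravel()]
        dist, idx = cKDTree(pts_mm).query(vox, k=1)
        cover = rad[idx] - dist
        inside = cover > 0
        if not inside.any():
            continue
        sub = tuple((vox[inside] / spacing).round().astype(int).T)
        deeper = cover[inside] > depth[sub]
        sel = tuple(c[deeper] for c in sub)
        depth[sel] = cover[inside][deeper].astype(np.float32)
        labels[sel] = seg.class_index
        mask[sub] = 1

    return mask, labels


def _synthesize_image(mask: np.ndarray, rng: np.random.Generator, *,
                      tissue_level: float = 100.0, vessel_level: float = 220.0,
                      bias_amplitude: float = 0.15, bias_sigma_vox: float = 16.0,
                      noise_sigma: float = 8.0) -> np.ndarray:
    """Bright-blood image: tissue background, brighter flow-like vessels,
    smooth multiplicative bias field, additive Gaussian noise."""
    img = np.where(mask > 0, vessel_level, tissue_level).astype(np.float32)
    bias = gaussian_filter(rng.normal(0.0, 1.0, mask.shape), bias_sigma_vox)
    sd = bias.std()
    if sd > 0:
        bias /= sd
    img *= (1.0 + bias_amplitude * bias).astype(np.float32)
    img += rng.normal(0.0, noise_sigma, mask.shape).astype(np.float32)
    return img


def sample_subject(seed: int, missing_prob: float = 0.8,
                   droppable: tuple[str, ...] = DEFAULT_DROPPABLE,
                   grid: GridSpec = DESK_GRID, *,
                   subject_id: str | None = None, cohort_tag: str = "A",
                   point_sigma_mm: float = 0.8, radius_sigma: float = 0.08,
                   nonannotated_tail_frac: float = 0.15,
                   noise: dict | None = None) -> PhantomSubject:
    """Draw one phantom subject, deterministic given ``seed``.

    With probability ``missing_prob`` the subject has pathologically missing
    segments: a random nonempty subset of ``droppable`` is removed (the
    common hypoplastic Circle-of-Willis elements by default, emulating the
    high prevalence of missing arterial segments in cerebrovascular
    cohorts).
    """
    if not 0.0 <= missing_prob <= 1.0:
        raise ValueError(f"missing_prob must be in [0, 1], got {missing_prob}")
    if any(d < 16 for d in grid.shape):
        raise ValueError(f"grid dims must each be >= 16, got {grid.shape}")

    rng = np.random.default_rng(seed)
    tree = _jitter_tree(build_template_tree(), rng, grid.extent_mm,
                        point_sigma_mm, radius_sigma)

    if droppable and rng.random() < missing_prob:
        keep_drawing = True
        while keep_drawing:
            drop = [c for c in droppable if rng.random() < 0.5]
            keep_drawing = not drop
        for c in drop:
            tree.present[c] = False

    mask, labels = rasterize_tree(tree, grid, nonannotated_tail_frac)
    img = _synthesize_image(mask, rng, **(noise or {}))

    sid = subject_id if subject_id is not None else f"sub-{seed}"
    return PhantomSubject(
        subject_id=sid, cohort_tag=cohort_tag, seed=int(seed),
        image=VolumeGrid(img, grid.spacing),
        vessel_mask=VolumeGrid(mask, grid.spacing),
        gt_labels=VolumeGrid(labels, grid.spacing),
        tree=tree,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def study_inclusion(enrolled_a: int = 82, no_imaging_a: int = 4,
                    low_quality_a: int = 6, processed_b: int = 170) -> dict:
    """Cohort accounting for the emulated two-study design.

    Cohort A emulates a steno-occlusive study: of ``enrolled_a`` patients,
    ``no_imaging_a`` lack angiographic imaging and ``low_quality_a`` are
    excluded for motion artifacts.  Cohort B emulates an acute-stroke study
    with ``processed_b`` fully processed patients.  Returns the included
    counts per cohort and in total.
    """
    a = enrolled_a - no_imaging_a - low_quality_a
    return {"A": a, "B": processed_b, "total": a + processed_b}


def _derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """n distinct per-subject seeds below 2**31 derived from base_seed."""
    ss = np.random.SeedSequence(base_seed)
    seeds = ss.generate_state(2 * n, dtype=np.uint32) % (2 ** 31)
    uniq = pd.unique(seeds)
    while len(uniq) < n:  # vanishingly unlikely
        seeds = np.r_[uniq, ss.generate_state(n, dtype=np.uint32) % (2 ** 31)]
        uniq = pd.unique(seeds)
    return uniq[:n].astype(np.int64)


def generate_cohort(n: int, tag_counts: dict[str, int] | None = None,
                    base_seed: int = 0, grid: GridSpec = DESK_GRID,
                    **subject_kwargs) -> list[PhantomSubject]:
    """Generate ``n`` subjects with per-subject seeds derived from
    ``base_seed`` and cohort tags assigned per ``tag_counts``."""
    if tag_counts is None:
        tag_counts = {"A": n}
    if any(c <= 0 for c in tag_counts.values()) or sum(tag_counts.values()) != n:
        raise ValueError(f"tag counts {tag_counts} must be positive and sum to {n}")
    tags = [t for t, c in tag_counts.items() for _ in range(c)]
    seeds = _derive_seeds(base_seed, n)
    return [
        sample_subject(int(seeds[i]), grid=grid, subject_id=f"sub-{i:03d}",
                       cohort_tag=tags[i], **subject_kwargs)
        for i in range(n)
    ]


def write_cohort(subjects: list[PhantomSubject], out_dir) -> pd.DataFrame:
    """Write per-subject NIfTI volumes + tree JSON and a TSV manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        d = out / s.subject_id
        d.mkdir(exist_ok=True)
        s.image.save(d / "image.nii.gz")
        s.vessel_mask.save(d / "mask.nii.gz")
        s.gt_labels.save(d / "labels.nii.gz")
        s.tree.to_json(d / "tree.json")
        rows.append({"subject_id": s.subject_id, "tag": s.cohort_tag,
                     "seed": s.seed, "missing": ",".join(s.missing_codes())})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
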