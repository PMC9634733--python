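"""Synthetic cohort generator: template topology, missing segments,
rasterization fidelity, determinism, cohort arithmetic."""

import numpy as np
import pytest

from arterylabel.geometry import skeletonize
from arterylabel.phantom import (DESK_GRID, GridSpec, build_template_tree,
                                 generate_cohort, rasterize_tree,
                                 sample_subject, study_inclusion, write_cohort)
from arterylabel.taxonomy import NON_ANNOTATED


def test_template_has_all_24_segments(detailed):
    tree = build_template_tree()
    assert len(tree.segments) == 24
    assert all(tree.present.values())
    assert {s.code for s in tree.segments} == {detailed.code(i) for i in detailed.artery_indices}
    assert all(np.all(s.radii_mm > 0) for s in tree.segments)


def test_template_topology_acom_bridges_aca_junctions():
    tree = build_template_tree()
    acom = tree.segment("ACOM")
    for side, end in (("D", acom.points[0]), ("S", acom.points[-1])):
        a1 = tree.segment(f"{side}-A1")
        a2 = tree.segment(f"{side}-A2")
        assert np.array_equal(end, a1.points[-1])
        assert np.array_equal(end, a2.points[0])


def test_template_m2_radii_not_exceeding_m1():
    tree = build_template_tree()
    for side in "DS":
        m1 = tree.segment(f"{side}-M1").radii_mm
        for branch in ("M2-sup", "M2-inf"):
            assert tree.segment(f"{side}-{branch}").radii_mm.max() <= m1.max()


def test_template_left_right_mirror():
    tree = build_template_tree()
    for code in ("ICA", "M1", "A1", "P2", "VA"):
        d = tree.segment(f"D-{code}")
        s = tree.segment(f"S-{code}")
        mirrored = d.points.copy()
        mirrored[:, 0] = 1.0 - mirrored[:, 0]
        np.testing.assert_allclose(s.points, mirrored)
        np.testing.assert_allclose(s.radii_mm, d.radii_mm)


def test_connected_segments_share_endpoints():
    tree = build_template_tree()
    pairs = tree.connectivity()
    assert ("D-ICA", "D-ICA-CoW") in pairs or ("D-ICA-CoW", "D-ICA") in pairs
    assert len(pairs) >= 20


def test_no_dropping_keeps_all_labels(subject_complete, detailed):
    present = set(np.unique(subject_complete.gt_labels.data))
    assert set(detailed.artery_indices) <= present


def test_forced_dropping_removes_labels(detailed):
    droppable = ("D-PCOM", "S-PCOM")
    s = sample_subject(seed=3, missing_prob=1.0, droppable=droppable)
    missing = s.missing_codes()
    assert missing and set(missing) <= set(droppable)
    present = set(np.unique(s.gt_labels.data))
    for code in missing:
        assert detailed.index_of(code) not in present


def test_same_seed_bit_identical():
    a = sample_subject(seed=42)
    b = sample_subject(seed=42)
    np.testing.assert_array_equal(a.image.data, b.image.data)
    np.testing.assert_array_equal(a.gt_labels.data, b.gt_labels.data)
    assert a.missing_codes() == b.missing_codes()


def test_labels_cover_exactly_the_mask(subject_complete, subject_missing):
    for s in (subject_complete, subject_missing):
        np.testing.assert_array_equal(np.asarray(s.gt_labels.data) > 0,
                                      np.asarray(s.vessel_mask.data) > 0)
        assert s.image.shape == s.vessel_mask.shape == s.gt_labels.shape


def test_vessel_brighter_than_background(subject_complete):
    img = np.asarray(subject_complete.image.data)
    mask = np.asarray(subject_complete.vessel_mask.data) > 0
    assert img[mask].mean() >= img[~mask].mean() + 2 * img[~mask].std()


def test_gt_constant_per_tree_segment(subject_complete):
    """Ground truth restricted to one tree segment is a single label
    (checked at each segment's deep-interior sample points)."""
    s = subject_complete
    extent = np.asarray(DESK_GRID.extent_mm)
    spacing = np.asarray(DESK_GRID.spacing)
    gt = np.asarray(s.gt_labels.data)
    for seg in s.tree.segments:
        pts = seg.points * extent
        # keep sample points well clear of both junctions, where a thin
        # vessel can run inside a thicker one's lumen
        clearance = max(2.0, 2.0 * float(seg.radii_mm.max()))
        arc = np.r_[0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        t = np.linspace(0, arc[-1], 20)
        interior = (t > clearance) & (t < arc[-1] - clearance)
        if not interior.any():
            continue
        samples = np.stack([np.interp(t[interior], arc, pts[:, a]) for a in range(3)], 1)
        vox = np.clip(np.round(samples / spacing).astype(int), 0,
                      np.asarray(DESK_GRID.shape) - 1)
        labels = {gt[tuple(v)] for v in vox} - {0}
        assert len(labels) <= 1


def test_rasterized_radius_matches_spec():
    """EDT radius at the centerline of a straight isolated tube is within
    one voxel of the requested radius."""
    from arterylabel.phantom import TreeSegment, VesselTreeSpec
    grid = GridSpec((48, 24, 24), (1.0, 1.0, 1.0))
    seg = TreeSegment("D-M1", 6, np.array([[0.1, 0.5, 0.5], [0.9, 0.5, 0.5]]),
                      np.array([4.0, 4.0]))
    mask, labels = rasterize_tree(VesselTreeSpec([seg]), grid,
                                  nonannotated_tail_frac=0.0)
    assert mask.sum() > 0
    cl = skeletonize(
        __import__("arterylabel.grid", fromlist=["VolumeGrid"]).VolumeGrid(mask, grid.spacing))
    mid = (cl.coords[:, 0] > 10) & (cl.coords[:, 0] < 38)
    assert np.all(np.abs(cl.radius_mm[mid] - 4.0) <= 1.0)


def test_nonannotated_extensions_present(subject_complete):
    assert NON_ANNOTATED in np.unique(subject_complete.gt_labels.data)


def test_cohort_sizes_and_tags():
    subs = generate_cohort(20, {"A": 8, "B": 12}, base_seed=5)
    assert len(subs) == 20
    tags = [s.cohort_tag for s in subs]
    assert tags.count("A") == 8 and tags.count("B") == 12
    assert len({s.seed for s in subs}) == 20
    assert len({s.subject_id for s in subs}) == 20


def test_cohort_invalid_tag_counts_rejected():
    with pytest.raises(ValueError):
        generate_cohort(5, {"A": 2, "B": 2}, base_seed=0)


def test_two_subjects_distinct_trees():
    a, b = generate_cohort(2, {"A": 2}, base_seed=9)
    assert a.seed != b.seed
    pa = a.tree.segment("D-M1").points
    pb = b.tree.segment("D-M1").points
    assert not np.allclose(pa, pb)


def test_study_inclusion_arithmetic():
    inc = study_inclusion()
    assert inc == {"A": 72, "B": 170, "total": 242}
    assert study_inclusion(enrolled_a=10, no_imaging_a=1, low_quality_a=2,
                           processed_b=5)["total"] == 12


def test_write_cohort_manifest(tmp_path):
    subs = generate_cohort(2, {"A": 2}, base_seed=3)
    manifest = write_cohort(subs, tmp_path)
    assert len(manifest) == 2
    assert (tmp_path / "manifest.tsv").exists()
    d = tmp_path / subs[0].subject_id
    for f in ("image.nii.gz", "mask.nii.gz", "labels.nii.gz", "tree.json"):
        assert (d / f).exists()
    from arterylabel.grid import VolumeGrid
    back = VolumeGrid.load(d / "labels.nii.gz")
    np.testing.assert_array_equal(back.data, subs[0].gt_labels.data)


def test_grid_too_small_rejected():
    with pytest.raises(ValueError, match="16"):
        sample_subject(seed=0, grid=GridSpec((8, 32, 32), (1, 1, 1)))


def test_bad_missing_prob_rejected():
    with pytest.raises(ValueError, match="missing_prob"):
        sample_subject(seed=0, missing_prob=1.5)
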