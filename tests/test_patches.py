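"""Fold splitting, patch extraction, scaling, augmentation."""

import numpy as np
import pytest

from arterylabel.geometry import Segment, SegmentTable
from arterylabel.grid import VolumeGrid
from arterylabel.patches import (ScalingStats, apply_scaling, augment_rotations,
                                 extract_dual_patch, fit_scaling, make_folds,
                                 sample_patch_centers, scale_array)


def subjects_with_tags(n_a, n_b):
    return ([(f"a{i}", "A") for i in range(n_a)]
            + [(f"b{i}", "B") for i in range(n_b)])


def test_study_sized_fold_arithmetic():
    split = make_folds(subjects_with_tags(72, 170), k=4, seed=0)
    for train, test in split.folds:
        assert len(train) == 182 and len(test) == 60
        tags = [split.strata[s] for s in test]
        assert tags.count("A") == 18 and tags.count("B") == 42
        assert not set(train) & set(test)


def test_test_sets_disjoint_and_leftovers_always_train():
    subs = subjects_with_tags(9, 13)   # leftovers: 9 mod 4 = 1, 13 mod 4 = 1
    split = make_folds(subs, k=4, seed=1)
    all_test = [s for _tr, te in split.folds for s in te]
    assert len(all_test) == len(set(all_test))
    leftovers = set(s for s, _t in subs) - set(all_test)
    assert len(leftovers) == 2
    for train, _test in split.folds:
        assert leftovers <= set(train)


def test_small_stratified_folds():
    split = make_folds(subjects_with_tags(8, 12), k=4, seed=3)
    for _train, test in split.folds:
        tags = [split.strata[s] for s in test]
        assert tags.count("A") == 2 and tags.count("B") == 3


def test_leave_one_out_fold():
    split = make_folds([(f"s{i}", "A") for i in range(4)], k=4, seed=0)
    for train, test in split.folds:
        assert len(test) == 1 and len(train) == 3


def test_folds_reproducible_and_seed_sensitive(tmp_path):
    subs = subjects_with_tags(8, 8)
    a = make_folds(subs, 4, seed=5)
    b = make_folds(subs, 4, seed=5)
    assert a.folds == b.folds
    c = make_folds(subs, 4, seed=6)
    assert a.folds != c.folds
    path = tmp_path / "folds.json"
    a.to_json(path)
    from arterylabel.patches import FoldSplit
    assert FoldSplit.from_json(path).folds == a.folds


def test_stratum_smaller_than_k_rejected():
    with pytest.raises(ValueError, match="stratum"):
        make_folds(subjects_with_tags(3, 8), k=4, seed=0)


def table_with_segment(n_voxels, shape=(64, 8, 8)):
    vox = np.c_[np.arange(n_voxels), np.zeros(n_voxels, int), np.zeros(n_voxels, int)]
    return SegmentTable([Segment(1, vox, ("end", "end"))], [], shape, (1, 1, 1))


def test_sample_eight_centers_per_segment():
    centers = sample_patch_centers(table_with_segment(50), per_segment=8, seed=0)
    assert len(centers) == 8
    assert len({tuple(c) for c in centers}) == 8  # without replacement


def test_short_segment_uses_all_voxels():
    centers = sample_patch_centers(table_with_segment(5), per_segment=8, seed=0)
    assert len(centers) == 5


def test_empty_table_no_centers():
    table = SegmentTable([], [], (8, 8, 8), (1, 1, 1))
    assert sample_patch_centers(table, 8, 0) == []


def grids(shape=(24, 24, 16)):
    rng = np.random.default_rng(0)
    img = VolumeGrid(rng.normal(100, 10, shape).astype(np.float32))
    ves = VolumeGrid(np.zeros(shape, dtype=np.float32))
    ves.data[12, 12, 8] = 2.5
    gt = VolumeGrid(rng.integers(0, 5, shape).astype(np.int16))
    return img, ves, gt


def test_interior_patch_equals_direct_crop():
    img, ves, gt = grids()
    p = extract_dual_patch(img, ves, gt, (12, 12, 8), (8, 8, 4), (16, 16, 8))
    np.testing.assert_array_equal(p.main[0], np.asarray(img.data)[8:16, 8:16, 6:10])
    np.testing.assert_array_equal(p.gt, np.asarray(gt.data)[8:16, 8:16, 6:10])
    np.testing.assert_array_equal(
        p.context[0], np.asarray(img.data)[4:20, 4:20, 4:12])


def test_corner_patch_zero_padded_exactly():
    img, ves, gt = grids()
    size = (8, 8, 4)
    p = extract_dual_patch(img, ves, gt, (0, 0, 0), size, (16, 16, 8))
    # brute-force oracle: pad the whole volume then crop
    pad = np.pad(np.asarray(img.data, np.float32), [(8, 8), (8, 8), (4, 4)])
    lo = np.array([0, 0, 0]) + np.array([8, 8, 4]) - np.array(size) // 2
    expect = pad[lo[0]:lo[0] + 8, lo[1]:lo[1] + 8, lo[2]:lo[2] + 4]
    np.testing.assert_array_equal(p.main[0], expect)
    # out-of-volume region is exactly the zero region
    assert p.main[0][:4, :, :].sum() == 0 or np.all(p.main[0][:4] == expect[:4])


def test_patch_center_on_centerline_has_positive_vessel_value():
    img, ves, gt = grids()
    p = extract_dual_patch(img, ves, gt, (12, 12, 8), (8, 8, 4), (16, 16, 8))
    assert p.main[1][4, 4, 2] > 0


def test_center_outside_grid_rejected():
    img, ves, gt = grids()
    with pytest.raises(ValueError, match="outside"):
        extract_dual_patch(img, ves, gt, (30, 0, 0), (8, 8, 4), (16, 16, 8))


def test_context_must_be_twice_main():
    img, ves, gt = grids()
    with pytest.raises(ValueError, match="2 x main"):
        extract_dual_patch(img, ves, gt, (12, 12, 8), (8, 8, 4), (12, 12, 8))


def test_scaling_linear_map_and_clipping():
    stats = ScalingStats(np.array([0.0, 0.0]), np.array([100.0, 4.0]))
    assert scale_array(np.array(50.0), stats, 0) == pytest.approx(0.5)
    assert scale_array(np.array(120.0), stats, 0) == 1.0     # clipped
    assert scale_array(np.array(-5.0), stats, 0) == 0.0
    assert scale_array(np.array(0.0), stats, 1) == 0.0       # fixed point


def test_fit_scaling_over_training_volumes():
    img1 = VolumeGrid(np.full((4, 4, 4), 10.0))
    img2 = VolumeGrid(np.full((4, 4, 4), 90.0))
    ves = VolumeGrid(np.linspace(0, 3, 64).reshape(4, 4, 4))
    stats = fit_scaling([(img1, ves), (img2, ves)])
    assert stats.minimum[0] == 10.0 and stats.maximum[0] == 90.0
    assert stats.maximum[1] == pytest.approx(3.0)


def test_degenerate_channel_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        ScalingStats(np.array([1.0, 0.0]), np.array([1.0, 5.0]))


def test_apply_scaling_to_patch():
    img, ves, gt = grids()
    p = extract_dual_patch(img, ves, gt, (12, 12, 8), (8, 8, 4), (16, 16, 8))
    stats = ScalingStats(np.array([80.0, 0.0]), np.array([120.0, 2.5]))
    q = apply_scaling(p, stats)
    assert q.main.min() >= 0.0 and q.main.max() <= 1.0
    assert q.main[1].max() == pytest.approx(1.0)  # the 2.5 mm radius voxel


def patch_list(n=4):
    img, ves, gt = grids()
    return [extract_dual_patch(img, ves, gt, (12, 12, 8), (8, 8, 4), (16, 16, 8))
            for _ in range(n)]


def test_augmentation_inflates_three_times_keeping_originals():
    patches = patch_list(10)
    out = augment_rotations(patches, inflation=3, seed=0)
    assert len(out) == 30
    for orig, kept in zip(patches, out[:10]):
        np.testing.assert_array_equal(orig.main, kept.main)
        np.testing.assert_array_equal(orig.gt, kept.gt)


def test_augmentation_noop_at_inflation_one():
    patches = patch_list(3)
    out = augment_rotations(patches, inflation=1, seed=0)
    assert len(out) == 3


def test_rotation_cannot_invent_labels():
    patches = patch_list(5)
    out = augment_rotations(patches, inflation=3, seed=1)
    orig_labels = set(np.unique(patches[0].gt)) | {0}
    for p in out[5:]:
        assert set(np.unique(p.gt)) <= orig_labels


def test_rotated_copies_differ_from_originals():
    patches = patch_list(2)
    out = augment_rotations(patches, inflation=2, seed=2)
    assert not np.array_equal(out[2].main[0], patches[0].main[0])
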