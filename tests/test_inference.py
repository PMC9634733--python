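"""Whole-volume tiling prediction and segment washing."""

import numpy as np
import pytest

from arterylabel.geometry import extract_segments, segment_id_volume, skeletonize
from arterylabel.grid import VolumeGrid
from arterylabel.inference import (SoftmaxVolume, argmax_labels, predict_volume,
                                   segment_wash, _tile_origins)
from arterylabel.network import ModelConfig, build_network
from arterylabel.patches import ScalingStats


def random_softmax(rng, K, shape):
    p = rng.uniform(0.01, 1.0, (K, *shape))
    return SoftmaxVolume(p / p.sum(0, keepdims=True), (1.0, 1.0, 1.0))


def test_argmax_matches_brute_force():
    rng = np.random.default_rng(0)
    probs = random_softmax(rng, 5, (6, 5, 4))
    out = np.asarray(argmax_labels(probs).data)
    for v in np.ndindex(6, 5, 4):
        assert out[v] == int(np.argmax(probs.probs[(slice(None), *v)]))


def test_argmax_tie_breaks_to_lowest_index():
    p = np.full((8, 2, 2, 2), 1 / 8.0)
    p[3] = p[7] = 0.25
    p[0] = 1 - p[1:].sum(0)
    probs = SoftmaxVolume(p / p.sum(0), (1, 1, 1))
    p2 = probs.probs
    np.testing.assert_allclose(p2[3], p2[7])
    assert np.all(np.asarray(argmax_labels(probs).data) == 3)


def test_one_hot_argmax():
    p = np.zeros((4, 2, 2, 2))
    p[2] = 1.0
    assert np.all(np.asarray(argmax_labels(SoftmaxVolume(p, (1, 1, 1))).data) == 2)


def test_washing_three_voxel_example():
    """Sum-and-argmax: rows (0.6,0.4), (0.4,0.6), (0.45,0.55) -> class 2."""
    p = np.zeros((3, 3, 1, 1))
    p[:, 0, 0, 0] = [0.0, 0.6, 0.4]
    p[:, 1, 0, 0] = [0.0, 0.4, 0.6]
    p[:, 2, 0, 0] = [0.0, 0.45, 0.55]
    seg = VolumeGrid(np.ones((3, 1, 1), np.int32))
    out = segment_wash(SoftmaxVolume(p, (1, 1, 1)), seg)
    assert np.all(np.asarray(out.data) == 2)


def test_washing_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        probs = random_softmax(rng, 6, (8, 8, 4))
        ids = VolumeGrid(rng.integers(0, 4, (8, 8, 4)).astype(np.int32))
        out = np.asarray(segment_wash(probs, ids).data)
        # explicit loop oracle
        expect = np.argmax(probs.probs, axis=0)
        for sid in range(1, 4):
            sel = np.asarray(ids.data) == sid
            if not sel.any():
                continue
            sums = [probs.probs[k][sel].sum() for k in range(6)]
            expect[sel] = int(np.argmax(sums))
        np.testing.assert_array_equal(out, expect)


def test_washing_homogeneous_and_idempotent():
    rng = np.random.default_rng(2)
    probs = random_softmax(rng, 5, (10, 8, 4))
    ids = VolumeGrid((rng.integers(0, 5, (10, 8, 4))).astype(np.int32))
    washed = segment_wash(probs, ids)
    data = np.asarray(washed.data)
    for sid in np.unique(ids.data):
        if sid == 0:
            continue
        assert len(np.unique(data[np.asarray(ids.data) == sid])) == 1
    # idempotence: wash the one-hot encoding of the washed result
    onehot = np.zeros_like(probs.probs)
    for k in range(5):
        onehot[k][data == k] = 1.0
    again = segment_wash(SoftmaxVolume(onehot, (1, 1, 1)), ids)
    np.testing.assert_array_equal(np.asarray(again.data), data)


def test_washing_keeps_argmax_outside_segments():
    rng = np.random.default_rng(3)
    probs = random_softmax(rng, 4, (6, 6, 4))
    ids = np.zeros((6, 6, 4), np.int32)
    ids[:3] = 1
    out = np.asarray(segment_wash(probs, VolumeGrid(ids)).data)
    plain = np.asarray(argmax_labels(probs).data)
    np.testing.assert_array_equal(out[3:], plain[3:])


def test_washing_noop_on_agreement():
    p = np.zeros((3, 4, 1, 1))
    p[2] = 0.9
    p[0] = 0.1
    ids = VolumeGrid(np.ones((4, 1, 1), np.int32))
    out = segment_wash(SoftmaxVolume(p / p.sum(0), (1, 1, 1)), ids)
    assert np.all(np.asarray(out.data) == 2)


def test_softmax_volume_validation():
    p = np.full((2, 2, 2, 2), 0.5)
    SoftmaxVolume(p, (1, 1, 1)).validate()
    with pytest.raises(ValueError, match="sum"):
        SoftmaxVolume(p * 0.7, (1, 1, 1)).validate()
    with pytest.raises(ValueError, match="non-negative"):
        bad = p.copy(); bad[0, 0, 0, 0] = -0.1; bad[1, 0, 0, 0] = 1.1
        SoftmaxVolume(bad, (1, 1, 1)).validate()


def test_tile_origins_cover_and_flush():
    assert _tile_origins(96, 32, 32) == [0, 32, 64]
    assert _tile_origins(40, 32, 32) == [0, 8]        # flush final tile
    assert _tile_origins(96, 32, 16) == [0, 16, 32, 48, 64]
    assert _tile_origins(16, 32, 32) == [0]


SMALL = dict(main_input=(8, 8, 4), context_input=(16, 16, 8), channels=2,
             classes=4, base_filters=2, depth=2)


def small_model_and_volumes(shape=(16, 16, 8)):
    model = build_network(ModelConfig(**SMALL), seed=0)
    rng = np.random.default_rng(4)
    img = VolumeGrid(rng.normal(100, 10, shape).astype(np.float32))
    ves = VolumeGrid(rng.uniform(0, 2, shape).astype(np.float32))
    stats = ScalingStats(np.array([50.0, 0.0]), np.array([150.0, 2.0]))
    return model, img, ves, stats


def test_exact_tiling_predicts_each_voxel_once():
    model, img, ves, stats = small_model_and_volumes()
    probs = predict_volume(model, img, ves, stats)
    probs.validate()
    # compare one tile against a direct patch prediction
    from arterylabel.patches import extract_dual_patch, apply_scaling
    center = np.array([4, 4, 2])
    p = apply_scaling(extract_dual_patch(img, ves, None, center, (8, 8, 4), (16, 16, 8)),
                      stats)
    direct = model.predict_proba(p.main.transpose(1, 2, 3, 0)[None],
                                 p.context.transpose(1, 2, 3, 0)[None])[0]
    np.testing.assert_allclose(probs.probs[:, :8, :8, :4],
                               np.moveaxis(direct, -1, 0), atol=1e-5)


def test_overlapping_tiles_average():
    model, img, ves, stats = small_model_and_volumes()
    half = predict_volume(model, img, ves, stats, stride=(4, 4, 2))
    half.validate()
    full = predict_volume(model, img, ves, stats)
    full.validate()
    assert half.probs.shape == full.probs.shape


def test_grid_mismatch_rejected():
    model, img, ves, stats = small_model_and_volumes()
    bad = VolumeGrid(np.zeros((16, 16, 9), np.float32))
    with pytest.raises(ValueError, match="share"):
        predict_volume(model, img, bad, stats)


def test_wash_pipeline_on_phantom(subject_complete):
    """Washing a phantom's ground-truth one-hot field reproduces per-segment
    majority labels and is segment-homogeneous."""
    cl = skeletonize(subject_complete.vessel_mask)
    table = extract_segments(cl)
    seg_ids = segment_id_volume(table, subject_complete.vessel_mask)
    gt = np.asarray(subject_complete.gt_labels.data)
    K = int(gt.max()) + 1
    onehot = np.zeros((K, *gt.shape), dtype=np.float32)
    for k in range(K):
        onehot[k][gt == k] = 1.0
    washed = segment_wash(SoftmaxVolume(onehot, subject_complete.gt_labels.spacing),
                          seg_ids)
    data = np.asarray(washed.data)
    ids = np.asarray(seg_ids.data)
    for sid in np.unique(ids[ids > 0]):
        labels = np.unique(data[ids == sid])
        assert len(labels) == 1
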