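"""Classifier construction, training mechanics, conv-engine parity, and the
random-forest baseline."""

import numpy as np
import pytest

from arterylabel import nn
from arterylabel.grid import VolumeGrid
from arterylabel.network import (ModelConfig, TrainConfig, build_network,
                                 rf_baseline, train)
from arterylabel.patches import PatchPair

SMALL = dict(main_input=(8, 8, 4), context_input=(16, 16, 8), channels=2,
             classes=5, base_filters=2, depth=2)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


def toy_batch(rng, B=2, classes=5):
    xm = rng.normal(size=(B, 8, 8, 4, 2)).astype(np.float32)
    xc = rng.normal(size=(B, 16, 16, 8, 2)).astype(np.float32)
    y = rng.integers(0, classes, size=(B, 8, 8, 4))
    return xm, xc, y


def test_probabilities_sum_to_one(rng):
    model = build_network(ModelConfig(**SMALL), seed=0)
    xm, xc, _ = toy_batch(rng)
    p = model.predict_proba(xm, xc)
    assert p.shape == (2, 8, 8, 4, 5)
    np.testing.assert_allclose(p.sum(-1), 1.0, atol=1e-5)
    assert np.all(p >= 0)


def test_context_off_accepts_main_only(rng):
    cfg = ModelConfig(**{**SMALL, "context_path": False})
    model = build_network(cfg, seed=0)
    xm, _, _ = toy_batch(rng)
    p = model.predict_proba(xm)
    assert p.shape == (2, 8, 8, 4, 5)


def test_context_path_increases_parameters():
    with_ctx = build_network(ModelConfig(**SMALL), seed=0)
    without = build_network(ModelConfig(**{**SMALL, "context_path": False}), seed=0)
    assert with_ctx.n_parameters > without.n_parameters


def test_inconsistent_dims_rejected():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(main_input=(10, 8, 4), context_input=(20, 16, 8), depth=2)
    with pytest.raises(ValueError, match="2 x main"):
        ModelConfig(main_input=(8, 8, 4), context_input=(16, 16, 16), depth=2)


def test_gradient_step_decreases_loss(rng):
    model = build_network(ModelConfig(**SMALL), seed=1)
    xm, xc, y = toy_batch(rng, B=4)
    opt = nn.Adam(model.params(), lr=1e-3)
    opt.zero_grad()
    l0 = model.loss_and_grads(xm, xc, y)
    for _ in range(15):
        opt.step()
        opt.zero_grad()
        l1 = model.loss_and_grads(xm, xc, y)
    assert l1 < l0


def test_l2_penalty_is_exact_weight_norm_sum():
    cfg = ModelConfig(**{**SMALL, "l2_weight": 1e-3})
    model = build_network(cfg, seed=2)
    direct = 1e-3 * sum(float(np.sum(p.value.astype(np.float64) ** 2))
                        for p in model.params() if p.is_kernel)
    assert model.l2_penalty() == pytest.approx(direct, rel=1e-12)
    cfg0 = ModelConfig(**{**SMALL, "l2_weight": 0.0})
    assert build_network(cfg0, seed=2).l2_penalty() == 0.0


def test_disabling_l2_changes_loss_by_penalty(rng):
    xm, xc, y = toy_batch(rng)
    losses = {}
    for w in (0.0, 1e-3):
        model = build_network(ModelConfig(**{**SMALL, "l2_weight": w}), seed=3)
        for p in model.params():
            p.zero_grad()
        losses[w] = model.loss_and_grads(xm, xc, y)
    model = build_network(ModelConfig(**{**SMALL, "l2_weight": 1e-3}), seed=3)
    assert losses[1e-3] - losses[0.0] == pytest.approx(model.l2_penalty(), rel=1e-4)


def test_conv_backends_agree(rng):
    x = rng.normal(size=(2, 6, 6, 4, 3)).astype(np.float32)
    gy = rng.normal(size=(2, 6, 6, 4, 5)).astype(np.float32)
    a = nn.Conv3D(np.random.default_rng(9), 3, 5, 3, backend="numba")
    b = nn.Conv3D(np.random.default_rng(9), 3, 5, 3, backend="numpy")
    np.testing.assert_allclose(a.forward(x), b.forward(x), atol=1e-5)
    np.testing.assert_allclose(a.backward(gy), b.backward(gy), atol=1e-5)
    np.testing.assert_allclose(a.W.grad, b.W.grad, atol=1e-4)
    np.testing.assert_allclose(a.b.grad, b.b.grad, atol=1e-4)


def test_model_gradients_match_finite_differences(rng):
    """Directional derivative along the analytic gradient matches the
    observed loss decrease."""
    model = build_network(ModelConfig(**SMALL), seed=0)
    xm, xc, y = toy_batch(rng)
    for p in model.params():
        p.zero_grad()
    l0 = model.loss_and_grads(xm, xc, y)
    grads = [p.grad.copy() for p in model.params()]
    gnorm2 = sum(float((g ** 2).sum()) for g in grads)
    eps = 1e-3 / np.sqrt(gnorm2)
    for p, g in zip(model.params(), grads):
        p.value -= (eps * g).astype(np.float32)
    for p in model.params():
        p.zero_grad()
    l1 = model.loss_and_grads(xm, xc, y)
    drop = l0 - l1
    assert drop == pytest.approx(eps * gnorm2, rel=0.15)


def test_training_reproducible_given_seed(rng):
    xm, xc, y = toy_batch(rng, B=6)
    patches = [PatchPair(np.zeros(3, int), xm[i].transpose(3, 0, 1, 2),
                         xc[i].transpose(3, 0, 1, 2), y[i]) for i in range(6)]
    traces = []
    for _ in range(2):
        model = build_network(ModelConfig(**SMALL), seed=4)
        _, hist = train(model, patches, None,
                        TrainConfig(epochs=2, batch_size=3, seed=11))
        traces.append(hist.train_loss.tolist())
    assert traces[0] == traces[1]


def test_overfit_single_patch(rng):
    """A couple hundred steps on one patch reach high training accuracy."""
    main = np.zeros((2, 8, 8, 4), np.float32)
    main[0] = rng.normal(0.5, 0.1, (8, 8, 4))
    main[1, 2:6, 2:6, 1:3] = 0.8
    gt = np.zeros((8, 8, 4), np.int16)
    gt[2:6, 2:6, 1:3] = 3
    patch = PatchPair(np.zeros(3, int), main, np.zeros((2, 16, 16, 8), np.float32), gt)
    model = build_network(ModelConfig(**SMALL), seed=5)
    model, _ = train(model, [patch], None, TrainConfig(epochs=200, batch_size=1, seed=0))
    pred = np.argmax(model.predict_proba(main.transpose(1, 2, 3, 0)[None],
                                         patch.context.transpose(1, 2, 3, 0)[None]), -1)[0]
    assert (pred == gt).mean() > 0.95


def test_empty_training_set_rejected():
    model = build_network(ModelConfig(**SMALL), seed=0)
    with pytest.raises(ValueError, match="empty"):
        train(model, [], None, TrainConfig(epochs=1))


def test_checkpoint_round_trip(tmp_path, rng):
    model = build_network(ModelConfig(**SMALL), seed=6)
    xm, xc, _ = toy_batch(rng)
    before = model.predict_proba(xm, xc)
    path = tmp_path / "weights.npz"
    model.save_weights(path)
    other = build_network(ModelConfig(**SMALL), seed=999)
    other.load_weights(path)
    np.testing.assert_allclose(other.predict_proba(xm, xc), before, atol=1e-6)


# -- random-forest baseline --------------------------------------------------

def rf_subject(rng, label=2):
    img = VolumeGrid(rng.normal(100, 5, (12, 12, 8)).astype(np.float32))
    ves = VolumeGrid(np.zeros((12, 12, 8), np.float32))
    gt = np.zeros((12, 12, 8), np.int16)
    gt[3:9, 3:9, 2:6] = label
    img.data[gt > 0] += 100
    ves.data[6, 6, 4] = 2.0
    return img, ves, VolumeGrid(gt)


def test_rf_default_settings(rng):
    clf = rf_baseline([rf_subject(rng)], per_class_voxels=20, seed=0)
    assert clf.forest.n_estimators == 50


def test_rf_single_class_predicts_it_everywhere(rng):
    img = VolumeGrid(rng.normal(100, 5, (8, 8, 4)).astype(np.float32))
    ves = VolumeGrid(np.zeros((8, 8, 4), np.float32))
    gt = VolumeGrid(np.full((8, 8, 4), 7, np.int16))
    clf = rf_baseline([(img, ves, gt)], per_class_voxels=10, seed=0)
    out = clf.predict_labels(img, ves)
    assert set(np.unique(out.data)) == {7}


def test_rf_separable_toy_high_accuracy(rng):
    subjects = [rf_subject(rng) for _ in range(3)]
    clf = rf_baseline(subjects, per_class_voxels=100, trees=50, seed=0)
    img, ves, gt = rf_subject(rng)
    pred = np.asarray(clf.predict_labels(img, ves).data)
    g = np.asarray(gt.data)
    recalls = [np.mean(pred[g == c] == c) for c in (0, 2)]
    assert np.mean(recalls) > 0.95


def test_rf_invalid_sample_count_rejected(rng):
    with pytest.raises(ValueError, match="per_class_voxels"):
        rf_baseline([rf_subject(rng)], per_class_voxels=0)
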