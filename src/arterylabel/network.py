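"""The multi-scale voxel classifier and its training loop, plus a
random-forest voxel baseline.

The network is an encoder-decoder over the main patch with an optional
parallel *context* encoder: the context patch (twice the main extent per
axis) is average-downsampled by two at entry, encoded by a twin encoder, and
its bottleneck features are concatenated with the main encoder's before
decoding.  Skip connections come from the main encoder only; optional deep
supervision adds auxiliary softmax heads at intermediate decoder levels.
Two 3 x 3 x 3 convolutions per resolution level, max pooling by 2,
transposed-convolution up-sampling, filter counts doubling with depth from
``base_filters``, Glorot-uniform initialization, Adam, categorical
cross-entropy, and an L2 penalty on convolutional kernels (no dropout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import nn
from .grid import VolumeGrid
from .patches import PatchPair
from .taxonomy import BACKGROUND, NON_ANNOTATED

__all__ = [
    "ModelConfig", "TrainConfig", "MultiScaleUNet", "build_network", "train",
    "RFVoxelClassifier", "rf_baseline",
]

logger = logging.getLogger(__name__)

#: Deep-supervision loss weights, finest auxiliary head first.
AUX_WEIGHTS = (1.0, 0.5, 0.25)


@dataclass
class ModelConfig:
    main_input: tuple[int, int, int] = (32, 32, 16)
    context_input: tuple[int, int, int] = (64, 64, 32)
    channels: int = 2
    classes: int = 13
    base_filters: int = 4
    depth: int = 3
    l2_weight: float = 1e-3
    deep_supervision: bool = True
    context_path: bool = True
    normalization: str = "encoder"    # "instance" | "encoder" | "none"

    def __post_init__(self) -> None:
        self.main_input = tuple(int(s) for s in self.main_input)
        self.context_input = tuple(int(s) for s in self.context_input)
        for s in self.main_input:
            if s % (2 ** self.depth):
                raise ValueError(
                    f"main input dims {self.main_input} must be divisible by "
                    f"2^depth = {2 ** self.depth}")
        if self.context_path and self.context_input != tuple(2 * s for s in self.main_input):
            raise ValueError(
                f"context input {self.context_input} must be 2 x main input "
                f"{self.main_input}")

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    seed: int = 0
    #: start the softmax heads at the training-set label frequencies, so no
    #: steps are spent learning the (heavily background-skewed) class prior
    prior_init: bool = True
    #: per-epoch schedule on the initial learning rate: "cosine" decays to
    #: one tenth over the run, "none" keeps it constant
    lr_schedule: str = "cosine"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class _ConvBlock:
    """Two 3 x 3 x 3 convolutions, each followed by (optional) instance
    normalization and ReLU."""

    def __init__(self, rng, cin, cout, name, normalization="instance"):
        self.ops = []
        for i, ci in enumerate((cin, cout)):
            self.ops.append(nn.Conv3D(rng, ci, cout, 3, f"{name}.c{i + 1}"))
            if normalization == "instance":
                self.ops.append(nn.InstanceNorm3D(cout, f"{name}.n{i + 1}"))
            self.ops.append(nn.ReLU())

    def params(self):
        return [p for op in self.ops for p in op.params()]

    def forward(self, x):
        for op in self.ops:
            x = op.forward(x)
        return x

    def backward(self, g):
        for op in reversed(self.ops):
            g = op.backward(g)
        return g


class MultiScaleUNet:
    """Trainable (main patch, context patch) -> per-voxel class probability
    function at main-patch resolution."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = [cfg.base_filters * 2 ** l for l in range(cfg.depth + 1)]
        C = cfg.channels
        d = cfg.depth

        # "encoder": normalized feature extraction, unnormalized decoding
        # (keeps the decoder's absolute calibration of class scores)
        enc_norm = "instance" if cfg.normalization in ("instance", "encoder") else "none"
        dec_norm = "instance" if cfg.normalization == "instance" else "none"
        self.enc_main = [_ConvBlock(rng, C if l == 0 else f[l - 1], f[l], f"enc_m{l}", enc_norm)
                         for l in range(d)]
        self.pool_main = [nn.MaxPool3D() for _ in range(d)]
        if cfg.context_path:
            self.enc_ctx = [_ConvBlock(rng, C if l == 0 else f[l - 1], f[l], f"enc_c{l}", enc_norm)
                            for l in range(d)]
            self.pool_ctx = [nn.MaxPool3D() for _ in range(d)]
        bott_in = f[d - 1] * (2 if cfg.context_path else 1)
        self.bottleneck = _ConvBlock(rng, bott_in, f[d], "bottleneck", enc_norm)
        self.up = [nn.ConvTranspose3D(rng, f[l + 1], f[l], f"up{l}") for l in range(d)]
        self.dec = [_ConvBlock(rng, 2 * f[l], f[l], f"dec{l}", dec_norm) for l in range(d)]
        self.aux_heads = {l: nn.Conv3D(rng, f[l], cfg.classes, 1, f"aux{l}")
                          for l in range(1, d)} if cfg.deep_supervision else {}
        self.head = nn.Conv3D(rng, f[0], cfg.classes, 1, "head")
        self._filters = f

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for blk in self.enc_main:
            ps += blk.params()
        if self.cfg.context_path:
            for blk in self.enc_ctx:
                ps += blk.params()
        ps += self.bottleneck.params()
        for up, dec in zip(self.up, self.dec):
            ps += up.params() + dec.params()
        for h in self.aux_heads.values():
            ps += h.params()
        ps += self.head.params()
        return ps

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- forward / backward -------------------------------------------------
    def forward(self, main: np.ndarray, context: np.ndarray | None = None):
        """``main``: (B, *main_input, C); ``context``: (B, *context_input, C)
        (required iff the context path is on).  Returns ``(logits,
        aux_logits)`` with logits at main resolution."""
        cfg = self.cfg
        if cfg.context_path and context is None:
            raise ValueError("context patch required when the context path is on")
        d = cfg.depth

        skips = []
        h = main.astype(np.float32)
        for l in range(d):
            h = self.enc_main[l].forward(h)
            skips.append(h)
            h = self.pool_main[l].forward(h)
        if cfg.context_path:
            c = nn.avg_downsample2(context.astype(np.float32))
            for l in range(d):
                c = self.enc_ctx[l].forward(c)
                c = self.pool_ctx[l].forward(c)
            h = np.concatenate([h, c], axis=-1)
        h = self.bottleneck.forward(h)

        aux: dict[int, np.ndarray] = {}
        for l in range(d - 1, -1, -1):
            h = self.up[l].forward(h)
            h = np.concatenate([h, skips[l]], axis=-1)
            h = self.dec[l].forward(h)
            if l in self.aux_heads:
                aux[l] = self.aux_heads[l].forward(h)
        logits = self.head.forward(h)
        return logits, aux

    def backward(self, glogits: np.ndarray, gaux: dict[int, np.ndarray]) -> None:
        cfg = self.cfg
        d = cfg.depth
        f = self._filters

        g = self.head.backward(glogits)
        gskips: dict[int, np.ndarray] = {}
        for l in range(d):
            if l in gaux:
                g = g + self.aux_heads[l].backward(gaux[l])
            g = self.dec[l].backward(g)
            g, gskips[l] = g[..., :f[l]], g[..., f[l]:]
            g = self.up[l].backward(g)
        g = self.bottleneck.backward(g)
        if cfg.context_path:
            g, gc = g[..., :f[d - 1]], g[..., f[d - 1]:]
            for l in range(d - 1, -1, -1):
                gc = self.pool_ctx[l].backward(gc)
                gc = self.enc_ctx[l].backward(gc)
        for l in range(d - 1, -1, -1):
            g = self.pool_main[l].backward(g)
            g = g + gskips[l]
            g = self.enc_main[l].backward(g)

    def predict_proba(self, main: np.ndarray, context: np.ndarray | None = None) -> np.ndarray:
        logits, _ = self.forward(main, context)
        return nn.softmax(logits)

    # -- loss ---------------------------------------------------------------
    def l2_penalty(self) -> float:
        return float(self.cfg.l2_weight
                     * sum(np.sum(p.value.astype(np.float64) ** 2)
                           for p in self.params() if p.is_kernel))

    def loss_and_grads(self, main, context, labels):
        """Total loss (main CE + weighted auxiliary CEs + L2 penalty) and
        parameter gradients (accumulated on the params)."""
        logits, aux = self.forward(main, context)
        loss, glogits = nn.softmax_cross_entropy(logits, labels)
        gaux = {}
        aux_levels = sorted(aux)  # finest first
        for i, l in enumerate(aux_levels):
            step = 2 ** l
            lab_l = labels[:, ::step, ::step, ::step]
            w = AUX_WEIGHTS[min(i, len(AUX_WEIGHTS) - 1)]
            li, gi = nn.softmax_cross_entropy(aux[l], lab_l)
            loss += w * li
            gaux[l] = w * gi
        self.backward(glogits, gaux)
        if self.cfg.l2_weight > 0:
            for p in self.params():
                if p.is_kernel:
                    p.grad += 2.0 * self.cfg.l2_weight * p.value
            loss += self.l2_penalty()
        return float(loss)

    # -- checkpointing ------------------------------------------------------
    def save_weights(self, path) -> None:
        np.savez(path, **{p.name: p.value for p in self.params()})

    def load_weights(self, path) -> None:
        with np.load(path) as z:
            for p in self.params():
                p.value[...] = z[p.name]


def build_network(cfg: ModelConfig, seed: int = 0) -> MultiScaleUNet:
    """Construct the classifier; rejects inconsistent dimensions at
    construction (via ``ModelConfig`` validation)."""
    return MultiScaleUNet(cfg, seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def stack_patches(patches: list[PatchPair], channel_idx: list[int] | None = None):
    """Stack patch pairs into channels-last training arrays, optionally
    selecting a channel subset (0 = image, 1 = vessel)."""
    sel = channel_idx if channel_idx is not None else [0, 1]
    Xm = np.stack([p.main[sel].transpose(1, 2, 3, 0) for p in patches]).astype(np.float32)
    Xc = np.stack([p.context[sel].transpose(1, 2, 3, 0) for p in patches]).astype(np.float32)
    Y = np.stack([p.gt for p in patches]).astype(np.int16)
    return Xm, Xc, Y


def _macro_f1(gt: np.ndarray, pred: np.ndarray, exclude=(BACKGROUND, NON_ANNOTATED)) -> float:
    from .metrics import scores, voxel_confusion
    conf = voxel_confusion(gt, pred, exclude=set(exclude))
    if not any(tp + fn > 0 for tp, fn in zip(conf.tp, conf.fn)):
        return float("nan")
    return scores(conf).mf1


def train(model: MultiScaleUNet, train_patches: list[PatchPair],
          val_patches: list[PatchPair] | None, tcfg: TrainConfig,
          channel_idx: list[int] | None = None, verbose: bool = False):
    """Train with Adam on shuffled mini-batches; returns ``(model,
    history)`` where history records per-epoch loss and validation macro F1
    (background / non-annotated excluded)."""
    if not len(train_patches):
        raise ValueError("empty training set")
    dataset = train_patches if hasattr(train_patches, "batch") else None
    if dataset is None:
        Xm, Xc, Y = stack_patches(train_patches, channel_idx)
    val = stack_patches(val_patches, channel_idx) if val_patches else None

    if tcfg.prior_init:
        K = model.cfg.classes
        if dataset is not None and hasattr(dataset, "label_counts"):
            counts = dataset.label_counts(K)
        else:
            counts = np.bincount((Y if dataset is None else
                                  dataset.batch(range(len(dataset)), channel_idx)[2]
                                  ).ravel(), minlength=K)
        priors = counts / max(counts.sum(), 1)
        logp = np.log(np.maximum(priors, 1e-8)).astype(np.float32)
        model.head.b.value[...] = logp
        for h in model.aux_heads.values():
            h.b.value[...] = logp
    rng = np.random.default_rng(tcfg.seed)
    opt = nn.Adam(model.params(), lr=tcfg.learning_rate)
    n = len(train_patches)
    ctx_on = model.cfg.context_path

    history = []
    for epoch in range(tcfg.epochs):
        if tcfg.lr_schedule == "cosine" and tcfg.epochs > 1:
            frac = 0.5 * (1 + np.cos(np.pi * epoch / (tcfg.epochs - 1)))
            opt.lr = tcfg.learning_rate * (0.1 + 0.9 * frac)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            if dataset is not None:
                bXm, bXc, bY = dataset.batch(idx, channel_idx)
            else:
                bXm, bXc, bY = Xm[idx], Xc[idx], Y[idx]
            opt.zero_grad()
            loss = model.loss_and_grads(bXm, bXc if ctx_on else None, bY)
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val is not None:
            vX, vC, vY = val
            preds = []
            for s in range(0, len(vY), tcfg.batch_size):
                p = model.predict_proba(vX[s:s + tcfg.batch_size],
                                        vC[s:s + tcfg.batch_size] if ctx_on else None)
                preds.append(np.argmax(p, axis=-1))
            row["val_mf1"] = _macro_f1(vY, np.concatenate(preds))
        history.append(row)
        if verbose:
            logger.info("epoch %d: %s", epoch, row)
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# random-forest baseline
# ---------------------------------------------------------------------------

@dataclass
class RFVoxelClassifier:
    """Per-voxel random forest on hand-crafted features: image intensity,
    vessel-channel radius value, and voxel coordinates normalized to [0, 1]
    per axis."""

    forest: RandomForestClassifier
    skipped_classes: list[int] = field(default_factory=list)

    @staticmethod
    def features(image: np.ndarray, vessel: np.ndarray, coords: np.ndarray) -> np.ndarray:
        shape = np.asarray(image.shape, dtype=np.float32)
        norm = coords / np.maximum(shape - 1, 1)
        return np.c_[image[tuple(coords.T)], vessel[tuple(coords.T)], norm].astype(np.float32)

    def predict_labels(self, image: VolumeGrid, vessel: VolumeGrid,
                       mask: VolumeGrid | None = None) -> VolumeGrid:
        """Predict a class for every voxel (restricted to ``mask`` when
        given; elsewhere background)."""
        img = np.asarray(image.data, dtype=np.float32)
        ves = np.asarray(vessel.data, dtype=np.float32)
        where = np.argwhere(np.asarray(mask.data) > 0) if mask is not None \
            else np.argwhere(np.ones(image.shape, dtype=bool))
        out = np.zeros(image.shape, dtype=np.int16)
        if len(where):
            out[tuple(where.T)] = self.forest.predict(self.features(img, ves, where))
        return image.with_data(out)


def rf_baseline(train_subjects: list[tuple[VolumeGrid, VolumeGrid, VolumeGrid]],
                per_class_voxels: int = 200, trees: int = 50,
                seed: int = 0) -> RFVoxelClassifier:
    """Fit the voxel-wise random-forest baseline.

    ``train_subjects`` holds (image, vessel-radius, ground-truth) volume
    triples; from each subject an equal number of voxels per class label is
    sampled.  Classes absent from every training subject are skipped and
    logged.
    """
    if per_class_voxels < 1:
        raise ValueError(f"per_class_voxels must be >= 1, got {per_class_voxels}")
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    seen: set[int] = set()
    for img, ves, gt in train_subjects:
        data = np.asarray(gt.data)
        for c in np.unique(data):
            vox = np.argwhere(data == c)
            n = min(per_class_voxels, len(vox))
            pick = vox[rng.choice(len(vox), size=n, replace=False)]
            feats.append(RFVoxelClassifier.features(
                np.asarray(img.data, np.float32), np.asarray(ves.data, np.float32), pick))
            labels.append(np.full(n, int(c)))
            seen.add(int(c))
    X = np.vstack(feats)
    y = np.concatenate(labels)
    forest = RandomForestClassifier(n_estimators=trees, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return RFVoxelClassifier(forest)
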