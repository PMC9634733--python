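"""A small CPU engine for 3-D convolutional networks.

Implements exactly the operations the labeling architecture needs — 3-D
convolution (im2col + BLAS matmul), transposed convolution, max pooling,
ReLU, softmax cross-entropy and Adam — with hand-written backward passes.
Arrays are channels-last ``(batch, x, y, z, channels)`` float32.  Every
layer caches what its backward pass needs; gradients accumulate on
:class:`Param` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param", "Conv3D", "ConvTranspose3D", "ReLU", "MaxPool3D", "InstanceNorm3D",
    "avg_downsample2", "softmax", "softmax_cross_entropy", "Adam",
    "glorot_uniform",
]


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    is_kernel: bool = True   # kernels carry the L2 penalty, biases do not

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float32)
        self.zero_grad()

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


try:  # fused direct-convolution kernels; the im2col path is the fallback
    from . import _conv_kernels
except ImportError:  # pragma: no cover
    _conv_kernels = None


class Conv3D:
    """k x k x k stride-1 'same' convolution (odd k).

    ``backend`` is "numba" (fused direct kernels, default when available) or
    "numpy" (im2col + BLAS); both compute the same function and gradients.
    Weight layout is ``(k**3 * cin, cout)`` in (a, b, c, cin) window order.
    """

    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 ksize: int = 3, name: str = "conv", backend: str | None = None):
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, ksize
        kk = ksize ** 3
        self.W = Param(f"{name}.W", glorot_uniform(rng, cin * kk, cout, (cin * kk, cout)))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=np.float32), is_kernel=False)
        if backend is None:
            backend = "numba" if _conv_kernels is not None else "numpy"
        if backend == "numba" and _conv_kernels is None:
            raise ValueError("numba backend requested but numba is unavailable")
        self.backend = backend
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        if not p:
            return np.ascontiguousarray(x, dtype=np.float32)
        B, D, H, Wd, C = x.shape
        xp = np.zeros((B, D + 2 * p, H + 2 * p, Wd + 2 * p, C), dtype=np.float32)
        xp[:, p:-p, p:-p, p:-p, :] = x
        return xp

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, D, H, Wd, C = x.shape
        k = self.k
        xp = self._pad(x)
        if self.backend == "numba":
            self._cache = ("numba", xp, (B, D, H, Wd, C))
            return _conv_kernels.conv3d_forward(xp, self.W.value, self.b.value,
                                                k, self.cin, self.cout)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        cols = np.ascontiguousarray(np.moveaxis(win, 4, 7)).reshape(B * D * H * Wd, k ** 3 * C)
        self._cache = ("numpy", cols, (B, D, H, Wd, C))
        y = cols @ self.W.value + self.b.value
        return y.reshape(B, D, H, Wd, self.cout)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        kind, cached, (B, D, H, Wd, C) = self._cache
        k, p = self.k, self.k // 2
        self._cache = None
        if kind == "numba":
            gxp, gW, gb = _conv_kernels.conv3d_backward(cached, self.W.value, gy,
                                                        k, self.cin, self.cout)
            self.W.grad += gW
            self.b.grad += gb
            return gxp[:, p:p + D, p:p + H, p:p + Wd, :] if p else gxp
        g = gy.reshape(-1, self.cout)
        self.W.grad += cached.T @ g
        self.b.grad += g.sum(axis=0)
        gcols = (g @ self.W.value.T).reshape(B, D, H, Wd, k, k, k, C)
        gxp = np.zeros((B, D + 2 * p, H + 2 * p, Wd + 2 * p, C), dtype=np.float32)
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    gxp[:, a:a + D, bb:bb + H, c:c + Wd, :] += gcols[:, :, :, :, a, bb, c]
        return gxp[:, p:p + D, p:p + H, p:p + Wd, :] if p else gxp


class ConvTranspose3D:
    """2 x 2 x 2 stride-2 transposed convolution (doubles each spatial dim)."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, name: str = "up"):
        self.cin, self.cout = cin, cout
        self.W = Param(f"{name}.W", glorot_uniform(rng, cin, cout * 8, (cin, 2, 2, 2, cout)))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=np.float32), is_kernel=False)
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        B, D, H, Wd, C = x.shape
        y8 = np.tensordot(x, self.W.value, axes=([4], [0]))    # (B,D,H,W,2,2,2,F)
        y = y8.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(B, 2 * D, 2 * H, 2 * Wd, self.cout)
        return y + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        B, D, H, Wd, C = x.shape
        g8 = gy.reshape(B, D, 2, H, 2, Wd, 2, self.cout).transpose(0, 1, 3, 5, 2, 4, 6, 7)
        self.b.grad += gy.sum(axis=(0, 1, 2, 3))
        self.W.grad += np.tensordot(x, g8, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        gx = np.tensordot(g8, self.W.value, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        self._x = None
        return gx


class InstanceNorm3D:
    """Per-sample, per-channel normalization over the spatial axes with a
    learnable affine (gamma, beta).  Batch-size independent, so train and
    inference behave identically."""

    def __init__(self, channels: int, name: str = "inorm", eps: float = 1e-5):
        self.gamma = Param(f"{name}.g", np.ones(channels, dtype=np.float32), is_kernel=False)
        self.beta = Param(f"{name}.b", np.zeros(channels, dtype=np.float32), is_kernel=False)
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (1, 2, 3)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        axes = (1, 2, 3)
        self.gamma.grad += (gy * xhat).sum(axis=(0, 1, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 1, 2, 3))
        dxhat = gy * self.gamma.value
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, gy, 0.0)
        self._mask = None
        return g


class MaxPool3D:
    """2 x 2 x 2 max pooling; gradient splits evenly across exact ties."""

    def __init__(self) -> None:
        self._cache = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, D, H, Wd, C = x.shape
        r = x.reshape(B, D // 2, 2, H // 2, 2, Wd // 2, 2, C)
        y = r.max(axis=(2, 4, 6))
        self._cache = (r, y)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        r, y = self._cache
        mask = (r == y[:, :, None, :, None, :, None, :])
        counts = mask.sum(axis=(2, 4, 6), keepdims=True)
        g = mask * (gy[:, :, None, :, None, :, None, :] / counts)
        self._cache = None
        B = r.shape[0]
        return g.reshape(B, r.shape[1] * 2, r.shape[3] * 2, r.shape[5] * 2, r.shape[7])


def avg_downsample2(x: np.ndarray) -> np.ndarray:
    """2 x 2 x 2 average downsampling (used on the context-path input; no
    gradient flows past the network input)."""
    B, D, H, Wd, C = x.shape
    return x.reshape(B, D // 2, 2, H // 2, 2, Wd // 2, 2, C).mean(axis=(2, 4, 6))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy over all voxels.

    Returns ``(loss, grad_wrt_logits)``; ``labels`` are integer class
    indices with the same spatial shape as ``logits`` minus the channel
    axis.
    """
    p = softmax(logits)
    n = labels.size
    flat = p.reshape(n, logits.shape[-1])
    idx = labels.reshape(n).astype(int)
    eps = 1e-12
    loss = -np.log(flat[np.arange(n), idx] + eps).mean()
    grad = flat.copy()
    grad[np.arange(n), idx] -= 1.0
    grad /= n
    return float(loss), grad.reshape(logits.shape)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
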