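"""Differentiable layer primitives (NCHW, float32 by default).

Each layer exposes ``forward(x, train)`` and ``backward(grad) -> dx`` and
caches only what its own backward pass needs.  Convolution is evaluated as
k*k shifted channel contractions (one BLAS ``tensordot`` per kernel tap),
which beats im2col on memory traffic for the wide 7x7 kernels used here;
the backward pass is the mirrored accumulation.  Computations follow the
input dtype, so a model cast to float64 can be finite-difference checked.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "UpsampleNearest2",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Conv2d:
    """Same-padded 2-D convolution (odd kernel), He-initialized."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.cin, self.cout = k, cin, cout
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        wv = self.w.value.astype(x.dtype, copy=False)
        out = np.empty((n, self.cout, h, w), dtype=x.dtype)
        out[...] = self.b.value.astype(x.dtype)[None, :, None, None]
        for i in range(k):
            for j in range(k):
                t = np.tensordot(wv[:, :, i, j], xp[:, :, i : i + h, j : j + w],
                                 axes=([1], [1]))
                out += t.transpose(1, 0, 2, 3)
        if train:
            self._cache = (xp, (n, c, h, w))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, (n, c, h, w) = self._cache
        self._cache = None
        k, p = self.k, self.k // 2
        wv = self.w.value.astype(grad.dtype, copy=False)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                self.w.grad[:, :, i, j] += np.tensordot(
                    grad, xp[:, :, i : i + h, j : j + w], axes=([0, 2, 3], [0, 2, 3])
                )
                t = np.tensordot(wv[:, :, i, j].T, grad, axes=([1], [1]))
                dxp[:, :, i : i + h, j : j + w] += t.transpose(1, 0, 2, 3)
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return grad * mask


class Sigmoid:
    def __init__(self):
        self._out = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out, self._out = self._out, None
        return grad * out * (1.0 - out)


class MaxPool2:
    """2x2 max pooling, stride 2; ties split the gradient evenly."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            am = xr == out[:, :, :, None, :, None]
            counts = am.sum(axis=(3, 5), keepdims=True)
            self._cache = (am, counts, (n, c, h, w))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        am, counts, (n, c, h, w) = self._cache
        self._cache = None
        g = grad[:, :, :, None, :, None] * am / counts
        return g.reshape(n, c, h, w)


class UpsampleNearest2:
    """2x nearest-neighbor upsampling; backward sums each 2x2 block."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = grad.shape
        return grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
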