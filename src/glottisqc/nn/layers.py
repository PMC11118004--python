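"""Minimal CPU neural-network layers with explicit backprop.

A compact, dependency-free stack sufficient for the residual regression
network: strided convolution (im2col + one big matmul), batch
normalization with running statistics, ReLU, 3x3/stride-2 max pooling,
global average pooling and a linear head. Everything is float32 and
deterministic given the NumPy RNG used at initialization.

Each layer caches what its backward pass needs during ``forward`` and
consumes the cache in ``backward``; parameters accumulate gradients in
``Param.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
]

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self):
        self.grad.fill(0.0)


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, k, k, oh, ow) sliding windows (a view copy)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    dxp = np.zeros(shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[
                :, :, i, j
            ]
    return dxp


class Conv2d:
    """2-D convolution, square kernel, no bias (batch norm follows)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)  # Kaiming (fan-in, ReLU gain)
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self._cache = None

    def params(self):
        return [self.weight]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, s, oh, ow)
        colmat = cols.transpose(1, 2, 3, 0, 4, 5).reshape(c * k * k, n * oh * ow)
        wmat = self.weight.data.reshape(self.cout, c * k * k)
        y = wmat @ colmat
        self._cache = (colmat, xp.shape, (n, oh, ow))
        return y.reshape(self.cout, n, oh, ow).transpose(1, 0, 2, 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        colmat, xpshape, (n, oh, ow) = self._cache
        c, k, s, p = self.cin, self.k, self.stride, self.pad
        dymat = dy.transpose(1, 0, 2, 3).reshape(self.cout, n * oh * ow)
        self.weight.grad += (dymat @ colmat.T).reshape(self.weight.data.shape)
        dcolmat = self.weight.data.reshape(self.cout, c * k * k).T @ dymat
        dcols = dcolmat.reshape(c, k, k, n, oh, ow).transpose(3, 0, 1, 2, 4, 5)
        dxp = _col2im(dcols, xpshape, k, s, oh, ow)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.gamma.data[None, :, None, None]
        b = self.beta.data[None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            ivar = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
            self._cache = (xhat, ivar, True)
            return (g * xhat + b).astype(DTYPE, copy=False)
        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar, False)
        return (g * xhat + b).astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, trained = self._cache
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.data[None, :, None, None]
        iv = ivar[None, :, None, None]
        if not trained:
            # running statistics are constants w.r.t. the batch
            return (g * iv * dy).astype(DTYPE, copy=False)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dx = (g * iv / m) * (
            m * dy - dbeta[None, :, None, None] - xhat * dgamma[None, :, None, None]
        )
        return dx.astype(DTYPE, copy=False)

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(DTYPE, copy=False)


class MaxPool2d:
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        cols = _im2col(xp, k, s, oh, ow).reshape(n, c, k * k, oh, ow)
        idx = cols.argmax(axis=2)
        out = np.take_along_axis(cols, idx[:, :, None], axis=2)[:, :, 0]
        self._cache = (idx, xp.shape, x.shape, (oh, ow))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, xpshape, xshape, (oh, ow) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros(xpshape, dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                sel = idx == (i * k + j)
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += np.where(sel, dy, 0.0)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool:
    def __init__(self):
        self._hw = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None] / (h * w), dy.shape + (h, w)).astype(
            DTYPE, copy=False
        )


class Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin)))
        self.bias = Param(np.zeros(cout))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data
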