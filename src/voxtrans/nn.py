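"""Minimal 3D conv-net layers with manual backpropagation, in numpy.

Supports exactly what the translation models need: strided 3D convolution
and transpose convolution (even kernels, stride 2, "same-halving" padding
p = (k-2)/2), instance normalization, leaky ReLU / ReLU / tanh / sigmoid,
decoder dropout, and Adam.  Batch size is fixed at 1: tensors are
channel-first ``(C, D, H, W)`` float32 without a batch axis.

Convolution is im2col + matmul; the transpose convolution and the
data-gradient of the convolution share one scatter (col2im) primitive whose
index map is cached per geometry, which keeps the whole thing fast enough
for 32^3-patch training on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv3d", "ConvTranspose3d", "InstanceNorm3d",
           "LeakyReLU", "ReLU", "Tanh", "Sigmoid", "Dropout", "Adam"]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class _ConvGeom:
    """Geometry between a 'big' spatial grid and the 'small' strided grid.

    A convolution maps big -> small; a transpose convolution maps
    small -> big.  Both directions reuse im2col (gather) and col2im
    (scatter); the scatter index map is built lazily and cached.
    """

    def __init__(self, big_shape, k: int, stride: int, pad: int):
        self.big = tuple(int(v) for v in big_shape)
        self.k, self.s, self.p = int(k), int(stride), int(pad)
        self.padded = tuple(b + 2 * self.p for b in self.big)
        self.small = tuple((b + 2 * self.p - self.k) // self.s + 1 for b in self.big)
        for b, sm in zip(self.big, self.small):
            if (b + 2 * self.p - self.k) % self.s != 0 or sm < 1:
                raise ValueError(
                    f"incompatible conv geometry: size {b}, k={self.k}, "
                    f"stride={self.s}, pad={self.p}")
        self.n_sites = int(np.prod(self.small))
        self._scatter_idx = None

    def im2col(self, x: np.ndarray) -> np.ndarray:
        """(C, *big) -> (n_sites, C*k^3) gathered patch matrix."""
        k, s, p = self.k, self.s, self.p
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        w = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))[:, ::s, ::s, ::s]
        # (C, S0, S1, S2, k, k, k) -> (S0, S1, S2, C, k, k, k) -> (N, C*k^3)
        cols = np.ascontiguousarray(w.transpose(1, 2, 3, 0, 4, 5, 6))
        return cols.reshape(self.n_sites, x.shape[0] * k ** 3)

    def _scatter_indices(self) -> np.ndarray:
        if self._scatter_idx is None:
            k, s = self.k, self.s
            base = np.arange(int(np.prod(self.padded)), dtype=np.int64).reshape(self.padded)
            w = sliding_window_view(base, (k, k, k))[::s, ::s, ::s]
            self._scatter_idx = np.ascontiguousarray(w).reshape(self.n_sites, k ** 3)
        return self._scatter_idx

    def col2im(self, cols: np.ndarray, channels: int) -> np.ndarray:
        """(n_sites, C*k^3) -> (C, *big): adjoint of :meth:`im2col`."""
        k, p = self.k, self.p
        idx = self._scatter_indices().ravel()
        size = int(np.prod(self.padded))
        cols = cols.reshape(self.n_sites, channels, k ** 3)
        out = np.empty((channels,) + self.padded, dtype=np.float64)
        flat = out.reshape(channels, -1)
        for c in range(channels):
            flat[c] = np.bincount(idx, weights=cols[:, c, :].ravel().astype(np.float64),
                                  minlength=size)
        if p:
            out = out[:, p:-p, p:-p, p:-p]
        return out.astype(np.float32)


def _init_weight(rng, shape, std=0.02):
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d:
    """3D convolution, kernel k^3, configurable stride; pad defaults to (k-2)/2
    for stride 2 (exact halving) and (k-1)/2 for stride 1 (odd k)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 2,
                 pad: int | None = None, rng=None):
        if pad is None:
            pad = (k - 2) // 2 if stride == 2 else (k - 1) // 2
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng()
        self.W = Param(_init_weight(rng, (cin * k ** 3, cout)))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._geom: _ConvGeom | None = None
        self._cols = None

    def _geometry(self, big_shape) -> _ConvGeom:
        if self._geom is None or self._geom.big != tuple(big_shape):
            self._geom = _ConvGeom(big_shape, self.k, self.stride, self.pad)
        return self._geom

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self._geometry(x.shape[1:])
        cols = g.im2col(np.asarray(x, dtype=np.float32))
        self._cols = cols if train else None
        out = cols @ self.W.data + self.b.data
        return np.ascontiguousarray(out.reshape(*g.small, self.cout)
                                    .transpose(3, 0, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self._geom
        dy_mat = np.ascontiguousarray(dy.transpose(1, 2, 3, 0)).reshape(g.n_sites, self.cout)
        self.W.grad += self._cols.T @ dy_mat
        self.b.grad += dy_mat.sum(axis=0)
        dcols = dy_mat @ self.W.data.T
        return g.col2im(dcols, self.cin)

    def params(self):
        return [self.W, self.b]


class ConvTranspose3d:
    """3D transpose convolution doubling each spatial axis (stride 2, even k,
    pad (k-2)/2).  Implemented as the adjoint of the matching convolution."""

    def __init__(self, cin: int, cout: int, k: int, rng=None):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad = 2, (k - 2) // 2
        rng = rng or np.random.default_rng()
        # weight of the adjoint conv: maps cout*k^3 -> cin
        self.W = Param(_init_weight(rng, (cout * k ** 3, cin)))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._geom: _ConvGeom | None = None
        self._x_mat = None

    def _geometry(self, small_shape) -> _ConvGeom:
        big = tuple(self.stride * s for s in small_shape)
        if self._geom is None or self._geom.big != big:
            self._geom = _ConvGeom(big, self.k, self.stride, self.pad)
        return self._geom

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self._geometry(x.shape[1:])
        x_mat = np.ascontiguousarray(np.asarray(x, dtype=np.float32)
                                     .transpose(1, 2, 3, 0)).reshape(g.n_sites, self.cin)
        self._x_mat = x_mat if train else None
        cols = x_mat @ self.W.data.T
        y = g.col2im(cols, self.cout)
        return y + self.b.data[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self._geom
        cols_dy = g.im2col(np.asarray(dy, dtype=np.float32))
        dx_mat = cols_dy @ self.W.data
        self.W.grad += cols_dy.T @ self._x_mat
        self.b.grad += dy.sum(axis=(1, 2, 3))
        return np.ascontiguousarray(dx_mat.reshape(*g.small, self.cin).transpose(3, 0, 1, 2))

    def params(self):
        return [self.W, self.b]


class InstanceNorm3d:
    """Per-channel normalization over the spatial axes (batch size 1)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv) if train else None
        return self.gamma.data[:, None, None, None] * xhat + self.beta.data[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        dxhat = dy * self.gamma.data[:, None, None, None]
        m = dxhat.mean(axis=(1, 2, 3), keepdims=True)
        mx = (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return inv * (dxhat - m - xhat * mx)

    def params(self):
        return [self.gamma, self.beta]


class LeakyReLU:
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self._mask = None

    def forward(self, x, train: bool = True):
        mask = x > 0
        self._mask = mask if train else None
        return np.where(mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)

    def params(self):
        return []


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Tanh:
    def __init__(self):
        self._y = None

    def forward(self, x, train: bool = True):
        y = np.tanh(x)
        self._y = y if train else None
        return y

    def backward(self, dy):
        return dy * (1.0 - self._y ** 2)

    def params(self):
        return []


class Sigmoid:
    def __init__(self):
        self._y = None

    def forward(self, x, train: bool = True):
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y if train else None
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity when ``train=False`` (inference is
    deterministic)."""

    def __init__(self, p: float = 0.5, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, train: bool = True):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class Adam:
    """Adam with the pix2pix defaults (lr 2e-4, beta1 0.5)."""

    def __init__(self, params, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
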