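"""3D layers with explicit forward/backward passes.

Tensors use the (N, C, D, H, W) layout throughout. Convolution is computed as
a sum over the k^3 kernel offsets, each offset contributing one tensordot of a
strided input view with a (C_in, C_out) weight slice; the backward pass runs
the same loop with the adjoint scatter. This keeps memory flat (no im2col
buffer) while staying inside BLAS for the heavy lifting.
"""

from __future__ import annotations

import numpy as np

from . import core
from .core import Module, Parameter


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3d(Module):
    """3D cross-correlation with stride and symmetric zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int = 1, rng: np.random.Generator | None = None, name: str = "conv"):
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = in_ch * kernel ** 3
        self.weight = Parameter(f"{name}.weight",
                                kaiming_normal(rng, (kernel, kernel, kernel, in_ch, out_ch), fan_in))
        self.bias = Parameter(f"{name}.bias", np.zeros(out_ch))
        self._xp: np.ndarray | None = None

    def _out_edge(self, n: int) -> int:
        return (n + 2 * self.padding - self.kernel) // self.stride + 1

    def forward(self, x, training=False):
        k, s, p = self.kernel, self.stride, self.padding
        n, c, d, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        do, ho, wo = self._out_edge(d), self._out_edge(h), self._out_edge(w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        out = np.zeros((n, do, ho, wo, self.out_ch),
                       dtype=np.result_type(xp.dtype, self.weight.data.dtype))
        for a in range(k):
            for b in range(k):
                for cc in range(k):
                    xs = xp[:, :, a:a + s * do:s, b:b + s * ho:s, cc:cc + s * wo:s]
                    # (N,Cin,Do,Ho,Wo) x (Cin,Cout) -> (N,Do,Ho,Wo,Cout)
                    out += np.tensordot(xs, self.weight.data[a, b, cc], axes=([1], [0]))
        out += self.bias.data
        if training:
            self._xp = xp
            self._in_shape = (d, h, w)
        return np.moveaxis(out, -1, 1)

    def backward(self, gout):
        k, s, p = self.kernel, self.stride, self.padding
        xp = self._xp
        if xp is None:
            raise RuntimeError("backward called without a training forward pass")
        g = np.moveaxis(gout, 1, -1)  # (N,Do,Ho,Wo,Cout)
        n, do, ho, wo, _ = g.shape
        self.bias.grad += g.sum(axis=(0, 1, 2, 3))
        gxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                for cc in range(k):
                    xs = xp[:, :, a:a + s * do:s, b:b + s * ho:s, cc:cc + s * wo:s]
                    self.weight.grad[a, b, cc] += np.tensordot(
                        xs, g, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
                    gslice = np.tensordot(g, self.weight.data[a, b, cc], axes=([4], [1]))
                    gxp[:, :, a:a + s * do:s, b:b + s * ho:s, cc:cc + s * wo:s] += \
                        np.moveaxis(gslice, -1, 1)
        self._xp = None
        d, h, w = self._in_shape
        if p:
            return gxp[:, :, p:p + d, p:p + h, p:p + w]
        return gxp


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None,
                 name: str = "linear"):
        if rng is None:
            rng = np.random.default_rng(0)
        self.weight = Parameter(f"{name}.weight", kaiming_normal(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(f"{name}.bias", np.zeros(out_dim))
        self._x = None

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, gout):
        self.weight.grad += self._x.T @ gout
        self.bias.grad += gout.sum(axis=0)
        gx = gout @ self.weight.data.T
        self._x = None
        return gx


class BatchNorm3d(Module):
    """Batch normalization over (N, D, H, W) per channel, with running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=core.DTYPE)
        self.running_var = np.ones(channels, dtype=core.DTYPE)
        self._cache = None

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None, None] * xhat + \
            self.beta.data[None, :, None, None, None]

    def backward(self, gout):
        xhat, inv = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        m = gout.shape[0] * gout.shape[2] * gout.shape[3] * gout.shape[4]
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        g = self.gamma.data[None, :, None, None, None]
        sum_g = gout.sum(axis=axes)[None, :, None, None, None]
        sum_gx = (gout * xhat).sum(axis=axes)[None, :, None, None, None]
        return (g * inv[None, :, None, None, None] / m) * (m * gout - sum_g - xhat * sum_gx)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x, training=False):
        mask = x > 0
        if training:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, gout):
        g = np.where(self._mask, gout, self.slope * gout)
        self._mask = None
        return g


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Sigmoid(Module):
    def __init__(self):
        self._y = None

    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        if training:
            self._y = y
        return y

    def backward(self, gout):
        g = gout * self._y * (1.0 - self._y)
        self._y = None
        return g


def _interp_matrix(n_in: int, scale: int = 2) -> np.ndarray:
    """1D linear interpolation matrix (scale*n_in, n_in), half-voxel aligned."""
    n_out = n_in * scale
    m = np.zeros((n_out, n_in))
    for i in range(n_out):
        pos = (i + 0.5) / scale - 0.5
        pos = min(max(pos, 0.0), n_in - 1.0)
        f = int(np.floor(pos))
        wgt = pos - f
        if f + 1 <= n_in - 1:
            m[i, f] += 1.0 - wgt
            m[i, f + 1] += wgt
        else:
            m[i, f] += 1.0
    return m


class TrilinearUpsample(Module):
    """x2 trilinear upsampling, implemented as separable 1D interpolation.

    The backward pass applies the exact adjoint (transposed matrices), so the
    layer passes finite-difference gradient checks to machine precision.
    """

    _matrices: dict[int, np.ndarray] = {}

    def __init__(self, scale: int = 2):
        self.scale = scale

    @classmethod
    def _matrix(cls, n_in: int, scale: int, dtype) -> np.ndarray:
        key = (n_in, scale, np.dtype(dtype).name)
        if key not in cls._matrices:
            cls._matrices[key] = _interp_matrix(n_in, scale).astype(dtype)
        return cls._matrices[key]

    @staticmethod
    def _apply(x: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
        return np.moveaxis(np.tensordot(m, x, axes=([1], [axis])), 0, axis)

    def forward(self, x, training=False):
        if training:
            self._in_edges = x.shape[2:]
        for axis in (2, 3, 4):
            x = self._apply(x, self._matrix(x.shape[axis], self.scale, x.dtype), axis)
        return x

    def backward(self, gout):
        for axis in (2, 3, 4):
            n_in = self._in_edges[axis - 2]
            gout = self._apply(gout, self._matrix(n_in, self.scale, gout.dtype).T, axis)
        return gout


class GlobalAvgPool3d(Module):
    """(N, C, D, H, W) -> (N, C) spatial mean."""

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, gout):
        n, c, d, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None, None], self._shape) / (d * h * w)
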