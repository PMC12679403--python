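"""Neural-network layer primitives with explicit forward/backward passes.

All layers operate on channels-last 5D tensors ``(N, Z, Y, X, C)``. Each
layer owns its parameters and accumulates parameter gradients during
``backward``; an optimiser consumes them via :meth:`Layer.parameters`.

Convolutions are evaluated as a sum of shifted matrix products: for each
kernel offset the (padded) input is sliced, flattened over voxels and
multiplied with the corresponding ``(C_in, C_out)`` weight slab. This keeps
peak memory at one input copy per offset instead of a full im2col buffer
and routes all arithmetic through BLAS.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "MaxPool3d",
    "GroupNorm",
    "LeakyReLU",
    "Dropout",
    "Softmax",
    "Sigmoid",
    "he_uniform",
]


def he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    """He (Kaiming) uniform initialisation: U(-b, b), b = sqrt(6 / fan_in)."""
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    """Base class: parameter bookkeeping shared by all layers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def parameters(self):
        for name, value in self.params.items():
            yield name, value, self.grads[name]

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, stride 1, zero 'same' padding.

    Weight layout: ``(k³ offsets, C_in, C_out)``; bias ``(C_out,)``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same-padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.offsets = list(itertools.product(range(kernel_size), repeat=3))
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size ** 3
        self.params["weight"] = he_uniform(
            rng, (len(self.offsets), in_channels, out_channels), fan_in, dtype)
        self.params["bias"] = np.zeros(out_channels, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x, train=False, rng=None):
        n, d, h, w, _ = x.shape
        p = self.kernel_size // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x
        weight = self.params["weight"]
        out = np.zeros((n * d * h * w, self.out_channels), dtype=x.dtype)
        for i, (dz, dy_, dx) in enumerate(self.offsets):
            sl = xp[:, dz:dz + d, dy_:dy_ + h, dx:dx + w, :]
            out += sl.reshape(-1, self.in_channels) @ weight[i]
        out += self.params["bias"]
        self._cache = (xp, x.shape)
        return out.reshape(n, d, h, w, self.out_channels)

    def backward(self, dy):
        xp, x_shape = self._cache
        n, d, h, w, _ = x_shape
        p = self.kernel_size // 2
        weight = self.params["weight"]
        dy_flat = dy.reshape(-1, self.out_channels)
        dxp = np.zeros_like(xp)
        for i, (dz, dy_, dx) in enumerate(self.offsets):
            sl = xp[:, dz:dz + d, dy_:dy_ + h, dx:dx + w, :]
            self.grads["weight"][i] += sl.reshape(-1, self.in_channels).T @ dy_flat
            dxp[:, dz:dz + d, dy_:dy_ + h, dx:dx + w, :] += (
                dy_flat @ weight[i].T).reshape(n, d, h, w, self.in_channels)
        self.grads["bias"] += dy_flat.sum(axis=0)
        if p:
            return dxp[:, p:-p, p:-p, p:-p, :]
        return dxp


class ConvTranspose3d(Layer):
    """Transpose convolution with kernel 2³ and stride 2 (exact 2x upsampling).

    Each input voxel populates a disjoint 2x2x2 output block, so there is no
    overlap and no checkerboarding: output[..., a::2, b::2, c::2] = x @ W[abc].
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.offsets = list(itertools.product(range(2), repeat=3))
        rng = rng or np.random.default_rng()
        self.params["weight"] = he_uniform(
            rng, (8, in_channels, out_channels), in_channels * 8, dtype)
        self.params["bias"] = np.zeros(out_channels, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x, train=False, rng=None):
        n, d, h, w, _ = x.shape
        weight = self.params["weight"]
        x_flat = x.reshape(-1, self.in_channels)
        out = np.empty((n, 2 * d, 2 * h, 2 * w, self.out_channels), dtype=x.dtype)
        for i, (a, b, c) in enumerate(self.offsets):
            out[:, a::2, b::2, c::2, :] = (
                x_flat @ weight[i]).reshape(n, d, h, w, self.out_channels)
        out += self.params["bias"]
        self._cache = x
        return out

    def backward(self, dy):
        x = self._cache
        n, d, h, w, _ = x.shape
        weight = self.params["weight"]
        x_flat = x.reshape(-1, self.in_channels)
        dx = np.zeros_like(x_flat)
        for i, (a, b, c) in enumerate(self.offsets):
            dy_off = dy[:, a::2, b::2, c::2, :].reshape(-1, self.out_channels)
            self.grads["weight"][i] += x_flat.T @ dy_off
            dx += dy_off @ weight[i].T
        self.grads["bias"] += dy.sum(axis=(0, 1, 2, 3))
        return dx.reshape(x.shape)


class MaxPool3d(Layer):
    """2x2x2 max pooling; requires even spatial dimensions."""

    def forward(self, x, train=False, rng=None):
        n, d, h, w, c = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"MaxPool3d needs even spatial dims, got {x.shape}")
        xr = (x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
               .transpose(0, 1, 3, 5, 2, 4, 6, 7)
               .reshape(n, d // 2, h // 2, w // 2, 8, c))
        idx = xr.argmax(axis=4)
        out = np.take_along_axis(xr, idx[..., None, :], axis=4)[..., 0, :]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dy):
        idx, x_shape = self._cache
        n, d, h, w, c = x_shape
        dxr = np.zeros((n, d // 2, h // 2, w // 2, 8, c), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None, :], dy[..., None, :], axis=4)
        return (dxr.reshape(n, d // 2, h // 2, w // 2, 2, 2, 2, c)
                   .transpose(0, 1, 4, 2, 5, 3, 6, 7)
                   .reshape(x_shape))


class GroupNorm(Layer):
    """Group normalization: per-sample statistics over (spatial, channels-in-group).

    Batch-size independent, which matters at batch size 6. Group count is
    clamped to the channel count for narrow layers.
    """

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.channels = channels
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x, train=False, rng=None):
        n, d, h, w, c = x.shape
        g = self.groups
        xg = x.reshape(n, d * h * w, g, c // g)
        mean = xg.mean(axis=(1, 3), keepdims=True)
        var = xg.var(axis=(1, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xg - mean) * inv_std
        out = xhat.reshape(x.shape) * self.params["gamma"] + self.params["beta"]
        self._cache = (xhat, inv_std, x.shape)
        return out

    def backward(self, dy):
        xhat, inv_std, x_shape = self._cache
        n, d, h, w, c = x_shape
        g = self.groups
        self.grads["gamma"] += (dy * xhat.reshape(x_shape)).sum(axis=(0, 1, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 1, 2, 3))
        dxhat = (dy * self.params["gamma"]).reshape(n, d * h * w, g, c // g)
        m1 = dxhat.mean(axis=(1, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 3), keepdims=True)
        dx = inv_std * (dxhat - m1 - xhat * m2)
        return dx.reshape(x_shape)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        super().__init__()
        self.alpha = alpha
        self._cache = None

    def forward(self, x, train=False, rng=None):
        mask = x >= 0
        self._cache = mask
        return np.where(mask, x, self.alpha * x)

    def backward(self, dy):
        mask = self._cache
        return np.where(mask, dy, np.asarray(self.alpha, dtype=dy.dtype) * dy)


class Dropout(Layer):
    """Inverted dropout: active only when ``train=True`` and an rng is given."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in train mode requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Softmax(Layer):
    """Softmax over the channel (last) axis."""

    def forward(self, x, train=False, rng=None):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)
        self._cache = y
        return y

    def backward(self, dy):
        y = self._cache
        return y * (dy - (dy * y).sum(axis=-1, keepdims=True))


class Sigmoid(Layer):
    def forward(self, x, train=False, rng=None):
        # numerically stable two-sided form
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._cache = y
        return y

    def backward(self, dy):
        y = self._cache
        return dy * y * (1.0 - y)
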