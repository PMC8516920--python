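"""Minimal 3D convolutional layers with explicit forward/backward passes.

Arrays are channel-first, (C, X, Y, Z), single sample (the training batch
size is 1).  Convolutions are lowered to matrix products via im2col with
precomputed scatter indices for the input-gradient pass, which keeps the
whole engine in BLAS calls.  float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _pad(x: np.ndarray, padding) -> np.ndarray:
    px, py, pz = padding
    if px == py == pz == 0:
        return x
    return np.pad(x, ((0, 0), (px, px), (py, py), (pz, pz)))


class Conv3d(Layer):
    """3D convolution (cross-correlation) with per-axis kernel/stride/padding."""

    def __init__(self, in_channels, out_channels, kernel, stride=(1, 1, 1),
                 padding=(0, 0, 0), rng: np.random.Generator | None = None,
                 init_std: float | None = None) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.padding = tuple(padding)
        rng = rng or np.random.default_rng(0)
        kx, ky, kz = self.kernel
        if init_std is None:
            # He scaling: keeps early gradients alive at small filter counts
            init_std = float(np.sqrt(2.0 / (in_channels * kx * ky * kz)))
        w = rng.normal(0.0, init_std, size=(out_channels, in_channels, kx, ky, kz))
        self.w = Param(w, "w")
        self.b = Param(np.zeros(out_channels), "b")
        self._idx_cache: dict[tuple, np.ndarray] = {}
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def out_shape(self, spatial):
        return tuple(
            (spatial[i] + 2 * self.padding[i] - self.kernel[i]) // self.stride[i] + 1
            for i in range(3)
        )

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        sx, sy, sz = self.stride
        v = sliding_window_view(xp, self.kernel, axis=(1, 2, 3))
        v = v[:, ::sx, ::sy, ::sz]
        # (C, Ox, Oy, Oz, kx, ky, kz) -> (Ox*Oy*Oz, C*kx*ky*kz)
        c, ox, oy, oz = v.shape[:4]
        cols = v.transpose(1, 2, 3, 0, 4, 5, 6).reshape(ox * oy * oz, -1)
        return np.ascontiguousarray(cols), (ox, oy, oz)

    def _scatter_idx(self, padded_shape) -> np.ndarray:
        key = padded_shape
        if key not in self._idx_cache:
            flat = np.arange(int(np.prod(padded_shape)), dtype=np.int64).reshape(padded_shape)
            idx, _ = self._im2col(flat)
            self._idx_cache[key] = idx
        return self._idx_cache[key]

    @staticmethod
    def _offset_conv(xp: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Unit-stride valid correlation via zero-copy flat-offset GEMMs.

        The padded input is viewed as (C, flat); shifting the flat view by a
        kernel offset aligns xp[x+i, y+j, z+k] with output position (x, y, z),
        so each offset contributes one BLAS GEMM on a strided view.  Positions
        whose window wraps a row boundary land outside the valid crop.
        """
        f, c, kx, ky, kz = w.shape
        _, xpx, xpy, xpz = xp.shape
        ox, oy, oz = xpx - kx + 1, xpy - ky + 1, xpz - kz + 1
        flat = xp.reshape(c, -1)
        n = (ox - 1) * xpy * xpz + (oy - 1) * xpz + oz  # last valid flat pos + 1
        out = np.zeros((f, n), dtype=np.float32)
        for i in range(kx):
            for j in range(ky):
                for k in range(kz):
                    off = (i * xpy + j) * xpz + k
                    out += w[:, :, i, j, k] @ flat[:, off: off + n]
        full = np.empty((f, ox, xpy, xpz), dtype=np.float32)
        full.reshape(f, -1)[:, :n] = out
        return np.ascontiguousarray(full[:, :, :oy, :oz])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        xp = _pad(x, self.padding)
        if self.stride == (1, 1, 1):
            out = self._offset_conv(xp, self.w.data)
            out += self.b.data[:, None, None, None]
            if train:
                self._cache = ("offset", xp, x.shape, out.shape[1:])
            return out
        cols, out_sp = self._im2col(xp)
        wmat = self.w.data.reshape(self.out_channels, -1)
        out = cols @ wmat.T + self.b.data
        out = out.reshape(*out_sp, self.out_channels).transpose(3, 0, 1, 2)
        if train:
            self._cache = ("im2col", cols, xp.shape, x.shape, out_sp)
        return np.ascontiguousarray(out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._cache[0] == "offset":
            return self._backward_unit_stride(gy)
        _, cols, padded_shape, x_shape, out_sp = self._cache
        gmat = gy.transpose(1, 2, 3, 0).reshape(-1, self.out_channels)
        wmat = self.w.data.reshape(self.out_channels, -1)
        self.w.grad += (gmat.T @ cols).reshape(self.w.data.shape)
        self.b.grad += gmat.sum(axis=0)
        gcols = gmat @ wmat
        idx = self._scatter_idx(padded_shape)
        flat = np.bincount(
            idx.ravel(), weights=gcols.astype(np.float64).ravel(),
            minlength=int(np.prod(padded_shape)),
        )
        gx = flat.reshape(padded_shape).astype(np.float32)
        px, py, pz = self.padding
        gx = gx[:, px: px + x_shape[1], py: py + x_shape[2], pz: pz + x_shape[3]]
        return np.ascontiguousarray(gx)

    def _backward_unit_stride(self, gy: np.ndarray) -> np.ndarray:
        _, xp, x_shape, out_sp = self._cache
        f, c = self.out_channels, self.in_channels
        kx, ky, kz = self.kernel
        px, py, pz = self.padding
        ox, oy, oz = out_sp
        _, xpx, xpy, xpz = xp.shape
        n = (ox - 1) * xpy * xpz + (oy - 1) * xpz + oz
        # embed gy into padded-flat layout so offset views align with xp
        gye = np.zeros((f, ox, xpy, xpz), dtype=np.float32)
        gye[:, :, :oy, :oz] = gy
        gyflat = gye.reshape(f, -1)[:, :n]
        xflat = xp.reshape(c, -1)
        for i in range(kx):
            for j in range(ky):
                for k in range(kz):
                    off = (i * xpy + j) * xpz + k
                    self.w.grad[:, :, i, j, k] += gyflat @ xflat[:, off: off + n].T
        self.b.grad += gy.reshape(f, -1).sum(axis=1)
        # grad w.r.t. input: full correlation with flipped, transposed kernels
        gp = np.pad(gy, ((0, 0), (kx - 1 - px,) * 2, (ky - 1 - py,) * 2,
                         (kz - 1 - pz,) * 2))
        wflip = np.ascontiguousarray(
            self.w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        return self._offset_conv(gp, wflip)


class InstanceNorm3d(Layer):
    """Per-channel normalization over all spatial axes with learnable affine.

    Statistics are per sample and per channel; gamma/beta let downstream
    non-linearities see non-zero-mean features (important because a ReLU
    follows the normalized skip concatenation in the generator).
    """

    def __init__(self, n_channels: int | None = None, eps: float = 1e-5) -> None:
        self.eps = eps
        self.freeze = False  # treat statistics as constants in backward (probes)
        self._cache = None
        self.gamma = Param(np.ones(n_channels or 1), "gamma")
        self.beta = Param(np.zeros(n_channels or 1), "beta")
        self._lazy = n_channels is None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self._lazy and self.gamma.data.shape[0] != x.shape[0]:
            self.gamma = Param(np.ones(x.shape[0]), "gamma")
            self.beta = Param(np.zeros(x.shape[0]), "beta")
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = self.gamma.data[:, None, None, None] * xhat + self.beta.data[:, None, None, None]
        if train:
            self._cache = (xhat, inv)
        return y.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += gy.sum(axis=(1, 2, 3))
        gh = gy * self.gamma.data[:, None, None, None]
        if self.freeze:
            return (gh * inv).astype(np.float32)
        m_g = gh.mean(axis=(1, 2, 3), keepdims=True)
        m_gy = (gh * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return ((gh - m_g - xhat * m_gy) * inv).astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        self.slope = slope
        self._mask = None

    def forward(self, x, train=True):
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x).astype(np.float32)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy).astype(np.float32)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(slope=0.0)


class Tanh(Layer):
    def __init__(self) -> None:
        self._y = None

    def forward(self, x, train=True):
        y = np.tanh(x).astype(np.float32)
        if train:
            self._y = y
        return y

    def backward(self, gy):
        return (gy * (1.0 - self._y**2)).astype(np.float32)


class NearestUpsample3d(Layer):
    """Nearest-neighbor upsampling by integer per-axis factors."""

    def __init__(self, factors) -> None:
        self.factors = tuple(int(f) for f in factors)

    def forward(self, x, train=True):
        fx, fy, fz = self.factors
        y = x
        if fx > 1:
            y = np.repeat(y, fx, axis=1)
        if fy > 1:
            y = np.repeat(y, fy, axis=2)
        if fz > 1:
            y = np.repeat(y, fz, axis=3)
        return np.ascontiguousarray(y)

    def backward(self, gy):
        fx, fy, fz = self.factors
        c, X, Y, Z = gy.shape
        g = gy.reshape(c, X // fx, fx, Y // fy, fy, Z // fz, fz)
        return np.ascontiguousarray(g.sum(axis=(2, 4, 6)).astype(np.float32))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy
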