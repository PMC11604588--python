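"""Minimal 3D convolutional-network primitives on numpy.

Implements exactly the layers the dual-decoder segmentation network needs
— 3D convolution (stride 1, zero padding), batch normalization, ReLU,
2x max-pooling that records argmax indices, max-unpooling from recorded
indices, and 2x trilinear upsampling — each with a hand-written backward
pass.  Layers cache what their backward pass needs during ``forward`` and
release it after ``backward``; every backward is validated against central
finite differences in the test suite.

Array convention: feature maps are ``(N, C, D, H, W)`` float32/float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "MaxUnpool3d",
    "Upsample2x",
    "sgd_step",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: a differentiable operation with optional parameters."""

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state to persist in checkpoints (e.g. BN stats)."""
        return {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _offsets(k: int):
    for i in range(k):
        for j in range(k):
            for l in range(k):
                yield i, j, l


class Conv3d(Layer):
    """3D convolution, stride 1, zero padding ``k // 2`` (shape-preserving).

    He-normal weight initialization (the natural default for ReLU networks);
    biases start at zero.  The spatial sums are evaluated as one GEMM per
    kernel offset over shifted views of the padded input, which keeps memory
    at feature-map scale instead of materializing an im2col matrix.
    """

    def __init__(self, cin: int, cout: int, ksize: int = 3,
                 rng: np.random.Generator | None = None, name: str = "conv",
                 dtype=np.float32):
        if ksize % 2 != 1:
            raise ValueError("ksize must be odd to preserve shape")
        rng = rng if rng is not None else np.random.default_rng()
        self.cin, self.cout, self.ksize = cin, cout, ksize
        self.pad = ksize // 2
        fan_in = cin * ksize ** 3
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(cout, cin, ksize, ksize, ksize))
        self.weight = Param(f"{name}.weight", w.astype(dtype))
        self.bias = Param(f"{name}.bias", np.zeros(cout, dtype=dtype))
        self._xp = None  # padded input cached for backward

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        n, c, d, h, w = x.shape
        if c != self.cin:
            raise ValueError(
                f"{self.weight.name}: expected {self.cin} input channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        W = self.weight.value
        k = self.ksize
        # accumulate in (cout, N*DHW) layout: one GEMM per kernel offset
        out = np.zeros((self.cout, n, d, h, w), dtype=W.dtype)
        out_2d = out.reshape(self.cout, -1)
        for i, j, l in _offsets(k):
            sl = xp[:, :, i:i + d, j:j + h, l:l + w]
            # (cout, cin) @ (cin, n*dhw) after moving channel axis out front
            out_2d += W[:, :, i, j, l] @ sl.transpose(1, 0, 2, 3, 4).reshape(c, -1)
        out += self.bias.value[:, None, None, None, None]
        self._xp = xp if train else None
        self._shape = (n, c, d, h, w)
        return np.ascontiguousarray(out.transpose(1, 0, 2, 3, 4))

    def backward(self, g):
        if self._xp is None:
            raise RuntimeError("backward called before forward(train=True)")
        n, c, d, h, w = self._shape
        k, p = self.ksize, self.pad
        xp, W = self._xp, self.weight.value
        gt = g.transpose(1, 0, 2, 3, 4)          # (cout, n, d, h, w)
        g2d = gt.reshape(self.cout, -1)
        self.bias.grad += g2d.sum(axis=1)
        gxp = np.zeros_like(xp)
        gW = self.weight.grad
        for i, j, l in _offsets(k):
            sl = xp[:, :, i:i + d, j:j + h, l:l + w]
            x2d = sl.transpose(1, 0, 2, 3, 4).reshape(c, -1)
            gW[:, :, i, j, l] += g2d @ x2d.T
            contrib = (W[:, :, i, j, l].T @ g2d).reshape(c, n, d, h, w)
            gxp[:, :, i:i + d, j:j + h, l:l + w] += contrib.transpose(1, 0, 2, 3, 4)
        self._xp = None
        if p:
            return gxp[:, :, p:-p, p:-p, p:-p]
        return gxp


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W).

    Training uses batch statistics and maintains exponential running
    averages (momentum 0.1); evaluation uses the running averages.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn", dtype=np.float32):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.dtype = dtype
        self.gamma = Param(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._name = name
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {f"{self._name}.running_mean": self.running_mean,
                f"{self._name}.running_var": self.running_var}

    def forward(self, x, train=True):
        if x.shape[1] != self.channels:
            raise ValueError(f"{self._name}: expected {self.channels} channels, "
                             f"got {x.shape[1]}")
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(self.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        bshape = (1, -1, 1, 1, 1)
        xhat = (x - mean.reshape(bshape)) * inv.reshape(bshape)
        out = self.gamma.value.reshape(bshape) * xhat + self.beta.value.reshape(bshape)
        self._cache = (xhat, inv) if train else None
        return out.astype(self.dtype, copy=False)

    def backward(self, g):
        xhat, inv = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        m = g.shape[0] * g.shape[2] * g.shape[3] * g.shape[4]
        bshape = (1, -1, 1, 1, 1)
        self.beta.grad += g.sum(axis=axes)
        self.gamma.grad += (g * xhat).sum(axis=axes)
        gxhat = g * self.gamma.value.reshape(bshape)
        gx = (inv.reshape(bshape) / m) * (
            m * gxhat
            - gxhat.sum(axis=axes).reshape(bshape)
            - xhat * (gxhat * xhat).sum(axes).reshape(bshape)
        )
        return gx.astype(self.dtype, copy=False)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0 if train else None
        return np.maximum(x, 0.0)

    def backward(self, g):
        m, self._mask = self._mask, None
        return g * m


def _pool_windows(x):
    """(N,C,D,H,W) -> (N,C,D/2,H/2,W/2,8) view-copy of 2x2x2 windows."""
    n, c, d, h, w = x.shape
    r = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    return np.ascontiguousarray(r.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
        n, c, d // 2, h // 2, w // 2, 8)


def _unpool_windows(win):
    """Inverse of :func:`_pool_windows`."""
    n, c, d2, h2, w2, _ = win.shape
    r = win.reshape(n, c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
    return np.ascontiguousarray(r).reshape(n, c, 2 * d2, 2 * h2, 2 * w2)


class MaxPool3d(Layer):
    """2x2x2 max pooling that records the argmax index (0..7) per window."""

    def __init__(self):
        self.indices: np.ndarray | None = None

    def forward(self, x, train=True):
        if any(s % 2 for s in x.shape[2:]):
            raise ValueError(f"spatial shape {x.shape[2:]} not divisible by 2")
        win = _pool_windows(x)
        self.indices = np.argmax(win, axis=-1)
        out = np.take_along_axis(win, self.indices[..., None], axis=-1)[..., 0]
        return out

    def backward(self, g):
        win = np.zeros(g.shape + (8,), dtype=g.dtype)
        np.put_along_axis(win, self.indices[..., None], g[..., None], axis=-1)
        return _unpool_windows(win)


class MaxUnpool3d(Layer):
    """Sparse 2x upsampling: place each value at its recorded pooling index,
    zero elsewhere (the SegNet decoder primitive)."""

    def forward(self, x, indices, train=True):
        if indices.shape != x.shape:
            raise ValueError(
                f"pooling-index shape {indices.shape} does not match input {x.shape}")
        if indices.min() < 0 or indices.max() > 7:
            raise ValueError("pooling index outside its 2x2x2 window (corrupted state)")
        self._indices = indices
        win = np.zeros(x.shape + (8,), dtype=x.dtype)
        np.put_along_axis(win, indices[..., None], x[..., None], axis=-1)
        return _unpool_windows(win)

    def backward(self, g):
        win = _pool_windows(g)
        out = np.take_along_axis(win, self._indices[..., None], axis=-1)[..., 0]
        self._indices = None
        return out


def _interp_coeffs(n: int):
    """1D factor-2 linear interpolation: output i samples input at
    (i + 0.5)/2 - 0.5 with edge clamping (half-pixel-centred convention)."""
    coord = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    j0f = np.floor(coord)
    t = (coord - j0f).astype(np.float32)
    j0 = np.clip(j0f, 0, n - 1).astype(np.intp)
    j1 = np.clip(j0f + 1, 0, n - 1).astype(np.intp)
    return j0, j1, t


class Upsample2x(Layer):
    """2x trilinear upsampling (separable linear interpolation per axis)."""

    def forward(self, x, train=True):
        self._in_shape = x.shape
        for axis in (2, 3, 4):
            x = self._up_axis(x, axis)
        return x

    @staticmethod
    def _up_axis(x, axis):
        j0, j1, t = _interp_coeffs(x.shape[axis])
        a = np.take(x, j0, axis=axis)
        b = np.take(x, j1, axis=axis)
        shape = [1] * x.ndim
        shape[axis] = len(t)
        t = t.reshape(shape)
        return a * (1 - t) + b * t

    @staticmethod
    def _down_axis(g, axis, n):
        j0, j1, t = _interp_coeffs(n)
        g0 = np.moveaxis(g, axis, 0)
        out = np.zeros((n,) + g0.shape[1:], dtype=g.dtype)
        shape = [1] * g0.ndim
        shape[0] = len(t)
        t = t.reshape(shape)
        np.add.at(out, j0, g0 * (1 - t))
        np.add.at(out, j1, g0 * t)
        return np.moveaxis(out, 0, axis)

    def backward(self, g):
        for axis in (4, 3, 2):
            g = self._down_axis(g, axis, self._in_shape[axis])
        return g


def sgd_step(params: list[Param], lr: float) -> None:
    """Plain stochastic gradient descent (no momentum, no weight decay)."""
    for p in params:
        p.value -= lr * p.grad
        p.zero_grad()
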