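"""Minimal reverse-mode neural-network engine on numpy.

Layers operate on float32 arrays shaped ``(N, C, *spatial)`` with 2 or 3
spatial axes.  Each layer caches what it needs in ``forward`` and returns
the input gradient from ``backward``; parameter gradients accumulate on the
:class:`Param` objects.  Convolutions use shift-and-add (one small GEMM per
kernel offset) rather than im2col, which keeps peak memory flat for the
9x9 head/tail kernels on 64x64 feature maps.

Reflection padding is used throughout so that constant inputs map to
constant outputs; its exact adjoint (fold-back accumulation at the borders)
is implemented via padded index maps, which keeps every gradient correct to
finite-difference precision.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "ConvND",
    "InstanceNorm",
    "ReLU",
    "UpsampleNearest",
    "Residual",
    "Sequential",
    "Adam",
    "reflect_pad",
    "reflect_unpad_adjoint",
    "separable_filter",
    "separable_filter_adjoint",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


# ---------------------------------------------------------------------------
# reflection padding and its exact adjoint
# ---------------------------------------------------------------------------

def reflect_pad(x: np.ndarray, pads: list[tuple[int, int]]) -> np.ndarray:
    """Reflect-pad (no edge repetition) with per-axis (lo, hi) widths."""
    return np.pad(x, pads, mode="reflect")


def _axis_unpad_adjoint(g: np.ndarray, axis: int, lo: int, hi: int) -> np.ndarray:
    """Adjoint of reflect-padding a single axis: accumulate pad gradients
    back onto their source positions."""
    if lo == 0 and hi == 0:
        return g
    n = g.shape[axis] - lo - hi
    idx = np.pad(np.arange(n), (lo, hi), mode="reflect")
    gm = np.moveaxis(g, axis, -1)
    lead = gm.shape[:-1]
    gm = gm.reshape(-1, gm.shape[-1])
    acc = np.zeros((gm.shape[0], n), dtype=g.dtype)
    np.add.at(acc, (slice(None), idx), gm)
    return np.moveaxis(acc.reshape(*lead, n), -1, axis)


def reflect_unpad_adjoint(g: np.ndarray, pads: list[tuple[int, int]]) -> np.ndarray:
    for axis, (lo, hi) in enumerate(pads):
        g = _axis_unpad_adjoint(g, axis, lo, hi)
    return g


# ---------------------------------------------------------------------------
# separable symmetric filtering (used by SSIM) with exact adjoint
# ---------------------------------------------------------------------------

def _correlate1d_valid(x: np.ndarray, w: np.ndarray, axis: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view

    xm = np.moveaxis(x, axis, -1)
    win = sliding_window_view(xm, len(w), axis=-1)
    out = win @ w.astype(x.dtype)
    return np.moveaxis(out, -1, axis)


def separable_filter(x: np.ndarray, w: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Correlate with a symmetric 1D kernel along each axis, reflect-padded."""
    r = (len(w) - 1) // 2
    for ax in axes:
        pads = [(0, 0)] * x.ndim
        pads[ax] = (r, r)
        x = _correlate1d_valid(np.pad(x, pads, mode="reflect"), w, ax)
    return x


def separable_filter_adjoint(g: np.ndarray, w: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Exact adjoint of :func:`separable_filter` (w symmetric)."""
    r = (len(w) - 1) // 2
    for ax in reversed(axes):
        pads = [(0, 0)] * g.ndim
        pads[ax] = (2 * r, 2 * r)
        # adjoint of (reflect-pad -> valid-correlate): full correlation with
        # the flipped kernel, then fold the pad region back onto its sources
        gp = _correlate1d_valid(np.pad(g, pads, mode="constant"), w[::-1], ax)
        g = _axis_unpad_adjoint(gp, ax, r, r)
    return g


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _kernel_offsets(k: int, nd: int):
    grids = np.meshgrid(*([np.arange(k)] * nd), indexing="ij")
    return list(zip(*(g.ravel() for g in grids)))


class ConvND(Layer):
    """Same-size convolution with reflection padding, stride 1.

    Weight shape ``(cout, cin, k, ..., k)``; He-normal initialization from
    the provided generator.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 nd: int = 2, gain: float = 2.0):
        if k % 2 == 0:
            raise ValueError("even kernel sizes have no centre; use an odd size")
        self.cin, self.cout, self.k, self.nd = cin, cout, k, nd
        fan_in = cin * k ** nd
        w = rng.standard_normal((cout, cin) + (k,) * nd) * np.sqrt(gain / fan_in)
        self.w = Param(w)
        self.b = Param(np.zeros(cout))
        self.offsets = _kernel_offsets(k, nd)
        self._xp: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _pads(self) -> list[tuple[int, int]]:
        r = (self.k - 1) // 2
        return [(0, 0), (0, 0)] + [(r, r)] * self.nd

    def forward(self, x: np.ndarray) -> np.ndarray:
        assert x.ndim == 2 + self.nd and x.shape[1] == self.cin
        self._in_shape = x.shape
        xp = reflect_pad(x, self._pads())
        self._xp = xp
        n = x.shape[0]
        spatial = x.shape[2:]
        s_flat = int(np.prod(spatial))
        y = np.zeros((n, self.cout, s_flat), dtype=np.float32)
        wv = self.w.value.reshape(self.cout, self.cin, -1)
        for i, off in enumerate(self.offsets):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + e) for o, e in zip(off, spatial)
            )
            xs = np.ascontiguousarray(xp[sl]).reshape(n, self.cin, s_flat)
            y += np.matmul(wv[:, :, i], xs)
        y += self.b.value[None, :, None]
        return y.reshape((n, self.cout) + spatial)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp = self._xp
        n = g.shape[0]
        spatial = g.shape[2:]
        s_flat = int(np.prod(spatial))
        g2 = np.ascontiguousarray(g).reshape(n, self.cout, s_flat)
        gw = np.zeros_like(self.w.value.reshape(self.cout, self.cin, -1))
        gxp = np.zeros_like(xp)
        wv = self.w.value.reshape(self.cout, self.cin, -1)
        for i, off in enumerate(self.offsets):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + e) for o, e in zip(off, spatial)
            )
            xs = np.ascontiguousarray(xp[sl]).reshape(n, self.cin, s_flat)
            gw[:, :, i] += np.matmul(g2, xs.transpose(0, 2, 1)).sum(axis=0)
            gxp[sl] += np.matmul(wv[:, :, i].T, g2).reshape((n, self.cin) + spatial)
        self.w.grad += gw.reshape(self.w.value.shape)
        self.b.grad += g2.sum(axis=(0, 2))
        return reflect_unpad_adjoint(gxp, self._pads()).astype(np.float32)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over the spatial axes with a
    learnable affine.  A constant map normalizes to zero (then beta), so
    constants stay spatially constant."""

    EPS = 1e-5

    def __init__(self, c: int):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._std = np.sqrt(var + self.EPS)
        self._xhat = (x - mu) / self._std
        shape = (1, -1) + (1,) * (x.ndim - 2)
        return self.gamma.value.reshape(shape) * self._xhat + self.beta.value.reshape(shape)

    def backward(self, g: np.ndarray) -> np.ndarray:
        axes = tuple(range(2, g.ndim))
        sum_axes = (0,) + axes
        shape = (1, -1) + (1,) * (g.ndim - 2)
        self.gamma.grad += (g * self._xhat).sum(axis=sum_axes)
        self.beta.grad += g.sum(axis=sum_axes)
        gh = g * self.gamma.value.reshape(shape)
        m1 = gh.mean(axis=axes, keepdims=True)
        m2 = (gh * self._xhat).mean(axis=axes, keepdims=True)
        return ((gh - m1 - self._xhat * m2) / self._std).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0).astype(np.float32)


class UpsampleNearest(Layer):
    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        for ax in range(2, x.ndim):
            x = np.repeat(x, f, axis=ax)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        f = self.factor
        for ax in range(2, g.ndim):
            shape = list(g.shape)
            shape[ax] = shape[ax] // f
            shape.insert(ax + 1, f)
            g = g.reshape(shape).sum(axis=ax + 1)
        return np.ascontiguousarray(g)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class Residual(Layer):
    """Additive skip connection around a body of layers."""

    def __init__(self, body: list[Layer]):
        self.body = Sequential(body)

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.body.forward(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g + self.body.backward(g)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with exponential-decay moment estimates and optional decoupled
    weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.value
            p.value -= self.lr * update
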