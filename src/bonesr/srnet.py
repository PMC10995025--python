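"""The super-resolution network and its loss functions.

The architecture follows the residual image-transformation design of
Johnson-style feed-forward SR, with the transposed convolutions replaced by
resize convolutions (nearest-neighbour x2 upsampling followed by a 3x3
convolution) to avoid checkerboard artifacts:

    conv9 -> IN -> ReLU
    [conv3 -> IN -> ReLU -> conv3 -> IN] + skip   (x n_residual_blocks)
    (upsample x2 -> conv3 -> IN -> ReLU)          (x2, realizing the x4 factor)
    conv9 -> 1 channel (linear; clamped to [0,1] at inference only)

Three composite loss recipes are provided:

``baseline``   0.8 * MSE + 0.2 * TV
``structure``  1 - SSIM
``visual``     0.1 * MAE + 1.0 * TV + 1.0 * perceptual

The perceptual term compares feature maps under a *frozen* convolutional
feature extractor.  Two backends exist: ``pretrained_vgg16`` (requires a
deep-learning runtime with downloadable weights, unavailable here and kept
as an explicit error) and ``seeded_random_conv``, a fixed randomly
initialized conv stack — random features are a standard, surprisingly
strong stand-in for trained perceptual features and keep the package fully
self-contained.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _engine as eng

__all__ = [
    "SRNetworkConfig",
    "LossRecipe",
    "LOSS_RECIPES",
    "FeatureExtractor",
    "TrainedModel",
    "build_network",
    "save_model",
    "load_model",
    "mse_loss",
    "mae_loss",
    "tv_loss",
    "ssim",
    "structure_loss",
    "perceptual_loss",
    "composite_loss",
]

UPSCALE = 4


@dataclass(frozen=True)
class SRNetworkConfig:
    dims: int = 2
    n_residual_blocks: int = 4
    base_channels: int = 64
    upscale: int = UPSCALE
    upsample_mode: str = "resize_convolution"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.upscale != UPSCALE:
            raise ValueError("the upscale factor is fixed at 4 (two x2 stages)")
        if self.n_residual_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.upsample_mode != "resize_convolution":
            raise ValueError("only resize_convolution upsampling is supported")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class LossRecipe:
    name: str
    terms: tuple[tuple[str, float], ...]


LOSS_RECIPES: dict[str, LossRecipe] = {
    "baseline": LossRecipe("baseline", (("mse", 0.8), ("tv", 0.2))),
    "structure": LossRecipe("structure", (("structure", 1.0),)),
    "visual": LossRecipe("visual", (("mae", 0.1), ("tv", 1.0), ("perceptual", 1.0))),
}


def _make_layers(config: SRNetworkConfig) -> list[eng.Layer]:
    rng = np.random.default_rng(config.seed)
    nd, c = config.dims, config.base_channels
    layers: list[eng.Layer] = [
        eng.ConvND(1, c, 9, rng, nd=nd), eng.InstanceNorm(c), eng.ReLU(),
    ]
    for _ in range(config.n_residual_blocks):
        layers.append(eng.Residual([
            eng.ConvND(c, c, 3, rng, nd=nd), eng.InstanceNorm(c), eng.ReLU(),
            eng.ConvND(c, c, 3, rng, nd=nd), eng.InstanceNorm(c),
        ]))
    for _ in range(2):  # two x2 resize-convolution stages -> x4 total
        layers += [
            eng.UpsampleNearest(2),
            eng.ConvND(c, c, 3, rng, nd=nd), eng.InstanceNorm(c), eng.ReLU(),
        ]
    tail = eng.ConvND(c, 1, 9, rng, nd=nd)
    tail.b.value[:] = 0.5  # start at mid-gray so luminance matching converges fast
    layers.append(tail)
    return layers


class TrainedModel:
    """A network handle: architecture config, parameters, and provenance."""

    def __init__(self, config: SRNetworkConfig, recipe: str = "", seed: int | None = None):
        self.config = config
        self.recipe = recipe
        self.seed = config.seed if seed is None else seed
        self.net = eng.Sequential(_make_layers(config))

    @property
    def dims(self) -> int:
        return self.config.dims

    @property
    def upscale(self) -> int:
        return self.config.upscale

    def parameters(self) -> list[eng.Param]:
        return self.net.params()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, lr_batch: np.ndarray) -> np.ndarray:
        """Raw (unclamped) forward pass on an ``(N, 1, *spatial)`` batch."""
        x = np.asarray(lr_batch, dtype=np.float32)
        if x.ndim != 2 + self.dims or x.shape[1] != 1:
            raise ValueError(
                f"expected (N, 1{', S' * self.dims}) input for a {self.dims}D model, "
                f"got shape {x.shape}"
            )
        return self.net.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def predict(self, lr_batch: np.ndarray) -> np.ndarray:
        """Inference forward pass, clamped to [0, 1]."""
        return np.clip(self.forward(lr_batch), 0.0, 1.0)


def build_network(config: SRNetworkConfig, recipe: str = "") -> TrainedModel:
    """Build a freshly initialized (untrained) model; seeded, reproducible."""
    return TrainedModel(config, recipe=recipe)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file checkpoint: config JSON + flat parameter arrays."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(
        str(path),
        _config=np.frombuffer(model.config.to_json().encode(), dtype=np.uint8),
        _hash=np.frombuffer(model.config.hash().encode(), dtype=np.uint8),
        _recipe=np.frombuffer(model.recipe.encode() or b" ", dtype=np.uint8),
        **arrays,
    )


def load_model(path: str | Path) -> TrainedModel:
    with np.load(str(path)) as z:
        cfg_json = bytes(z["_config"]).decode()
        stored_hash = bytes(z["_hash"]).decode()
        recipe = bytes(z["_recipe"]).decode().strip()
        config = SRNetworkConfig(**json.loads(cfg_json))
        if config.hash() != stored_hash:
            raise ValueError("checkpoint config hash mismatch; refusing to load")
        model = TrainedModel(config, recipe=recipe)
        for i, p in enumerate(model.parameters()):
            stored = z[f"p{i}"]
            if stored.shape != p.value.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.value[...] = stored
    return model


# ---------------------------------------------------------------------------
# losses (each has an internal value+gradient form used by the trainer)
# ---------------------------------------------------------------------------

def _check_shapes(pred: np.ndarray, target: np.ndarray) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    _check_shapes(pred, target)
    return float(np.mean((np.asarray(pred, dtype=np.float64) - target) ** 2))


def _mse_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    return (2.0 / pred.size) * (pred - target)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> float:
    _check_shapes(pred, target)
    return float(np.mean(np.abs(np.asarray(pred, dtype=np.float64) - target)))


def _mae_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    return np.sign(pred - target) / pred.size


def _spatial_axes_of(x: np.ndarray, spatial_dims: int | None) -> tuple[int, ...]:
    if spatial_dims is None:
        spatial_dims = x.ndim if x.ndim <= 3 else 2
    return tuple(range(x.ndim - spatial_dims, x.ndim))


def tv_loss(pred: np.ndarray, spatial_dims: int | None = None) -> float:
    """Anisotropic total variation: sum over spatial axes of the mean
    absolute forward difference along that axis (a 1D ramp 0,1,2,3 scores 1)."""
    x = np.asarray(pred, dtype=np.float64)
    total = 0.0
    for ax in _spatial_axes_of(x, spatial_dims):
        if x.shape[ax] < 2:
            continue
        total += float(np.mean(np.abs(np.diff(x, axis=ax))))
    return total


def _tv_grad(pred: np.ndarray, spatial_dims: int | None = None) -> np.ndarray:
    g = np.zeros_like(pred, dtype=np.float64)
    for ax in _spatial_axes_of(pred, spatial_dims):
        if pred.shape[ax] < 2:
            continue
        d = np.diff(pred, axis=ax)
        s = np.sign(d) / d.size
        sl_hi = [slice(None)] * pred.ndim
        sl_lo = [slice(None)] * pred.ndim
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        g[tuple(sl_hi)] += s
        g[tuple(sl_lo)] -= s
    return g.astype(np.float32)


def _gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    i = np.arange(size) - (size - 1) / 2.0
    w = np.exp(-(i ** 2) / (2 * sigma ** 2))
    return (w / w.sum()).astype(np.float64)


_SSIM_K1, _SSIM_K2 = 0.01, 0.03


def _ssim_stats(pred, target, axes, win):
    f = lambda a: eng.separable_filter(a, win, axes)
    mu_p, mu_t = f(pred), f(target)
    s_pp = f(pred * pred) - mu_p ** 2
    s_tt = f(target * target) - mu_t ** 2
    s_pt = f(pred * target) - mu_p * mu_t
    c1 = (_SSIM_K1 * 1.0) ** 2
    c2 = (_SSIM_K2 * 1.0) ** 2
    a1 = 2 * mu_p * mu_t + c1
    a2 = 2 * s_pt + c2
    b1 = mu_p ** 2 + mu_t ** 2 + c1
    b2 = s_pp + s_tt + c2
    return mu_p, mu_t, a1, a2, b1, b2


def ssim(pred: np.ndarray, target: np.ndarray, window_size: int = 11,
         sigma: float = 1.5, spatial_dims: int | None = None) -> float:
    """Mean local SSIM with a Gaussian window (size 11, sd 1.5), dynamic
    range 1.0, stabilizers K1=0.01, K2=0.03."""
    _check_shapes(pred, target)
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    axes = _spatial_axes_of(x, spatial_dims)
    for ax in axes:
        if x.shape[ax] < window_size:
            raise ValueError(
                f"window size {window_size} exceeds image extent {x.shape[ax]} on axis {ax}"
            )
    win = _gaussian_window(window_size, sigma)
    _, _, a1, a2, b1, b2 = _ssim_stats(x, y, axes, win)
    return float(np.mean((a1 * a2) / (b1 * b2)))


def structure_loss(pred: np.ndarray, target: np.ndarray, **kw) -> float:
    """The complement of SSIM, optimized by the structure recipe."""
    return 1.0 - ssim(pred, target, **kw)


def _structure_grad(pred: np.ndarray, target: np.ndarray, window_size: int = 11,
                    sigma: float = 1.5, spatial_dims: int | None = None) -> np.ndarray:
    """Analytic gradient of 1 - mean(SSIM map) w.r.t. pred.

    The local statistics are window filterings of p, p^2 and p*t; the chain
    rule therefore routes each partial back through the (exact) filter
    adjoint.
    """
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    axes = _spatial_axes_of(x, spatial_dims)
    win = _gaussian_window(window_size, sigma)
    mu_p, mu_t, a1, a2, b1, b2 = _ssim_stats(x, y, axes, win)
    m = a1.size
    # partials of the per-pixel SSIM map S = (a1/b1)*(a2/b2)
    f_mu = (a2 / b2) * (2 * mu_t * b1 - 2 * mu_p * a1) / b1 ** 2
    f_spp = -(a1 / b1) * a2 / b2 ** 2
    f_spt = (a1 / b1) * 2.0 / b2
    adj = lambda a: eng.separable_filter_adjoint(a, win, axes)
    grad_s = (
        adj(f_mu)
        + 2 * x * adj(f_spp) - 2 * adj(f_spp * mu_p)
        + y * adj(f_spt) - adj(f_spt * mu_t)
    ) / m
    return (-grad_s).astype(np.float32)  # loss = 1 - mean(S)


class FeatureExtractor:
    """Frozen convolutional feature extractor for the perceptual loss.

    ``seeded_random_conv``: four 3x3 conv stages (1->8->8->8->8 channels,
    ReLU between), He-initialized from ``seed`` and never trained; taps after
    the second and fourth stages.  ``pretrained_vgg16`` is declared but
    unavailable in a self-contained offline build and raises with a pointer
    to the fallback.
    """

    TAPS = (1, 3)  # conv indices (0-based) after which features are tapped

    def __init__(self, backend: str = "seeded_random_conv", seed: int = 0,
                 channels: int = 8, nd: int = 2):
        if backend == "pretrained_vgg16":
            raise RuntimeError(
                "the pretrained_vgg16 perceptual backend requires downloadable "
                "weights and a deep-learning runtime; use "
                "backend='seeded_random_conv' instead"
            )
        if backend != "seeded_random_conv":
            raise ValueError(f"unknown perceptual backend {backend!r}")
        self.backend = backend
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = channels
        self.convs = [
            eng.ConvND(1, c, 3, rng, nd=nd),
            eng.ConvND(c, c, 3, rng, nd=nd),
            eng.ConvND(c, c, 3, rng, nd=nd),
            eng.ConvND(c, c, 3, rng, nd=nd),
        ]
        self.relus = [eng.ReLU() for _ in self.convs]

    def features(self, x: np.ndarray) -> list[np.ndarray]:
        feats = []
        h = x
        for i, (conv, relu) in enumerate(zip(self.convs, self.relus)):
            h = relu.forward(conv.forward(h))
            if i in self.TAPS:
                feats.append(h)
        return feats

    def backprop_feature_grads(self, grads: list[np.ndarray]) -> np.ndarray:
        """Propagate tap gradients back to the extractor input (parameters
        stay frozen; their accumulated grads are discarded)."""
        tap_iter = dict(zip(self.TAPS, grads))
        g = None
        for i in reversed(range(len(self.convs))):
            if i in tap_iter:
                g = tap_iter[i] if g is None else g + tap_iter[i]
            if g is None:
                continue
            g = self.convs[i].backward(self.relus[i].backward(g))
        for conv in self.convs:
            for p in conv.params():
                p.grad[...] = 0.0
        return g


def perceptual_loss(pred: np.ndarray, target: np.ndarray,
                    fx: FeatureExtractor) -> float:
    """Sum over tap points of the mean squared feature difference."""
    _check_shapes(pred, target)
    p4, t4, _ = _as_batch(pred, target, fx)
    fp = fx.features(p4)
    ft = fx.features(t4)
    return float(sum(np.mean((a.astype(np.float64) - b) ** 2) for a, b in zip(fp, ft)))


def _as_batch(pred, target, fx):
    """Lift bare 2D/3D images to (N, 1, *spatial) for the extractor."""
    nd = fx.convs[0].nd
    p = np.asarray(pred, dtype=np.float32)
    t = np.asarray(target, dtype=np.float32)
    lead = p.ndim - nd
    if lead == 0:
        reshape = lambda a: a[None, None]
    elif lead == 1:
        reshape = lambda a: a[:, None]
    elif lead == 2:
        reshape = lambda a: a
    else:
        raise ValueError(f"cannot interpret shape {p.shape} for a {nd}D extractor")
    return reshape(p), reshape(t), lead


def _perceptual_grad(pred: np.ndarray, target: np.ndarray,
                     fx: FeatureExtractor) -> np.ndarray:
    p4, t4, lead = _as_batch(pred, target, fx)
    fp = fx.features(p4)
    ft = fx.features(t4)
    grads = [(2.0 / a.size) * (a - b) for a, b in zip(fp, ft)]
    g = fx.backprop_feature_grads(grads)
    return g.reshape(pred.shape).astype(np.float32)


_TERM_FUNCS = {
    "mse": (lambda p, t, fx: mse_loss(p, t), lambda p, t, fx: _mse_grad(p, t)),
    "mae": (lambda p, t, fx: mae_loss(p, t), lambda p, t, fx: _mae_grad(p, t)),
    "tv": (lambda p, t, fx: tv_loss(p), lambda p, t, fx: _tv_grad(p)),
    "structure": (lambda p, t, fx: structure_loss(p, t),
                  lambda p, t, fx: _structure_grad(p, t)),
    "perceptual": (lambda p, t, fx: perceptual_loss(p, t, fx),
                   lambda p, t, fx: _perceptual_grad(p, t, fx)),
}


def composite_loss(recipe: str | LossRecipe, pred: np.ndarray, target: np.ndarray,
                   fx: FeatureExtractor | None = None,
                   with_grad: bool = False):
    """Weighted sum of the recipe's terms; optionally also the gradient
    w.r.t. ``pred`` (used by the trainer)."""
    if isinstance(recipe, str):
        try:
            recipe = LOSS_RECIPES[recipe]
        except KeyError:
            raise ValueError(
                f"unknown recipe {recipe!r}; expected one of {sorted(LOSS_RECIPES)}"
            ) from None
    needs_fx = any(name == "perceptual" for name, _ in recipe.terms)
    if needs_fx and fx is None:
        raise ValueError("the visual recipe requires a FeatureExtractor")
    total = 0.0
    grad = np.zeros_like(np.asarray(pred, dtype=np.float32)) if with_grad else None
    for name, weight in recipe.terms:
        value_fn, grad_fn = _TERM_FUNCS[name]
        total += weight * value_fn(pred, target, fx)
        if with_grad:
            grad += np.float32(weight) * grad_fn(pred, target, fx)
    if with_grad:
        return float(total), grad
    return float(total)
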