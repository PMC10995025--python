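"""Paired stochastic augmentation of (input, target) patches.

Geometric transforms (flips, rotations, translations) are drawn once per
pair and applied to both members — with translations scaled by 4 on the
high-resolution grid — so the pair keeps depicting the same tissue.
Brightness and contrast jitter are likewise applied identically to both
members.  Random blur, in contrast, degrades only the input: blurring the
target would teach the network to blur.

The final ``crop_pad_to_net`` step cuts the co-located network-sized windows
(16 on the input grid, 64 on the target grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .degrade import UPSCALE_FACTOR, PatchPair

__all__ = ["AugmentPolicy", "augment_pair", "crop_pad_to_net"]


@dataclass
class AugmentPolicy:
    """Augmentation probabilities and ranges.

    Rotations are right-angle multiples (lossless) plus an optional
    small-angle bilinear rotation of up to ``rotation_deg`` degrees with
    reflection padding; translations are integer voxels on the input grid.
    """

    p_flip: float = 0.5
    p_rot90: float = 0.5
    rotation_deg: float = 0.0
    translation_vox: int = 0
    brightness: float = 0.0       # additive, float01 units
    contrast: float = 0.0         # multiplicative half-range, e.g. 0.1 -> [0.9, 1.1]
    p_blur: float = 0.0
    blur_sd: tuple[float, float] = (0.3, 1.0)
    crop_lr: int = 16

    def __post_init__(self) -> None:
        for p in (self.p_flip, self.p_rot90, self.p_blur):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.crop_lr < 1:
            raise ValueError("crop size must be positive")


def _spatial_axes(ndim: int) -> tuple[int, ...]:
    return tuple(range(ndim))


def augment_pair(pair: PatchPair, policy: AugmentPolicy,
                 rng: np.random.Generator) -> PatchPair:
    """Apply one random draw of the policy consistently to both patches."""
    lr = pair.lr.astype(np.float32, copy=True)
    hr = pair.hr.astype(np.float32, copy=True)
    nd = lr.ndim
    axes = _spatial_axes(nd)

    for ax in axes:
        if rng.random() < policy.p_flip:
            lr = np.flip(lr, axis=ax)
            hr = np.flip(hr, axis=ax)
    # in-plane right-angle rotation (last two axes; square patches)
    if rng.random() < policy.p_rot90:
        k = int(rng.integers(1, 4))
        lr = np.rot90(lr, k, axes=(nd - 2, nd - 1))
        hr = np.rot90(hr, k, axes=(nd - 2, nd - 1))
    if policy.rotation_deg > 0:
        ang = float(rng.uniform(-policy.rotation_deg, policy.rotation_deg))
        lr = ndimage.rotate(lr, ang, axes=(nd - 2, nd - 1), reshape=False,
                            order=1, mode="reflect")
        hr = ndimage.rotate(hr, ang, axes=(nd - 2, nd - 1), reshape=False,
                            order=1, mode="reflect")
    if policy.translation_vox > 0:
        t = rng.integers(-policy.translation_vox, policy.translation_vox + 1, size=nd)
        lr = np.roll(lr, shift=tuple(t), axis=axes)
        hr = np.roll(hr, shift=tuple(UPSCALE_FACTOR * t), axis=axes)

    if policy.brightness > 0 or policy.contrast > 0:
        b = float(rng.uniform(-policy.brightness, policy.brightness)) if policy.brightness > 0 else 0.0
        c = float(rng.uniform(1 - policy.contrast, 1 + policy.contrast)) if policy.contrast > 0 else 1.0
        m = float(lr.mean())
        lr = (lr - m) * c + m + b
        hr = (hr - m) * c + m + b
    if policy.p_blur > 0 and rng.random() < policy.p_blur:
        sd = float(rng.uniform(*policy.blur_sd))
        lr = ndimage.gaussian_filter(lr, sd, mode="reflect")

    lr = np.clip(lr, 0.0, 1.0)
    hr = np.clip(hr, 0.0, 1.0)
    return PatchPair(lr=np.ascontiguousarray(lr), hr=np.ascontiguousarray(hr),
                     sample_id=pair.sample_id, patient_id=pair.patient_id,
                     origin=pair.origin, meta=dict(pair.meta))


def _sym_pad(n_missing: int) -> tuple[int, int]:
    lo = n_missing // 2
    return lo, n_missing - lo


def crop_pad_to_net(pair: PatchPair, policy: AugmentPolicy,
                    rng: np.random.Generator) -> PatchPair:
    """Random co-located crop to network size; zero-pad if the patch is small.

    The high-resolution crop origin is exactly 4x the low-resolution origin,
    so the two windows cover the same physical extent.
    """
    size = policy.crop_lr
    lr, hr = pair.lr, pair.hr
    nd = lr.ndim

    pad_lr, pad_hr = [], []
    for ax in range(nd):
        missing = max(0, size - lr.shape[ax])
        lo, hi = _sym_pad(missing)
        pad_lr.append((lo, hi))
        pad_hr.append((UPSCALE_FACTOR * lo, UPSCALE_FACTOR * hi))
    if any(lo or hi for lo, hi in pad_lr):
        lr = np.pad(lr, pad_lr, mode="constant")
        hr = np.pad(hr, pad_hr, mode="constant")

    origin = tuple(
        int(rng.integers(0, lr.shape[ax] - size + 1)) for ax in range(nd)
    )
    sl_lr = tuple(slice(o, o + size) for o in origin)
    sl_hr = tuple(slice(UPSCALE_FACTOR * o, UPSCALE_FACTOR * (o + size)) for o in origin)
    return PatchPair(lr=np.ascontiguousarray(lr[sl_lr]),
                     hr=np.ascontiguousarray(hr[sl_hr]),
                     sample_id=pair.sample_id, patient_id=pair.patient_id,
                     origin=pair.origin, meta=dict(pair.meta))
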