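"""Degradation cascade: build (input, target) training pairs from
high-resolution volumes.

Training data are synthesized from micro-CT-grade volumes in two stages.
The *target* is the volume resampled to the desired output resolution with a
light anti-aliasing Gaussian (kernel size 7, sd 0.5).  The *input* emulates
the clinical scan: the target is downscaled by exactly 4 (block averaging),
then Gaussian-blurred (sd 1.0) and median-filtered (size 3) to mimic the
softer point-spread and the non-linear artifact suppression of the low-end
imaging chain.  Three resolution cascades are supported out of the box
(200→50 µm, 400→100 µm, 488→122 µm), all with the fixed ×4 factor.

Patches are tiled on aligned grids (HR offsets are 4× the LR offsets) and
cross-validation folds are split *by patient* so a patient never appears in
both the training and validation side of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .volio import Volume

__all__ = [
    "ResolutionCascade",
    "CASCADES",
    "PatchPair",
    "make_target",
    "make_input",
    "tile_patches",
    "grouped_kfold",
]

UPSCALE_FACTOR = 4


@dataclass(frozen=True)
class ResolutionCascade:
    """An (input resolution, target resolution) pair with the fixed ×4 gap."""

    input_um: float
    target_um: float
    factor: int = UPSCALE_FACTOR

    def __post_init__(self) -> None:
        if self.factor != UPSCALE_FACTOR:
            raise ValueError("the cascade factor is fixed at 4")
        if abs(self.input_um - self.factor * self.target_um) > 1e-9:
            raise ValueError(
                f"input_um must equal {self.factor} x target_um, got "
                f"{self.input_um} vs {self.factor} x {self.target_um}"
            )


CASCADES: dict[str, ResolutionCascade] = {
    "200to50": ResolutionCascade(200.0, 50.0),
    "400to100": ResolutionCascade(400.0, 100.0),
    "488to122": ResolutionCascade(488.0, 122.0),
}


@dataclass
class PatchPair:
    """A co-registered low-resolution / high-resolution patch pair."""

    lr: np.ndarray
    hr: np.ndarray
    sample_id: str = ""
    patient_id: str = ""
    origin: tuple[int, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lr.ndim != self.hr.ndim:
            raise ValueError("lr and hr patches must have the same dimensionality")
        for a, b in zip(self.lr.shape, self.hr.shape):
            if b != UPSCALE_FACTOR * a:
                raise ValueError(
                    f"hr extents must be 4 x lr extents, got {self.lr.shape} vs {self.hr.shape}"
                )


# gaussian_filter truncated to a 7-tap kernel at sd 0.5: radius 3 -> truncate 6
_TARGET_BLUR_SD = 0.5
_TARGET_BLUR_TRUNCATE = 3.0 / _TARGET_BLUR_SD
# stated blur after downscaling has sd 1.0 with an (even, centreless) size-4
# kernel; realized as the nearest odd size 5 -> radius 2
_INPUT_BLUR_SD = 1.0
_INPUT_BLUR_TRUNCATE = 2.0 / _INPUT_BLUR_SD


def make_target(hr: Volume, cascade: ResolutionCascade) -> Volume:
    """Resample a high-resolution volume to the cascade's target resolution.

    Linear, anti-aliased resampling to ``round(extent * voxel / target)``
    voxels per axis, followed by a Gaussian (7-tap, sd 0.5) to suppress any
    residual aliasing.  If the volume is already at target resolution only
    the blur is applied.
    """
    if np.any(hr.voxel_size_um > cascade.target_um + 1e-9):
        raise ValueError(
            f"cannot upsample: source voxel {hr.voxel_size_um} um is coarser "
            f"than target {cascade.target_um} um"
        )
    x = hr.data.astype(np.float64)
    new_shape = tuple(
        int(round(n * vs / cascade.target_um))
        for n, vs in zip(hr.shape, hr.voxel_size_um)
    )
    if new_shape != hr.shape:
        x = _sk_resize(x, new_shape, order=1, anti_aliasing=True, mode="reflect",
                       preserve_range=True)
    x = ndimage.gaussian_filter(x, _TARGET_BLUR_SD, truncate=_TARGET_BLUR_TRUNCATE,
                                mode="reflect")
    out = hr.with_data(np.clip(x, 0.0, 1.0).astype(np.float32), dtype_tag="float01")
    out.voxel_size_um = np.full(3, float(cascade.target_um))
    return out


def _block_average(x: np.ndarray, factor: int, axes: tuple[int, ...]) -> np.ndarray:
    """Non-overlapping block mean over the given axes; trailing rows beyond
    the last full block are discarded."""
    slicer = [slice(None)] * x.ndim
    for ax in axes:
        slicer[ax] = slice(0, (x.shape[ax] // factor) * factor)
    x = x[tuple(slicer)]
    for ax in sorted(axes):
        shape = list(x.shape)
        shape[ax] = shape[ax] // factor
        shape.insert(ax + 1, factor)
        x = x.reshape(shape).mean(axis=ax + 1)
    return x


def make_input(target: Volume, dims: int = 3) -> Volume:
    """Degrade a target volume into the matching low-resolution input.

    Downscale by exactly 4 (block averaging), Gaussian blur (sd 1.0), then
    median filter (size 3).  With ``dims=2`` the degradation acts in-plane
    only, slice by slice, matching the per-slice 2D models.
    """
    axes = (0, 1, 2) if dims == 3 else (1, 2)
    for ax in axes:
        if target.shape[ax] < UPSCALE_FACTOR:
            raise ValueError(f"target extent {target.shape[ax]} on axis {ax} is below 4")
    x = _block_average(target.data.astype(np.float64), UPSCALE_FACTOR, axes)
    sd = [_INPUT_BLUR_SD if ax in axes else 0.0 for ax in range(3)]
    x = ndimage.gaussian_filter(x, sd, truncate=_INPUT_BLUR_TRUNCATE, mode="reflect")
    size = tuple(3 if ax in axes else 1 for ax in range(3))
    x = ndimage.median_filter(x, size=size, mode="reflect")
    out = target.with_data(np.clip(x, 0.0, 1.0).astype(np.float32), dtype_tag="float01")
    out.voxel_size_um = target.voxel_size_um * UPSCALE_FACTOR
    return out


def tile_patches(
    lr: Volume,
    hr: Volume,
    patch_lr: int = 32,
    stride: int | None = None,
    sample_id: str = "",
    patient_id: str = "",
    dims: int = 3,
) -> list[PatchPair]:
    """Tile an aligned (lr, hr) volume pair into fully-inside patch pairs.

    The default stride equals the patch size (a partition).  In 2D mode each
    slice is tiled in-plane into 2D pairs.
    """
    stride = patch_lr if stride is None else stride
    # in-plane axes are always 4x; the slice axis may be 1x (in-plane-only
    # degradation, 2D mode) or 4x (volumetric degradation)
    slice_ratio = hr.shape[0] // max(lr.shape[0], 1)
    for ax in (1, 2):
        if hr.shape[ax] != UPSCALE_FACTOR * lr.shape[ax]:
            raise ValueError(
                f"misaligned pair: hr shape {hr.shape} is not 4 x lr shape {lr.shape}"
            )
    if hr.shape[0] not in (lr.shape[0], UPSCALE_FACTOR * lr.shape[0]):
        raise ValueError(
            f"slice extents {hr.shape[0]} vs {lr.shape[0]} are neither equal nor 4x"
        )
    if dims == 3 and hr.shape[0] != UPSCALE_FACTOR * lr.shape[0]:
        raise ValueError("3D tiling requires a 4x slice axis")
    pairs: list[PatchPair] = []
    if dims == 3:
        grids = [range(0, lr.shape[ax] - patch_lr + 1, stride) for ax in range(3)]
        for z in grids[0]:
            for y in grids[1]:
                for x in grids[2]:
                    o = (z, y, x)
                    lrp = lr.data[z:z + patch_lr, y:y + patch_lr, x:x + patch_lr]
                    ho = tuple(4 * c for c in o)
                    p = UPSCALE_FACTOR * patch_lr
                    hrp = hr.data[ho[0]:ho[0] + p, ho[1]:ho[1] + p, ho[2]:ho[2] + p]
                    pairs.append(PatchPair(lr=lrp, hr=hrp, sample_id=sample_id,
                                           patient_id=patient_id, origin=o))
    elif dims == 2:
        # with a 4x slice axis, use the hr slice at 4*z (grid-aligned with
        # the lr slice's leading face); with an equal axis, the same slice
        grids = [range(0, lr.shape[ax] - patch_lr + 1, stride) for ax in (1, 2)]
        for z in range(lr.shape[0]):
            hz = z if slice_ratio == 1 else UPSCALE_FACTOR * z
            for y in grids[0]:
                for x in grids[1]:
                    lrp = lr.data[z, y:y + patch_lr, x:x + patch_lr]
                    p = UPSCALE_FACTOR * patch_lr
                    hrp = hr.data[hz, 4 * y:4 * y + p, 4 * x:4 * x + p]
                    pairs.append(PatchPair(lr=lrp, hr=hrp, sample_id=sample_id,
                                           patient_id=patient_id, origin=(z, y, x)))
    else:
        raise ValueError("dims must be 2 or 3")
    return pairs


def grouped_kfold(
    pairs: list[PatchPair], k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-grouped k-fold splits over a patch-pair list.

    Every patient's patches land in exactly one validation fold; folds are
    balanced by patient count to within one.  Returns ``k`` pairs of
    ``(train_indices, val_indices)``.
    """
    patients = sorted({p.patient_id for p in pairs})
    if len(patients) < k:
        raise ValueError(f"need at least {k} distinct patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    fold_of_patient = {patients[j]: int(i % k) for i, j in enumerate(order)}
    fold_of_pair = np.array([fold_of_patient[p.patient_id] for p in pairs])
    splits = []
    for f in range(k):
        val = np.flatnonzero(fold_of_pair == f)
        train = np.flatnonzero(fold_of_pair != f)
        splits.append((train, val))
    return splits
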