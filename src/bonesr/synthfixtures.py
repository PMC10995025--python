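"""Synthetic test objects with known ground truth.

Real trabecular bone, clinical scanners and physical QA phantoms cannot be
shipped with a software package, so every quantitative experiment here runs
on synthetic stand-ins whose answer is known by construction:

* a trabecular surrogate — a thresholded Gaussian random field whose bone
  volume fraction is forced by quantile thresholding and whose strut size is
  set by the smoothing kernel;
* a parallel-plate phantom with analytic thickness/separation;
* a line-pair resolution phantom with bar groups at chosen spatial
  frequencies plus uniform material inserts;
* a slanted-edge phantom for edge-spread checks.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volio import Volume

__all__ = [
    "TrabecularSpec",
    "LinePairPhantomSpec",
    "GroundTruth",
    "make_trabecular",
    "make_plate_phantom",
    "make_line_pair_phantom",
    "make_edge_phantom",
    "default_roi_layout",
]


@dataclass
class TrabecularSpec:
    """Parameters of the Gaussian-random-field trabecular surrogate.

    ``feature_scale_um`` controls the strut thickness: the white-noise field
    is smoothed with a Gaussian of sd ``feature_scale_um / voxel_size_um / 2``
    before quantile thresholding, so doubling the scale roughly doubles the
    mean local thickness of the mask.
    """

    extents: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = 50.0
    target_bvtv: float = 0.3
    feature_scale_um: float = 240.0
    bone_level: float = 0.85
    background_level: float = 0.15
    noise_sd: float = 0.03
    blur_sd_vox: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_bvtv < 1.0:
            raise ValueError("target_bvtv must lie strictly inside (0, 1)")
        if self.bone_level <= self.background_level:
            raise ValueError("bone_level must exceed background_level")
        if min(self.extents) < 4:
            raise ValueError("extents too small for a structured field")


@dataclass
class LinePairPhantomSpec:
    """A slice-stacked QA phantom: six bar groups plus uniform inserts.

    Frequencies are in line pairs per cm (one bar + one gap per pair).  The
    default six groups are geometrically spaced over 2–10 lp/cm, bracketing
    the 3.5–8.3 lp/cm range where clinical CT resolution limits live.
    """

    pixel_size_um: float = 250.0
    group_frequencies_lp_per_cm: tuple[float, ...] = (2.0, 2.76, 3.81, 5.25, 7.25, 10.0)
    bar_level: float = 0.9
    background_level: float = 0.1
    uniform_inserts: tuple[tuple[str, float], ...] = (("plexiglass", 0.6), ("water", 0.3))
    slices: int = 8
    group_height: int = 24
    group_width: int = 96
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.group_frequencies_lp_per_cm, dtype=float)
        if freqs.ndim != 1 or len(freqs) < 1 or np.any(np.diff(freqs) <= 0):
            raise ValueError("group frequencies must be strictly increasing")
        period_px = 1e4 / (freqs * self.pixel_size_um)
        if np.any(period_px < 2.0):
            raise ValueError(
                "bar period below 2 pixels is not representable; "
                f"max representable frequency is {1e4 / (2 * self.pixel_size_um):.2f} lp/cm"
            )


@dataclass
class GroundTruth:
    """Reference values travelling with a synthetic volume."""

    mask: np.ndarray
    bvtv: float
    tbth_um: float | None = None
    tbsp_um: float | None = None
    meta: dict = field(default_factory=dict)


def _grf_mask(spec: TrabecularSpec, rng: np.random.Generator) -> np.ndarray:
    sd_vox = spec.feature_scale_um / spec.voxel_size_um / 2.0
    noise = rng.standard_normal(spec.extents)
    fieldv = ndimage.gaussian_filter(noise, sd_vox, mode="wrap")
    thr = np.quantile(fieldv, 1.0 - spec.target_bvtv)
    return fieldv > thr


def make_trabecular(spec: TrabecularSpec) -> tuple[Volume, GroundTruth]:
    """Generate a grayscale trabecular surrogate and its ground-truth mask."""
    rng = np.random.default_rng(spec.seed)
    mask = _grf_mask(spec, rng)
    gray = np.where(mask, spec.bone_level, spec.background_level).astype(np.float64)
    if spec.blur_sd_vox > 0:
        gray = ndimage.gaussian_filter(gray, spec.blur_sd_vox, mode="reflect")
    if spec.noise_sd > 0:
        gray = gray + rng.normal(0.0, spec.noise_sd, size=gray.shape)
    gray = np.clip(gray, 0.0, 1.0).astype(np.float32)
    vol = Volume(
        data=gray,
        voxel_size_um=spec.voxel_size_um,
        dtype_tag="float01",
        meta={"kind": "trabecular", "seed": spec.seed},
    )
    gt = GroundTruth(mask=mask, bvtv=float(mask.mean()))
    return vol, gt


def make_plate_phantom(
    plate_thickness_vox: int,
    gap_vox: int,
    extents: tuple[int, int, int],
    voxel_size_um: float = 100.0,
    bone_level: float = 0.9,
    background_level: float = 0.1,
) -> tuple[Volume, GroundTruth]:
    """Parallel slabs normal to axis 0 with analytic Tb.Th and Tb.Sp."""
    if plate_thickness_vox < 1 or gap_vox < 1:
        raise ValueError("plate thickness and gap must both be >= 1 voxel")
    period = plate_thickness_vox + gap_vox
    if extents[0] < period:
        raise ValueError("pattern does not fit the requested extents")
    z = np.arange(extents[0]) % period
    mask = (z < plate_thickness_vox)[:, None, None] & np.ones(extents, dtype=bool)
    gray = np.where(mask, bone_level, background_level).astype(np.float32)
    vol = Volume(data=gray, voxel_size_um=voxel_size_um, dtype_tag="float01",
                 meta={"kind": "plate"})
    gt = GroundTruth(
        mask=mask,
        bvtv=float(mask.mean()),
        tbth_um=plate_thickness_vox * voxel_size_um,
        tbsp_um=gap_vox * voxel_size_um,
    )
    return vol, gt


# layout constants: left margin, bar-group vertical pitch, right-column
# material/noise block geometry.  ROIs are inset far enough (2 px rows for
# bar groups, 14 px elsewhere) that a test blur of a few pixels sd does not
# bleed neighbouring structures into any ROI.
_MARGIN = 4
_BLOCK_H = 48
_BLOCK_W = 44
_BLOCK_PITCH = 72
_ROI_INSET = 14


def _bar_group_rows(spec: LinePairPhantomSpec) -> list[tuple[int, int]]:
    rows = []
    y = spec.group_height  # top margin
    for _ in spec.group_frequencies_lp_per_cm:
        rows.append((y, y + spec.group_height))
        y += 2 * spec.group_height
    return rows


def _right_column_blocks(spec: LinePairPhantomSpec) -> tuple[int, list[tuple[int, int]], tuple[int, int]]:
    """x-offset of the right column plus (y0, y1) of each material block and
    of the noise block."""
    x0 = _MARGIN + spec.group_width + 2 * _MARGIN
    mats = [(spec.group_height + i * _BLOCK_PITCH,
             spec.group_height + i * _BLOCK_PITCH + _BLOCK_H)
            for i in range(len(spec.uniform_inserts))]
    n0 = spec.group_height + len(spec.uniform_inserts) * _BLOCK_PITCH
    return x0, mats, (n0, n0 + _BLOCK_H)


def default_roi_layout(spec: LinePairPhantomSpec) -> dict:
    """ROI rectangles matching :func:`make_line_pair_phantom` geometry.

    Returns ``{"groups": [(y0,y1,x0,x1), ...], "noise": ..., "materials":
    {label: ...}}`` in (row, column) pixel coordinates, valid on every slice.
    """
    x0, x1 = _MARGIN, _MARGIN + spec.group_width
    groups = [
        (y0 + 2, y1 - 2, x0 + _ROI_INSET, x1 - _ROI_INSET)
        for (y0, y1) in _bar_group_rows(spec)
    ]
    mat_x0, mat_blocks, noise_block = _right_column_blocks(spec)
    inset = _ROI_INSET
    materials = {
        label: (b0 + inset, b1 - inset, mat_x0 + inset, mat_x0 + _BLOCK_W - inset)
        for (label, _level), (b0, b1) in zip(spec.uniform_inserts, mat_blocks)
    }
    n0, n1 = noise_block
    noise = (n0 + inset, n1 - inset, mat_x0 + inset, mat_x0 + _BLOCK_W - inset)
    return {"groups": groups, "noise": noise, "materials": materials}


def make_line_pair_phantom(spec: LinePairPhantomSpec) -> Volume:
    """Render the bar-pattern phantom as a stack of identical noisy slices.

    Bars run vertically (modulation along the column axis); each group is a
    binary square wave sampled at pixel centres, so the rendered period is
    within one pixel of ``1 / f``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = _bar_group_rows(spec)
    bar_bottom = rows[-1][1] + spec.group_height
    _, mat_blocks, noise_block = _right_column_blocks(spec)
    height = max(bar_bottom, noise_block[1] + spec.group_height)
    height += (-height) % 4
    width = _MARGIN + spec.group_width + 2 * _MARGIN + _BLOCK_W + _MARGIN
    width += (-width) % 4
    slice_img = np.full((height, width), spec.background_level, dtype=np.float64)

    x = (np.arange(spec.group_width) + 0.5) * spec.pixel_size_um / 1e4  # cm
    for (y0, y1), f in zip(rows, spec.group_frequencies_lp_per_cm):
        # bar where the square wave is in its first half-period
        phase = np.floor(2.0 * f * x).astype(int) % 2
        bar = np.where(phase == 0, spec.bar_level, spec.background_level)
        slice_img[y0:y1, _MARGIN:_MARGIN + spec.group_width] = bar[None, :]

    mat_x0, _, _ = _right_column_blocks(spec)
    for (label, level), (b0, b1) in zip(spec.uniform_inserts, mat_blocks):
        slice_img[b0:b1, mat_x0:mat_x0 + _BLOCK_W] = level
    # the noise block stays at background level by construction

    data = np.repeat(slice_img[None, :, :], spec.slices, axis=0)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 1.0).astype(np.float32)
    return Volume(
        data=data,
        voxel_size_um=spec.pixel_size_um,
        dtype_tag="float01",
        meta={"kind": "line_pair", "frequencies_lp_cm": list(spec.group_frequencies_lp_per_cm)},
    )


def make_edge_phantom(
    angle_deg: float,
    levels: tuple[float, float],
    extents: tuple[int, int, int],
    edge_col: float | None = None,
) -> Volume:
    """Slanted binary step edge (an alternative MTF fixture)."""
    lo, hi = levels
    if lo == hi:
        raise ValueError("edge phantom needs two distinct levels")
    nz, ny, nx = extents
    if edge_col is None:
        edge_col = nx / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    # signed distance of pixel centre from the slanted edge line
    boundary = edge_col + np.tan(np.deg2rad(angle_deg)) * (yy - ny / 2.0)
    img = np.where(xx + 0.5 > boundary, hi, lo).astype(np.float32)
    data = np.repeat(img[None, :, :], nz, axis=0)
    return Volume(data=np.clip(data, 0.0, 1.0), voxel_size_um=100.0,
                  dtype_tag="float01", meta={"kind": "edge", "angle_deg": angle_deg})
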