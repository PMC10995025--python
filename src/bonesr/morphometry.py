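"""Trabecular bone morphometry: Otsu binarization and the four standard
structural parameters.

* **BV/TV** — bone volume fraction, the foreground fraction of the mask.
* **Tb.Th / Tb.Sp** — mean *local thickness* of the bone / marrow phase:
  each voxel is assigned the diameter of the largest sphere that lies fully
  inside its phase and contains it (the model-independent definition of
  Hildebrand & Rüegsegger), and the phase mean is taken.
* **Tb.N** — trabecular number per millimetre, derived as (BV/TV)/Tb.Th
  (model-independent), with the plate-model alternative 1/(Tb.Th+Tb.Sp)
  selectable.

Local thickness is computed from the Euclidean distance transform: every
foreground voxel is the centre of an inscribed sphere with radius equal to
its distance-transform value, and spheres are rasterized in decreasing
radius order so each voxel keeps the diameter of the largest sphere
covering it.  Spheres are clipped at the volume faces, so border voxels are
included rather than discarded (excluding them would bias small volumes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import Volume, to_float01

__all__ = [
    "MorphometryResult",
    "otsu_threshold",
    "bvtv",
    "local_thickness",
    "trabecular_number",
    "analyze",
]


@dataclass
class MorphometryResult:
    bvtv: float
    tbth_um: float
    tbsp_um: float
    tbn_per_mm: float
    threshold_used: float
    mask: np.ndarray
    voxel_size_um: float
    tbn_formula: str = "bvtv_over_tbth"

    def as_dict(self) -> dict:
        return {
            "bvtv": self.bvtv, "tbth_um": self.tbth_um, "tbsp_um": self.tbsp_um,
            "tbn_per_mm": self.tbn_per_mm, "threshold": self.threshold_used,
            "voxel_size_um": self.voxel_size_um, "tbn_formula": self.tbn_formula,
        }


def _as_levels(vol: Volume | np.ndarray) -> np.ndarray:
    """Quantize intensities to the 256 levels of 8-bit clinical processing."""
    if isinstance(vol, Volume):
        data = to_float01(vol).data
    else:
        data = np.asarray(vol, dtype=np.float64)
        if data.max() > 1.0 or data.min() < 0.0:
            raise ValueError("bare arrays must already be scaled to [0, 1]")
    return np.rint(np.clip(data, 0.0, 1.0) * 255.0).astype(np.uint8)


def otsu_threshold(vol: Volume | np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu's threshold on the 256-bin histogram.

    Returns ``(threshold, mask)`` where the threshold is the 8-bit level
    maximizing the between-class variance and ``mask = level > threshold``.
    """
    levels = _as_levels(vol)
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu thresholding needs at least two distinct values")
    p = hist / hist.sum()
    bins = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)[:-1]              # mass at levels <= t, t = 0..254
    w1 = 1.0 - w0
    m0 = np.cumsum(p * bins)[:-1]
    mu_total = float((p * bins).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        between = w0 * w1 * (mean0 - mean1) ** 2
    between[~np.isfinite(between)] = -1.0
    t = int(np.argmax(between))
    return float(t), levels > t


def bvtv(mask: np.ndarray) -> float:
    """Foreground fraction of a binary mask."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty volume")
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ValueError("bvtv expects a binary mask")
    return float(np.count_nonzero(mask) / mask.size)


def _sphere_radii(mask: np.ndarray) -> np.ndarray:
    """Inscribed-sphere radius (in voxels) at every foreground voxel: the
    Euclidean distance to the nearest background voxel centre, with the
    volume faces acting as phase boundaries (spheres are clipped there)."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    edt = ndimage.distance_transform_edt(padded)
    return edt[(slice(1, -1),) * mask.ndim]


def local_thickness(mask: np.ndarray, phase: str = "foreground",
                    voxel_size_um: float = 1.0) -> np.ndarray:
    """Local-thickness map of the selected phase, in µm.

    ``thickness(p) = 2 * max{ r(q) : |p - q| < r(q) }`` over sphere centres
    ``q`` of the phase, with ``r`` the distance-transform radius.  Values
    are zero outside the phase.
    """
    mask = np.asarray(mask).astype(bool)
    if phase == "background":
        mask = ~mask
    elif phase != "foreground":
        raise ValueError("phase must be 'foreground' or 'background'")
    if not mask.any():
        raise ValueError(f"selected phase is empty")

    # squared EDT distances on the voxel grid are exact integers, so all
    # sphere-coverage comparisons below are exact
    radii_sq = np.rint(_sphere_radii(mask) ** 2).astype(np.int64)
    thickness = np.zeros(mask.shape, dtype=np.float64)
    # process exact radii in decreasing order; a voxel's thickness is set by
    # the first (largest) sphere that covers it
    values = np.unique(radii_sq[mask])[::-1]
    unassigned = mask.copy()
    for r_sq in values:
        if not unassigned.any():
            break
        centres = radii_sq == r_sq
        # voxels strictly inside a sphere of radius r about any such centre
        dist_sq = np.rint(ndimage.distance_transform_edt(~centres) ** 2).astype(np.int64)
        covered = (dist_sq < r_sq) & mask
        covered |= centres
        newly = covered & unassigned
        thickness[newly] = 2.0 * np.sqrt(r_sq)
        unassigned &= ~covered
    return thickness * voxel_size_um


def trabecular_number(bvtv_value: float, tbth_um: float, tbsp_um: float | None = None,
                      formula: str = "bvtv_over_tbth") -> float:
    """Trabecular number per millimetre.

    ``bvtv_over_tbth``: Tb.N = (BV/TV) / Tb.Th (model independent).
    ``inverse_spacing``: Tb.N = 1 / (Tb.Th + Tb.Sp) (plate-model).
    """
    if formula == "bvtv_over_tbth":
        if bvtv_value == 0.0:
            return 0.0
        if tbth_um <= 0:
            raise ValueError("Tb.Th must be positive")
        return bvtv_value / (tbth_um / 1000.0)
    if formula == "inverse_spacing":
        if tbsp_um is None:
            raise ValueError("inverse_spacing formula requires Tb.Sp")
        return 1.0 / ((tbth_um + tbsp_um) / 1000.0)
    raise ValueError(f"unknown Tb.N formula {formula!r}")


def analyze(vol: Volume | np.ndarray, voxel_size_um: float | None = None,
            tbn_formula: str = "bvtv_over_tbth") -> MorphometryResult:
    """Full morphometry of a grayscale volume or a pre-binarized mask.

    Grayscale input is Otsu-thresholded first; a boolean array is used as
    the mask directly (threshold reported as NaN).
    """
    if isinstance(vol, Volume):
        voxel = float(vol.voxel_size_um[0]) if voxel_size_um is None else voxel_size_um
        if vol.data.dtype == bool:
            mask, threshold = vol.data, float("nan")
        else:
            threshold, mask = otsu_threshold(vol)
    else:
        arr = np.asarray(vol)
        if voxel_size_um is None:
            raise ValueError("voxel_size_um is required for bare arrays")
        voxel = voxel_size_um
        if arr.dtype == bool:
            mask, threshold = arr, float("nan")
        else:
            threshold, mask = otsu_threshold(arr)

    frac = bvtv(mask)
    if 0.0 < frac < 1.0:
        th_map = local_thickness(mask, "foreground", voxel)
        sp_map = local_thickness(mask, "background", voxel)
        tbth = float(th_map[mask].mean())
        tbsp = float(sp_map[~mask].mean())
    elif frac == 0.0:
        tbth, tbsp = 0.0, float(mask.shape[0] * voxel)
    else:
        tbth, tbsp = float(mask.shape[0] * voxel), 0.0
    tbn = (trabecular_number(frac, tbth, tbsp, tbn_formula)
           if tbth > 0 else 0.0)
    return MorphometryResult(
        bvtv=frac, tbth_um=tbth, tbsp_um=tbsp, tbn_per_mm=tbn,
        threshold_used=threshold, mask=mask, voxel_size_um=voxel,
        tbn_formula=tbn_formula,
    )
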