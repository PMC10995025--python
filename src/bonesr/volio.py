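"""Volume container, readers/writers, and bit-depth normalization.

The whole pipeline trades in one currency: a 3D scalar grid with a physical
voxel size.  Axis order is fixed as ``(slice, row, column)`` with the axial
plane being axis 0; TIFF stacks, NIfTI files and raw dumps are all converted
to this layout on read.

Supported on-disk formats
-------------------------
``tiff_stack``
    A directory holding one 2D TIFF per slice, lexicographic filename order,
    plus a ``meta.json`` sidecar carrying the voxel size.
``nifti``
    A single NIfTI-1 file; the voxel size is stored in the affine (mm).
``raw``
    Little-endian C-order binary plus a JSON sidecar
    ``{"shape": [...], "dtype": ..., "voxel_size_um": ...}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = [
    "Volume",
    "PlaneAxis",
    "PLANE_TO_AXIS",
    "read_volume",
    "write_volume",
    "normalize_to_8bit",
    "to_float01",
    "from_float01",
]

#: Mapping of anatomical plane name to grid axis; axial slices are stacked
#: along axis 0, so an axial in-plane image is ``data[i, :, :]``.
PLANE_TO_AXIS: dict[str, int] = {"axial": 0, "coronal": 1, "sagittal": 2}


class PlaneAxis:
    """The three orthogonal planes, mapped to fixed grid axes."""

    AXIAL = "axial"
    CORONAL = "coronal"
    SAGITTAL = "sagittal"

    @staticmethod
    def axis(plane: str) -> int:
        try:
            return PLANE_TO_AXIS[plane]
        except KeyError:
            raise ValueError(
                f"unknown plane {plane!r}; expected one of {sorted(PLANE_TO_AXIS)}"
            ) from None


_DTYPE_TAGS = {"uint8": np.uint8, "uint16": np.uint16, "float01": np.float32}
_DTYPE_MAX = {"uint8": 255.0, "uint16": 65535.0}


def _infer_dtype_tag(data: np.ndarray) -> str:
    if data.dtype == np.uint8:
        return "uint8"
    if data.dtype == np.uint16:
        return "uint16"
    if np.issubdtype(data.dtype, np.floating):
        return "float01"
    raise TypeError(f"unsupported volume dtype {data.dtype}")


@dataclass
class Volume:
    """A 3D scalar grid with physical voxel size in micrometres.

    Parameters
    ----------
    data
        Array of shape ``(slices, rows, columns)``.
    voxel_size_um
        Positive voxel edge length per axis (scalar is broadcast to all
        three axes).
    dtype_tag
        One of ``uint8``, ``uint16``, ``float01``; inferred from ``data``
        when omitted.  ``float01`` volumes must lie in ``[0, 1]``.
    meta
        Free-form provenance (modality, sample id, patient id, ...).
    """

    data: np.ndarray
    voxel_size_um: np.ndarray
    dtype_tag: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a non-empty 3D grid, got shape {self.data.shape}")
        vs = np.broadcast_to(np.asarray(self.voxel_size_um, dtype=float), (3,)).copy()
        if not np.all(vs > 0):
            raise ValueError(f"voxel size must be positive on every axis, got {vs}")
        self.voxel_size_um = vs
        if not self.dtype_tag:
            self.dtype_tag = _infer_dtype_tag(self.data)
        if self.dtype_tag not in _DTYPE_TAGS:
            raise ValueError(f"unknown dtype_tag {self.dtype_tag!r}")
        if self.dtype_tag == "float01":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(
                    f"float01 volume values outside [0, 1]: range [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, dtype_tag: str | None = None) -> "Volume":
        """Return a copy carrying new voxel data but the same metadata."""
        return Volume(
            data=data,
            voxel_size_um=self.voxel_size_um.copy(),
            dtype_tag=dtype_tag or _infer_dtype_tag(np.asarray(data)),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _read_tiff_stack(path: Path) -> Volume:
    import tifffile

    if not path.is_dir():
        raise FileNotFoundError(f"tiff_stack expects a directory: {path}")
    slices = sorted(p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"})
    if not slices:
        raise FileNotFoundError(f"no TIFF slices found in {path}")
    planes = [tifffile.imread(str(p)) for p in slices]
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes in TIFF stack: {sorted(shapes)}")
    data = np.stack(planes, axis=0)
    meta_path = path / "meta.json"
    voxel = 1.0
    meta: dict = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        voxel = meta.pop("voxel_size_um", 1.0)
    return Volume(data=data, voxel_size_um=np.asarray(voxel, dtype=float), meta=meta)


def _write_tiff_stack(v: Volume, path: Path) -> None:
    import tifffile

    if v.dtype_tag == "float01":
        raise TypeError(
            "float01 volume cannot be written as a TIFF stack; "
            "convert with from_float01() or normalize_to_8bit() first"
        )
    path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(v.shape[0])))
    for i in range(v.shape[0]):
        tifffile.imwrite(str(path / f"slice_{i:0{width}d}.tif"), v.data[i])
    (path / "meta.json").write_text(
        json.dumps({"voxel_size_um": v.voxel_size_um.tolist(), **v.meta}, default=str)
    )


def _read_nifti(path: Path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    # NIfTI stores (x, y, z) with x fastest; transpose back to (slice,row,col)
    data = np.asarray(img.dataobj).T
    zooms = img.header.get_zooms()[:3]
    voxel = np.asarray(zooms[::-1], dtype=float) * 1000.0  # mm -> um
    return Volume(data=data, voxel_size_um=voxel)


def _write_nifti(v: Volume, path: Path) -> None:
    import nibabel as nib

    affine = np.diag(list(v.voxel_size_um[::-1] / 1000.0) + [1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(v.data.T), affine)
    img.header.set_zooms(tuple(v.voxel_size_um[::-1] / 1000.0))
    nib.save(img, str(path))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_raw(path: Path) -> Volume:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"raw volume requires a JSON sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    dtype = np.dtype(meta["dtype"]).newbyteorder("<")
    data = np.fromfile(str(path), dtype=dtype).reshape(shape)
    return Volume(
        data=data.astype(dtype.newbyteorder("=")),
        voxel_size_um=np.asarray(meta["voxel_size_um"], dtype=float),
        meta={k: v for k, v in meta.items() if k not in {"shape", "dtype", "voxel_size_um"}},
    )


def _write_raw(v: Volume, path: Path) -> None:
    data = np.ascontiguousarray(v.data)
    data.astype(data.dtype.newbyteorder("<")).tofile(str(path))
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "shape": list(v.shape),
                "dtype": v.data.dtype.name,
                "voxel_size_um": v.voxel_size_um.tolist(),
                **v.meta,
            },
            default=str,
        )
    )


_READERS = {"tiff_stack": _read_tiff_stack, "nifti": _read_nifti, "raw": _read_raw}
_WRITERS = {"tiff_stack": _write_tiff_stack, "nifti": _write_nifti, "raw": _write_raw}


def read_volume(path: str | Path, format: str) -> Volume:
    """Read a volume from disk in one of the supported formats."""
    path = Path(path)
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_READERS)}")
    if format != "tiff_stack" and not path.exists():
        raise FileNotFoundError(str(path))
    return _READERS[format](path)


def write_volume(v: Volume, path: str | Path, format: str) -> None:
    """Write a volume to disk; integer volumes round-trip bit-exactly."""
    path = Path(path)
    if format not in _WRITERS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_WRITERS)}")
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    _WRITERS[format](v, path)


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def normalize_to_8bit(v: Volume, clip_percentiles: tuple[float, float] | None = None) -> Volume:
    """Linear min--max (or percentile-clipped) map to ``[0, 255]``.

    Rounding is half-to-even.  A constant input maps to all zeros so that a
    degenerate range cannot poison downstream stages.
    """
    x = v.data.astype(np.float64)
    if clip_percentiles is not None:
        lo_p, hi_p = clip_percentiles
        if not (0 <= lo_p < hi_p <= 100):
            raise ValueError(f"invalid clip percentiles {clip_percentiles}")
        lo, hi = np.percentile(x, [lo_p, hi_p])
        x = np.clip(x, lo, hi)
    else:
        lo, hi = x.min(), x.max()
    if hi <= lo:
        out = np.zeros_like(x, dtype=np.uint8)
    else:
        out = np.rint((x - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return v.with_data(out, dtype_tag="uint8")


def to_float01(v: Volume) -> Volume:
    """Scale an integer volume linearly to ``[0, 1]`` by its dtype maximum."""
    if v.dtype_tag == "float01":
        return v.with_data(v.data.astype(np.float32), dtype_tag="float01")
    scale = _DTYPE_MAX[v.dtype_tag]
    return v.with_data((v.data.astype(np.float32) / scale), dtype_tag="float01")


def from_float01(v: Volume, target_dtype: str = "uint8") -> Volume:
    """Inverse of :func:`to_float01`; rounding is half-to-even."""
    if v.dtype_tag != "float01":
        raise TypeError(f"from_float01 expects a float01 volume, got {v.dtype_tag}")
    if target_dtype not in _DTYPE_MAX:
        raise ValueError(f"target dtype must be uint8 or uint16, got {target_dtype!r}")
    scale = _DTYPE_MAX[target_dtype]
    out = np.rint(np.clip(v.data, 0.0, 1.0) * scale).astype(_DTYPE_TAGS[target_dtype])
    return v.with_data(out, dtype_tag=target_dtype)
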