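"""Volumetric I/O: TIFF slice stacks and NIfTI with voxel-size metadata.

Axis convention throughout the package: ``data[slice, row, col]`` with the
first axis being the axial slice direction (the annotation/training/
inference plane).  Voxel sizes are stored in µm per axis in the same order.
TIFF has no canonical spacing tag, so TIFF volumes carry a JSON sidecar
``{"voxel_size_um": [z, y, x]}``; NIfTI stores spacing in its header in mm
and is converted on read.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = ["Volume", "LabelMask", "read_volume", "write_volume", "read_mask"]

_SIDEAR_SUFFIX = ".json"


@dataclass
class Volume:
    """A 3-D intensity grid with per-axis voxel size in µm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    dtype_origin: np.dtype = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        self.voxel_size = vs
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.dtype_origin is None:
            self.dtype_origin = self.data.dtype

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        return max(self.voxel_size) - min(self.voxel_size) < 1e-9


@dataclass
class LabelMask:
    """A binary {0,1} grid aligned to a companion :class:`Volume`."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be binary, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be positive")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())


def _numeric_key(p: Path):
    m = re.findall(r"\d+", p.stem)
    return (int(m[-1]) if m else 0, p.name)


def _read_tiff(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")],
            key=_numeric_key)
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice dimensions in stack: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
        sidecar = path / ("voxel_size" + _SIDEAR_SUFFIX)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar = path.with_suffix(path.suffix + _SIDEAR_SUFFIX)
    if not sidecar.exists():
        raise ValueError(
            f"missing voxel-size metadata: sidecar file {sidecar} not found "
            "(expected JSON with field 'voxel_size_um')")
    meta = json.loads(sidecar.read_text())
    if "voxel_size_um" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks required field 'voxel_size_um'")
    return data, tuple(float(v) for v in meta["voxel_size_um"])


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    # stored as (x, y, z); transpose to (slice, row, col)
    data = np.asanyarray(img.dataobj).T
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid voxel size in NIfTI header pixdim: {zooms}")
    voxel_um = tuple(float(z) * 1000.0 for z in reversed(zooms))
    return data, voxel_um


def read_volume(path, format_hint: str | None = None) -> Volume:
    """Read a TIFF stack (directory or multipage file) or NIfTI volume.

    Integer intensities are preserved bit-exactly.  Raises if voxel-size
    metadata is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        name = path.name.lower()
        if path.is_dir() or name.endswith((".tif", ".tiff")):
            fmt = "tiff"
        elif name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        else:
            raise ValueError(
                f"cannot infer format of {path}; pass format_hint='tiff' or 'nifti'")
    if fmt == "tiff":
        data, voxel = _read_tiff(path)
    elif fmt == "nifti":
        data, voxel = _read_nifti(path)
    else:
        raise ValueError(f"unsupported format {fmt!r}; supported: tiff, nifti")
    return Volume(data=data, voxel_size=voxel)


def write_volume(vol: Volume, path, format: str = None) -> None:  # noqa: A002
    """Write a volume as multipage TIFF (+ JSON sidecar) or NIfTI.

    Roundtrips are bit-exact for integer data; voxel size is persisted in
    the sidecar (TIFF, µm) or header (NIfTI, mm).
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        if name.endswith((".tif", ".tiff")):
            format = "tiff"
        elif name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise ValueError(
                f"cannot infer output format of {path}; supported formats: tiff, nifti")
    if format == "tiff":
        tifffile.imwrite(path, vol.data, photometric="minisblack")
        sidecar = path.with_suffix(path.suffix + _SIDEAR_SUFFIX)
        sidecar.write_text(json.dumps({"voxel_size_um": list(vol.voxel_size)}))
    elif format == "nifti":
        zooms_mm = [v / 1000.0 for v in reversed(vol.voxel_size)]
        affine = np.diag(zooms_mm + [1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(vol.data.T), affine)
        img.header.set_zooms(zooms_mm)
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported format {format!r}; supported formats: tiff, nifti")


def read_mask(path, reference: Volume | None = None) -> LabelMask:
    """Read a segmentation mask; any nonzero value becomes foreground (1).

    If ``reference`` is given the mask shape is validated against it.
    """
    vol = read_volume(path)
    if reference is not None and vol.data.shape != reference.data.shape:
        raise ValueError(
            f"mask shape {vol.data.shape} does not match reference volume "
            f"shape {reference.data.shape}")
    return LabelMask(data=(vol.data != 0).astype(np.uint8), voxel_size=vol.voxel_size)
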