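"""Geometric preparation of volumes for the fixed-size network input grid.

The pipeline brings every scan onto a common grid before training or
inference: in-plane rescaling to a unified voxel size (bilinear for
intensities, nearest-neighbour for masks, per axial slice), centred
zero-padding or centre-cropping onto a fixed canvas, and z-score
standardization.  Every geometric step is recorded in a
:class:`GridTransform` so a predicted mask can be mapped back onto the
native grid of the input scan.

Resampling convention: pixel-centre alignment (output centre ``i`` samples
input coordinate ``(i + 0.5) * n_in / n_out - 0.5``) with edge clamping —
the convention of ``skimage.transform.resize(mode='edge')``.  The slice
axis is never resampled; slice spacing is carried as metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from skimage.transform import resize

from .volio import LabelMask, Volume

__all__ = [
    "CanvasSpec",
    "GridTransform",
    "rescale_voxels",
    "fit_to_canvas",
    "standardize",
    "interpolate_sparse_labels",
    "invert_mask_transform",
]


@dataclass(frozen=True)
class CanvasSpec:
    """Fixed network input plane: height × width pixels at ``target_voxel`` µm."""

    height: int = 1792
    width: int = 1280
    target_voxel: float = 6.0

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("canvas dimensions must be positive")
        if self.target_voxel <= 0:
            raise ValueError("target_voxel must be positive")


@dataclass
class GridTransform:
    """Record of in-plane rescale + pad/crop, sufficient for inversion."""

    original_shape: tuple[int, int] = (0, 0)   # native (rows, cols)
    scaled_shape: tuple[int, int] = (0, 0)     # after rescale, before canvas
    scale_factor: tuple[float, float] = (1.0, 1.0)
    pad: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))
    crop: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))
    source_voxel: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_voxel: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "GridTransform":
        d = json.loads(s)
        for key in ("original_shape", "scaled_shape", "scale_factor"):
            d[key] = tuple(d[key])
        for key in ("pad", "crop"):
            d[key] = tuple(tuple(p) for p in d[key])
        d["source_voxel"] = tuple(d["source_voxel"])
        return cls(**d)


def _resize_planes(data: np.ndarray, out_shape: tuple[int, int], order: int) -> np.ndarray:
    """Resize the two in-plane axes of a (slices, rows, cols) array."""
    out = np.empty((data.shape[0], *out_shape), dtype=np.float32)
    for i in range(data.shape[0]):
        out[i] = resize(data[i].astype(np.float32), out_shape, order=order,
                        mode="edge", anti_aliasing=False, preserve_range=True)
    return out


def rescale_voxels(vol: Volume, target_voxel: float,
                   mask: LabelMask | None = None
                   ) -> tuple[Volume, GridTransform, LabelMask | None]:
    """Rescale each axial slice to ``target_voxel`` µm in-plane.

    Intensities are resampled bilinearly; a companion mask (if given)
    receives the identical geometric transform with nearest-neighbour
    sampling so it stays binary.  The slice axis is untouched.
    """
    if target_voxel <= 0:
        raise ValueError("target_voxel must be positive")
    _, vy, vx = vol.voxel_size
    fy, fx = vy / target_voxel, vx / target_voxel
    rows, cols = vol.data.shape[1:]
    gt = GridTransform(
        original_shape=(rows, cols), scale_factor=(fy, fx),
        source_voxel=vol.voxel_size, target_voxel=float(target_voxel))
    if abs(fy - 1.0) < 1e-12 and abs(fx - 1.0) < 1e-12:
        gt.scaled_shape = (rows, cols)
        out = Volume(vol.data.copy(),
                     (vol.voxel_size[0], target_voxel, target_voxel),
                     dtype_origin=vol.dtype_origin)
        m = LabelMask(mask.data.copy(), out.voxel_size) if mask is not None else None
        return out, gt, m
    out_shape = (max(1, round(rows * fy)), max(1, round(cols * fx)))
    gt.scaled_shape = out_shape
    data = _resize_planes(vol.data, out_shape, order=1)
    out = Volume(data, (vol.voxel_size[0], target_voxel, target_voxel),
                 dtype_origin=vol.dtype_origin)
    m = None
    if mask is not None:
        md = _resize_planes(mask.data, out_shape, order=0)
        m = LabelMask((md > 0.5).astype(np.uint8), out.voxel_size)
    return out, gt, m


def _split(delta: int) -> tuple[int, int]:
    """Centre split of a nonnegative extent difference; odd remainder high side."""
    lo = delta // 2
    return lo, delta - lo


def fit_to_canvas(vol: Volume, canvas: CanvasSpec,
                  transform: GridTransform | None = None,
                  mask: LabelMask | None = None
                  ) -> tuple[Volume, GridTransform, LabelMask | None]:
    """Centre each slice on the canvas: zero-pad smaller, centre-crop larger.

    Original voxel values are preserved inside the placed region.  Updates
    (or creates) the :class:`GridTransform` with the pad/crop applied.
    """
    rows, cols = vol.data.shape[1:]
    gt = transform if transform is not None else GridTransform(
        original_shape=(rows, cols), scaled_shape=(rows, cols),
        source_voxel=vol.voxel_size, target_voxel=canvas.target_voxel)

    def _fit(arr: np.ndarray) -> np.ndarray:
        pads, crops = [], []
        for axis, target in ((1, canvas.height), (2, canvas.width)):
            size = arr.shape[axis]
            if size < target:
                pads.append(_split(target - size))
                crops.append((0, 0))
            else:
                pads.append((0, 0))
                crops.append(_split(size - target))
        (cy0, _), (cx0, _) = crops
        arr = arr[:, cy0:cy0 + min(arr.shape[1], canvas.height),
                  cx0:cx0 + min(arr.shape[2], canvas.width)]
        arr = np.pad(arr, ((0, 0), pads[0], pads[1]))
        gt.pad = (tuple(pads[0]), tuple(pads[1]))
        gt.crop = (tuple(crops[0]), tuple(crops[1]))
        return arr

    data = _fit(vol.data)
    out = Volume(data, vol.voxel_size, dtype_origin=vol.dtype_origin)
    m = None
    if mask is not None:
        m = LabelMask(_fit(mask.data), vol.voxel_size)
    return out, gt, m


def invert_mask_transform(mask_canvas: np.ndarray, gt: GridTransform) -> np.ndarray:
    """Map a canvas-grid binary mask back onto the native grid.

    Undoes the pad (crop it away) or crop (zero-pad back), then resamples
    to the recorded native in-plane shape with nearest-neighbour sampling.
    Padded-border pixels can never contribute foreground.
    """
    arr = np.asarray(mask_canvas)
    (py0, py1), (px0, px1) = gt.pad
    arr = arr[:, py0:arr.shape[1] - py1 or None, px0:arr.shape[2] - px1 or None]
    (cy0, cy1), (cx0, cx1) = gt.crop
    if any((cy0, cy1, cx0, cx1)):
        arr = np.pad(arr, ((0, 0), (cy0, cy1), (cx0, cx1)))
    if arr.shape[1:] != tuple(gt.original_shape):
        arr = _resize_planes(arr, tuple(gt.original_shape), order=0)
    return (arr > 0.5).astype(np.uint8)


def standardize(vol: Volume) -> Volume:
    """Z-score the whole volume to zero mean, unit standard deviation."""
    data = vol.data.astype(np.float64)
    sd = data.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant volume (zero variance)")
    out = ((data - data.mean()) / sd).astype(np.float32)
    return Volume(out, vol.voxel_size, dtype_origin=vol.dtype_origin)


def interpolate_sparse_labels(annotated: LabelMask, k: int) -> LabelMask:
    """Fill unannotated slices by voxelwise linear blending of annotations.

    Emulates the sparse manual-annotation protocol in which only every
    ``k``-th axial slice is delineated and intermediate slices are linearly
    interpolated between the bracketing annotated slices, then thresholded
    at 0.5 (>= 0.5 → foreground) to restore binarity.  Annotated slices are
    returned unchanged; trailing slices past the last annotated index copy
    the last annotation.
    """
    if k < 1:
        raise ValueError("annotation stride k must be >= 1")
    if k == 1:
        return LabelMask(annotated.data.copy(), annotated.voxel_size)
    data = annotated.data.astype(np.float32)
    n = data.shape[0]
    out = np.zeros_like(data)
    anchors = list(range(0, n, k))
    for a in anchors:
        out[a] = data[a]
    for a, b in zip(anchors[:-1], anchors[1:]):
        for j in range(1, b - a):
            w = j / (b - a)
            out[a + j] = (1.0 - w) * data[a] + w * data[b]
    last = anchors[-1]
    for i in range(last + 1, n):
        out[i] = data[last]
    return LabelMask((out >= 0.5).astype(np.uint8), annotated.voxel_size)
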