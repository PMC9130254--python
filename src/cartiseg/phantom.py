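"""Synthetic µCT-like phantoms with ground-truth cartilage-shell masks.

A phantom emulates the structural situation the segmentation method is
built for: a large, bright soft-tissue "head" (contrast-stained tissue),
containing a thin curved cartilage shell whose intensity differs from the
surrounding tissue by only a few noise standard deviations, an optional
planar septum-like wall inside the shell, partial-volume blur, and
additive noise.  Two controls mirror the difficult cases in a real
database: ``staining_quality`` scales the cartilage contrast towards zero
(an improperly stained sample) and ``mutant_severity`` removes a fraction
of the septum (an underdeveloped-septum morphology).

The ground-truth mask is the rasterised shell geometry and is independent
of the intensity rendering; everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volio import LabelMask, Volume

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "generate_dataset"]

# sd of the smooth intensity texture inside the head, in base-intensity units;
# together with the additive noise it defines the "background sd" in which
# the cartilage contrast is expressed
_TEXTURE_SD = 0.08


@dataclass(frozen=True)
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (96, 128, 128)  # (slices, rows, cols)
    voxel_size: float = 6.0            # µm, isotropic
    shell_thickness: tuple[float, float] = (30.0, 30.0)  # µm range, low == high fixes it
    contrast: float = 3.0              # cartilage-vs-tissue separation, background-sd units
    staining_quality: float = 1.0      # 1 = proper; -> 0 emulates improper staining
    mutant_severity: float = 0.0       # fraction of the septum removed
    noise_sd: float = 0.05             # additive Gaussian noise, base-intensity units
    blur_sigma: float = 0.7            # partial-volume blur, voxels
    seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.volume_shape):
            raise ValueError("volume_shape dimensions must be >= 8 voxels")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        lo, hi = self.shell_thickness
        if not (0 < lo <= hi):
            raise ValueError("shell_thickness must be a positive low <= high range")
        if self.contrast < 0:
            raise ValueError("contrast must be nonnegative")
        if not 0.0 <= self.staining_quality <= 1.0:
            raise ValueError("staining_quality must lie in [0, 1]")
        if not 0.0 <= self.mutant_severity <= 1.0:
            raise ValueError("mutant_severity must lie in [0, 1]")

    @property
    def background_sd(self) -> float:
        return float(np.hypot(_TEXTURE_SD, self.noise_sd))


@dataclass
class PhantomSample:
    volume: Volume
    truth: LabelMask
    spec_used: PhantomSpec

    @property
    def category(self) -> str:
        if self.spec_used.staining_quality < 0.5:
            return "poor-staining"
        if self.spec_used.mutant_severity > 0.0:
            return "mutant"
        return "control"


def _normalized_radius(shape, center, semi_axes, rng) -> np.ndarray:
    """||(q-c)/a|| with a smooth low-order directional perturbation."""
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float32) for s in shape),
                             indexing="ij")
    d = np.stack([(zz - center[0]) / semi_axes[0],
                  (yy - center[1]) / semi_axes[1],
                  (xx - center[2]) / semi_axes[2]])
    rho = np.sqrt((d ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(rho > 1e-6, d / np.maximum(rho, 1e-6), 0.0)
    # random quadratic-form perturbation of the radius (low-order lobes)
    eps = rng.uniform(-0.08, 0.08, size=(3, 3))
    eps = (eps + eps.T) / 2.0
    pert = np.einsum("iqrs,ij,jqrs->qrs", u, eps, u)
    return rho * (1.0 + pert)


def _rasterize_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Head region, shell mask, septum mask (before severity removal)."""
    shape = spec.volume_shape
    center = np.array([(s - 1) / 2.0 for s in shape])
    center += rng.uniform(-0.02, 0.02, 3) * np.array(shape)
    head_axes = np.array(shape) * rng.uniform(0.40, 0.44, 3)
    head = _normalized_radius(shape, center, head_axes, rng) <= 1.0

    cart_axes = head_axes * rng.uniform(0.52, 0.60, 3)
    inside = _normalized_radius(shape, center, cart_axes, rng) <= 1.0
    w_um = rng.uniform(*spec.shell_thickness)
    w_vox = w_um / spec.voxel_size
    if w_vox < 1.0:
        raise ValueError(
            f"shell thickness {w_um:.1f} µm is thinner than one voxel "
            f"({spec.voxel_size} µm) after rasterization")
    depth = ndimage.distance_transform_edt(inside)
    shell = inside & (depth > 0) & (depth <= w_vox)
    interior = inside & (depth > w_vox)
    # septum: a wall of the same thickness spanning the interior cavity
    cols = np.arange(shape[2], dtype=np.float32)
    septum_plane = np.abs(cols[None, None, :] - center[2]) <= w_vox / 2.0
    septum = interior & np.broadcast_to(septum_plane, shape)
    return head, shell, septum


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom volume plus its ground-truth mask."""
    rng = np.random.default_rng(spec.seed)
    head, shell, septum = _rasterize_geometry(spec, rng)

    truth = shell.copy()
    if septum.any() and spec.mutant_severity < 1.0:
        zs = np.flatnonzero(septum.any(axis=(1, 2)))
        z0, z1 = zs[0], zs[-1]
        n_keep = int(round((1.0 - spec.mutant_severity) * (z1 - z0 + 1)))
        if n_keep > 0:
            kept = np.zeros_like(septum)
            kept[z0:z0 + n_keep] = septum[z0:z0 + n_keep]
            truth |= kept

    # intensity rendering (does not feed back into the truth mask)
    texture = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, spec.volume_shape).astype(np.float32),
        sigma=[s / 8.0 for s in spec.volume_shape])
    tsd = texture.std()
    if tsd > 0:
        texture *= _TEXTURE_SD / tsd
    intensity = np.where(head, 1.0 + texture, 0.05).astype(np.float32)
    offset = -spec.contrast * spec.staining_quality * spec.background_sd
    intensity[truth] += offset
    if spec.blur_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.blur_sigma)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, spec.noise_sd, spec.volume_shape).astype(np.float32)

    vs = (spec.voxel_size,) * 3
    return PhantomSample(
        volume=Volume(intensity.astype(np.float32), vs),
        truth=LabelMask(truth.astype(np.uint8), vs),
        spec_used=spec)


def generate_dataset(n: int, base_spec: PhantomSpec | None = None,
                     n_mutant: int = 3, n_poor_staining: int = 1,
                     seed: int = 0) -> tuple[list[PhantomSample], dict]:
    """Generate a reproducible phantom cohort and its composition report.

    The default composition mirrors a realistic study database: mostly
    control morphology, a few mutants of moderate-to-severe septum loss,
    and one improperly stained sample.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if n_mutant + n_poor_staining > n:
        raise ValueError("composition exceeds cohort size")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    for i in range(n):
        sub = int(master.integers(0, 2**31 - 1))
        kw: dict = {"seed": sub}
        if i < n_mutant:
            kw["mutant_severity"] = float(np.random.default_rng(sub).uniform(0.4, 1.0))
        elif i < n_mutant + n_poor_staining:
            kw["staining_quality"] = 0.1
        samples.append(generate_phantom(replace(base, **kw)))
    order = master.permutation(n)
    samples = [samples[i] for i in order]
    report = {
        "control": sum(1 for s in samples if s.category == "control"),
        "mutant": sum(1 for s in samples if s.category == "mutant"),
        "poor-staining": sum(1 for s in samples if s.category == "poor-staining"),
    }
    return samples, report
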