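"""Stochastic training-time augmentation.

Each training slice undergoes two consecutive transforms drawn jointly from
a 6×6 probability matrix over the ordered pairs of {rotation, vertical
flip, gamma, elastic, scaling, none}.  The default policy ships the
reference operating point: rotation in [-10°, 10°], gamma exponent in
[0.9, 1.1], scale in [0.9, 1.1], and a joint matrix whose 36 entries sum
to 1 (e.g. P(elastic, elastic) = 0.09).

Geometric transforms are applied identically to image and mask (bilinear
vs nearest-neighbour sampling, zero fill outside the canvas); the gamma
transform touches the image only, on a min–max normalised copy so it is
well defined for z-scored intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "TRANSFORM_IDS",
    "AugmentationPolicy",
    "TransformDraw",
    "reference_policy",
    "sample_transform_pair",
    "apply_transform",
    "augment_example",
]

TRANSFORM_IDS = ("rotation", "vflip", "gamma", "elastic", "scaling", "none")

# Marginal weights of the reference joint matrix; the reference 6×6 matrix
# factorises exactly as the outer product of this vector with itself.
_REFERENCE_MARGINALS = np.array([0.1, 0.2, 0.1, 0.3, 0.2, 0.1])


@dataclass
class AugmentationPolicy:
    rotation_range: tuple[float, float] = (-10.0, 10.0)
    gamma_range: tuple[float, float] = (0.9, 1.1)
    scale_range: tuple[float, float] = (0.9, 1.1)
    elastic_spacing: float = 128.0     # control-point spacing, px
    elastic_magnitude: float = 10.0    # max control-point displacement, px
    pair_probabilities: np.ndarray = field(
        default_factory=lambda: np.outer(_REFERENCE_MARGINALS, _REFERENCE_MARGINALS))

    def __post_init__(self):
        self.pair_probabilities = np.asarray(self.pair_probabilities, dtype=float)
        if self.pair_probabilities.shape != (6, 6):
            raise ValueError("pair_probabilities must be a 6x6 matrix")
        if np.any(self.pair_probabilities < 0):
            raise ValueError("pair_probabilities entries must be nonnegative")
        if abs(self.pair_probabilities.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"pair_probabilities must sum to 1, got {self.pair_probabilities.sum()!r}")
        for name in ("rotation_range", "gamma_range", "scale_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"{name} must be finite with low <= high")


def reference_policy() -> AugmentationPolicy:
    """The package's default policy (reference parameter ranges and matrix)."""
    return AugmentationPolicy()


@dataclass
class TransformDraw:
    first: str
    second: str
    parameters: dict = field(default_factory=dict)  # slot -> {param: value}


def _draw_params(name: str, policy: AugmentationPolicy,
                 rng: np.random.Generator) -> dict:
    if name == "rotation":
        return {"angle": float(rng.uniform(*policy.rotation_range))}
    if name == "gamma":
        return {"gamma": float(rng.uniform(*policy.gamma_range))}
    if name == "scaling":
        return {"scale": float(rng.uniform(*policy.scale_range))}
    if name == "elastic":
        return {"seed": int(rng.integers(0, 2**31 - 1))}
    return {}


def sample_transform_pair(policy: AugmentationPolicy,
                          rng: np.random.Generator) -> TransformDraw:
    """Draw an ordered transform pair and its continuous parameters."""
    p = policy.pair_probabilities.ravel()
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("pair_probabilities must sum to 1")
    idx = rng.choice(36, p=p / p.sum())
    first, second = TRANSFORM_IDS[idx // 6], TRANSFORM_IDS[idx % 6]
    return TransformDraw(
        first=first, second=second,
        parameters={"first": _draw_params(first, policy, rng),
                    "second": _draw_params(second, policy, rng)})


def _elastic_field(shape: tuple[int, int], spacing: float, magnitude: float,
                   seed: int) -> np.ndarray:
    """Smooth random displacement field from a coarse control grid."""
    rng = np.random.default_rng(seed)
    grid = tuple(max(2, int(np.ceil(s / spacing)) + 1) for s in shape)
    coarse = rng.uniform(-magnitude, magnitude, (2, *grid))
    field_ = np.stack([
        resize(coarse[a], shape, order=3, mode="edge",
               anti_aliasing=False, preserve_range=True)
        for a in range(2)])
    return field_.astype(np.float32)


def _apply_one(name: str, params: dict, image: np.ndarray, mask: np.ndarray,
               policy: AugmentationPolicy) -> tuple[np.ndarray, np.ndarray]:
    if name == "none":
        return image, mask
    if name == "vflip":
        return image[::-1].copy(), mask[::-1].copy()
    if name == "rotation":
        angle = params["angle"]
        img = ndimage.rotate(image, angle, reshape=False, order=1,
                             mode="constant", cval=0.0)
        msk = ndimage.rotate(mask, angle, reshape=False, order=0,
                             mode="constant", cval=0)
        return img, msk
    if name == "scaling":
        s = params["scale"]
        c = (np.asarray(image.shape, dtype=float) - 1.0) / 2.0
        matrix = np.diag([1.0 / s, 1.0 / s])
        offset = c - c / s
        img = ndimage.affine_transform(image, matrix, offset=offset, order=1,
                                       mode="constant", cval=0.0)
        msk = ndimage.affine_transform(mask, matrix, offset=offset, order=0,
                                       mode="constant", cval=0)
        return img, msk
    if name == "elastic":
        disp = _elastic_field(image.shape, policy.elastic_spacing,
                              policy.elastic_magnitude, params["seed"])
        yy, xx = np.meshgrid(np.arange(image.shape[0]), np.arange(image.shape[1]),
                             indexing="ij")
        coords = np.stack([yy + disp[0], xx + disp[1]])
        img = ndimage.map_coordinates(image, coords, order=1,
                                      mode="constant", cval=0.0)
        msk = ndimage.map_coordinates(mask, coords, order=0,
                                      mode="constant", cval=0)
        return img, msk
    if name == "gamma":
        g = params["gamma"]
        lo, hi = float(image.min()), float(image.max())
        if hi - lo <= 0:
            raise ValueError(
                "gamma transform undefined: image intensity range is degenerate")
        norm = (image - lo) / (hi - lo)
        return (norm ** g) * (hi - lo) + lo, mask
    raise ValueError(f"unknown transform {name!r}")


def apply_transform(image: np.ndarray, mask: np.ndarray,
                    draw: TransformDraw,
                    policy: AugmentationPolicy | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the two drawn transforms in order to an (image, mask) slice pair."""
    if image.shape != mask.shape:
        raise ValueError(f"image/mask shape mismatch: {image.shape} vs {mask.shape}")
    policy = policy or reference_policy()
    img = np.asarray(image, dtype=np.float32)
    msk = np.asarray(mask)
    img, msk = _apply_one(draw.first, draw.parameters.get("first", {}), img, msk, policy)
    img, msk = _apply_one(draw.second, draw.parameters.get("second", {}), img, msk, policy)
    return img, (msk > 0.5).astype(np.uint8)


def augment_example(image: np.ndarray, mask: np.ndarray,
                    policy: AugmentationPolicy,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw a fresh transform pair and apply it to one training example."""
    draw = sample_transform_pair(policy, rng)
    return apply_transform(image, mask, draw, policy)
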