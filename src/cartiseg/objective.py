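"""Overlap metrics and training objectives.

The evaluation metric is the Dice similarity coefficient
``DSC = 2*TP / (2*TP + FP + FN)`` between binary masks; training minimises
its differentiable soft relaxation, optionally combined across the
deep-supervision heads with fixed weights (deepest to shallowest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor, add, scale, soft_dice_loss

__all__ = [
    "ConfusionCounts",
    "LossWeights",
    "REFERENCE_SUPERVISION_WEIGHTS",
    "confusion_counts",
    "dice_coefficient",
    "dice_loss",
    "deep_supervision_loss",
]

# Loss weights for the 7 supervised outputs of the depth-6 network,
# deepest head first, main (full-resolution) head last; they sum to 1.
REFERENCE_SUPERVISION_WEIGHTS = (0.03, 0.05, 0.08, 0.12, 0.15, 0.2, 0.37)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class LossWeights:
    weights: tuple[float, ...] = REFERENCE_SUPERVISION_WEIGHTS

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        if any(x < 0 for x in w):
            raise ValueError("supervision weights must be nonnegative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"supervision weights must sum to 1, got {sum(w)}")
        object.__setattr__(self, "weights", w)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, truth {truth.shape}")
    p = pred != 0
    t = truth != 0
    return ConfusionCounts(
        tp=int(np.sum(p & t)), tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t)))


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity of two binary grids; both-empty is defined as 1."""
    c = confusion_counts(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def dice_loss(pred, truth, smooth: float = 1e-6):
    """Soft Dice loss ``1 - (2 Σ p·t + s) / (Σ p + Σ t + s)``.

    Accepts plain arrays (returns a float) or an autodiff
    :class:`~cartiseg.nn.tensor.Tensor` prediction (returns a scalar Tensor
    for backpropagation).  Computed per sample over the leading axis and
    averaged, so slices with large foreground do not dominate a batch.
    """
    if isinstance(pred, Tensor):
        return soft_dice_loss(pred, truth, smooth=smooth)
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape}, truth {t.shape}")
    if p.ndim < 3:  # single slice/volume: treat as one sample
        p, t = p[None], t[None]
    n = p.shape[0]
    ps, ts = p.reshape(n, -1), t.reshape(n, -1)
    num = 2.0 * (ps * ts).sum(axis=1) + smooth
    den = ps.sum(axis=1) + ts.sum(axis=1) + smooth
    return float(np.mean(1.0 - num / den))


def deep_supervision_loss(head_preds, truth, weights: LossWeights | None = None,
                          smooth: float = 1e-6):
    """Weighted sum of per-head Dice losses, all heads at truth resolution."""
    weights = weights or LossWeights()
    if len(head_preds) != len(weights.weights):
        raise ValueError(
            f"{len(head_preds)} heads but {len(weights.weights)} weights")
    if isinstance(head_preds[0], Tensor):
        total = None
        for w, head in zip(weights.weights, head_preds):
            term = scale(soft_dice_loss(head, truth, smooth=smooth), w)
            total = term if total is None else add(total, term)
        return total
    return float(sum(w * dice_loss(h, truth, smooth=smooth)
                     for w, h in zip(weights.weights, head_preds)))
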