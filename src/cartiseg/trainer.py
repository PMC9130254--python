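"""Training loop, k-fold cross-validation planning, slice subsampling.

Training minimises the (optionally deep-supervised) soft Dice loss with
Adam/AMSGrad over shuffled mini-batches of axial slices, applying the
stochastic two-transform augmentation policy on the fly.  The weights
returned are those of the epoch with the lowest validation loss.  All
stochastic sources (fold shuffling, batch shuffling, augmentation draws)
derive from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import AugmentationPolicy, augment_example, reference_policy
from .infer import segment_volume
from .netarch import NetworkSpec, SegmentationNetwork, build_network
from .nn import Adam, Tensor
from .objective import LossWeights, deep_supervision_loss, dice_coefficient
from .preprocess import CanvasSpec, fit_to_canvas, rescale_voxels, standardize
from .volio import LabelMask, Volume

__all__ = [
    "TrainingConfig",
    "FoldPlan",
    "SubsampleRule",
    "make_folds",
    "subsample_slices",
    "prepare_slice_examples",
    "train_model",
    "cross_validate",
]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 50
    amsgrad: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass(frozen=True)
class FoldPlan:
    assignments: dict  # sample id -> fold index
    k: int

    def validation_ids(self, fold: int) -> list:
        return [s for s, f in self.assignments.items() if f == fold]

    def training_ids(self, fold: int) -> list:
        return [s for s, f in self.assignments.items() if f != fold]


@dataclass(frozen=True)
class SubsampleRule:
    background_stride: int = 200
    foreground_stride: int = 30

    def __post_init__(self):
        if self.background_stride < 1 or self.foreground_stride < 1:
            raise ValueError("strides must be >= 1")


def make_folds(sample_ids, k: int, seed: int = 0) -> FoldPlan:
    """Deterministically partition samples into k validation folds.

    Every sample validates exactly once; fold sizes differ by at most one.
    With 14 samples and k=7 each fold validates 2 and trains on 12.
    """
    ids = list(sample_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} samples")
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignments = {ids[j]: i % k for i, j in enumerate(order)}
    return FoldPlan(assignments=assignments, k=k)


def subsample_slices(mask: LabelMask, rule: SubsampleRule) -> list[int]:
    """Slice indices for reduced training sets.

    Within the contiguous index interval spanned by foreground-containing
    slices, every ``foreground_stride``-th slice is taken; in the runs
    before and after it, every ``background_stride``-th slice (counting
    from each run's first index).  Sorted and duplicate-free.
    """
    n = mask.data.shape[0]
    has_fg = mask.data.reshape(n, -1).any(axis=1)
    picked: set[int] = set()
    if not has_fg.any():
        picked.update(range(0, n, rule.background_stride))
    else:
        first = int(np.argmax(has_fg))
        last = n - 1 - int(np.argmax(has_fg[::-1]))
        picked.update(range(first, last + 1, rule.foreground_stride))
        picked.update(range(0, first, rule.background_stride))
        picked.update(range(last + 1, n, rule.background_stride))
    return sorted(picked)


def prepare_slice_examples(vol: Volume, mask: LabelMask, canvas: CanvasSpec,
                           rule: SubsampleRule | None = None
                           ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Preprocess one sample to canvas-grid, standardized (image, mask) slices."""
    scaled, gt, m = rescale_voxels(vol, canvas.target_voxel, mask=mask)
    fitted, gt, m = fit_to_canvas(scaled, canvas, transform=gt, mask=m)
    prepared = standardize(fitted)
    indices = (subsample_slices(m, rule) if rule is not None
               else range(prepared.data.shape[0]))
    return [(prepared.data[i], m.data[i]) for i in indices]


def _composite_loss_value(net: SegmentationNetwork, examples, weights: LossWeights,
                          batch_size: int) -> float:
    """Graph-free composite loss over a set of examples (for validation)."""
    params = net.parameters()
    flags = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
    try:
        losses = []
        for start in range(0, len(examples), batch_size):
            chunk = examples[start:start + batch_size]
            x = np.stack([im for im, _ in chunk])[:, None]
            t = np.stack([mk for _, mk in chunk])[:, None].astype(np.float32)
            heads = net.forward(Tensor(x))
            losses.append(
                (deep_supervision_loss([h.data for h in heads], t, weights),
                 len(chunk)))
        total = sum(l * n for l, n in losses)
        return float(total / sum(n for _, n in losses))
    finally:
        for p, f in zip(params, flags):
            p.requires_grad = f


def train_model(network: SegmentationNetwork, training_set,
                config: TrainingConfig | None = None,
                policy: AugmentationPolicy | None = None,
                validation_set=None,
                augment: bool = True) -> tuple[SegmentationNetwork, pd.DataFrame]:
    """Train on canvas-grid slice examples; return best-epoch weights.

    ``training_set``/``validation_set`` are lists of ``(image, mask)`` 2-D
    arrays already on the network's input grid.  Mini-batches are shuffled
    uniformly across samples each epoch, each example drawing a fresh
    augmentation pair.  If a validation set is given, the weights from the
    epoch with the lowest validation loss are restored before returning.
    """
    config = config or TrainingConfig()
    if not training_set:
        raise ValueError("training set is empty")
    policy = policy or reference_policy()
    weights = LossWeights(network.spec.supervision_weights
                          if network.spec.use_deep_supervision else (1.0,))
    rng = np.random.default_rng(config.seed)
    opt = Adam(network.parameters(), lr=config.learning_rate,
               amsgrad=config.amsgrad)

    history = []
    best_val = np.inf
    best_state = None
    for epoch in range(config.epochs):
        order = rng.permutation(len(training_set))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            images, masks = [], []
            for i in batch_idx:
                im, mk = training_set[i]
                if augment:
                    im, mk = augment_example(im, mk, policy, rng)
                images.append(im)
                masks.append(mk)
            x = Tensor(np.stack(images)[:, None])
            t = np.stack(masks)[:, None].astype(np.float32)
            heads = network.forward(x)
            loss = deep_supervision_loss(heads, t, weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        row = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if validation_set:
            val = _composite_loss_value(network, validation_set, weights,
                                        config.batch_size)
            row["val_loss"] = val
            if val < best_val:
                best_val = val
                best_state = network.state_dict()
        history.append(row)
    if best_state is not None:
        network.load_state_dict(best_state)
    return network, pd.DataFrame(history)


def cross_validate(samples, plan: FoldPlan, spec: NetworkSpec,
                   config: TrainingConfig | None = None,
                   policy: AugmentationPolicy | None = None,
                   canvas: CanvasSpec | None = None,
                   rule: SubsampleRule | None = None,
                   augment: bool = True) -> pd.DataFrame:
    """k-fold cross-validation over whole samples.

    ``samples`` is a list of ``(sample_id, Volume, LabelMask)`` triples.
    For each fold a fresh network is trained on the training samples'
    slices and evaluated with volume-level Dice on each validation sample
    via :func:`~cartiseg.infer.segment_volume`.  One row per sample.
    """
    config = config or TrainingConfig()
    canvas = canvas or CanvasSpec(height=spec.input_height, width=spec.input_width,
                                  target_voxel=6.0)
    by_id = {sid: (vol, mask) for sid, vol, mask in samples}
    if set(by_id) != set(plan.assignments):
        raise ValueError("fold plan ids do not match the provided samples")
    rows = []
    for fold in range(plan.k):
        train_examples = []
        for sid in plan.training_ids(fold):
            vol, mask = by_id[sid]
            train_examples.extend(prepare_slice_examples(vol, mask, canvas, rule))
        val_examples = []
        for sid in plan.validation_ids(fold):
            vol, mask = by_id[sid]
            val_examples.extend(prepare_slice_examples(vol, mask, canvas, rule))
        net = build_network(spec, seed=config.seed + fold)
        net, _ = train_model(net, train_examples, config, policy,
                             validation_set=val_examples, augment=augment)
        for sid in plan.validation_ids(fold):
            vol, mask = by_id[sid]
            result = segment_volume(vol, net, canvas)
            rows.append({
                "sample_id": sid, "fold": fold,
                "dice": dice_coefficient(result.mask.data, mask.data),
            })
    return pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
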