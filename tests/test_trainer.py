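"""Fold planning, slice subsampling, the training loop, cross-validation."""

import numpy as np
import pytest

from cartiseg.netarch import NetworkSpec, build_network
from cartiseg.objective import dice_coefficient
from cartiseg.phantom import PhantomSpec, generate_dataset
from cartiseg.preprocess import CanvasSpec
from cartiseg.trainer import (
    FoldPlan,
    SubsampleRule,
    TrainingConfig,
    cross_validate,
    make_folds,
    subsample_slices,
    train_model,
)
from cartiseg.volio import LabelMask


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------

def test_sevenfold_over_fourteen_validates_two_trains_twelve():
    ids = [f"s{i}" for i in range(14)]
    plan = make_folds(ids, k=7, seed=1)
    for fold in range(7):
        assert len(plan.validation_ids(fold)) == 2
        assert len(plan.training_ids(fold)) == 12


def test_folds_partition_samples():
    ids = list("abcdefghij")
    plan = make_folds(ids, k=3, seed=2)
    val_sets = [set(plan.validation_ids(f)) for f in range(3)]
    assert set().union(*val_sets) == set(ids)
    for i in range(3):
        for j in range(i + 1, 3):
            assert not val_sets[i] & val_sets[j]
    sizes = sorted(len(v) for v in val_sets)
    assert sizes[-1] - sizes[0] <= 1  # near-equal when not divisible


def test_k_equal_n_is_leave_one_out():
    plan = make_folds(["a", "b", "c"], k=3, seed=0)
    assert all(len(plan.validation_ids(f)) == 1 for f in range(3))


def test_fold_plan_deterministic_given_seed():
    ids = [f"s{i}" for i in range(9)]
    assert make_folds(ids, 3, seed=5) == make_folds(ids, 3, seed=5)
    assert make_folds(ids, 3, seed=5) != make_folds(ids, 3, seed=6)


def test_too_many_folds_rejected():
    with pytest.raises(ValueError):
        make_folds(["a", "b"], k=3, seed=0)


# --------------------------------------------------------------------------
# slice subsampling
# --------------------------------------------------------------------------

def _mask_with_fg(n_slices, fg_range):
    data = np.zeros((n_slices, 4, 4), np.uint8)
    if fg_range is not None:
        data[fg_range[0]:fg_range[1], 1:3, 1:3] = 1
    return LabelMask(data, (6.0,) * 3)


def test_unit_strides_select_all_slices():
    mask = _mask_with_fg(20, (5, 10))
    assert subsample_slices(mask, SubsampleRule(1, 1)) == list(range(20))


def test_empty_mask_uses_background_stride_from_zero():
    mask = _mask_with_fg(1000, None)
    got = subsample_slices(mask, SubsampleRule(200, 30))
    assert got == [0, 200, 400, 600, 800]


def test_matches_direct_sentence_oracle():
    """Every 200th slice outside the cartilage-containing interval, every
    30th inside it — brute-force reading of the rule, scaled down."""
    n, first, last = 100, 30, 59
    bg_stride, fg_stride = 20, 7
    mask = _mask_with_fg(n, (first, last + 1))
    got = subsample_slices(mask, SubsampleRule(bg_stride, fg_stride))

    expected = set()
    i = first
    while i <= last:
        expected.add(i)
        i += fg_stride
    run = list(range(0, first))
    for pos, idx in enumerate(run):
        if pos % bg_stride == 0:
            expected.add(idx)
    run = list(range(last + 1, n))
    for pos, idx in enumerate(run):
        if pos % bg_stride == 0:
            expected.add(idx)
    assert got == sorted(expected)


def test_output_sorted_unique_and_in_range():
    rng = np.random.default_rng(0)
    data = (rng.random((50, 4, 4)) > 0.95).astype(np.uint8)
    mask = LabelMask(data, (6.0,) * 3)
    got = subsample_slices(mask, SubsampleRule(7, 3))
    assert got == sorted(set(got))
    assert all(0 <= i < 50 for i in got)


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

def _toy_example(rng, size=32):
    """A single learnable slice: bright square on noisy background."""
    mask = np.zeros((size, size), np.uint8)
    mask[10:22, 8:20] = 1
    img = rng.normal(0, 0.3, (size, size)).astype(np.float32)
    img[mask.astype(bool)] += 2.0
    img = (img - img.mean()) / img.std()
    return img, mask


def test_zero_epochs_returns_initial_weights(rng):
    spec = NetworkSpec(input_height=32, input_width=32, depth=2, base_filters=2)
    net = build_network(spec, seed=0)
    before = [p.copy() for p in net.state_dict()]
    net, history = train_model(net, [_toy_example(rng)],
                               TrainingConfig(epochs=0), augment=False)
    for a, b in zip(before, net.state_dict()):
        assert np.array_equal(a, b)
    assert history.empty


def test_empty_training_set_rejected(rng):
    spec = NetworkSpec(input_height=32, input_width=32, depth=2, base_filters=2)
    net = build_network(spec, seed=0)
    with pytest.raises(ValueError, match="empty"):
        train_model(net, [], TrainingConfig(epochs=1))


def test_defaults_match_reference_training_configuration():
    cfg = TrainingConfig()
    assert cfg.learning_rate == 1e-4
    assert cfg.batch_size == 4
    assert cfg.epochs == 50
    assert cfg.amsgrad is True


def test_network_memorizes_single_example_within_200_steps(rng):
    """Overfit sanity oracle: one synthetic slice must be memorized
    (training Dice > 0.99) in at most 200 optimization steps."""
    spec = NetworkSpec(input_height=32, input_width=32, depth=2, base_filters=4)
    net = build_network(spec, seed=1)
    img, mask = _toy_example(rng)
    net, _ = train_model(
        net, [(img, mask)],
        TrainingConfig(epochs=200, batch_size=1, learning_rate=3e-3, seed=1),
        augment=False)
    pred = (net.predict(img[None])[0] >= 0.5).astype(np.uint8)
    assert dice_coefficient(pred, mask) > 0.99


def test_training_loss_decreases_across_seeds(rng):
    """On a fixed learnable toy problem the final loss beats the initial
    loss for every seed."""
    examples = [_toy_example(np.random.default_rng(s)) for s in range(4)]
    for seed in range(10):
        spec = NetworkSpec(input_height=32, input_width=32, depth=2,
                           base_filters=2)
        net = build_network(spec, seed=seed)
        net, hist = train_model(
            net, examples,
            TrainingConfig(epochs=5, batch_size=4, learning_rate=1e-3,
                           seed=seed),
            augment=False)
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]


def test_best_epoch_weights_restored(rng):
    """The returned weights reproduce the minimum recorded validation loss."""
    spec = NetworkSpec(input_height=32, input_width=32, depth=2, base_filters=2)
    net = build_network(spec, seed=3)
    train = [_toy_example(np.random.default_rng(s)) for s in range(2)]
    val = [_toy_example(np.random.default_rng(99))]
    net, hist = train_model(
        net, train,
        TrainingConfig(epochs=4, batch_size=2, learning_rate=1e-3, seed=3),
        validation_set=val, augment=False)
    from cartiseg.objective import LossWeights
    from cartiseg.trainer import _composite_loss_value
    weights = LossWeights(spec.supervision_weights)
    final = _composite_loss_value(net, val, weights, 2)
    assert final == pytest.approx(hist["val_loss"].min(), abs=1e-5)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def _micro_cohort():
    cohort, _ = generate_dataset(
        14, base_spec=PhantomSpec(volume_shape=(8, 16, 16)),
        n_mutant=0, n_poor_staining=0, seed=21)
    return [(f"s{i:02d}", s.volume, s.truth) for i, s in enumerate(cohort)]


def test_cross_validation_yields_one_row_per_sample():
    samples = _micro_cohort()
    plan = make_folds([s[0] for s in samples], k=7, seed=4)
    spec = NetworkSpec(input_height=16, input_width=16, depth=2, base_filters=2)
    cfg = TrainingConfig(epochs=1, batch_size=4, seed=4)
    canvas = CanvasSpec(16, 16, 6.0)
    table = cross_validate(samples, plan, spec, cfg, canvas=canvas, augment=False)
    assert len(table) == 14
    assert sorted(table["sample_id"]) == sorted(s[0] for s in samples)
    assert table["sample_id"].is_unique
    assert set(table["fold"]) == set(range(7))

    # determinism: identical seed reproduces the table exactly
    again = cross_validate(samples, plan, spec, cfg, canvas=canvas, augment=False)
    assert np.allclose(table["dice"].to_numpy(), again["dice"].to_numpy())


def test_fold_plan_mismatch_rejected():
    samples = _micro_cohort()
    plan = make_folds(["x", "y"], k=2, seed=0)
    spec = NetworkSpec(input_height=16, input_width=16, depth=2, base_filters=2)
    with pytest.raises(ValueError, match="ids"):
        cross_validate(samples, plan, spec, TrainingConfig(epochs=0))
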