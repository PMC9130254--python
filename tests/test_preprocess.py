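"""Grid preparation: rescaling, canvas fitting, standardization,
sparse-annotation interpolation, and transform inversion."""

import numpy as np
import pytest

from cartiseg.preprocess import (
    CanvasSpec,
    GridTransform,
    fit_to_canvas,
    interpolate_sparse_labels,
    invert_mask_transform,
    rescale_voxels,
    standardize,
)
from cartiseg.volio import LabelMask, Volume


def _vol(data, voxel=6.0):
    return Volume(np.asarray(data, np.float32), (voxel,) * 3)


# --------------------------------------------------------------------------
# rescale_voxels
# --------------------------------------------------------------------------

def test_rescale_identity_when_voxel_matches():
    vol = _vol(np.random.default_rng(0).random((3, 10, 10)))
    out, gt, _ = rescale_voxels(vol, 6.0)
    assert np.array_equal(out.data, vol.data)
    assert gt.scale_factor == (1.0, 1.0)


def test_rescale_factor_two_doubles_in_plane_dims():
    vol = Volume(np.zeros((2, 10, 10), np.float32), (12.0, 12.0, 12.0))
    out, gt, _ = rescale_voxels(vol, 6.0)
    assert out.data.shape == (2, 20, 20)
    assert out.voxel_size == (12.0, 6.0, 6.0)  # slice axis untouched


def _bilinear_oracle(img, out_shape):
    """Pixel-centre-aligned bilinear sampling with edge clamping."""
    h, w = img.shape
    oh, ow = out_shape
    out = np.zeros(out_shape)
    for i in range(oh):
        for j in range(ow):
            y = np.clip((i + 0.5) * h / oh - 0.5, 0, h - 1)
            x = np.clip((j + 0.5) * w / ow - 0.5, 0, w - 1)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
            fy, fx = y - y0, x - x0
            out[i, j] = (img[y0, x0] * (1 - fy) * (1 - fx)
                         + img[y0, x1] * (1 - fy) * fx
                         + img[y1, x0] * fy * (1 - fx)
                         + img[y1, x1] * fy * fx)
    return out


def test_rescale_matches_bilinear_weight_formula():
    slice_ = np.array([[0.0, 1.0], [2.0, 3.0]], np.float32)
    vol = Volume(slice_[None], (12.0, 12.0, 12.0))
    out, _, _ = rescale_voxels(vol, 6.0)
    expected = _bilinear_oracle(slice_, (4, 4))
    assert np.allclose(out.data[0], expected, atol=1e-5)


def test_rescale_mask_stays_binary():
    rng = np.random.default_rng(3)
    mask = LabelMask((rng.random((2, 8, 8)) > 0.5).astype(np.uint8), (9.0,) * 3)
    vol = Volume(rng.random((2, 8, 8)).astype(np.float32), (9.0,) * 3)
    _, _, m = rescale_voxels(vol, 6.0, mask=mask)
    assert set(np.unique(m.data)) <= {0, 1}
    assert m.data.shape == (2, 12, 12)


def test_rescale_rejects_nonpositive_target():
    with pytest.raises(ValueError):
        rescale_voxels(_vol(np.zeros((1, 4, 4))), 0.0)


# --------------------------------------------------------------------------
# fit_to_canvas
# --------------------------------------------------------------------------

def test_padding_preserves_interior_and_zeroes_border(rng):
    data = rng.random((2, 10, 9)).astype(np.float32) + 1.0  # strictly positive
    vol = _vol(data)
    canvas = CanvasSpec(16, 12, 6.0)
    out, gt, _ = fit_to_canvas(vol, canvas)
    assert out.data.shape == (2, 16, 12)
    (py0, py1), (px0, px1) = gt.pad
    interior = out.data[:, py0:16 - py1, px0:12 - px1]
    assert np.array_equal(interior, data)
    border_only = out.data.copy()
    border_only[:, py0:16 - py1, px0:12 - px1] = 0.0
    assert not border_only.any()


def test_center_crop_when_larger_than_canvas(rng):
    data = rng.random((1, 20, 14)).astype(np.float32)
    out, gt, _ = fit_to_canvas(_vol(data), CanvasSpec(16, 12, 6.0))
    assert out.data.shape == (1, 16, 12)
    (cy0, cy1), (cx0, cx1) = gt.crop
    assert (cy0, cy1) == (2, 2)
    assert (cx0, cx1) == (1, 1)
    assert np.array_equal(out.data[0], data[0, 2:18, 1:13])


def test_odd_remainder_goes_to_high_side():
    data = np.ones((1, 5, 5), np.float32)
    out, gt, _ = fit_to_canvas(_vol(data), CanvasSpec(8, 8, 6.0))
    assert gt.pad == ((1, 2), (1, 2))


def test_pad_roundtrip_recovers_original_extent(rng):
    mask = (rng.random((3, 10, 9)) > 0.5).astype(np.uint8)
    vol = _vol(rng.random((3, 10, 9)))
    out, gt, m = fit_to_canvas(vol, CanvasSpec(16, 16, 6.0),
                               mask=LabelMask(mask, (6.0,) * 3))
    recovered = invert_mask_transform(m.data, gt)
    assert recovered.shape == mask.shape
    assert np.array_equal(recovered, mask)


def test_rescale_then_fit_inversion_on_smooth_phantom(small_phantom):
    """Upscale (9 µm -> 6 µm) + pad, then invert: mask Dice >= 0.99."""
    from cartiseg.objective import dice_coefficient

    truth = small_phantom.truth
    vol = Volume(small_phantom.volume.data, (9.0, 9.0, 9.0))
    mask = LabelMask(truth.data, (9.0, 9.0, 9.0))
    scaled, gt, m = rescale_voxels(vol, 6.0, mask=mask)
    fitted, gt, m = fit_to_canvas(scaled, CanvasSpec(96, 96, 6.0),
                                  transform=gt, mask=m)
    recovered = invert_mask_transform(m.data, gt)
    assert recovered.shape == truth.data.shape
    assert dice_coefficient(recovered, truth.data) >= 0.99


def test_grid_transform_json_roundtrip():
    gt = GridTransform(original_shape=(10, 9), scaled_shape=(15, 14),
                       scale_factor=(1.5, 1.5), pad=((1, 2), (0, 0)),
                       crop=((0, 0), (3, 4)), source_voxel=(9.0, 9.0, 9.0),
                       target_voxel=6.0)
    assert GridTransform.from_json(gt.to_json()) == gt


# --------------------------------------------------------------------------
# standardize
# --------------------------------------------------------------------------

def test_standardize_zero_mean_unit_sd(rng):
    vol = _vol(rng.random((4, 8, 8)) * 100 + 40)
    out = standardize(vol)
    assert abs(out.data.mean()) < 1e-6
    assert abs(out.data.std() - 1.0) < 1e-6


def test_standardize_affine_invariant(rng):
    data = rng.random((3, 6, 6))
    a = standardize(_vol(data))
    b = standardize(_vol(3.5 * data + 12.0))
    assert np.allclose(a.data, b.data, atol=1e-5)


def test_standardize_idempotent(rng):
    vol = _vol(rng.random((3, 6, 6)))
    once = standardize(vol)
    twice = standardize(once)
    assert np.allclose(once.data, twice.data, atol=1e-6)


def test_standardize_rejects_constant_volume():
    with pytest.raises(ValueError, match="variance"):
        standardize(_vol(np.full((2, 4, 4), 7.0)))


# --------------------------------------------------------------------------
# interpolate_sparse_labels
# --------------------------------------------------------------------------

def test_identical_bracketing_slices_fill_identically():
    data = np.zeros((7, 4, 4), np.uint8)
    data[0, 1:3, 1:3] = 1
    data[3, 1:3, 1:3] = 1
    data[6, 1:3, 1:3] = 1
    out = interpolate_sparse_labels(LabelMask(data, (6.0,) * 3), k=3)
    for i in range(7):
        assert np.array_equal(out.data[i], data[0])


def test_stride_one_is_identity(rng):
    data = (rng.random((5, 4, 4)) > 0.5).astype(np.uint8)
    out = interpolate_sparse_labels(LabelMask(data, (6.0,) * 3), k=1)
    assert np.array_equal(out.data, data)


def test_linear_blend_threshold_rule():
    """Pixel set at slice 0, unset at slice 3: fractions 2/3 and 1/3
    threshold at 0.5 to (set, unset)."""
    data = np.zeros((4, 2, 2), np.uint8)
    data[0, 0, 0] = 1
    out = interpolate_sparse_labels(LabelMask(data, (6.0,) * 3), k=3)
    assert out.data[1, 0, 0] == 1   # weight 2/3 on the set slice
    assert out.data[2, 0, 0] == 0   # weight 1/3
    assert out.data[0, 0, 0] == 1 and out.data[3, 0, 0] == 0  # anchors kept


def test_interpolation_matches_voxelwise_blend_oracle(rng):
    data = np.zeros((7, 6, 6), np.uint8)
    for a in (0, 3, 6):
        data[a] = rng.random((6, 6)) > 0.5
    out = interpolate_sparse_labels(LabelMask(data, (6.0,) * 3), k=3)
    for a in (0, 3):
        for j in (1, 2):
            w = j / 3
            expected = ((1 - w) * data[a] + w * data[a + 3] >= 0.5).astype(np.uint8)
            assert np.array_equal(out.data[a + j], expected)


def test_invalid_stride_rejected():
    mask = LabelMask(np.zeros((3, 2, 2), np.uint8), (6.0,) * 3)
    with pytest.raises(ValueError):
        interpolate_sparse_labels(mask, k=0)
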