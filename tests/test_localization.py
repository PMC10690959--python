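"""Box derivation, loss closed forms, crop/consolidate round trips,
hierarchical features and fusion."""

import numpy as np
import pytest

from mvtseg import nn
from mvtseg.errors import BoxError, ConfigError, EmptyMaskError, RecordError
from mvtseg.localization import (BoundingBox, FeatureMap, LocalizerConfig,
                                 LocalizerNet, consolidate, crop_to_box,
                                 cubic_resample_matrix, derive_gt_box,
                                 fuse_features, localization_loss)
from mvtseg.volume_io import LabelMap, Volume


# -- derive_gt_box ------------------------------------------------------

def test_gt_box_single_voxel():
    data = np.zeros((9, 9, 9), dtype=np.int16)
    data[4, 4, 4] = 1
    box = derive_gt_box(LabelMap(data), margin=0)
    assert box.center == (4.0, 4.0, 4.0)
    assert box.extent == (1.0, 1.0, 1.0)


def test_gt_box_span_oracle():
    data = np.zeros((10, 10, 10), dtype=np.int16)
    data[3:8, 2, 0:10] = 2
    box = derive_gt_box(LabelMap(data), margin=0)
    assert box.center == (5.0, 2.0, 4.5)
    assert box.extent == (5.0, 1.0, 10.0)


def test_gt_box_margin_and_clipping():
    data = np.zeros((10, 10, 10), dtype=np.int16)
    data[0:2, 4:6, 8:10] = 1
    box = derive_gt_box(LabelMap(data), margin=2)
    assert box.extent == (4.0, 6.0, 4.0)  # clipped at the 0 and 9 faces


def test_gt_box_empty_raises():
    with pytest.raises(EmptyMaskError):
        derive_gt_box(LabelMap(np.zeros((5, 5, 5), dtype=np.int16)))


# -- localization loss --------------------------------------------------

def test_loss_zero_iff_equal():
    b = BoundingBox((10, 10, 10), (5, 6, 7))
    assert localization_loss(b, b, 0.5, (20, 20, 20)) == 0.0
    other = BoundingBox((10, 10, 10.5), (5, 6, 7))
    assert localization_loss(b, other, 0.5, (20, 20, 20)) > 0


def test_loss_center_only_345_triangle():
    c = BoundingBox((10, 10, 10), (4, 4, 4))
    c_hat = BoundingBox((13, 14, 10), (4, 4, 4))
    assert localization_loss(c, c_hat, 0.5, (20, 20, 20)) == pytest.approx(
        5.0, abs=1e-9)


def test_loss_size_only_hand_value():
    c = BoundingBox((10, 10, 10), (10, 4, 4))
    c_hat = BoundingBox((10, 10, 10), (6, 4, 4))
    assert localization_loss(c, c_hat, 0.5, (20, 20, 20)) == pytest.approx(
        0.2, abs=1e-9)


def test_loss_symmetric_in_extents_and_nonnegative(rng):
    for _ in range(50):
        c1 = BoundingBox(rng.uniform(2, 18, 3), rng.uniform(1, 15, 3))
        c2 = BoundingBox(rng.uniform(2, 18, 3), rng.uniform(1, 15, 3))
        l12 = localization_loss(c1, c2, 0.5, (20, 20, 20))
        l21 = localization_loss(c2, c1, 0.5, (20, 20, 20))
        assert l12 >= 0
        assert l12 == pytest.approx(l21)


# -- crop / consolidate -------------------------------------------------

def test_crop_interior_no_padding():
    v = Volume(np.full((20, 20, 20), 7.0, dtype=np.float32))
    box = BoundingBox((10, 10, 10), (5, 5, 5))
    crop, rec = crop_to_box(v, box, (8, 8, 8))
    assert crop.shape == (8, 8, 8)
    assert (crop.data == 7.0).all()
    assert rec.pad_before == (0, 0, 0) and rec.pad_after == (0, 0, 0)


def test_crop_corner_padding_arithmetic():
    v = Volume(np.ones((10, 10, 10), dtype=np.float32))
    box = BoundingBox((1, 1, 8), (4, 4, 4))
    crop, rec = crop_to_box(v, box, (8, 8, 8))
    # start = floor(center - 4) = (-3, -3, 4); overhang: 3 before x/y, 2 after z
    assert rec.pad_before == (3, 3, 0)
    assert rec.pad_after == (0, 0, 2)
    assert crop.data.sum() == (8 - 3) * (8 - 3) * (8 - 2)
    assert (crop.data[:3] == 0).all() and (crop.data[:, :, 6:] == 0).all()


def test_crop_center_outside_raises():
    v = Volume(np.zeros((10, 10, 10), dtype=np.float32))
    with pytest.raises(BoxError):
        crop_to_box(v, BoundingBox((12, 5, 5), (2, 2, 2)), (4, 4, 4))


def test_consolidate_shape_mismatch_raises():
    lm = LabelMap(np.zeros((4, 4, 4), dtype=np.int16))
    _, rec = crop_to_box(lm, BoundingBox((2, 2, 2), (2, 2, 2)), (3, 3, 3))
    with pytest.raises(RecordError):
        consolidate(lm, rec)


def test_crop_consolidate_round_trip_property(rng):
    """consolidate∘crop is the identity inside the crop window, including
    corner boxes that need zero padding (200 random geometries)."""
    for _ in range(200):
        shape = tuple(int(s) for s in rng.integers(6, 30, 3))
        data = rng.integers(0, 3, size=shape).astype(np.int16)
        lm = LabelMap(data)
        center = tuple(rng.uniform(0, s - 1) for s in shape)
        target = tuple(int(t) for t in rng.integers(2, 16, 3))
        crop, rec = crop_to_box(lm, BoundingBox(center, (1, 1, 1)), target)
        back = consolidate(crop, rec)
        win = tuple(slice(a, b) for a, b in zip(rec.crop_start, rec.crop_stop))
        assert np.array_equal(back.data[win], data[win])
        outside = np.ones(shape, bool)
        outside[win] = False
        assert (back.data[outside] == 0).all()


def test_consolidate_single_voxel_index_oracle():
    lm = LabelMap(np.zeros((12, 12, 12), dtype=np.int16))
    _, rec = crop_to_box(lm, BoundingBox((6, 6, 6), (4, 4, 4)), (4, 4, 4))
    seg = np.zeros((4, 4, 4), dtype=np.int16)
    seg[0, 0, 0] = 2
    out = consolidate(LabelMap(seg), rec)
    assert out.data[rec.crop_start] == 2
    assert out.data.sum() == 2


def test_gt_crop_consolidate_recovers_truth(small_phantom):
    box = derive_gt_box(small_phantom.truth, margin=2)
    crop, rec = crop_to_box(small_phantom.truth, box, (32, 32, 24))
    back = consolidate(crop, rec)
    assert np.array_equal(back.data, small_phantom.truth.data)


# -- hierarchy / fusion -------------------------------------------------

def test_feature_pyramid_shapes():
    cfg = LocalizerConfig(levels=3, base_channels=4, seed=0)
    model = LocalizerNet(cfg)
    feats = model.features(np.zeros((1, 1, 32, 32, 32), dtype=np.float32))
    assert [f.shape[2:] for f in feats] == [(16, 16, 16), (8, 8, 8), (4, 4, 4)]


def test_feature_pyramid_too_small_volume():
    model = LocalizerNet(LocalizerConfig(levels=3, base_channels=4, seed=0))
    with pytest.raises(ConfigError):
        model.features(np.zeros((1, 1, 4, 4, 4), dtype=np.float32))


def test_zero_weights_give_zero_features():
    model = LocalizerNet(LocalizerConfig(levels=2, base_channels=4, seed=0))
    for p in model.parameters():
        p.data[:] = 0.0
    feats = model.features(np.random.default_rng(0).normal(
        size=(1, 1, 16, 16, 16)).astype(np.float32))
    for f in feats:
        assert np.all(f.data == 0.0)


def test_features_deterministic():
    x = np.random.default_rng(5).normal(size=(1, 1, 16, 16, 16)).astype(np.float32)
    m1 = LocalizerNet(LocalizerConfig(levels=2, base_channels=4, seed=9))
    m2 = LocalizerNet(LocalizerConfig(levels=2, base_channels=4, seed=9))
    f1, f2 = m1.features(x), m2.features(x)
    for a, b in zip(f1, f2):
        assert np.array_equal(a.data, b.data)


def test_fuse_single_level_identity(rng):
    f = FeatureMap(rng.normal(size=(3, 8, 8, 8)).astype(np.float32), level=1)
    fused = fuse_features([f])
    assert np.array_equal(fused.data, f.data)


def test_fuse_zero_second_level(rng):
    f1 = FeatureMap(rng.normal(size=(3, 8, 8, 8)).astype(np.float32), level=1)
    f2 = FeatureMap(np.zeros((3, 4, 4, 4), dtype=np.float32), level=2)
    fused = fuse_features([f1, f2])
    assert np.allclose(fused.data, f1.data)


def test_fuse_constant_preservation():
    f1 = FeatureMap(np.full((2, 8, 8, 8), 1.5, dtype=np.float32), level=1)
    f2 = FeatureMap(np.full((2, 4, 4, 4), 2.25, dtype=np.float32), level=2)
    fused = fuse_features([f1, f2])
    assert np.allclose(fused.data, 3.75, atol=1e-5)


def test_fuse_channel_mismatch_errors(rng):
    f1 = FeatureMap(rng.normal(size=(3, 8, 8, 8)).astype(np.float32), level=1)
    f2 = FeatureMap(rng.normal(size=(4, 4, 4, 4)).astype(np.float32), level=2)
    with pytest.raises(ConfigError):
        fuse_features([f1, f2])


def test_resample_matrix_partition_of_unity():
    for n_in, n_out in [(4, 8), (8, 4), (6, 24), (5, 7)]:
        w = cubic_resample_matrix(n_in, n_out)
        assert np.allclose(w.sum(axis=0), 1.0, atol=1e-6)


# -- head parameterization ---------------------------------------------

def test_zero_weight_head_closed_form():
    model = LocalizerNet(LocalizerConfig(levels=2, base_channels=4, seed=0))
    for p in model.parameters():
        p.data[:] = 0.0
    x = np.random.default_rng(1).normal(size=(1, 1, 16, 16, 16)).astype(np.float32)
    centers, extents = model.forward_boxes(x)
    assert np.allclose(centers.data, 8.0)                    # sigmoid(0)·dim
    assert np.allclose(extents.data, np.log(2.0) + 1.0)      # softplus(0)+1


def test_head_range_contract(rng):
    model = LocalizerNet(LocalizerConfig(levels=2, base_channels=4, seed=3))
    x = rng.normal(size=(2, 1, 16, 16, 16)).astype(np.float32)
    centers, extents = model.forward_boxes(x)
    assert (extents.data >= 1.0).all()
    assert (centers.data >= 0).all() and (centers.data <= 16).all()


def test_predict_box_deterministic(small_phantom):
    model = LocalizerNet(LocalizerConfig(levels=3, base_channels=8, seed=4))
    b1 = model.predict_box(small_phantom.image)
    b2 = model.predict_box(small_phantom.image)
    assert b1.center == b2.center and b1.extent == b2.extent


def test_localization_head_decodes_from_fused_map():
    from mvtseg.localization import localization_head
    model = LocalizerNet(LocalizerConfig(levels=2, base_channels=4, seed=0))
    rng = np.random.default_rng(2)
    fused = FeatureMap(rng.normal(size=(4, 8, 8, 8)).astype(np.float32), level=1)
    box = localization_head(fused, model)
    assert all(1.0 <= e for e in box.extent)
    assert all(0.0 <= c <= 16.0 for c in box.center)
    # zero weights -> midpoint / softplus(0)+1 closed form
    for p in model.parameters():
        p.data[:] = 0.0
    box0 = localization_head(fused, model)
    assert box0.center == (8.0, 8.0, 8.0)
    assert np.allclose(box0.extent, np.log(2.0) + 1.0)
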