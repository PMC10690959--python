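"""MVT architecture contracts, loss closed forms, and small training runs."""

import numpy as np
import pandas as pd
import pytest

from mvtseg.errors import ConfigError
from mvtseg.phantoms import PhantomParams, generate_dataset
from mvtseg.segmenter import (MVTConfig, build_mvt, combined_loss, gce_loss,
                              gdl_loss, segment_case, train_segmenter)



def tiny_cfg(**kw):
    base = dict(in_shape=(16, 16, 8), enc_layers=2, enc_channels=(4, 8),
                se_size=3, token_dim=16, n_heads=2, n_tx_layers=1,
                mlp_ratio=2.0, seed=0)
    base.update(kw)
    return MVTConfig(**base)


# -- architecture -------------------------------------------------------

def test_output_shape_matches_input():
    model = build_mvt(tiny_cfg())
    x = np.random.default_rng(0).normal(size=(2, 1, 16, 16, 8)).astype(np.float32)
    p = model.forward(x)
    assert p.shape == (2, 3, 16, 16, 8)


def test_forward_finite_and_normalized_on_zero_input():
    model = build_mvt(tiny_cfg())
    p = model.forward(np.zeros((1, 1, 16, 16, 8), dtype=np.float32))
    assert np.all(np.isfinite(p.data))
    assert np.allclose(p.data.sum(axis=1), 1.0, atol=1e-5)


def test_ablation_has_fewer_parameters():
    with_m = build_mvt(tiny_cfg(use_morphology=True))
    without = build_mvt(tiny_cfg(use_morphology=False))
    assert without.n_parameters() < with_m.n_parameters()


def test_indivisible_shape_rejected():
    with pytest.raises(ConfigError):
        tiny_cfg(in_shape=(18, 16, 8))


def test_bad_loss_weights_rejected():
    with pytest.raises(ConfigError):
        tiny_cfg(loss_weights=(0.0, 0.0))


def test_forward_deterministic():
    x = np.random.default_rng(1).normal(size=(1, 1, 16, 16, 8)).astype(np.float32)
    p1 = build_mvt(tiny_cfg(seed=5)).forward(x)
    p2 = build_mvt(tiny_cfg(seed=5)).forward(x)
    assert np.array_equal(p1.data, p2.data)


# -- losses -------------------------------------------------------------

def hard_onehot(labels):
    oh = np.zeros((3,) + labels.shape, dtype=np.float32)
    for c in range(3):
        oh[c] = labels == c
    return oh


def test_gce_perfect_prediction_near_zero():
    t = hard_onehot(np.ones((4, 4, 4), dtype=int))
    assert gce_loss(t, t) <= 1e-6


def test_gce_uniform_prediction_ln3():
    t = hard_onehot(np.random.default_rng(0).integers(0, 3, (5, 5, 5)))
    p = np.full_like(t, 1 / 3)
    assert gce_loss(t, p) == pytest.approx(np.log(3.0), abs=1e-6)


def test_gce_single_voxel_half_confidence():
    t = np.zeros((3, 1, 1, 1), dtype=np.float32)
    t[1] = 1
    p = np.array([0.25, 0.5, 0.25], dtype=np.float32).reshape(3, 1, 1, 1)
    assert gce_loss(t, p) == pytest.approx(np.log(2.0), abs=1e-6)


def test_gdl_perfect_prediction():
    lab = np.zeros((6, 6, 6), dtype=int)
    lab[1:3, 1:3, 1:3] = 1
    lab[3:5, 1:3, 1:3] = 2
    t = hard_onehot(lab)
    assert gdl_loss(t, t) < 1e-6


def test_gdl_disjoint_prediction_is_one():
    truth_lab = np.zeros((8, 4, 4), dtype=int)
    truth_lab[:2, :2, :2] = 1
    pred_lab = np.zeros((8, 4, 4), dtype=int)
    pred_lab[4:6, :2, :2] = 1
    assert gdl_loss(hard_onehot(truth_lab), hard_onehot(pred_lab)) == pytest.approx(
        1.0, abs=1e-6)


def test_gdl_half_overlap_is_half():
    """Both foreground classes sized 2N with N overlapping voxels each."""
    truth_lab = np.zeros((8, 8, 2), dtype=int)
    pred_lab = np.zeros((8, 8, 2), dtype=int)
    truth_lab[0:4, 0, 0] = 1
    pred_lab[2:6, 0, 0] = 1
    truth_lab[0:4, 1, 0] = 2
    pred_lab[2:6, 1, 0] = 2
    assert gdl_loss(hard_onehot(truth_lab), hard_onehot(pred_lab)) == pytest.approx(
        0.5, abs=1e-6)


def test_gdl_bounded_unit_interval(rng):
    for _ in range(20):
        t = hard_onehot(rng.integers(0, 3, (5, 5, 5)))
        p = rng.random((3, 5, 5, 5)).astype(np.float32)
        p /= p.sum(axis=0, keepdims=True)
        assert 0.0 <= gdl_loss(t, p) <= 1.0


def test_losses_decrease_toward_truth(rng):
    """GCE and GDL both fall monotonically as the prediction is linearly
    interpolated from uniform toward the truth."""
    t = hard_onehot(rng.integers(0, 3, (6, 6, 6)))
    uniform = np.full_like(t, 1 / 3)
    gces, gdls = [], []
    for alpha in np.linspace(0, 1, 5):
        p = (1 - alpha) * uniform + alpha * t
        gces.append(gce_loss(t, p))
        gdls.append(gdl_loss(t, p))
    assert all(np.diff(gces) < 0)
    assert all(np.diff(gdls) < 0)


def test_combined_loss_weights():
    t = hard_onehot(np.random.default_rng(2).integers(0, 3, (4, 4, 4)))
    p = np.random.default_rng(3).random((3, 4, 4, 4)).astype(np.float32)
    p /= p.sum(axis=0, keepdims=True)
    only_gce = combined_loss(t, p, tiny_cfg(loss_weights=(1.0, 0.0)))
    only_gdl = combined_loss(t, p, tiny_cfg(loss_weights=(0.0, 1.0)))
    both = combined_loss(t, p, tiny_cfg(loss_weights=(1.0, 1.0)))
    assert only_gce == pytest.approx(gce_loss(t, p))
    assert only_gdl == pytest.approx(gdl_loss(t, p))
    assert both == pytest.approx(only_gce + only_gdl)
    assert combined_loss(t, t, tiny_cfg()) <= 2e-6


def test_loss_shape_mismatch_raises():
    t = hard_onehot(np.zeros((4, 4, 4), dtype=int))
    p = hard_onehot(np.zeros((4, 4, 5), dtype=int))
    with pytest.raises(ConfigError):
        gce_loss(t, p)
    with pytest.raises(ConfigError):
        gdl_loss(t, p)


# -- training -----------------------------------------------------------

@pytest.fixture(scope="module")
def mini_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("miniset")
    params = PhantomParams(volume_shape=(32, 32, 32), max_translation=2.0,
                           anterior_semiaxes_range=(5.0, 7.0),
                           posterior_semiaxes_range=(4.0, 6.0))
    return generate_dataset(6, params, 900, out)


def seg_train_cfg(**kw):
    base = dict(in_shape=(24, 24, 24), enc_layers=2, enc_channels=(4, 8),
                se_size=3, token_dim=24, n_heads=2, n_tx_layers=1,
                mlp_ratio=2.0, seed=1)
    base.update(kw)
    return MVTConfig(**base)


def test_training_reduces_loss(mini_dataset):
    _, hist = train_segmenter(mini_dataset, seg_train_cfg(), epochs=8,
                              lr=2e-3, batch=3, seed=5)
    assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
    assert np.isfinite(hist[["train_loss", "val_loss"]].to_numpy()).all()


def test_zero_lr_constant_history(mini_dataset):
    # full-batch so the batch-aggregated Dice term sees identical inputs
    _, hist = train_segmenter(mini_dataset, seg_train_cfg(), epochs=3,
                              lr=0.0, batch=8, seed=5, jitter=0)
    assert hist["train_loss"].std() < 1e-7


def test_training_deterministic(mini_dataset):
    _, h1 = train_segmenter(mini_dataset, seg_train_cfg(), epochs=3,
                            lr=2e-4, batch=3, seed=5)
    _, h2 = train_segmenter(mini_dataset, seg_train_cfg(), epochs=3,
                            lr=2e-4, batch=3, seed=5)
    pd.testing.assert_frame_equal(h1, h2)


def test_segment_case_contracts(mini_dataset, small_phantom):
    from mvtseg.localization import LocalizerConfig, LocalizerNet
    cfg = seg_train_cfg()
    seg_model, _ = train_segmenter(mini_dataset, cfg, epochs=1, lr=2e-4,
                                   batch=3, seed=5)
    loc = LocalizerNet(LocalizerConfig(levels=2, base_channels=4, seed=0))
    from mvtseg.volume_io import read_volume
    img = read_volume(mini_dataset.iloc[0]["image_path"])
    seg, probs = segment_case(img, loc, seg_model, cfg)
    assert seg.shape == img.shape
    assert set(np.unique(seg.data)) <= {0, 1, 2}
    assert probs.shape == (3,) + tuple(img.shape)
    assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-5)


def test_overfit_single_phantom_crop(small_phantom):
    """Sanity fit: ~300 gradient steps on one case reach near-perfect
    training DSC for both substructures."""
    import pandas as pd
    from mvtseg.localization import crop_to_box, derive_gt_box
    from mvtseg.volume_io import write_volume
    import tempfile, os
    from pathlib import Path
    out = Path(tempfile.mkdtemp(prefix="overfit"))
    write_volume(small_phantom.image, out / "img.nii.gz")
    write_volume(small_phantom.truth, out / "lab.nii.gz")
    b = small_phantom.gt_box
    mf = pd.DataFrame([{"case_id": "c", "image_path": str(out / "img.nii.gz"),
                        "label_path": str(out / "lab.nii.gz"),
                        "x_c": b.center[0], "y_c": b.center[1], "z_c": b.center[2],
                        "w_c": b.extent[0], "h_c": b.extent[1], "d_c": b.extent[2]}])
    cfg = MVTConfig(in_shape=(24, 24, 24), enc_layers=2, enc_channels=(4, 8),
                    se_size=3, token_dim=32, n_heads=2, n_tx_layers=1,
                    mlp_ratio=2.0, seed=3)
    model, hist = train_segmenter(mf, cfg, epochs=300, lr=2e-3, batch=1,
                                  seed=3, jitter=0)
    assert hist["train_loss"].iloc[-1] < 0.1 * hist["train_loss"].iloc[0]
    crop, _ = crop_to_box(small_phantom.truth, b, cfg.in_shape)
    img_norm = (small_phantom.image.data - small_phantom.image.data.min()) / (
        small_phantom.image.data.max() - small_phantom.image.data.min())
    from mvtseg.volume_io import Volume
    xcrop, _ = crop_to_box(Volume(img_norm.astype("float32")), b, cfg.in_shape)
    pred = np.argmax(model.forward(xcrop.data[None, None]).data[0], axis=0)
    for c in (1, 2):
        a_mask = crop.data == c
        b_mask = pred == c
        d = 2 * np.logical_and(a_mask, b_mask).sum() / (a_mask.sum() + b_mask.sum())
        assert d >= 0.95, f"class {c} training DSC {d:.3f}"
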