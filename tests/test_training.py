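"""Dice loss closed forms, patch sampling, and the optimisation loop."""

import numpy as np
import pytest

from pclseg.agnet import AGNetConfig
from pclseg.errors import ConfigurationError, ShapeError, SizeError
from pclseg.preprocess import PreprocessConfig
from pclseg.training import (TrainConfig, dice_loss, sample_patch_offsets,
                             sample_patches, train)

from conftest import make_study


def test_dice_loss_perfect_prediction_is_zero():
    labels = np.array([[[0, 1], [2, 1]]])
    probs = np.zeros((3,) + labels.shape)
    for c in range(3):
        probs[c][labels == c] = 1.0
    assert dice_loss(probs, labels, eps=1e-12) == pytest.approx(0.0, abs=1e-9)


def test_dice_loss_disjoint_prediction_is_one():
    labels = np.zeros((1, 2, 2), dtype=int)       # all class 0
    probs = np.zeros((2, 1, 2, 2))
    probs[1] = 1.0                                # all mass on class 1
    assert dice_loss(probs, labels, eps=1e-12) == pytest.approx(1.0, abs=1e-9)


def test_dice_loss_two_voxel_worked_example():
    """truth = [A, B], probs = [(1,0), (1,0)]:
    Dice_A = 2/3, Dice_B = 0, loss = 1 - 1/3 = 2/3."""
    labels = np.array([[[0]], [[1]]])             # 2 voxels
    probs = np.zeros((2, 2, 1, 1))
    probs[0] = 1.0
    assert dice_loss(probs, labels, eps=1e-12) == pytest.approx(2 / 3, abs=1e-6)


def test_dice_loss_invariant_under_class_permutation(rng):
    labels = rng.integers(0, 3, size=(5, 5, 2))
    probs = rng.dirichlet(np.ones(3), size=(5, 5, 2)).transpose(3, 0, 1, 2)
    perm = np.array([2, 0, 1])
    inv = np.argsort(perm)
    loss1 = dice_loss(probs, labels)
    loss2 = dice_loss(probs[perm], inv[labels])
    assert loss1 == pytest.approx(loss2, abs=1e-12)


def test_dice_loss_shape_mismatch():
    with pytest.raises(ShapeError):
        dice_loss(np.zeros((3, 4, 4, 4)), np.zeros((4, 4, 5), dtype=int))


def test_patch_offsets_span_valid_range_uniformly(rng):
    """240x240 crop, 160x160 patch: offsets live in 0..80 inclusive; the
    valid set is the exhaustive 81x81 enumeration."""
    valid = {(i, j) for i in range(81) for j in range(81)}
    offs = sample_patch_offsets((240, 240), (160, 160), 4000, rng)
    seen = {tuple(o) for o in offs.tolist()}
    assert seen <= valid
    assert offs.min() == 0 and offs.max() == 80
    # coarse uniformity: each third of the range gets a fair share per axis
    for ax in range(2):
        hist, _ = np.histogram(offs[:, ax], bins=3, range=(0, 81))
        assert hist.min() > 0.7 * 4000 / 3 and hist.max() < 1.3 * 4000 / 3


def test_patch_equals_volume_when_exact_size(rng):
    ct = rng.normal(size=(32, 32, 8)).astype(np.float32)
    lab = np.zeros_like(ct, dtype=np.int16)
    cfg = TrainConfig(patch_inplane=32, patch_depth=8, fg_bias=0.0)
    pairs = sample_patches(ct, lab, cfg, 3, seed=0)
    for x, y in pairs:
        assert np.array_equal(x, ct) and np.array_equal(y, lab)


def test_patch_sampling_reproducible_by_seed(rng):
    ct = rng.normal(size=(64, 64, 16)).astype(np.float32)
    lab = (ct > 1).astype(np.int16)
    cfg = TrainConfig(patch_inplane=32, patch_depth=8)
    a = sample_patches(ct, lab, cfg, 5, seed=7)
    b = sample_patches(ct, lab, cfg, 5, seed=7)
    for (xa, _), (xb, _) in zip(a, b):
        assert np.array_equal(xa, xb)


def test_patch_larger_than_volume_errors(rng):
    with pytest.raises(SizeError):
        sample_patch_offsets((16, 16, 4), (32, 32, 4), 1, rng)


def test_foreground_bias_hits_foreground(rng):
    ct = np.zeros((64, 64, 8), np.float32)
    lab = np.zeros_like(ct, dtype=np.int16)
    lab[50:53, 50:53, 3:5] = 2
    offs = sample_patch_offsets(ct.shape, (16, 16, 8), 50, rng,
                                labels=lab, fg_bias=1.0)
    for o in offs:
        window = lab[o[0]:o[0] + 16, o[1]:o[1] + 16, o[2]:o[2] + 8]
        assert (window > 0).any()


def _quick_cfg(**kw):
    base = dict(epochs=2, steps_per_epoch=2, batch_size=1, lr_initial=1e-3,
                patch_inplane=16, patch_depth=16, val_fraction=0.0, seed=0)
    base.update(kw)
    return TrainConfig(**base)


TINY = AGNetConfig(n_scales=2, base_channels=2)
PRE64 = PreprocessConfig(crop_size=64)


def test_history_length_equals_epochs_run():
    _, hist = train([make_study(seed=1)], TINY, _quick_cfg(), PRE64)
    assert len(hist) == 2
    assert {"epoch", "train_loss", "val_loss", "lr"} <= set(hist.epochs[0])


def test_empty_training_set_rejected():
    with pytest.raises(ConfigurationError):
        train([make_study(seed=1, split="test")], TINY, _quick_cfg(), PRE64)


def test_training_is_reproducible():
    study = make_study(seed=2)
    _, h1 = train([study], TINY, _quick_cfg(), PRE64)
    _, h2 = train([study], TINY, _quick_cfg(), PRE64)
    assert [e["train_loss"] for e in h1.epochs] == [e["train_loss"] for e in h2.epochs]


def test_plateau_scheduler_reduces_lr():
    """With patience 2 and a tiny frozen problem the lr must drop below the
    initial rate and never below the floor."""
    cfg = _quick_cfg(epochs=12, plateau_patience=2, lr_initial=1e-10,
                     lr_floor=1e-13)
    # lr so small the loss cannot improve => plateau fires
    _, hist = train([make_study(seed=3)], TINY, cfg, PRE64)
    lrs = [e["lr"] for e in hist.epochs]
    assert lrs[-1] < cfg.lr_initial
    assert min(lrs) >= cfg.lr_floor


def test_2d_per_slice_mode_trains():
    """The 2D network consumes single-slice patches end to end."""
    cfg = _quick_cfg(patch_inplane=16, batch_size=2)
    net2d = AGNetConfig(n_scales=2, base_channels=2, spatial_dims=2)
    _, hist = train([make_study(seed=6)], net2d, cfg, PRE64)
    assert len(hist) == 2
    assert np.isfinite([e["train_loss"] for e in hist.epochs]).all()


def test_loss_decreases_on_small_overfit():
    """A few dozen steps on one study must clearly reduce the Dice loss."""
    cfg = TrainConfig(epochs=5, steps_per_epoch=8, batch_size=2,
                      lr_initial=5e-3, patch_inplane=32, patch_depth=32,
                      val_fraction=0.0, seed=0)
    _, hist = train([make_study(seed=4, n_cysts=2)],
                    AGNetConfig(n_scales=2, base_channels=4), cfg, PRE64)
    first, last = hist.epochs[0]["train_loss"], hist.epochs[-1]["train_loss"]
    assert last < first - 0.1
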