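"""Patch sampling, multiclass soft-Dice loss and the optimisation loop.

Training follows the reference recipe: Adam from an initial learning rate of
1e-4, Kaiming weight initialisation, batches of 4 random in-plane patches of
160x160 drawn from the centrally cropped, soft-tissue-normalized volumes, and
the complement of the multiclass Dice coefficient as the loss.  The learning
rate is reduced by a factor of 10 whenever the validation loss has not
improved for ``plateau_patience`` epochs and never drops below ``lr_floor``.
Patches are 3D slabs of ``patch_inplane^2 x patch_depth`` by default; a 2D
per-slice mode is available for 2D networks.  Because cysts occupy a tiny
fraction of a volume, patch sampling optionally forces a foreground (pancreas
or cyst) voxel into the patch with probability ``fg_bias``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import nn
from .agnet import AGNet, AGNetConfig
from .errors import ConfigurationError, ShapeError, SizeError
from .phantom import StudyRecord
from .preprocess import PreprocessConfig, central_crop, soft_tissue_normalize

__all__ = ["TrainConfig", "TrainHistory", "dice_loss", "sample_patch_offsets",
           "sample_patches", "train"]


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    epochs: int = Field(default=700, gt=0)
    steps_per_epoch: int = Field(default=10, gt=0)
    batch_size: int = Field(default=4, gt=0)
    lr_initial: float = Field(default=1e-4, gt=0)
    lr_factor: float = Field(default=0.1, gt=0, lt=1)
    plateau_patience: int = Field(default=30, gt=0)
    lr_floor: float = Field(default=1e-6, gt=0)
    patch_inplane: int = Field(default=160, gt=0)
    patch_depth: int = Field(default=16, gt=0)   # ignored by 2D networks
    fg_bias: float = Field(default=0.5, ge=0, le=1)
    val_fraction: float = Field(default=0.1, ge=0, lt=1)
    include_background: bool = True
    dice_eps: float = Field(default=1e-5, gt=0)
    seed: int = 0

    def model_post_init(self, _ctx) -> None:
        if self.lr_floor >= self.lr_initial:
            raise ValueError("lr_floor must be below lr_initial")


@dataclass
class TrainHistory:
    """Per-epoch loss and learning-rate trace."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.epochs.append(row)

    def __len__(self) -> int:
        return len(self.epochs)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out


def dice_loss(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-5,
              include_background: bool = True) -> float:
    """1 - mean over classes of soft Dice between probabilities and labels.

    ``probs``: (K, *S) class probabilities; ``labels``: (*S) integers in
    [0, K).  The epsilon stabilises empty classes; with eps -> 0 a perfect
    one-hot match gives 0 and fully disjoint one-hot predictions give 1.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.shape[1:] != labels.shape:
        raise ShapeError(
            f"probs spatial shape {probs.shape[1:]} != labels {labels.shape}")
    k = probs.shape[0]
    y = _one_hot(labels, k)
    axes = tuple(range(1, probs.ndim))
    inter = (probs * y).sum(axis=axes)
    dice = (2 * inter + eps) / (probs.sum(axis=axes) + y.sum(axis=axes) + eps)
    sel = slice(None) if include_background else slice(1, None)
    return float(1.0 - dice[sel].mean())


def sample_patch_offsets(shape: tuple[int, ...], patch: tuple[int, ...],
                         n: int, rng: np.random.Generator,
                         labels: np.ndarray | None = None,
                         fg_bias: float = 0.0) -> np.ndarray:
    """Uniform in-bounds patch corner offsets, optionally foreground-biased.

    A biased draw picks a random foreground voxel and a patch corner uniform
    over the offsets whose window contains it.
    """
    if any(p > s for p, s in zip(patch, shape)):
        raise SizeError(f"volume {shape} smaller than patch {patch}")
    hi = [s - p for s, p in zip(shape, patch)]
    fg = None
    if fg_bias > 0 and labels is not None:
        fg = np.argwhere(labels > 0)
        if fg.size == 0:
            fg = None
    out = np.empty((n, len(shape)), dtype=np.intp)
    for i in range(n):
        if fg is not None and rng.random() < fg_bias:
            v = fg[rng.integers(len(fg))]
            lo_c = np.maximum(0, v - np.asarray(patch) + 1)
            hi_c = np.minimum(hi, v)
            out[i] = [rng.integers(a, b + 1) for a, b in zip(lo_c, hi_c)]
        else:
            out[i] = [rng.integers(0, h + 1) for h in hi]
    return out


def sample_patches(ct: np.ndarray, labels: np.ndarray, cfg: TrainConfig,
                   n: int, seed: int | None = None,
                   spatial_dims: int = 3) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``n`` random training patches from one (normalized) volume."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if spatial_dims == 3:
        patch = (cfg.patch_inplane, cfg.patch_inplane,
                 min(cfg.patch_depth, ct.shape[2]))
    else:
        patch = (cfg.patch_inplane, cfg.patch_inplane, 1)
    offs = sample_patch_offsets(ct.shape, patch, n, rng,
                                labels=labels, fg_bias=cfg.fg_bias)
    pairs = []
    for o in offs:
        sl = tuple(slice(int(a), int(a + p)) for a, p in zip(o, patch))
        pairs.append((ct[sl], labels[sl]))
    return pairs


def _prepare_study(rec: StudyRecord, pre_cfg: PreprocessConfig):
    ct = central_crop(soft_tissue_normalize(rec.ct, pre_cfg), pre_cfg)
    lab = central_crop(rec.labels.voxels, pre_cfg)
    return ct, lab


class _PlateauScheduler:
    """Reduce-on-plateau: lr *= factor after `patience` epochs w/o improvement."""

    def __init__(self, lr, factor, patience, floor):
        self.lr, self.factor, self.patience, self.floor = lr, factor, patience, floor
        self.best = np.inf
        self.bad = 0

    def update(self, loss: float) -> float:
        if loss < self.best - 1e-9:
            self.best = loss
            self.bad = 0
        else:
            self.bad += 1
            if self.bad >= self.patience:
                self.lr = max(self.lr * self.factor, self.floor)
                self.bad = 0
        return self.lr


def train(cohort: list[StudyRecord], agnet_cfg: AGNetConfig,
          train_cfg: TrainConfig,
          preprocess_cfg: PreprocessConfig | None = None,
          model: AGNet | None = None) -> tuple[AGNet, TrainHistory]:
    """Train an attention-gate U-Net on the cohort's training split.

    Volumes are normalized and centrally cropped; each optimisation step draws
    ``batch_size`` random patches from randomly chosen training studies.  A
    held-out fraction of the training studies drives the plateau scheduler
    (falling back to the training loss when too few studies exist).  Fully
    deterministic given (cohort, configs, seed).
    """
    pre_cfg = preprocess_cfg or PreprocessConfig()
    studies = [r for r in cohort if r.split == "train"]
    if not studies:
        raise ConfigurationError("cohort has no studies with split='train'")

    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 0x7A]))
    n_val = int(np.floor(train_cfg.val_fraction * len(studies)))
    order = rng.permutation(len(studies))
    val_idx = set(order[:n_val].tolist())
    train_data = [_prepare_study(studies[i], pre_cfg)
                  for i in range(len(studies)) if i not in val_idx]
    val_data = [_prepare_study(studies[i], pre_cfg) for i in sorted(val_idx)]

    model = model or AGNet(agnet_cfg, seed=train_cfg.seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.lr_initial)
    sched = _PlateauScheduler(train_cfg.lr_initial, train_cfg.lr_factor,
                              train_cfg.plateau_patience, train_cfg.lr_floor)
    history = TrainHistory()

    def _batch(data, rand):
        xs, ys = [], []
        for _ in range(train_cfg.batch_size):
            ct, lab = data[rand.integers(len(data))]
            (x, y), = sample_patches(ct, lab, train_cfg, 1,
                                     seed=int(rand.integers(2 ** 31)),
                                     spatial_dims=agnet_cfg.spatial_dims)
            if agnet_cfg.spatial_dims == 2:
                x, y = x[..., 0], y[..., 0]
            xs.append(x)
            ys.append(y)
        x = np.asarray(xs, dtype=np.float32)[:, None]
        y = np.stack([_one_hot(l, agnet_cfg.n_classes) for l in ys])
        return x, y

    for epoch in range(train_cfg.epochs):
        losses = []
        for _ in range(train_cfg.steps_per_epoch):
            x, y = _batch(train_data, rng)
            opt.zero_grad()
            loss = nn.softmax_dice_loss(
                model.forward(x), y, eps=train_cfg.dice_eps,
                include_background=train_cfg.include_background)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        train_loss = float(np.mean(losses))

        if val_data:
            vrng = np.random.default_rng(
                np.random.SeedSequence([train_cfg.seed, 0x5B, epoch]))
            vx, vy = _batch(val_data, vrng)
            vloss = nn.softmax_dice_loss(
                model.forward(vx), vy, eps=train_cfg.dice_eps,
                include_background=train_cfg.include_background).item()
        else:
            vloss = train_loss
        opt.lr = sched.update(vloss)
        history.append(epoch=epoch, train_loss=train_loss,
                       val_loss=float(vloss), lr=float(opt.lr))
    return model, history
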