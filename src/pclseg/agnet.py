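"""Attention-gate U-Net ("AGNet") for multiclass abdominal CT segmentation.

The network is a standard U-Net encoder/decoder: each encoder scale applies two
3x3(x3) convolutions with ReLU and halves the spatial grid with factor-2
max-pooling; each decoder scale upsamples linearly (trilinear in 3D, bilinear
in 2D) by factor 2 and receives the corresponding encoder feature map through
an additive attention gate before concatenation.  The gate computes

    alpha = sigmoid( psi( relu( W_x * x  +  W_g * g  +  b ) ) )

from the skip features ``x`` and a gating signal ``g`` taken from the previous
(coarser) decoding stage, resampled to ``x``'s grid; the gated skip is the
element-wise product ``alpha * x``.  With ``multidim_attention`` the psi
projection produces one attention map per class; they are averaged into a
single per-voxel coefficient before multiplying, so the gated output always
keeps the shape of ``x``.
"""

from __future__ import annotations

import json

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import nn
from .errors import ShapeError

__all__ = ["AGNetConfig", "AttentionGate", "AGNet", "attention_gate"]


class AGNetConfig(BaseModel):
    """Architecture hyperparameters.

    ``n_scales`` counts resolution levels including the bottleneck; channel
    width doubles at each scale starting from ``base_channels``.
    """

    model_config = ConfigDict(extra="forbid")

    n_classes: int = Field(default=3, ge=2)
    n_scales: int = Field(default=4, ge=2)
    base_channels: int = Field(default=16, ge=1)
    spatial_dims: int = Field(default=3)
    multidim_attention: bool = True

    def model_post_init(self, _ctx) -> None:
        if self.spatial_dims not in (2, 3):
            raise ValueError("spatial_dims must be 2 or 3")


class AttentionGate:
    """Additive attention gate between a skip connection and a gating signal."""

    def __init__(self, rng: np.random.Generator, c_x: int, c_g: int,
                 c_int: int, n_att: int, dims: int):
        self.dims = dims
        self.n_att = n_att
        self.w_x = nn.Tensor(nn.kaiming_normal(rng, (c_int, c_x) + (1,) * dims, c_x),
                             requires_grad=True)
        self.w_g = nn.Tensor(nn.kaiming_normal(rng, (c_int, c_g) + (1,) * dims, c_g),
                             requires_grad=True)
        self.b = nn.Tensor(np.zeros(c_int, dtype=np.float32), requires_grad=True)
        self.psi = nn.Tensor(nn.kaiming_normal(rng, (n_att, c_int) + (1,) * dims, c_int),
                             requires_grad=True)
        self.psi_b = nn.Tensor(np.zeros(n_att, dtype=np.float32), requires_grad=True)

    def parameters(self) -> list[nn.Tensor]:
        return [self.w_x, self.w_g, self.b, self.psi, self.psi_b]

    def coefficients(self, x: nn.Tensor, g: nn.Tensor) -> nn.Tensor:
        """Attention coefficients alpha in [0, 1] on x's grid."""
        if x.data.shape[2:] != g.data.shape[2:]:
            raise ShapeError(
                f"attention gate needs x and g on a common grid, got "
                f"{x.data.shape[2:]} vs {g.data.shape[2:]}")
        s = nn.relu(nn.add_bias(nn.add(nn.convnd(x, self.w_x),
                                       nn.convnd(g, self.w_g)), self.b))
        return nn.sigmoid(nn.add_bias(nn.convnd(s, self.psi), self.psi_b))

    def __call__(self, x: nn.Tensor, g: nn.Tensor) -> nn.Tensor:
        alpha = self.coefficients(x, g)
        if alpha.data.shape[1] > 1:
            alpha = nn.channel_mean(alpha)
        return nn.mul(x, alpha)


def attention_gate(x, g, gate: AttentionGate) -> np.ndarray:
    """Functional wrapper: gate plain arrays (B, C, *S) and return an array."""
    return gate(nn.Tensor(x), nn.Tensor(g)).data


class _DoubleConv:
    """Two 3x3(x3) convolutions, each followed by instance norm and ReLU."""

    def __init__(self, rng, c_in, c_out, dims):
        self.c1 = nn.Conv(rng, c_in, c_out, 3, dims)
        self.c2 = nn.Conv(rng, c_out, c_out, 3, dims)
        self.g1 = nn.Tensor(np.ones(c_out, np.float32), requires_grad=True)
        self.b1 = nn.Tensor(np.zeros(c_out, np.float32), requires_grad=True)
        self.g2 = nn.Tensor(np.ones(c_out, np.float32), requires_grad=True)
        self.b2 = nn.Tensor(np.zeros(c_out, np.float32), requires_grad=True)

    def __call__(self, x):
        h = nn.relu(nn.instance_norm(self.c1(x), self.g1, self.b1))
        return nn.relu(nn.instance_norm(self.c2(h), self.g2, self.b2))

    def parameters(self):
        return (self.c1.parameters() + self.c2.parameters()
                + [self.g1, self.b1, self.g2, self.b2])


class AGNet:
    """The full encoder/decoder with attention-gated skip connections."""

    def __init__(self, cfg: AGNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA6]))
        d = cfg.spatial_dims
        ch = [cfg.base_channels * 2 ** i for i in range(cfg.n_scales)]
        n_att = cfg.n_classes if cfg.multidim_attention else 1

        self.encoders = [_DoubleConv(rng, 1 if i == 0 else ch[i - 1], ch[i], d)
                         for i in range(cfg.n_scales)]
        self.gates = [AttentionGate(rng, c_x=ch[i], c_g=ch[i + 1],
                                    c_int=max(ch[i] // 2, 1), n_att=n_att, dims=d)
                      for i in range(cfg.n_scales - 1)]
        self.decoders = [_DoubleConv(rng, ch[i] + ch[i + 1], ch[i], d)
                         for i in range(cfg.n_scales - 1)]
        self.head = nn.Conv(rng, ch[0], cfg.n_classes, 1, d)

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[nn.Tensor]:
        ps: list[nn.Tensor] = []
        for block in (*self.encoders, *self.gates, *self.decoders, self.head):
            ps.extend(block.parameters())
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward ------------------------------------------------------------

    def _check_patch(self, spatial: tuple[int, ...]) -> None:
        div = 2 ** (self.cfg.n_scales - 1)
        if len(spatial) != self.cfg.spatial_dims:
            raise ShapeError(
                f"expected {self.cfg.spatial_dims} spatial axes, got {spatial}")
        if any(s % div for s in spatial):
            raise ShapeError(
                f"patch spatial sizes {spatial} must be divisible by "
                f"2**(n_scales-1) = {div}")

    def forward(self, x, zero_skips: bool = False) -> nn.Tensor:
        """Logits (B, n_classes, *S) for a batch of normalized patches.

        ``zero_skips`` is a diagnostic switch that replaces every gated skip
        with zeros, exposing the bottleneck-only signal path.
        """
        x = x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, np.float32))
        self._check_patch(x.data.shape[2:])
        skips = []
        h = x
        for i, enc in enumerate(self.encoders):
            if i > 0:
                h = nn.maxpool2(h)
            h = enc(h)
            skips.append(h)
        d = skips[-1]
        for i in range(self.cfg.n_scales - 2, -1, -1):
            g = nn.upsample_linear2(d)
            if zero_skips:
                gated = nn.Tensor(np.zeros_like(skips[i].data))
            else:
                gated = self.gates[i](skips[i], g)
            d = self.decoders[i](nn.concat([gated, g], axis=1))
        return self.head(d)

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        """Inference entry point: one patch (*S) -> logits (n_classes, *S).

        3D patches of depth 1 are accepted by 2D networks (the slice axis is
        squeezed and restored), so the sliding-window driver can treat both
        modes uniformly.
        """
        patch = np.asarray(patch, dtype=np.float32)
        squeeze = (self.cfg.spatial_dims == 2 and patch.ndim == 3
                   and patch.shape[2] == 1)
        if squeeze:
            patch = patch[:, :, 0]
        logits = self.forward(patch[None, None]).data[0]
        return logits[..., None] if squeeze else logits

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, __config__=np.frombuffer(
            json.dumps(self.cfg.model_dump()).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "AGNet":
        with np.load(path) as z:
            cfg = AGNetConfig(**json.loads(bytes(z["__config__"]).decode()))
            model = cls(cfg, seed=0)
            for i, p in enumerate(model.parameters()):
                arr = z[f"p{i}"]
                if arr.shape != p.data.shape:
                    raise ShapeError(
                        f"checkpoint parameter {i} has shape {arr.shape}, "
                        f"expected {p.data.shape}")
                p.data = arr
        return model
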