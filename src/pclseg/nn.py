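"""Minimal reverse-mode automatic differentiation and neural-network layers.

The segmentation network in this package is small (a test-scale encoder/decoder
with attention gates), so instead of depending on a deep-learning framework it
runs on a compact tape-based autodiff engine over numpy arrays.  The engine
supports exactly the operations the network needs: N-dimensional convolution
(stride 1, "same" padding), factor-2 max-pooling, factor-2 linear upsampling
(bilinear/trilinear), ReLU, sigmoid, channel concatenation, broadcast
multiplication, and a fused softmax + multiclass soft-Dice loss.  Every
vector-Jacobian product is checked against central finite differences in the
test suite.

Array convention: activations are ``(batch, channels, *spatial)`` with 2 or 3
spatial axes.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from .errors import ShapeError

__all__ = [
    "Tensor",
    "add",
    "add_bias",
    "channel_mean",
    "concat",
    "convnd",
    "maxpool2",
    "mul",
    "relu",
    "sigmoid",
    "softmax",
    "softmax_dice_loss",
    "upsample_linear2",
    "Conv",
    "Adam",
    "kaiming_normal",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, _parents=(), _vjp=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` into every upstream tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graph depth grows with network depth
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: Sequence[Tensor], vjp: Callable) -> Tensor:
    requires = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=requires, _parents=tuple(parents),
                  _vjp=vjp if requires else None)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def vjp(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _node(out, (a, b), vjp)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def vjp(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return _node(out, (a, b), vjp)


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def vjp(g):
        return (g * mask,)

    return _node(np.where(mask, a.data, 0), (a,), vjp)


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    # overflow-free evaluation on both tails
    pos = a.data >= 0
    e = np.exp(np.where(pos, -a.data, a.data))
    out = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e))

    def vjp(g):
        return (g * out * (1.0 - out),)

    return _node(out, (a,), vjp)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def vjp(g):
        return tuple(np.split(g, np.cumsum(sizes)[:-1], axis=axis))

    return _node(out, tensors, vjp)


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    """Add a per-channel bias ``b`` of shape (C,) to ``x`` of shape (B, C, *S)."""
    x, b = _as_tensor(x), _as_tensor(b)
    shape = (1, -1) + (1,) * (x.data.ndim - 2)
    out = x.data + b.data.reshape(shape)

    def vjp(g):
        axes = (0,) + tuple(range(2, g.ndim))
        return g, g.sum(axis=axes)

    return _node(out, (x, b), vjp)


def channel_mean(x: Tensor) -> Tensor:
    """Mean over the channel axis, keeping it with size 1."""
    x = _as_tensor(x)
    n = x.data.shape[1]
    out = x.data.mean(axis=1, keepdims=True)

    def vjp(g):
        return (np.broadcast_to(g / n, x.data.shape).copy(),)

    return _node(out, (x,), vjp)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _offset_slices(kernel: tuple[int, ...], spatial: tuple[int, ...]):
    for offs in np.ndindex(*kernel):
        yield (slice(None),) + tuple(slice(o, o + s)
                                     for o, s in zip(offs, spatial)) + (slice(None),)


def _conv_cl(al: np.ndarray, wmats: list[np.ndarray],
             kernel: tuple[int, ...]) -> np.ndarray:
    """Channels-last stride-1 "same" correlation.

    ``al``: (B, *S, Ca); ``wmats``: one (Ca, Cb) matrix per kernel offset in
    C-order.  Accumulating one broadcast matmul per offset avoids the
    cache-hostile im2col gather entirely.
    """
    spatial = al.shape[1:-1]
    pad = [(0, 0)] + [(k // 2, k // 2) for k in kernel] + [(0, 0)]
    ap = np.pad(al, pad)
    out = np.zeros(al.shape[:-1] + (wmats[0].shape[1],), dtype=al.dtype)
    for sl, wk in zip(_offset_slices(kernel, spatial), wmats):
        out += ap[sl] @ wk
    return out


def convnd(x: Tensor, w: Tensor) -> Tensor:
    """Stride-1, zero-padded ("same") convolution in 2 or 3 spatial dims.

    ``x``: (B, Cin, *S); ``w``: (Cout, Cin, *K) with odd kernel sizes.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    kernel = tuple(w.data.shape[2:])
    d = len(kernel)
    if x.data.ndim != d + 2 or x.data.shape[1] != w.data.shape[1]:
        raise ShapeError(
            f"conv expects input (B, {w.data.shape[1]}, *S) with {d} spatial "
            f"axes, got shape {x.data.shape}")
    spatial = x.data.shape[2:]
    xl = np.ascontiguousarray(np.moveaxis(x.data, 1, -1))
    wflat = w.data.reshape(w.data.shape[0], w.data.shape[1], -1)
    fwd_mats = [np.ascontiguousarray(wflat[:, :, j].T)
                for j in range(wflat.shape[2])]
    out = np.moveaxis(_conv_cl(xl, fwd_mats, kernel), -1, 1)

    def vjp(g):
        gl = np.ascontiguousarray(np.moveaxis(g, 1, -1), dtype=xl.dtype)
        # input gradient of a zero-padded correlation = correlation of the
        # output gradient with the spatially flipped, channel-swapped kernel
        flip = np.flip(w.data, axis=tuple(range(2, w.data.ndim)))
        bwd_mats = [np.ascontiguousarray(m)
                    for m in flip.reshape(flip.shape[0], flip.shape[1], -1)
                    .transpose(2, 0, 1)]
        gx = np.moveaxis(_conv_cl(gl, bwd_mats, kernel), -1, 1)
        # weight gradient: per-offset (Cout, Cin) = g^T . shifted-input
        pad = [(0, 0)] + [(k // 2, k // 2) for k in kernel] + [(0, 0)]
        xpl = np.pad(xl, pad)
        gmat = gl.reshape(-1, gl.shape[-1])
        gw = np.empty_like(wflat)
        for j, sl in enumerate(_offset_slices(kernel, spatial)):
            xs = np.ascontiguousarray(xpl[sl]).reshape(-1, xl.shape[-1])
            gw[:, :, j] = gmat.T @ xs
        return gx, gw.reshape(w.data.shape)

    return _node(out, (x, w), vjp)


# ---------------------------------------------------------------------------
# pooling and upsampling
# ---------------------------------------------------------------------------

def maxpool2(x: Tensor) -> Tensor:
    """Factor-2 max pooling over every spatial axis (sizes must be even).

    Gradient of tied maxima is split evenly between the tied entries.
    """
    x = _as_tensor(x)
    spatial = x.data.shape[2:]
    if any(s % 2 for s in spatial):
        raise ShapeError(f"maxpool2 needs even spatial sizes, got {spatial}")
    d = len(spatial)
    blocked = (x.data.shape[:2]
               + tuple(v for s in spatial for v in (s // 2, 2)))
    axes = tuple(3 + 2 * i for i in range(d))
    r = x.data.reshape(blocked)
    out = r.max(axis=axes)

    def _upsample_nearest(a):
        for i in range(d):
            a = np.repeat(a, 2, axis=2 + i)
        return a

    def vjp(g):
        mask = (x.data == _upsample_nearest(out))
        counts = mask.reshape(blocked).sum(axis=axes)
        gx = _upsample_nearest(g / counts) * mask
        return (gx,)

    return _node(out, (x,), vjp)


def _up2_axis(a: np.ndarray, ax: int) -> np.ndarray:
    """Factor-2 linear upsampling along one axis (centres aligned: output
    voxel j samples source coordinate (j + 0.5)/2 - 0.5, clamped at edges),
    written as even/odd slice arithmetic."""
    am = np.moveaxis(a, ax, 0)
    n = am.shape[0]
    out = np.empty((2 * n,) + am.shape[1:], dtype=a.dtype)
    if n == 1:
        out[:] = am[0]
    else:
        out[0] = am[0]
        out[2::2] = 0.25 * am[:-1] + 0.75 * am[1:]
        out[1:-1:2] = 0.75 * am[:-1] + 0.25 * am[1:]
        out[-1] = am[-1]
    return np.moveaxis(out, 0, ax)


def _down2_axis(g: np.ndarray, ax: int) -> np.ndarray:
    """Adjoint of :func:`_up2_axis` along one axis."""
    gm = np.moveaxis(g, ax, 0)
    n = gm.shape[0] // 2
    ge, go = gm[0::2], gm[1::2]
    gx = np.zeros((n,) + gm.shape[1:], dtype=g.dtype)
    if n == 1:
        gx[0] = ge[0] + go[0]
    else:
        gx[0] = ge[0]
        gx[:-1] += 0.25 * ge[1:] + 0.75 * go[:-1]
        gx[1:] += 0.75 * ge[1:] + 0.25 * go[:-1]
        gx[-1] += go[-1]
    return np.moveaxis(gx, 0, ax)


def upsample_linear2(x: Tensor) -> Tensor:
    """Factor-2 linear (bilinear/trilinear) upsampling of every spatial axis."""
    x = _as_tensor(x)
    d = x.data.ndim - 2
    out = x.data
    for ax in range(2, 2 + d):
        out = _up2_axis(out, ax)

    def vjp(g):
        for ax in reversed(range(2, 2 + d)):
            g = _down2_axis(g, ax)
        return (g,)

    return _node(out, (x,), vjp)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Instance normalization: per-sample, per-channel standardisation over
    the spatial axes, followed by a learnable affine (gamma, beta)."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = tuple(range(2, x.data.ndim))
    n = int(np.prod(x.data.shape[2:]))
    mean = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    shape = (1, -1) + (1,) * (x.data.ndim - 2)
    out = xhat * gamma.data.reshape(shape) + beta.data.reshape(shape)

    def vjp(g):
        gsum_axes = (0,) + axes
        ggamma = (g * xhat).sum(axis=gsum_axes)
        gbeta = g.sum(axis=gsum_axes)
        gxhat = g * gamma.data.reshape(shape)
        gx = (inv / n) * (n * gxhat
                          - gxhat.sum(axis=axes, keepdims=True)
                          - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True))
        return gx, ggamma, gbeta

    return _node(out, (x, gamma, beta), vjp)


# ---------------------------------------------------------------------------
# softmax and the fused Dice loss
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = 0) -> np.ndarray:
    """Numerically stable softmax on a plain array (inference-time helper)."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_dice_loss(logits: Tensor, onehot: np.ndarray, eps: float = 1e-5,
                      include_background: bool = True) -> Tensor:
    """``1 - mean_c softDice_c`` of softmax(logits) against one-hot labels.

    ``logits``: (B, K, *S); ``onehot``: same shape, {0,1}.  Per-class Dice is
    pooled over the whole batch.  The gradient through both the Dice ratio and
    the softmax is provided analytically.
    """
    logits = _as_tensor(logits)
    z = logits.data.astype(np.float64)   # keep softmax gradients alive
    y = np.asarray(onehot)
    if y.shape != z.shape:
        raise ShapeError(f"one-hot labels {y.shape} do not match logits {z.shape}")
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    p = e / e.sum(axis=1, keepdims=True)
    axes = (0,) + tuple(range(2, z.ndim))
    inter = (p * y).sum(axis=axes)
    psum = p.sum(axis=axes)
    ysum = y.sum(axis=axes)
    dice = (2.0 * inter + eps) / (psum + ysum + eps)
    sel = np.ones(z.shape[1], dtype=bool)
    if not include_background:
        sel[0] = False
    loss = 1.0 - dice[sel].mean()

    def vjp(g):
        k = sel.sum()
        denom = (psum + ysum + eps)
        # d(loss)/d(dice_c) = -1/k for selected classes
        gdice = np.where(sel, -1.0 / k, 0.0)
        shape = (1, -1) + (1,) * (z.ndim - 2)
        gp = gdice.reshape(shape) * (
            2.0 * y * denom.reshape(shape) - (2.0 * inter + eps).reshape(shape)
        ) / (denom ** 2).reshape(shape)
        gz = p * (gp - (gp * p).sum(axis=1, keepdims=True))
        return ((g * gz).astype(logits.data.dtype),)

    return _node(np.asarray(loss), (logits,), vjp)


# ---------------------------------------------------------------------------
# layers and optimisation
# ---------------------------------------------------------------------------

def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, dtype=np.float32) -> np.ndarray:
    """He/Kaiming normal initialisation: std = sqrt(2 / fan_in)."""
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Conv:
    """Convolution layer (stride 1, same padding) with per-channel bias."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel: int, dims: int, dtype=np.float32):
        fan_in = c_in * kernel ** dims
        self.w = Tensor(kaiming_normal(rng, (c_out, c_in) + (kernel,) * dims,
                                       fan_in, dtype), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add_bias(convnd(x, self.w), self.b)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]


class Adam:
    """Adam optimiser (Kingma & Ba) over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
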