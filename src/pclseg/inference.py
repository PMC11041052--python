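"""Whole-volume inference: sliding patches, test-time augmentation, merging.

Inference iterates 160x160 patches over the central crop, averaging logits
where patches overlap.  Test-time augmentation (TTA) runs four extra passes on
geometrically transformed copies of the volume — in-plane rotations of +7 and
-11 degrees and in-plane translations of +5 and +10 voxels — inverse-transforms
the per-class outputs back to the original grid, and averages them with the
untransformed pass.  Per-class scores are averaged *before* the softmax that
produces the final probabilities; the label map is the per-voxel argmax.
Voxels that re-enter the field of view from outside after the inverse
transform are tracked with a validity mask and excluded from the average for
that pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, SizeError
from .nn import softmax

__all__ = ["TTATransform", "default_tta", "sliding_window_infer", "tta_predict"]

_VALID_KINDS = ("rotation", "translation")


@dataclass(frozen=True)
class TTATransform:
    """An invertible in-plane geometric transform.

    ``magnitude`` is degrees (counter-clockwise) for rotations about the
    in-plane centre, or voxels along the first in-plane axis for translations.
    """

    kind: str
    magnitude: float

    def __post_init__(self):
        if self.kind not in _VALID_KINDS:
            raise ConfigurationError(
                f"transform kind {self.kind!r} has no exact inverse here; "
                f"expected one of {_VALID_KINDS}")

    def _move(self, volume, magnitude, cval, order):
        volume = np.asarray(volume, dtype=np.float32)
        if self.kind == "rotation":
            return ndimage.rotate(volume, magnitude, axes=(0, 1),
                                  reshape=False, order=order,
                                  mode="constant", cval=cval)
        shift = (magnitude,) + (0,) * (volume.ndim - 1)
        return ndimage.shift(volume, shift, order=order,
                             mode="constant", cval=cval)

    def apply(self, volume, cval: float = 0.0, order: int = 1) -> np.ndarray:
        return self._move(volume, self.magnitude, cval, order)

    def invert(self, volume, cval: float = 0.0, order: int = 1) -> np.ndarray:
        return self._move(volume, -self.magnitude, cval, order)


def default_tta() -> list[TTATransform]:
    """The standard 4-transform TTA set: rotate +7deg / -11deg, translate +5 / +10."""
    return [TTATransform("rotation", 7.0), TTATransform("rotation", -11.0),
            TTATransform("translation", 5.0), TTATransform("translation", 10.0)]


def _axis_offsets(size: int, patch: int, stride: int) -> list[int]:
    offs = list(range(0, size - patch + 1, stride))
    if offs[-1] != size - patch:
        offs.append(size - patch)   # flush final window against the edge
    return offs


def sliding_window_infer(model, volume: np.ndarray,
                         patch_size, stride=None) -> np.ndarray:
    """Tile the volume with patches and average logits where they overlap.

    ``model`` maps a patch (*patch_size) to logits (n_classes, *patch_size).
    Every voxel is covered by at least one patch (the last window along each
    axis is flushed to the boundary).
    """
    volume = np.asarray(volume, dtype=np.float32)
    patch = tuple(np.broadcast_to(patch_size, (volume.ndim,)).astype(int))
    if stride is None:
        stride = tuple(max(p // 2, 1) for p in patch)
    stride = tuple(np.broadcast_to(stride, (volume.ndim,)).astype(int))
    if any(p > s for p, s in zip(patch, volume.shape)):
        raise SizeError(f"volume {volume.shape} smaller than patch {patch}")
    if any(st > p for st, p in zip(stride, patch)):
        raise ConfigurationError(
            f"stride {stride} exceeds patch {patch}: coverage gaps")

    offsets = [_axis_offsets(s, p, st)
               for s, p, st in zip(volume.shape, patch, stride)]
    out = None
    count = np.zeros(volume.shape, dtype=np.float32)
    for corner in np.array(np.meshgrid(*offsets, indexing="ij")).reshape(volume.ndim, -1).T:
        sl = tuple(slice(int(c), int(c + p)) for c, p in zip(corner, patch))
        logits = np.asarray(model(volume[sl]), dtype=np.float32)
        if out is None:
            out = np.zeros((logits.shape[0],) + volume.shape, dtype=np.float32)
        out[(slice(None),) + sl] += logits
        count[sl] += 1.0
    return out / count


def tta_predict(model, volume: np.ndarray,
                transforms: list[TTATransform] | None = None,
                patch_size=None, stride=None,
                pad_value: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """TTA-merged prediction: (probabilities (K, *S), labels (*S)).

    Each pass transforms the volume, runs sliding-window inference, and maps
    the per-class scores back with the inverse transform (linear interpolation
    on score channels, never nearest-neighbour on labels).  Scores are averaged
    over the untransformed pass and every valid transformed pass, a softmax
    turns the merged scores into probabilities, and the label map is the
    per-voxel argmax.
    """
    volume = np.asarray(volume, dtype=np.float32)
    transforms = list(transforms) if transforms is not None else default_tta()
    patch_size = patch_size if patch_size is not None else volume.shape

    base = sliding_window_infer(model, volume, patch_size, stride)
    acc = base.copy()
    weight = np.ones(volume.shape, dtype=np.float32)

    for t in transforms:
        moved = t.apply(volume, cval=pad_value)
        logits = sliding_window_infer(model, moved, patch_size, stride)
        back = np.stack([t.invert(c, cval=0.0) for c in logits])
        valid = t.invert(t.apply(np.ones(volume.shape, np.float32), cval=0.0),
                         cval=0.0) > 0.999
        acc += back * valid
        weight += valid
    merged = acc / weight
    probs = softmax(merged, axis=0)
    labels = np.argmax(merged, axis=0).astype(np.int16)
    return probs, labels
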