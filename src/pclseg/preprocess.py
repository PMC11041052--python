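"""Preprocessing: soft-tissue intensity windowing and central in-plane cropping.

The pancreas and most cystic lesions sit near 50 HU, so intensities are
clipped to a window of +/-100 HU around 50 HU and rescaled linearly to [0, 1].
The abdomen centre (where the pancreas lies) is then kept by cropping the
axial plane from the scanner's 512x512 grid to 240x240; the slice axis is
never cropped.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .errors import SizeError, ShapeError, ValidationError
from .imaging_io import CTVolume

__all__ = ["PreprocessConfig", "soft_tissue_normalize", "central_crop",
           "crop_offset", "uncrop"]


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    window_center: float = 50.0    # HU
    window_halfwidth: float = Field(default=100.0, gt=0)   # HU
    crop_size: int = Field(default=240, gt=0)              # in-plane voxels


def _as_array(volume) -> np.ndarray:
    return volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)


def soft_tissue_normalize(ct, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Clip HU to [center-halfwidth, center+halfwidth] and rescale to [0, 1].

    Monotone non-decreasing in the input; the window floor maps to 0.0, the
    ceiling to 1.0 and the window centre to 0.5.
    """
    cfg = cfg or PreprocessConfig()
    hu = _as_array(ct).astype(np.float32)
    if not np.isfinite(hu).all():
        raise ValidationError("cannot normalize a volume with non-finite HU")
    lo = cfg.window_center - cfg.window_halfwidth
    hi = cfg.window_center + cfg.window_halfwidth
    return (np.clip(hu, lo, hi) - lo) / (hi - lo)


def crop_offset(inplane_shape: tuple[int, int], crop_size: int) -> tuple[int, int]:
    """Low-corner offset of the centred crop window.

    Odd remainders keep the extra voxel on the high side (offset = floor of
    half the remainder).
    """
    n0, n1 = inplane_shape
    if n0 < crop_size or n1 < crop_size:
        raise SizeError(
            f"in-plane shape {inplane_shape} smaller than crop {crop_size}; "
            "no padding is performed")
    return (n0 - crop_size) // 2, (n1 - crop_size) // 2


def central_crop(volume, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Crop the axial plane to (crop_size, crop_size); slices untouched."""
    cfg = cfg or PreprocessConfig()
    arr = _as_array(volume)
    o0, o1 = crop_offset(arr.shape[:2], cfg.crop_size)
    return arr[o0:o0 + cfg.crop_size, o1:o1 + cfg.crop_size, ...]


def uncrop(cropped, original_shape: tuple[int, ...],
           cfg: PreprocessConfig | None = None,
           fill=0) -> np.ndarray:
    """Place a cropped prediction back into the original grid (rest = fill)."""
    cfg = cfg or PreprocessConfig()
    cropped = np.asarray(cropped)
    if cropped.shape[0] != cfg.crop_size or cropped.shape[1] != cfg.crop_size:
        raise ShapeError(
            f"cropped in-plane shape {cropped.shape[:2]} does not match "
            f"crop_size {cfg.crop_size}")
    if cropped.shape[2:] != tuple(original_shape[2:]):
        raise ShapeError(
            f"slice axes {cropped.shape[2:]} do not match original "
            f"{tuple(original_shape[2:])}")
    o0, o1 = crop_offset(tuple(original_shape[:2]), cfg.crop_size)
    out = np.full(tuple(original_shape), fill, dtype=cropped.dtype)
    out[o0:o0 + cfg.crop_size, o1:o1 + cfg.crop_size, ...] = cropped
    return out
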