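"""NIfTI reading/writing with one canonical orientation for the whole package.

Every volume is reoriented to RAS (right-anterior-superior) on load, so the
"axial plane" used by cropping, patch sampling and the test-time-augmentation
transforms is always the first two array axes and the slice axis is the third.
Voxel indexing is 0-based and shapes are quoted as (in-plane, in-plane, slices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, FormatError, ValidationError

__all__ = ["CTVolume", "LabelVolume", "CLASS_MAP",
           "read_volume", "read_label_volume", "write_volume"]

CLASS_MAP = {0: "background", 1: "pancreas", 2: "cyst"}


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class CTVolume:
    """A 3D CT grid in Hounsfield units plus geometry metadata."""

    voxels: np.ndarray                  # (x, y, z) float32, HU
    spacing: tuple[float, float, float]  # mm per axis
    affine: np.ndarray | None = None    # 4x4 voxel->world (RAS) map

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"CT volume must be 3D, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if not np.isfinite(self.voxels).all():
            raise ValidationError("CT volume contains non-finite HU values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelVolume:
    """Integer segmentation aligned with a CT volume (0=bg, 1=pancreas, 2=cyst)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    class_map: dict = field(default_factory=lambda: dict(CLASS_MAP))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"label volume must be 3D, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValidationError("label volume must have an integer dtype")
        bad = set(np.unique(self.voxels)) - set(self.class_map)
        if bad:
            raise ValidationError(f"label volume contains unknown classes {bad}")
        self.voxels = self.voxels.astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def _load_canonical(path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if len(img.shape) != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D volume, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return img, spacing


def read_volume(path) -> CTVolume:
    """Read a CT volume, reoriented to canonical RAS."""
    img, spacing = _load_canonical(path)
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    return CTVolume(data, spacing, np.asarray(img.affine))


def read_label_volume(path) -> LabelVolume:
    """Read a segmentation volume, reoriented to canonical RAS."""
    img, spacing = _load_canonical(path)
    data = np.rint(np.asarray(img.get_fdata())).astype(np.int16)
    return LabelVolume(data, spacing, np.asarray(img.affine))


def write_volume(volume: CTVolume | LabelVolume, path) -> Path:
    """Write a volume as NIfTI-1; spacing/orientation round-trip exactly."""
    path = Path(path)
    data = volume.voxels
    if isinstance(volume, LabelVolume):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    return path
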