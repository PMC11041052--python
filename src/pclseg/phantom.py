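"""Synthetic abdominal CT phantoms with ground-truth pancreas/cyst labels.

A phantom is a deliberately simple abdomen: a superellipse soft-tissue cross
section wrapped in a fat ring and surrounded by air, a vertebral body of bone
posteriorly, an elongated ellipsoidal pancreas near the centre, and spherical
near-water cysts that (by default) are seeded on the pancreas surface so they
touch it.  Intensities are drawn per tissue as Gaussian HU around the tissue
mean.  The geometry is intentionally minimal: the downstream pipeline's
filters depend only on intensity, adjacency and component size, not on
anatomical realism.

Cohorts pair cyst-bearing cases with cyst-free controls, assign each case a
cyst risk group (mirroring the mucinous "high risk" vs serous/pseudocyst
"low risk" grouping used clinically; high-risk cysts are drawn from the upper
half of the radius range, low-risk from the lower half), and stratify the
train/test split by case/control status.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage

from .errors import PlacementError, SizeError, ValidationError
from .imaging_io import CTVolume, LabelVolume, write_volume

__all__ = ["TissueModel", "PhantomSpec", "StudyRecord", "DEFAULT_TISSUES",
           "generate_phantom", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class TissueModel:
    """Gaussian HU model for one tissue class."""

    name: str
    mean_hu: float
    sd_hu: float

    def __post_init__(self):
        if self.sd_hu < 0:
            raise ValidationError("sd_hu must be non-negative")


#: Default tissue table.  Means honour the CT ordering
#: air < fat < cyst (near water) < soft tissue <= pancreas < bone.
DEFAULT_TISSUES: dict[str, TissueModel] = {
    "air": TissueModel("air", -1000.0, 20.0),
    "fat": TissueModel("fat", -100.0, 10.0),
    "cyst": TissueModel("cyst", 8.0, 8.0),
    "soft": TissueModel("soft", 40.0, 10.0),
    "pancreas": TissueModel("pancreas", 55.0, 10.0),
    "bone": TissueModel("bone", 300.0, 30.0),
}


class PhantomSpec(BaseModel):
    """Everything needed to generate one phantom deterministically."""

    model_config = ConfigDict(extra="forbid")

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.5, 1.5, 5.0)   # mm
    n_cysts: int = Field(default=1, ge=0)
    cyst_radius_range: tuple[float, float] = (2.0, 4.0)     # voxels
    cyst_attached: bool = True
    risk_group: str = "high"          # {"high", "low"}: sets cyst size band
    noise_sd: float = Field(default=0.0, ge=0)              # extra global HU noise
    seed: int = 0

    def model_post_init(self, _ctx) -> None:
        lo, hi = self.cyst_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("cyst_radius_range must be 0 < lo <= hi")
        if self.risk_group not in ("high", "low"):
            raise ValueError("risk_group must be 'high' or 'low'")


@dataclass
class StudyRecord:
    """One study: volumes plus case/control and split metadata."""

    study_id: str
    ct: CTVolume
    labels: LabelVolume
    is_case: bool
    risk_group: str            # {"high", "low", "none"}
    split: str                 # {"train", "test"}

    def __post_init__(self):
        has_cyst = bool((self.labels.voxels == 2).any())
        if has_cyst != self.is_case:
            raise ValidationError(
                f"{self.study_id}: is_case={self.is_case} inconsistent with "
                f"cyst voxels present={has_cyst}")
        if (self.risk_group == "none") == self.is_case:
            raise ValidationError(
                f"{self.study_id}: controls must have risk_group='none' and "
                "cases a real risk group")


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _superellipse(nx, ny, ax, ay, power=4.0):
    x = np.arange(nx)[:, None] - (nx - 1) / 2.0
    y = np.arange(ny)[None, :] - (ny - 1) / 2.0
    return (np.abs(x) / ax) ** power + (np.abs(y) / ay) ** power


def _sphere_mask(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def _geometry(shape):
    """Static tissue masks (everything except the cysts)."""
    nx, ny, nz = shape
    r = _superellipse(nx, ny, 0.42 * nx, 0.40 * ny)
    body2d = r <= 1.0
    soft2d = r <= 0.70
    body = np.broadcast_to(body2d[:, :, None], shape).copy()
    soft = np.broadcast_to(soft2d[:, :, None], shape).copy()
    fat = body & ~soft

    # vertebral body: posterior cylinder through all slices
    cx, cy = (nx - 1) / 2.0, 0.76 * ny
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    bone2d = (x ** 2 + y ** 2) <= (0.06 * nx) ** 2
    bone = np.broadcast_to((bone2d & soft2d)[:, :, None], shape).copy()

    # elongated pancreas: ellipsoid, slightly anterior of centre
    center = np.array([(nx - 1) / 2.0, 0.44 * ny, (nz - 1) / 2.0])
    semi = np.array([0.30 * nx, 0.10 * ny, 0.18 * nz])
    gx = np.arange(nx)[:, None, None]
    gy = np.arange(ny)[None, :, None]
    gz = np.arange(nz)[None, None, :]
    panc = (((gx - center[0]) / semi[0]) ** 2
            + ((gy - center[1]) / semi[1]) ** 2
            + ((gz - center[2]) / semi[2]) ** 2) <= 1.0
    panc &= soft & ~bone
    return body, soft, fat, bone, panc


def _place_cysts(rng, spec: PhantomSpec, soft, panc):
    """Choose cyst centres/radii; returns list of (center, radius) or raises."""
    lo, hi = spec.cyst_radius_range
    mid = (lo + hi) / 2.0
    band = (mid, hi) if spec.risk_group == "high" else (lo, mid)

    if spec.cyst_attached:
        surface = panc & ~ndimage.binary_erosion(panc, structure=_STRUCT26)
        candidates = np.argwhere(surface)
    else:
        candidates = np.argwhere(soft & ~panc)
    if candidates.size == 0:
        raise PlacementError("no candidate voxels for cyst placement")

    interior = soft  # cysts must stay inside the soft-tissue interior
    placed: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.n_cysts):
        ok = False
        for _attempt in range(200):
            center = candidates[rng.integers(len(candidates))]
            radius = float(rng.uniform(*band))
            m = _sphere_mask(soft.shape, center, radius)
            if not (m & ~interior).any():
                if all(np.linalg.norm(center - c) > radius + r0 + 1.5
                       for c, r0 in placed):
                    placed.append((center, radius))
                    ok = True
                    break
        if not ok:
            raise PlacementError(
                f"could not place cyst {len(placed) + 1}/{spec.n_cysts} after "
                "200 attempts; reduce n_cysts or cyst radii")
    return placed


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelVolume]:
    """Generate one phantom; identical (spec, seed) pairs are bit-identical."""
    shape = tuple(spec.grid_shape)
    if any(n < 32 for n in shape):
        raise SizeError(f"grid_shape must be >= 32 per axis, got {shape}")
    lo, hi = spec.cyst_radius_range
    if 2 * hi + 2 > min(shape):
        raise SizeError("cyst radii too large for the grid")

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x9C]))
    body, soft, fat, bone, panc = _geometry(shape)

    for _retry in range(5):
        labels = np.zeros(shape, dtype=np.int16)
        labels[panc] = 1
        cyst_mask = np.zeros(shape, dtype=bool)
        for center, radius in _place_cysts(rng, spec, soft, panc) if spec.n_cysts else []:
            cyst_mask |= _sphere_mask(shape, center, radius)
        labels[cyst_mask] = 2
        n_comp = ndimage.label(labels == 2, structure=_STRUCT26)[1]
        if n_comp == spec.n_cysts:
            break
    else:
        raise PlacementError(
            f"cyst components merged or vanished in 5 retries "
            f"(wanted {spec.n_cysts}, got {n_comp})")

    tissue_masks = [
        ("air", ~body),
        ("fat", fat),
        ("soft", soft & ~bone & (labels == 0)),
        ("bone", bone & (labels == 0)),
        ("pancreas", labels == 1),
        ("cyst", labels == 2),
    ]
    hu = np.empty(shape, dtype=np.float32)
    for name, mask in tissue_masks:
        t = DEFAULT_TISSUES[name]
        hu[mask] = rng.normal(t.mean_hu, t.sd_hu, size=int(mask.sum()))
    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    ct = CTVolume(hu, spec.spacing)
    lab = LabelVolume(labels, spec.spacing)
    return ct, lab


def _stratified_split(rng, ids: list[int], train_ratio: float):
    """Return the set of indices assigned to 'train' (floor(ratio*n) of them)."""
    n_train = int(np.floor(train_ratio * len(ids)))
    order = list(ids)
    rng.shuffle(order)
    return set(order[:n_train])


def generate_cohort(n_cases: int, n_controls: int,
                    spec_template: PhantomSpec | None = None,
                    seed: int = 0, train_ratio: float = 0.7) -> list[StudyRecord]:
    """Generate a case/control cohort with a stratified train/test split.

    Cases carry at least one cyst and alternate between the high- and low-risk
    groups; controls are cyst-free.  The split is stratified by case/control
    with ``floor(train_ratio * n)`` training studies per stratum.
    """
    if n_cases < 0 or n_controls < 0:
        raise ValueError("n_cases and n_controls must be >= 0")
    template = spec_template or PhantomSpec()
    ss = np.random.SeedSequence(int(seed))
    study_seeds = [int(s) & 0x7FFFFFFF
                   for s in ss.generate_state(n_cases + n_controls + 1)]
    split_rng = np.random.default_rng(study_seeds[-1])
    case_train = _stratified_split(split_rng, list(range(n_cases)), train_ratio)
    ctrl_train = _stratified_split(split_rng, list(range(n_controls)), train_ratio)

    records: list[StudyRecord] = []
    for i in range(n_cases):
        risk = "high" if i % 2 == 0 else "low"
        spec = template.model_copy(update={
            "seed": study_seeds[i],
            "n_cysts": max(template.n_cysts, 1),
            "risk_group": risk,
        })
        ct, lab = generate_phantom(spec)
        records.append(StudyRecord(
            study_id=f"case_{i:03d}", ct=ct, labels=lab, is_case=True,
            risk_group=risk, split="train" if i in case_train else "test"))
    for j in range(n_controls):
        spec = template.model_copy(update={
            "seed": study_seeds[n_cases + j], "n_cysts": 0})
        ct, lab = generate_phantom(spec)
        records.append(StudyRecord(
            study_id=f"ctrl_{j:03d}", ct=ct, labels=lab, is_case=False,
            risk_group="none", split="train" if j in ctrl_train else "test"))
    return records


def write_cohort(records: list[StudyRecord], outdir) -> Path:
    """Write `<id>_ct.nii.gz` / `<id>_seg.nii.gz` pairs plus a CSV manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        ct_path = outdir / f"{rec.study_id}_ct.nii.gz"
        seg_path = outdir / f"{rec.study_id}_seg.nii.gz"
        write_volume(rec.ct, ct_path)
        write_volume(rec.labels, seg_path)
        rows.append({"study_id": rec.study_id, "is_case": rec.is_case,
                     "risk_group": rec.risk_group, "split": rec.split,
                     "ct_path": ct_path.name, "seg_path": seg_path.name})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
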