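"""False-positive filtering of raw network predictions.

Three anatomically motivated filters are applied in order:

1. **Abdomen mask** — threshold the raw HU volume, keep the largest connected
   component, fill internal holes, erode; predictions outside this eroded body
   mask (edges of the abdomen, air, couch) are discarded.
2. **Pancreas contact** — predicted cyst components with no voxel adjacent to
   a predicted pancreas voxel are discarded (pancreatic cysts touch the
   pancreas).
3. **Minimum size** — predicted cyst components smaller than 10 voxels are
   discarded; components of exactly the minimum size survive.

Each removed component is recorded once in a :class:`ComponentReport` with the
filter that removed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage
from skimage.morphology import ball

from .errors import DegenerateInputError, ShapeError
from .imaging_io import CTVolume

__all__ = ["PostprocessConfig", "ComponentRecord", "ComponentReport",
           "abdomen_mask", "filter_outside_abdomen", "filter_noncontact_cysts",
           "filter_small_components", "postprocess_pipeline"]


class PostprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    abdomen_hu_threshold: float = -500.0
    erosion_radius: int = Field(default=3, ge=0)
    contact_connectivity: int = 26          # 6, 18 or 26-neighbourhood
    component_connectivity: int = 26        # for labelling cyst components
    min_cyst_voxels: int = Field(default=10, ge=1)

    def model_post_init(self, _ctx) -> None:
        for name in ("contact_connectivity", "component_connectivity"):
            if getattr(self, name) not in (6, 18, 26):
                raise ValueError(f"{name} must be 6, 18 or 26")


@dataclass
class ComponentRecord:
    """Fate of one predicted cyst component."""

    component_id: int
    voxel_count: int
    touches_pancreas: bool
    inside_abdomen: bool
    removed_by: str = "none"     # none | abdomen | contact | size


ComponentReport = list  # list[ComponentRecord]


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def _cyst_components(pred: np.ndarray, cfg: PostprocessConfig):
    return ndimage.label(pred == 2, structure=_structure(cfg.component_connectivity))


def _touches(mask: np.ndarray, pancreas: np.ndarray, cfg: PostprocessConfig) -> bool:
    grown = ndimage.binary_dilation(mask, structure=_structure(cfg.contact_connectivity))
    return bool((grown & pancreas).any())


def abdomen_mask(ct, cfg: PostprocessConfig | None = None) -> np.ndarray:
    """Eroded binary mask of the abdomen from the raw HU volume."""
    cfg = cfg or PostprocessConfig()
    hu = ct.voxels if isinstance(ct, CTVolume) else np.asarray(ct)
    body = hu >= cfg.abdomen_hu_threshold
    if not body.any():
        raise DegenerateInputError(
            f"no voxel above {cfg.abdomen_hu_threshold} HU: empty abdomen mask")
    lab, n = ndimage.label(body, structure=_structure(26))
    largest = np.argmax(ndimage.sum_labels(np.ones_like(lab), lab,
                                           index=range(1, n + 1))) + 1
    mask = ndimage.binary_fill_holes(lab == largest)
    if cfg.erosion_radius > 0:
        mask = ndimage.binary_erosion(mask, structure=ball(cfg.erosion_radius))
    return mask


def _report_components(pred, cfg, keep_fn, reason, pancreas=None, mask=None):
    """Shared driver: label cyst components, drop those failing keep_fn."""
    comp, n = _cyst_components(pred, cfg)
    out = pred.copy()
    records = []
    for cid in range(1, n + 1):
        m = comp == cid
        count = int(m.sum())
        keep = keep_fn(m, count)
        touches = _touches(m, pred == 1 if pancreas is None else pancreas, cfg)
        inside = True if mask is None else bool((m & ~mask).sum() == 0)
        rec = ComponentRecord(cid, count, touches, inside,
                              removed_by="none" if keep else reason)
        if not keep:
            out[m] = 0
        records.append(rec)
    return out, records


def filter_outside_abdomen(pred: np.ndarray, mask: np.ndarray,
                           cfg: PostprocessConfig | None = None):
    """Zero predicted pancreas/cyst voxels outside the eroded abdomen mask.

    Components that lose *all* voxels are reported as removed_by='abdomen';
    straddling components keep their inside voxels.
    """
    cfg = cfg or PostprocessConfig()
    pred = np.asarray(pred)
    if pred.shape != mask.shape:
        raise ShapeError(f"prediction {pred.shape} vs mask {mask.shape}")
    comp, n = _cyst_components(pred, cfg)
    out = pred.copy()
    out[(pred > 0) & ~mask] = 0
    records = []
    for cid in range(1, n + 1):
        m = comp == cid
        surviving = int((m & mask).sum())
        records.append(ComponentRecord(
            cid, int(m.sum()), _touches(m, pred == 1, cfg),
            inside_abdomen=bool((m & ~mask).sum() == 0),
            removed_by="none" if surviving else "abdomen"))
    return out, records


def filter_noncontact_cysts(pred: np.ndarray,
                            cfg: PostprocessConfig | None = None):
    """Remove cyst components with no voxel adjacent to predicted pancreas."""
    cfg = cfg or PostprocessConfig()
    pred = np.asarray(pred)
    pancreas = pred == 1
    return _report_components(
        pred, cfg, keep_fn=lambda m, _c: _touches(m, pancreas, cfg),
        reason="contact", pancreas=pancreas)


def filter_small_components(pred: np.ndarray,
                            cfg: PostprocessConfig | None = None):
    """Remove cyst components below the minimum voxel count (>= min survives)."""
    cfg = cfg or PostprocessConfig()
    pred = np.asarray(pred)
    return _report_components(
        pred, cfg, keep_fn=lambda _m, c: c >= cfg.min_cyst_voxels,
        reason="size", pancreas=pred == 1)


def postprocess_pipeline(pred: np.ndarray, ct,
                         cfg: PostprocessConfig | None = None):
    """Apply abdomen -> contact -> size filtering; one report row per component.

    Components are identified on the *input* prediction; each is attributed to
    the first filter that eliminates it.  Filters only ever remove voxels, so
    the pipeline is idempotent.
    """
    cfg = cfg or PostprocessConfig()
    pred = np.asarray(pred)
    hu = ct.voxels if isinstance(ct, CTVolume) else np.asarray(ct)
    if pred.shape != hu.shape:
        raise ShapeError(f"prediction {pred.shape} vs CT {hu.shape}")
    mask = abdomen_mask(hu, cfg)

    out = pred.copy()
    out[(out > 0) & ~mask] = 0          # pancreas and cysts alike
    pancreas = out == 1

    comp, n = _cyst_components(pred, cfg)
    records = []
    for cid in range(1, n + 1):
        m = comp == cid
        inside = m & mask
        rec = ComponentRecord(
            cid, int(m.sum()),
            touches_pancreas=_touches(inside, pancreas, cfg),
            inside_abdomen=bool((m & ~mask).sum() == 0))
        if not inside.any():
            rec.removed_by = "abdomen"
        elif not rec.touches_pancreas:
            rec.removed_by = "contact"
            out[inside] = 0
        elif int(inside.sum()) < cfg.min_cyst_voxels:
            rec.removed_by = "size"
            out[inside] = 0
        records.append(rec)
    return out, records
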