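"""Pipeline configuration and end-to-end orchestration.

One YAML file configures every stage; one seed feeds every source of
randomness.  ``run_pipeline`` drives a manifest of studies through
preprocess -> (TTA) inference -> uncrop -> postprocess -> evaluation, keeps
going when single studies fail, and writes predictions, per-study outcomes,
cohort metrics and the resolved configuration next to each other so a run is
reproducible from (config, seed, checkpoint).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .agnet import AGNet, AGNetConfig
from .evaluation import classify_study, cohort_metrics, dice_score
from .imaging_io import LabelVolume, read_label_volume, read_volume, write_volume
from .inference import TTATransform, default_tta, tta_predict
from .postprocess import PostprocessConfig, postprocess_pipeline
from .preprocess import PreprocessConfig, central_crop, soft_tissue_normalize, uncrop
from .training import TrainConfig

__all__ = ["TTAConfig", "InferenceConfig", "PipelineConfig",
           "load_config", "dump_config", "run_pipeline"]


class TTAConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    enabled: bool = True
    rotations_deg: tuple[float, ...] = (7.0, -11.0)
    translations_vox: tuple[float, ...] = (5.0, 10.0)

    def transforms(self) -> list[TTATransform]:
        return ([TTATransform("rotation", r) for r in self.rotations_deg]
                + [TTATransform("translation", t) for t in self.translations_vox])


class InferenceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patch_inplane: int = Field(default=160, gt=0)
    patch_depth: int = Field(default=16, gt=0)
    stride_fraction: float = Field(default=0.5, gt=0, le=1)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    preprocess: PreprocessConfig = PreprocessConfig()
    model: AGNetConfig = AGNetConfig()
    train: TrainConfig = TrainConfig()
    inference: InferenceConfig = InferenceConfig()
    tta: TTAConfig = TTAConfig()
    postprocess: PostprocessConfig = PostprocessConfig()
    min_overlap_voxels: int = Field(default=1, ge=1)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def dump_config(cfg: PipelineConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(cfg.model_dump_json()), fh, sort_keys=False)
    return path


def _predict_study(model: AGNet, ct, cfg: PipelineConfig) -> np.ndarray:
    """Full-resolution label prediction for one CT volume."""
    norm = soft_tissue_normalize(ct, cfg.preprocess)
    cropped = central_crop(norm, cfg.preprocess)
    patch = (min(cfg.inference.patch_inplane, cropped.shape[0]),
             min(cfg.inference.patch_inplane, cropped.shape[1]),
             min(cfg.inference.patch_depth, cropped.shape[2]))
    stride = tuple(max(int(p * cfg.inference.stride_fraction), 1) for p in patch)
    transforms = cfg.tta.transforms() if cfg.tta.enabled else []
    _probs, labels = tta_predict(model, cropped, transforms, patch, stride)
    return uncrop(labels, ct.voxels.shape, cfg.preprocess)


def run_pipeline(manifest_path, cfg: PipelineConfig, checkpoint_path,
                 outdir) -> dict:
    """Run inference + postprocessing + evaluation over a cohort manifest.

    Returns a summary dict with ``metrics``, ``outcomes``, and ``failures``.
    Per-study errors are recorded (study_id, stage, message) and the remaining
    studies still run.
    """
    manifest_path = Path(manifest_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    model = AGNet.load(checkpoint_path)

    outcomes, failures, rows = [], [], []
    dice_p, dice_c = [], []
    for row in manifest.itertuples(index=False):
        stage = "read"
        try:
            ct = read_volume(manifest_path.parent / row.ct_path)
            truth = None
            if isinstance(getattr(row, "seg_path", None), str) and row.seg_path:
                truth = read_label_volume(manifest_path.parent / row.seg_path)
            stage = "inference"
            pred_full = _predict_study(model, ct, cfg)
            stage = "postprocess"
            pred_pp, report = postprocess_pipeline(pred_full, ct, cfg.postprocess)
            stage = "evaluation"
            outcome = classify_study(
                pred_pp, truth.voxels if truth is not None else None,
                bool(row.is_case), study_id=row.study_id,
                risk_group=row.risk_group,
                min_overlap_voxels=cfg.min_overlap_voxels)
            outcomes.append(outcome)
            if truth is not None:
                dice_p.append(dice_score(pred_pp, truth.voxels, 1))
                dice_c.append(dice_score(pred_pp, truth.voxels, 2))
            stage = "write"
            write_volume(LabelVolume(pred_pp, ct.spacing, ct.affine),
                         outdir / f"{row.study_id}_pred.nii.gz")
            rows.extend({"study_id": row.study_id, **asdict(r)} for r in report)
        except Exception as exc:
            failures.append({"study_id": row.study_id, "stage": stage,
                             "error": str(exc)})

    metrics = cohort_metrics(outcomes, dice_p, dice_c) if outcomes else None
    summary = {
        "metrics": asdict(metrics) if metrics else None,
        "outcomes": [asdict(o) for o in outcomes],
        "failures": failures,
        "version": __version__,
    }
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    pd.DataFrame(rows).to_csv(outdir / "component_report.csv", index=False)
    dump_config(cfg, outdir / "resolved_config.yaml")
    return summary
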