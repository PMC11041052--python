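"""Study-level detection metrics with cyst-risk-group stratification.

A cyst-bearing study counts as a true positive when at least one surviving
predicted cyst component overlaps the ground-truth cyst mask in at least one
voxel (the minimum defensible criterion; the overlap threshold is
configurable).  A control study is a true negative when no predicted cyst
survives postprocessing.  Sensitivity is reported overall and per risk group;
specificity is computed once over controls and shared across groups.  Voxel
quality is reported as per-class Dice alongside the study-level metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ShapeError

__all__ = ["StudyOutcome", "CohortMetrics", "classify_study",
           "cohort_metrics", "dice_score"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class StudyOutcome:
    study_id: str
    is_case: bool
    risk_group: str            # high | low | none
    detected: bool
    outcome: str               # TP | FP | TN | FN

    def __post_init__(self):
        allowed = ("TP", "FN") if self.is_case else ("FP", "TN")
        if self.outcome not in allowed:
            raise ValueError(
                f"{self.study_id}: outcome {self.outcome} invalid for "
                f"is_case={self.is_case}")


@dataclass
class CohortMetrics:
    sensitivity: float | None
    specificity: float | None
    group_sensitivity: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)   # TP/FP/TN/FN
    dice_pancreas: float | None = None
    dice_cyst: float | None = None


def classify_study(pred: np.ndarray, truth: np.ndarray | None, is_case: bool,
                   study_id: str = "", risk_group: str = "none",
                   min_overlap_voxels: int = 1) -> StudyOutcome:
    """Decide TP/FN (cases) or FP/TN (controls) for one study.

    ``pred``/``truth`` are label volumes (0/1/2).  For a case the truth volume
    is required and detection means some predicted cyst component overlaps the
    truth cyst mask in >= ``min_overlap_voxels`` voxels.
    """
    pred = np.asarray(pred)
    if is_case:
        if truth is None:
            raise ConfigurationError(f"{study_id}: case study requires truth labels")
        truth = np.asarray(truth)
        if truth.shape != pred.shape:
            raise ShapeError(f"{study_id}: pred {pred.shape} vs truth {truth.shape}")
        comp, n = ndimage.label(pred == 2, structure=_STRUCT26)
        truth_cyst = truth == 2
        detected = any(
            int(((comp == cid) & truth_cyst).sum()) >= min_overlap_voxels
            for cid in range(1, n + 1))
        outcome = "TP" if detected else "FN"
    else:
        detected = bool((pred == 2).any())
        outcome = "FP" if detected else "TN"
    return StudyOutcome(study_id, is_case, risk_group, detected, outcome)


def cohort_metrics(outcomes: list[StudyOutcome],
                   dice_pancreas: list[float] | None = None,
                   dice_cyst: list[float] | None = None) -> CohortMetrics:
    """Aggregate study outcomes into sensitivity/specificity (+ per group).

    A metric whose denominator is empty (no cases, or no controls) is reported
    as None rather than a number.
    """
    if not outcomes:
        raise ValueError("cannot compute metrics for an empty outcome list")
    counts = {k: sum(o.outcome == k for o in outcomes)
              for k in ("TP", "FP", "TN", "FN")}
    n_cases = counts["TP"] + counts["FN"]
    n_controls = counts["TN"] + counts["FP"]
    sens = counts["TP"] / n_cases if n_cases else None
    spec = counts["TN"] / n_controls if n_controls else None

    groups = sorted({o.risk_group for o in outcomes if o.is_case})
    group_sens = {}
    for g in groups:
        sub = [o for o in outcomes if o.is_case and o.risk_group == g]
        group_sens[g] = sum(o.outcome == "TP" for o in sub) / len(sub)

    return CohortMetrics(
        sensitivity=sens, specificity=spec, group_sensitivity=group_sens,
        counts=counts,
        dice_pancreas=float(np.mean(dice_pancreas)) if dice_pancreas else None,
        dice_cyst=float(np.mean(dice_cyst)) if dice_cyst else None)


def dice_score(pred: np.ndarray, truth: np.ndarray, class_id: int) -> float:
    """Hard Dice 2|P&T| / (|P|+|T|) for one class; 1.0 when both are empty."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"pred {pred.shape} vs truth {truth.shape}")
    p = pred == class_id
    t = truth == class_id
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom
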