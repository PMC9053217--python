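"""Evaluation statistics for lesion segmentation.

Voxel-overlap metrics are computed from confusion counts in the subject's
original raw space:

    Dice        = 2 TP / (2 TP + FN + FP)
    Precision   = TP / (TP + FP)
    Sensitivity = TP / (TP + FN)

Cohort-level summaries include the subject detection rate (SDR; on
lesion-free cohorts this measures false-positive detection), lesion volume
strata (small < 1.7 ml, medium 1.7-14 ml, large >= 14 ml), lesion contrast
ratios kappa_DWI / kappa_ADC, and Spearman correlations with Fisher-z 95%
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .volspace import VolumeImage

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dice_precision_sensitivity",
    "subject_detection_rate",
    "lesion_contrast",
    "spearman_with_ci",
    "stratify_volume",
    "cohort_table",
]

#: lesion-volume strata boundaries in ml
SMALL_MAX_ML = 1.7
MEDIUM_MAX_ML = 14.0


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    """Per-subject evaluation record (serializable to JSON/CSV rows)."""

    dice: float
    precision: float
    sensitivity: float
    volume_ml: float
    stratum: str
    kappa_dwi: float = np.nan
    kappa_adc: float = np.nan
    TP: int = 0
    FP: int = 0
    FN: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _as_bool(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, VolumeImage) else mask
    return np.asarray(data) > 0.5


def confusion(pred, truth) -> ConfusionCounts:
    """Exact voxel counts of true/false positives and false negatives."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must share a grid")
    return ConfusionCounts(TP=int(np.sum(p & t)),
                           FP=int(np.sum(p & ~t)),
                           FN=int(np.sum(~p & t)))


def dice_precision_sensitivity(c: ConfusionCounts) -> tuple[float, float, float]:
    """Dice, precision and sensitivity from confusion counts.

    When both masks are empty all three are defined as 1 (the two raters
    agree there is no lesion); such subjects are reported separately from
    lesion-positive Dice tables.
    """
    if c.TP == 0 and c.FP == 0 and c.FN == 0:
        return 1.0, 1.0, 1.0
    dice = 2.0 * c.TP / (2.0 * c.TP + c.FN + c.FP)
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    sensitivity = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    return float(dice), float(precision), float(sensitivity)


def subject_detection_rate(preds, truths) -> dict:
    """Cohort detection summary.

    A lesion-positive subject counts as detected if its prediction overlaps
    the true mask by at least one voxel.  A lesion-free ("not visible")
    subject counts as a false-positive detection if its prediction is
    nonempty.  Also reports the count of subjects with more than 10
    false-positive voxels.
    """
    preds, truths = list(preds), list(truths)
    if not preds or len(preds) != len(truths):
        raise ValueError("need matched, non-empty prediction/truth lists")
    detected = fp_detected = n_pos = n_neg = fp_gt10 = 0
    for pred, truth in zip(preds, truths):
        p, t = _as_bool(pred), _as_bool(truth)
        if t.any():
            n_pos += 1
            if (p & t).any():
                detected += 1
        else:
            n_neg += 1
            if p.any():
                fp_detected += 1
        if int(np.sum(p & ~t)) > 10:
            fp_gt10 += 1
    return {
        "sdr": detected / n_pos if n_pos else np.nan,
        "fp_sdr": fp_detected / n_neg if n_neg else np.nan,
        "n_lesioned": n_pos,
        "n_not_visible": n_neg,
        "n_fp_gt10_voxels": fp_gt10,
    }


def lesion_contrast(img: VolumeImage, lesion, brain) -> float:
    """Contrast kappa: mean intensity inside the lesion over mean intensity
    of normal brain tissue (brain minus lesion), on raw intensities."""
    les, br = _as_bool(lesion), _as_bool(brain)
    if np.any(les & ~br):
        raise ValueError("lesion mask must lie inside the brain mask")
    normal = br & ~les
    if not les.any() or not normal.any():
        raise ValueError("empty lesion or normal-tissue region")
    data = np.asarray(img.data, dtype=np.float64)
    return float(data[les].mean() / data[normal].mean())


def spearman_with_ci(x, y, z: float = 1.96) -> tuple[float, float, float]:
    """Spearman rank correlation with a Fisher-transform 95% CI.

    CI = tanh(atanh(rho) -/+ z / sqrt(n - 3)).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired samples")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if abs(rho) >= 1.0:
        return rho, rho, rho
    zr = np.arctanh(rho)
    se = 1.0 / np.sqrt(n - 3)
    return rho, float(np.tanh(zr - z * se)), float(np.tanh(zr + z * se))


def stratify_volume(volume_ml: float) -> str:
    """Volume stratum: 'S' < 1.7 ml <= 'M' < 14 ml <= 'L'."""
    if volume_ml < SMALL_MAX_ML:
        return "S"
    if volume_ml < MEDIUM_MAX_ML:
        return "M"
    return "L"


def evaluate_subject(pred, truth, voxel_volume_mm3: float,
                     dwi: VolumeImage | None = None,
                     adc: VolumeImage | None = None,
                     brain=None) -> MetricsReport:
    """Full per-subject metrics from native-space masks."""
    c = confusion(pred, truth)
    dice, prec, sens = dice_precision_sensitivity(c)
    vol_ml = float(_as_bool(truth).sum()) * voxel_volume_mm3 / 1000.0
    kappa_d = kappa_a = np.nan
    if brain is not None and _as_bool(truth).any():
        if dwi is not None:
            kappa_d = lesion_contrast(dwi, truth, brain)
        if adc is not None:
            kappa_a = lesion_contrast(adc, truth, brain)
    return MetricsReport(dice=dice, precision=prec, sensitivity=sens,
                         volume_ml=vol_ml, stratum=stratify_volume(vol_ml),
                         kappa_dwi=kappa_d, kappa_adc=kappa_a,
                         TP=c.TP, FP=c.FP, FN=c.FN)


def cohort_table(reports) -> pd.DataFrame:
    """Stack per-subject reports into a cohort DataFrame (CSV-ready)."""
    return pd.DataFrame([r.to_dict() for r in reports])
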