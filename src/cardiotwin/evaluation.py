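"""Segmentation metrics and infarct-localization scoring.

Beyond the standard per-class Dice / precision / recall on point
clouds, the module implements a composite localization metric on the
17-segment AHA map:

    AHA-loc-score = beta_c_id * delta + beta_ids * IoU_ids
                    + beta_c_d * (1 - d_c)

where ``delta`` is 1 iff the AHA segment of the predicted infarct
centroid matches that of the ground truth, ``IoU_ids`` is the
intersection-over-union of the AHA segment index sets touched by the
predicted and true infarct, and ``d_c`` is the centroid distance
normalized by the bounding-box diagonal (clipped to [0, 1]).  The
weights default to (0.5, 0.2, 0.3) and must sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import AHABands, aha_segment_of, lv_mask_coord


class MetricError(ValueError):
    pass


@dataclass
class AHALocScoreConfig:
    beta_c_id: float = 0.5
    beta_ids: float = 0.2
    beta_c_d: float = 0.3
    scar_only: bool = False   # centroid/segments over scar only vs scar+BZ

    def validate(self):
        if abs(self.beta_c_id + self.beta_ids + self.beta_c_d - 1.0) > 1e-9:
            raise MetricError("AHA-loc-score weights must sum to 1")


def dice_precision_recall(pred: np.ndarray, gt: np.ndarray, cls: int):
    """Set-overlap metrics of class ``cls``.  Empty-vs-empty counts as
    perfect (1, 1, 1); empty-vs-nonempty as (0, 0, 0)."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise MetricError("label arrays differ in length")
    for arr in (pred, gt):
        if not np.isin(arr, (0, 1, 2)).all():
            raise MetricError("labels must be in {0, 1, 2}")
    p = pred == cls
    g = gt == cls
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        return 1.0, 1.0, 1.0
    inter = int((p & g).sum())
    dice = 2 * inter / (np_ + ng) if (np_ + ng) else 0.0
    precision = inter / np_ if np_ else 0.0
    recall = inter / ng if ng else 0.0
    return float(dice), float(precision), float(recall)


def _mi_mask(labels: np.ndarray, scar_only: bool) -> np.ndarray:
    labels = np.asarray(labels)
    return labels == 1 if scar_only else labels > 0


def _segments_of_points(xyz: np.ndarray, cobiveco: np.ndarray,
                        bands: AHABands) -> np.ndarray:
    segs = np.zeros(len(xyz), dtype=int)
    for i, c in enumerate(cobiveco):
        if lv_mask_coord(*c):
            segs[i] = aha_segment_of(c, bands)
    return segs


def _centroid_segment(centroid: np.ndarray, xyz: np.ndarray,
                      segs: np.ndarray) -> int:
    """AHA segment at a centroid: segment of the nearest LV-region point."""
    lv = segs > 0
    d = np.linalg.norm(xyz[lv] - centroid, axis=1)
    return int(segs[lv][np.argmin(d)])


def aha_loc_score_from_terms(delta: float, iou: float, dc: float,
                             cfg: AHALocScoreConfig | None = None) -> float:
    cfg = cfg or AHALocScoreConfig()
    cfg.validate()
    return float(cfg.beta_c_id * delta + cfg.beta_ids * iou
                 + cfg.beta_c_d * (1.0 - np.clip(dc, 0.0, 1.0)))


def aha_loc_score(pred: np.ndarray, gt: np.ndarray,
                  xyz: np.ndarray, cobiveco: np.ndarray,
                  cfg: AHALocScoreConfig | None = None,
                  bands: AHABands | None = None) -> float:
    """Composite localization score of a predicted infarct labeling
    against the ground truth on a point cloud."""
    cfg = cfg or AHALocScoreConfig()
    cfg.validate()
    bands = bands or AHABands()
    g = _mi_mask(gt, cfg.scar_only)
    p = _mi_mask(pred, cfg.scar_only)
    if not g.any():
        raise MetricError("ground-truth infarct is empty")
    if not p.any():
        warnings.warn("empty infarct prediction: AHA-loc-score = 0",
                      stacklevel=2)
        return 0.0
    segs = _segments_of_points(xyz, cobiveco, bands)
    c_pre = xyz[p].mean(axis=0)
    c_gd = xyz[g].mean(axis=0)
    delta = float(_centroid_segment(c_pre, xyz, segs)
                  == _centroid_segment(c_gd, xyz, segs))
    ids_pre = set(segs[p & (segs > 0)])
    ids_gd = set(segs[g & (segs > 0)])
    union = ids_pre | ids_gd
    iou = len(ids_pre & ids_gd) / len(union) if union else 0.0
    diag = float(np.linalg.norm(xyz.max(axis=0) - xyz.min(axis=0)))
    dc = np.linalg.norm(c_pre - c_gd) / diag if diag > 0 else 0.0
    return aha_loc_score_from_terms(delta, iou, dc, cfg)


def evaluate_case(pred: np.ndarray, gt: np.ndarray, xyz: np.ndarray,
                  cobiveco: np.ndarray,
                  cfg: AHALocScoreConfig | None = None) -> dict:
    out = {}
    for name, cls in (("scar", 1), ("bz", 2)):
        d, p, r = dice_precision_recall(pred, gt, cls)
        out[f"dice_{name}"] = d
        out[f"precision_{name}"] = p
        out[f"recall_{name}"] = r
    try:
        out["aha_loc_score"] = aha_loc_score(pred, gt, xyz, cobiveco, cfg)
    except MetricError:
        out["aha_loc_score"] = np.nan
    return out


def summarize_results(rows: list[dict]) -> pd.DataFrame:
    """Aggregate per-case metric dicts (must carry a 'scenario' key)
    into a scenario-by-metric table of mean and standard deviation."""
    df = pd.DataFrame(rows)
    metrics = [c for c in df.columns if c not in ("scenario", "subject")]
    return df.groupby("scenario")[metrics].agg(["mean", "std"])


def recon_inference_correlation(results: pd.DataFrame) -> dict:
    """OLS r^2 between each reconstruction loss and the scar/BZ Dice.

    ``results`` needs columns pc_rec, qrs_rec, dice_scar, dice_bz and at
    least 10 rows.  A constant column yields NaN (undefined r^2).
    """
    if len(results) < 10:
        raise MetricError("need at least 10 result rows")
    out = {}
    for branch in ("pc_rec", "qrs_rec"):
        for tissue in ("dice_scar", "dice_bz"):
            x = results[branch].to_numpy(dtype=float)
            y = results[tissue].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                out[f"r2_{branch}_{tissue}"] = float("nan")
                continue
            r = stats.linregress(x, y)
            out[f"r2_{branch}_{tissue}"] = float(r.rvalue ** 2)
    return out
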