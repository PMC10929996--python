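"""Segmentation evaluation: Dice overlap and Hausdorff distance.

Dice = 2|X∩Y| / (|X|+|Y|) over voxel sets.  The Hausdorff distance is the
symmetric directed max over Euclidean distances between foreground voxel
centers, computed in physical millimetres using the voxel spacing; the
95th-percentile variant (HD95) replaces each directed maximum with the 95th
percentile of that direction's distance distribution, which makes it robust
to single-voxel outliers.

Conventions for empty masks (the definitions are silent): Dice of two empty
masks is 1; Dice of one empty mask is 0; HD is undefined (returned as NaN and
flagged) whenever either mask is empty, rather than silently 0 or infinity.

Cases are stratified by the number of 6-connected ground-truth components
into single-tumor and multiple-tumor, and multiple-tumor cases additionally
get per-lesion metrics with predicted components matched by maximal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import SegMask

# 6-connectivity in 3D
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class MetricResult:
    dice: float
    hd: float  # NaN when undefined
    hd95: float  # NaN when undefined
    hd_defined: bool
    n_components_gt: int = 0
    n_components_pred: int = 0
    single_tumor: bool = True
    per_lesion: list["MetricResult"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "dice": self.dice,
            "hd": self.hd,
            "hd95": self.hd95,
            "hd_defined": self.hd_defined,
            "n_components_gt": self.n_components_gt,
            "n_components_pred": self.n_components_pred,
            "single_tumor": self.single_tumor,
        }
        if self.per_lesion:
            d["per_lesion"] = [m.to_dict() for m in self.per_lesion]
        return d


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, SegMask):
        mask = mask.voxels
    return np.asarray(mask) > 0


def dice_score(pred, gt) -> float:
    """Dice overlap; both masks empty -> 1.0 by convention."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        return 1.0
    inter = int(np.logical_and(p, g).sum())
    return 2.0 * inter / (np_ + ng)


def _directed_distances(src: np.ndarray, dst: np.ndarray, spacing) -> np.ndarray:
    """Distance from every foreground voxel of ``src`` to the nearest
    foreground voxel of ``dst`` (exact Euclidean, in mm)."""
    dt = ndimage.distance_transform_edt(~dst, sampling=spacing)
    return dt[src]


def hausdorff_distance(pred, gt, spacing=(1.0, 1.0, 1.0), percentile: float = 1.0) -> float:
    """Symmetric Hausdorff distance in mm over foreground voxel centers.

    ``percentile`` < 1 replaces each directed maximum by that percentile of
    the directed distance distribution (0.95 gives HD95).  Returns NaN when
    either mask is empty.
    """
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must be in (0, 1]")
    if p.sum() == 0 or g.sum() == 0:
        return float("nan")
    d_pg = _directed_distances(p, g, spacing)
    d_gp = _directed_distances(g, p, spacing)
    if percentile >= 1.0:
        return float(max(d_pg.max(), d_gp.max()))
    q = 100.0 * percentile
    return float(max(np.percentile(d_pg, q), np.percentile(d_gp, q)))


def _score_pair(pred_arr: np.ndarray, gt_arr: np.ndarray, spacing) -> tuple[float, float, float, bool]:
    dice = dice_score(pred_arr, gt_arr)
    hd = hausdorff_distance(pred_arr, gt_arr, spacing)
    hd95 = hausdorff_distance(pred_arr, gt_arr, spacing, percentile=0.95)
    return dice, hd, hd95, np.isfinite(hd)


def split_and_score(pred, gt, spacing=(1.0, 1.0, 1.0)) -> MetricResult:
    """Global + per-lesion metrics, stratified single vs multiple tumor.

    Ground-truth components are 6-connected; for multiple-tumor cases each
    ground-truth component is matched to the predicted component with maximal
    voxel overlap (an unmatched lesion scores Dice 0 with undefined HD).
    """
    p, g = _as_bool(pred), _as_bool(gt)
    if isinstance(gt, SegMask):
        spacing = gt.spacing
    gl, n_gt = ndimage.label(g, structure=_STRUCT6)
    pl, n_pred = ndimage.label(p, structure=_STRUCT6)
    dice, hd, hd95, defined = _score_pair(p, g, spacing)
    result = MetricResult(dice=dice, hd=hd, hd95=hd95, hd_defined=defined,
                          n_components_gt=int(n_gt), n_components_pred=int(n_pred),
                          single_tumor=(n_gt <= 1))
    if n_gt > 1:
        for lab in range(1, n_gt + 1):
            g_comp = gl == lab
            overlap_labels = pl[g_comp]
            overlap_labels = overlap_labels[overlap_labels > 0]
            if overlap_labels.size:
                match = int(np.bincount(overlap_labels).argmax())
                p_comp = pl == match
            else:
                p_comp = np.zeros_like(g_comp)
            d, h, h95, ok = _score_pair(p_comp, g_comp, spacing)
            result.per_lesion.append(MetricResult(
                dice=d, hd=h, hd95=h95, hd_defined=ok,
                n_components_gt=1, n_components_pred=int(p_comp.any()),
                single_tumor=True))
    return result


def aggregate(results: list[MetricResult]) -> dict:
    """Unweighted per-case means; HD means are over cases where HD is defined."""
    if not results:
        return {"n_cases": 0}
    dices = [r.dice for r in results]
    hds = [r.hd for r in results if r.hd_defined]
    hd95s = [r.hd95 for r in results if r.hd_defined]
    out = {
        "n_cases": len(results),
        "mean_dice": float(np.mean(dices)),
        "mean_hd": float(np.mean(hds)) if hds else float("nan"),
        "mean_hd95": float(np.mean(hd95s)) if hd95s else float("nan"),
        "n_hd_undefined": len(results) - len(hds),
    }
    for label, sel in (("single_tumor", True), ("multiple_tumors", False)):
        sub = [r for r in results if r.single_tumor == sel]
        if sub:
            sub_hd = [r.hd for r in sub if r.hd_defined]
            out[label] = {
                "n_cases": len(sub),
                "mean_dice": float(np.mean([r.dice for r in sub])),
                "mean_hd": float(np.mean(sub_hd)) if sub_hd else float("nan"),
            }
    return out
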