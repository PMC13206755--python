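"""Segmentation evaluation: DSC, bootstrap CI, HD95, ASD, dataset reports.

Regions are binary pixel masks.  For joint disc+cup labels {0,1,2} the disc
region is the anatomical union (labels {1,2}; the cup sits inside the disc)
and the cup region is label {2}.  Surface distances operate on boundary
pixels: a region pixel is a boundary pixel if any 4-neighbour lies outside
the region or off the image.  The 95 % operator uses the nearest-rank
percentile (⌈0.95·n⌉-th order statistic), making every value reproducible by
exhaustive enumeration.

Empty-region policy: if exactly one of the two regions is empty the surface
distances return the image diagonal (flagged in reports); if both are empty
they return 0 and DSC returns 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) pixel counts for two binary maps."""
    pred, gt = _check_pair(pred, gt)
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = pred.size - tp - fp - fn
    return tp, fp, fn, tn


def dsc(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity coefficient 2TP/(2TP+FP+FN).

    Both regions empty → 1 (perfect agreement on absence); exactly one
    empty → 0.
    """
    tp, fp, fn, _ = confusion_counts(pred, gt)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def _check_pair(pred, gt):
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred, gt


# ---------------------------------------------------------------------------
# bootstrap confidence interval
# ---------------------------------------------------------------------------

def bootstrap_ci(values, reps: int = 10_000, level: float = 0.95,
                 seed: int | None = None) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean (resampling with replacement)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("bootstrap_ci requires at least one value")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(reps, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# surface distances
# ---------------------------------------------------------------------------

def boundary_points(region: np.ndarray) -> np.ndarray:
    """(n, 2) array of (row, col) boundary pixels (4-connectivity)."""
    region = np.asarray(region).astype(bool)
    if not region.any():
        return np.empty((0, 2), dtype=np.int64)
    interior = binary_erosion(region, structure=_CROSS, border_value=0)
    return np.argwhere(region & ~interior)


def _nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    values = np.sort(values)
    rank = int(np.ceil(q * values.size))  # 1-based nearest rank
    return float(values[max(rank, 1) - 1])


def directional_h95(points_a: np.ndarray, points_b: np.ndarray, q: float = 0.95) -> float:
    """Nearest-rank ``q`` percentile of min-distances from A's points to B."""
    points_a = np.asarray(points_a, dtype=np.float64).reshape(-1, 2)
    points_b = np.asarray(points_b, dtype=np.float64).reshape(-1, 2)
    if points_a.size == 0 or points_b.size == 0:
        raise ValueError("directional_h95 requires nonempty point sets")
    dists, _ = cKDTree(points_b).query(points_a, k=1)
    return _nearest_rank_percentile(dists, q)


def _surface_sets(pred, gt, use_boundary: bool):
    pred, gt = _check_pair(pred, gt)
    if use_boundary:
        return boundary_points(pred), boundary_points(gt), pred.shape
    return np.argwhere(pred), np.argwhere(gt), pred.shape


def _diagonal(shape) -> float:
    return float(np.hypot(*shape))


def hd95(pred: np.ndarray, gt: np.ndarray, use_boundary: bool = True,
         return_flag: bool = False):
    """Symmetric 95th-percentile Hausdorff distance between boundary sets."""
    pts_p, pts_g, shape = _surface_sets(pred, gt, use_boundary)
    empty_p, empty_g = pts_p.size == 0, pts_g.size == 0
    if empty_p and empty_g:
        value, flagged = 0.0, False
    elif empty_p or empty_g:
        value, flagged = _diagonal(shape), True
    else:
        value = max(directional_h95(pts_p, pts_g), directional_h95(pts_g, pts_p))
        flagged = False
    return (value, flagged) if return_flag else value


def asd(pred: np.ndarray, gt: np.ndarray, use_boundary: bool = True,
        symmetric: bool = False, return_flag: bool = False):
    """Average surface distance, prediction boundary → ground-truth boundary.

    One-directional by default; ``symmetric=True`` averages both directions.
    """
    pts_p, pts_g, shape = _surface_sets(pred, gt, use_boundary)
    empty_p, empty_g = pts_p.size == 0, pts_g.size == 0
    if empty_p and empty_g:
        value, flagged = 0.0, False
    elif empty_p or empty_g:
        value, flagged = _diagonal(shape), True
    else:
        d_pg = cKDTree(pts_g.astype(np.float64)).query(pts_p.astype(np.float64), k=1)[0]
        if symmetric:
            d_gp = cKDTree(pts_p.astype(np.float64)).query(pts_g.astype(np.float64), k=1)[0]
            value = float((d_pg.sum() + d_gp.sum()) / (d_pg.size + d_gp.size))
        else:
            value = float(d_pg.mean())
        flagged = False
    return (value, flagged) if return_flag else value


# ---------------------------------------------------------------------------
# dataset-level evaluation
# ---------------------------------------------------------------------------

def regions_from_labels(mask: np.ndarray, num_classes: int) -> dict[str, np.ndarray]:
    """Binary evaluation regions from an integer label mask.

    K=3: disc = labels {1,2} (cup ⊂ disc), cup = label {2}.  K=2: disc only.
    """
    mask = np.asarray(mask)
    if num_classes == 3:
        return {"OD": mask >= 1, "OC": mask == 2}
    if num_classes == 2:
        return {"OD": mask == 1}
    raise ValueError("num_classes must be 2 or 3")


@dataclass
class MetricReport:
    per_image: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_files(self, directory, name: str = "metrics"):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_image.to_csv(directory / f"{name}_per_image.csv", index=False)
        with open(directory / f"{name}_summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2)
        return directory / f"{name}_summary.json"


def evaluate_dataset(pred_masks, gt_masks, num_classes: int,
                     reps: int = 10_000, seed: int | None = None,
                     with_distances: bool = True) -> MetricReport:
    """Per-image DSC (optionally HD95/ASD) per region, means and DSC 95% CI."""
    pred_masks, gt_masks = list(pred_masks), list(gt_masks)
    if len(pred_masks) != len(gt_masks):
        raise ValueError(
            f"{len(pred_masks)} predictions vs {len(gt_masks)} ground truths"
        )
    if not pred_masks:
        raise ValueError("empty evaluation set")
    rows = []
    for i, (pm, gm) in enumerate(zip(pred_masks, gt_masks)):
        pred_regions = regions_from_labels(pm, num_classes)
        gt_regions = regions_from_labels(gm, num_classes)
        for region in pred_regions:
            row = {"image": i, "region": region,
                   "dsc": dsc(pred_regions[region], gt_regions[region])}
            if with_distances:
                h, hf = hd95(pred_regions[region], gt_regions[region], return_flag=True)
                a, af = asd(pred_regions[region], gt_regions[region], return_flag=True)
                row.update(hd95=h, asd=a, empty_region_flag=bool(hf or af))
            rows.append(row)
    per_image = pd.DataFrame(rows)
    summary: dict = {"n_images": len(pred_masks), "regions": {}}
    for region, grp in per_image.groupby("region"):
        vals = grp["dsc"].to_numpy()
        lo, hi = bootstrap_ci(vals, reps=reps, seed=seed)
        entry = {"dsc_mean": float(vals.mean()), "dsc_ci95": [lo, hi]}
        if with_distances:
            entry["hd95_mean"] = float(grp["hd95"].mean())
            entry["asd_mean"] = float(grp["asd"].mean())
        summary["regions"][region] = entry
    means = [summary["regions"][r]["dsc_mean"] for r in summary["regions"]]
    summary["dsc_mean_all_regions"] = float(np.mean(means))
    return MetricReport(per_image=per_image, summary=summary)


def mean_foreground_dsc(pred_masks, gt_masks, num_classes: int) -> float:
    """Mean DSC over images and foreground regions (validation criterion)."""
    vals = []
    for pm, gm in zip(pred_masks, gt_masks):
        pr = regions_from_labels(pm, num_classes)
        gr = regions_from_labels(gm, num_classes)
        vals.extend(dsc(pr[r], gr[r]) for r in pr)
    return float(np.mean(vals))
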