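"""Segmentation evaluation metrics for binary mask volumes.

Eight metrics commonly reported for medical image segmentation: accuracy,
sensitivity, precision, specificity, Dice similarity coefficient (DSC),
intersection-over-union (IoU), Matthews correlation coefficient (MCC) and
the 95th-percentile Hausdorff distance (HD95) in physical millimetres.

Ratio metrics are computed from the voxel-level confusion counts, either
pooled over the whole volume (default) or averaged per slice/image.  HD95
uses boundary voxels (foreground voxels with at least one background
face-neighbour), centre-to-centre distances under anisotropic spacing, and
a linearly interpolated percentile over the pooled directed distances from
both directions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .volume import MaskVolume

__all__ = [
    "SegMetrics",
    "confusion_counts",
    "compute_seg_metrics",
    "hausdorff95",
    "boundary_voxels",
    "metrics_to_json",
    "metrics_to_csv",
]


@dataclass
class SegMetrics:
    """The eight-metric evaluation bundle; ratios in [0, 1], mcc in [-1, 1], hd95 in mm."""

    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    dsc: float
    iou: float
    mcc: float
    hd95: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _check_grids(pred: MaskVolume, gt: MaskVolume) -> None:
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if not np.allclose(pred.spacing_zyx, gt.spacing_zyx):
        raise ValueError(
            f"spacing mismatch: pred {pred.spacing_zyx} vs gt {gt.spacing_zyx}"
        )


def confusion_counts(pred: MaskVolume, gt: MaskVolume) -> tuple[int, int, int, int]:
    """Voxel-level (TP, FP, FN, TN) between a prediction and ground truth."""
    _check_grids(pred, gt)
    p = pred.voxels.astype(bool)
    g = gt.voxels.astype(bool)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return tp, fp, fn, tn


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return math.nan
    return num / den


def _ratios_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    n = tp + fp + fn + tn
    accuracy = _safe_ratio(tp + tn, n, "accuracy")
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity")
    precision = _safe_ratio(tp, tp + fp, "precision")
    specificity = _safe_ratio(tn, tn + fp, "specificity")
    dsc = _safe_ratio(2 * tp, 2 * tp + fp + fn, "dsc")
    iou = _safe_ratio(tp, tp + fp + fn, "iou")
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_ratio(float(tp) * tn - float(fp) * fn, mcc_den, "mcc")
    return dict(accuracy=accuracy, sensitivity=sensitivity, precision=precision,
                specificity=specificity, dsc=dsc, iou=iou, mcc=mcc)


def compute_seg_metrics(pred: MaskVolume, gt: MaskVolume,
                        mode: str = "pooled") -> SegMetrics:
    """Compute all eight metrics.

    Parameters
    ----------
    mode
        ``"pooled"`` computes ratio metrics from whole-volume counts;
        ``"per_slice"`` averages each ratio over slices (slices where a
        ratio is undefined are dropped from its average).  HD95 is always
        a volume-level surface distance.
    """
    _check_grids(pred, gt)
    if mode == "pooled":
        ratios = _ratios_from_counts(*confusion_counts(pred, gt))
    elif mode == "per_slice":
        per_slice = []
        for k in range(pred.shape[0]):
            sp = MaskVolume(pred.voxels[k:k + 1], pred.pixel_size, pred.slice_spacing)
            sg = MaskVolume(gt.voxels[k:k + 1], gt.pixel_size, gt.slice_spacing)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                per_slice.append(_ratios_from_counts(*confusion_counts(sp, sg)))
        ratios = {k: float(np.nanmean([d[k] for d in per_slice]))
                  for k in per_slice[0]}
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'pooled' or 'per_slice'")

    if pred.foreground_count() and gt.foreground_count():
        hd = hausdorff95(pred, gt)
    else:
        warnings.warn("hd95 undefined for an empty mask; reporting NaN",
                      RuntimeWarning, stacklevel=2)
        hd = math.nan
    return SegMetrics(hd95=hd, **ratios)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 background face-neighbour (6-connectivity).

    The volume border counts as background, so foreground touching the
    array edge is boundary.
    """
    m = np.asarray(mask, dtype=bool)
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1, 1, :] = structure[1, :, 1] = structure[:, 1, 1] = True
    interior = binary_erosion(m, structure=structure, border_value=0)
    return m & ~interior


def _directed_distances(a_pts: np.ndarray, b_pts: np.ndarray) -> np.ndarray:
    tree = cKDTree(b_pts)
    d, _ = tree.query(a_pts, k=1)
    return d


def _boundary_points_mm(vol: MaskVolume) -> np.ndarray:
    idx = np.argwhere(boundary_voxels(vol.voxels))
    dz, dy, dx = vol.spacing_zyx
    return idx * np.array([dz, dy, dx])


def hausdorff95(pred: MaskVolume, gt: MaskVolume, percentile: float = 95.0) -> float:
    """Symmetric percentile Hausdorff distance in mm.

    Pools the directed boundary distances from both masks and takes the
    linearly interpolated percentile of the combined multiset, so the
    result is symmetric in its arguments by construction.
    """
    _check_grids(pred, gt)
    if pred.foreground_count() == 0 or gt.foreground_count() == 0:
        raise ValueError("hausdorff95 requires both masks to be nonempty")
    a = _boundary_points_mm(pred)
    b = _boundary_points_mm(gt)
    d_ab = _directed_distances(a, b)
    d_ba = _directed_distances(b, a)
    pooled = np.concatenate([d_ab, d_ba])
    return float(np.percentile(pooled, percentile, method="linear"))


def metrics_to_json(metrics: SegMetrics, path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics.as_dict(), fh, indent=2)


def metrics_to_csv(metrics: SegMetrics, path) -> None:
    import pandas as pd

    pd.DataFrame([metrics.as_dict()]).to_csv(path, index=False)
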