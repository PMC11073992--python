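"""Reliability-based voxel selection (RBVS).

Selects voxels whose condition-wise response profile replicates across two
split halves of the data:

1. at every voxel, correlate the vector of condition parameter estimates
   in one half with the corresponding vector in the other half, per
   participant, and average into a group voxelwise-reliability map;
2. for each region of interest, anchor a contiguous suprathreshold cluster
   at the region's peak voxel over a grid of reliability thresholds;
3. at each threshold, compute multivoxel pattern reliability (per
   condition, the across-voxel correlation of the two halves within the
   mask, averaged over conditions and participants);
4. z-score each region's pattern-reliability curve across thresholds,
   average across regions, and select the threshold with the maximum
   average z (ties toward the lower threshold, i.e. the larger ROI).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "voxelwise_reliability_map",
    "grow_cluster_roi",
    "pattern_reliability_curve",
    "select_threshold",
    "ReliabilityVoxelSelector",
]

MIN_ROI_VOXELS = 33   # 3-voxel-radius spherical searchlight size


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation along axis 0 for each column pair; NaN if degenerate."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.sqrt((a ** 2).sum(axis=0))
    nb = np.sqrt((b ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r


def voxelwise_reliability_map(half1: np.ndarray, half2: np.ndarray,
                              grid_shape=None) -> np.ndarray:
    """Group-mean split-half reliability at every voxel.

    ``half1``/``half2`` are ``(n_participants, n_conditions, n_voxels)``
    parameter-estimate arrays.  At each voxel the condition vector of one
    half is correlated with the other half's, per participant; undefined
    correlations (zero-variance condition vectors) are excluded from the
    group mean with a logged count.
    """
    half1 = np.asarray(half1, dtype=float)
    half2 = np.asarray(half2, dtype=float)
    if half1.shape != half2.shape or half1.ndim != 3:
        raise ValueError("halves must share a (participants, conditions, "
                         "voxels) shape")
    if half1.shape[1] < 3:
        raise ValueError("need >= 3 conditions")
    maps = np.stack([_rowwise_corr(h1, h2) for h1, h2 in zip(half1, half2)])
    n_bad = int(np.isnan(maps).sum())
    if n_bad:
        logger.warning("%d undefined voxelwise correlations excluded", n_bad)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels
        group = np.nanmean(maps, axis=0)
    if grid_shape is not None:
        group = group.reshape(grid_shape)
    return group


def grow_cluster_roi(rel_map: np.ndarray, threshold: float,
                     peak: tuple[int, ...], connectivity: int = 1) -> np.ndarray:
    """Contiguous suprathreshold cluster containing the peak voxel.

    ``connectivity=1`` is face adjacency (6 neighbors in 3-D);
    ``connectivity=rel_map.ndim`` allows corner adjacency.  A peak below
    the threshold yields an empty, flagged mask.
    """
    rel_map = np.asarray(rel_map, dtype=float)
    peak = tuple(int(i) for i in peak)
    supra = rel_map > threshold
    if not supra[peak]:
        logger.warning("peak voxel below threshold %.3f; empty mask", threshold)
        return np.zeros_like(supra)
    structure = ndimage.generate_binary_structure(rel_map.ndim, connectivity)
    labels, _ = ndimage.label(supra, structure=structure)
    return labels == labels[peak]


def pattern_reliability(half1: np.ndarray, half2: np.ndarray,
                        mask_flat: np.ndarray) -> float:
    """Group-mean multivoxel pattern reliability within one mask.

    Per participant and condition, the across-voxel pattern in one half is
    correlated with the other half's; averaged over conditions, then
    participants.
    """
    a = half1[:, :, mask_flat]   # (part, cond, voxels in mask)
    b = half2[:, :, mask_flat]
    a = a - a.mean(axis=2, keepdims=True)
    b = b - b.mean(axis=2, keepdims=True)
    na = np.sqrt((a ** 2).sum(axis=2))
    nb = np.sqrt((b ** 2).sum(axis=2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=2) / (na * nb)
    return float(np.nanmean(np.nanmean(r, axis=1)))


def pattern_reliability_curve(half1, half2, masks: list[np.ndarray],
                              min_voxels: int = MIN_ROI_VOXELS) -> np.ndarray:
    """Pattern reliability per threshold mask; NaN once the mask shrinks
    below ``min_voxels`` (the curve is truncated, logged)."""
    curve = np.full(len(masks), np.nan)
    for k, mask in enumerate(masks):
        flat = np.asarray(mask).ravel()
        if flat.sum() < max(min_voxels, 2):
            logger.info("mask %d below %d voxels; curve truncated", k, min_voxels)
            continue
        curve[k] = pattern_reliability(half1, half2, flat)
    return curve


def select_threshold(thresholds: np.ndarray,
                     curves: dict[str, np.ndarray]) -> tuple[float, int]:
    """Pick the threshold balancing pattern reliability across regions.

    Each region's curve is z-scored across the thresholds where every
    region is valid, the z curves are averaged, and the argmax taken; ties
    break toward the lower threshold.  A region with zero variance across
    thresholds contributes a zero z-curve (logged).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    valid = np.ones(len(thresholds), dtype=bool)
    for c in curves.values():
        valid &= ~np.isnan(np.asarray(c, dtype=float))
    if valid.sum() < 2:
        raise ValueError("need >= 2 thresholds with valid curves in every ROI")
    zsum = np.zeros(int(valid.sum()))
    for name, c in curves.items():
        c = np.asarray(c, dtype=float)[valid]
        sd = c.std(ddof=0)
        if sd == 0:
            logger.warning("ROI %r has zero variance across thresholds", name)
            continue
        zsum += (c - c.mean()) / sd
    idx_valid = np.flatnonzero(valid)
    best = idx_valid[int(np.argmax(zsum / max(len(curves), 1)))]
    return float(thresholds[best]), int(best)


class ReliabilityVoxelSelector(BaseEstimator):
    """RBVS as a scikit-learn style estimator.

    Parameters
    ----------
    region_masks : dict mapping region name -> boolean search-region mask
        (grid-shaped).  The peak voxel is the reliability-map argmax
        within each region.
    threshold_range : (low, high) voxelwise-reliability range examined.
    threshold_step : grid step over the range.
    connectivity : cluster adjacency (1 = faces).
    min_voxels : ROI floor below which the curve is truncated.

    Attributes
    ----------
    reliability_map_ : group voxelwise reliability (grid-shaped).
    peaks_ : per-region peak voxel coordinates.
    curves_ : per-region pattern-reliability curve over thresholds.
    thresholds_ : the examined threshold grid.
    selected_threshold_ : the z-balanced choice.
    masks_ : final per-region ROI masks at the selected threshold.
    """

    def __init__(self, region_masks=None, threshold_range=(0.16, 0.42),
                 threshold_step=0.002, connectivity=1,
                 min_voxels=MIN_ROI_VOXELS):
        self.region_masks = region_masks
        self.threshold_range = threshold_range
        self.threshold_step = threshold_step
        self.connectivity = connectivity
        self.min_voxels = min_voxels

    def fit(self, halves, y=None, grid_shape=None):
        half1, half2 = halves
        half1 = np.asarray(half1, dtype=float)
        half2 = np.asarray(half2, dtype=float)
        if grid_shape is None:
            if self.region_masks:
                grid_shape = next(iter(self.region_masks.values())).shape
            else:
                raise ValueError("grid_shape required without region masks")
        rel = voxelwise_reliability_map(half1, half2, grid_shape)
        regions = self.region_masks or {"whole": np.ones(grid_shape, bool)}

        lo, hi = self.threshold_range
        thresholds = np.arange(lo, hi + self.threshold_step / 2,
                               self.threshold_step)
        peaks, per_region_masks, curves = {}, {}, {}
        for name, region in regions.items():
            masked = np.where(region, rel, -np.inf)
            peaks[name] = np.unravel_index(int(np.argmax(masked)), grid_shape)
            masks = [grow_cluster_roi(rel, th, peaks[name], self.connectivity)
                     for th in thresholds]
            per_region_masks[name] = masks
            curves[name] = pattern_reliability_curve(
                half1, half2, masks, self.min_voxels)

        sel, idx = select_threshold(thresholds, curves)
        self.reliability_map_ = rel
        self.peaks_ = peaks
        self.thresholds_ = thresholds
        self.curves_ = curves
        self.selected_threshold_ = sel
        self.masks_ = {name: per_region_masks[name][idx] for name in regions}
        return self
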