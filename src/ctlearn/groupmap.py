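"""Behaviourally weighted group statistical image and cluster reporting.

Each subject's Repeated-Random contrast image is multiplied by that
subject's behavioural difference-score weight; the weighted images are
summed and divided by the square root of the number of subjects, giving a
voxelwise brain-behaviour correlation statistic.  The image is thresholded
under a one-sided standard-normal null (positive correlations) and
suprathreshold voxels are kept only in connected clusters above a minimum
extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import GroupConfig

__all__ = ["WeightedGroupImage", "Cluster", "ClusterReport", "weight_and_sum",
           "threshold_and_cluster", "day_overlap"]


@dataclass
class WeightedGroupImage:
    """Voxelwise group statistic sum(w_i * c_i) / sqrt(N)."""

    data: np.ndarray
    measure: str = ""
    day: int = 1
    n_subjects: int = 0
    weights_centered: bool = False
    affine: np.ndarray | None = None


@dataclass(frozen=True)
class Cluster:
    size_voxels: int
    peak_coordinate: tuple
    peak_value: float
    peak_mm: tuple | None = None


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    threshold_p: float
    threshold_z: float
    cluster_min_voxels: int
    mask: np.ndarray = None
    labels: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "size_voxels": c.size_voxels,
            "peak_x": c.peak_coordinate[0], "peak_y": c.peak_coordinate[1],
            "peak_z": c.peak_coordinate[2], "peak_value": c.peak_value,
        } for c in self.clusters])


def weight_and_sum(contrasts, weights, center_weights: bool = False,
                   measure: str = "", day: int = 1,
                   affine: np.ndarray | None = None) -> WeightedGroupImage:
    """Weighted group image: sum over subjects of w_i * c_i, over sqrt(N).

    ``contrasts`` maps subject id -> 3-D statistic array (or an ordered
    sequence of arrays); ``weights`` maps subject id -> scalar weight (or a
    matching sequence).  Optional mean-centering of the weights removes the
    confound that regions active uniformly in every subject correlate with
    any all-positive weight vector; the default (off) is the literal
    summed-image procedure.
    """
    if isinstance(contrasts, dict):
        subjects = sorted(contrasts)
        if not isinstance(weights, dict):
            raise TypeError("weights must be a dict when contrasts is a dict")
        missing = [s for s in subjects if s not in weights]
        if missing:
            raise ValueError(f"missing weights for subjects: {missing}")
        imgs = [np.asarray(contrasts[s], dtype=float) for s in subjects]
        w = np.array([weights[s] for s in subjects], dtype=float)
    else:
        imgs = [np.asarray(c, dtype=float) for c in contrasts]
        w = np.asarray(weights, dtype=float)
        if len(imgs) != w.size:
            raise ValueError("one weight per contrast image required")
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"contrast images on different grids: {shapes}")
    if center_weights:
        w = w - w.mean()
    n = len(imgs)
    data = np.zeros(imgs[0].shape)
    for wi, im in zip(w, imgs):
        data += wi * im
    data /= np.sqrt(n)
    return WeightedGroupImage(data=data, measure=measure, day=day, n_subjects=n,
                              weights_centered=center_weights, affine=affine)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def threshold_and_cluster(img: WeightedGroupImage | np.ndarray,
                          p_threshold: float = 0.005,
                          min_cluster_voxels: int = 200,
                          connectivity: int = 6) -> ClusterReport:
    """One-sided threshold under a standard-normal null plus cluster extent.

    Voxels with statistic above ``z_crit = Phi^-1(1 - p)`` are labelled by
    the requested 3-D connectivity (6 face / 18 edge / 26 corner
    neighbours); clusters smaller than ``min_cluster_voxels`` are dropped.
    Clusters are reported largest first with 0-based peak coordinates (and
    peak mm positions when an affine is attached).
    """
    data = img.data if isinstance(img, WeightedGroupImage) else np.asarray(img)
    affine = img.affine if isinstance(img, WeightedGroupImage) else None
    if not np.all(np.isfinite(data)):
        raise ValueError("group image must be finite")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    z_crit = float(stats.norm.isf(p_threshold))
    supra = data > z_crit
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_labels = ndimage.label(supra, structure=structure)
    clusters = []
    keep = np.zeros_like(supra)
    for lab in range(1, n_labels + 1):
        mask = labels == lab
        size = int(mask.sum())
        if size < min_cluster_voxels:
            labels[mask] = 0
            continue
        keep |= mask
        vals = np.where(mask, data, -np.inf)
        peak = np.unravel_index(np.argmax(vals), data.shape)
        peak_mm = None
        if affine is not None:
            peak_mm = tuple((affine @ np.array([*peak, 1.0]))[:3])
        clusters.append(Cluster(size_voxels=size, peak_coordinate=tuple(int(i) for i in peak),
                                peak_value=float(data[peak]), peak_mm=peak_mm))
    clusters.sort(key=lambda c: c.size_voxels, reverse=True)
    return ClusterReport(clusters=clusters, threshold_p=p_threshold,
                         threshold_z=z_crit, cluster_min_voxels=min_cluster_voxels,
                         mask=keep, labels=labels)


def day_overlap(report_day1: ClusterReport | np.ndarray,
                report_day7: ClusterReport | np.ndarray):
    """Separate performance-related from learning-specific activation.

    Voxels suprathreshold on both day 1 and day 7 are deemed
    performance-related; the learning-specific mask is the day-7
    suprathreshold set minus that overlap.  Returns
    ``(overlap_mask, learning_specific_mask)``.
    """
    m1 = report_day1.mask if isinstance(report_day1, ClusterReport) else np.asarray(report_day1, bool)
    m7 = report_day7.mask if isinstance(report_day7, ClusterReport) else np.asarray(report_day7, bool)
    if m1.shape != m7.shape:
        raise ValueError("day-1 and day-7 masks are on different grids")
    overlap = m1 & m7
    return overlap, m7 & ~overlap
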