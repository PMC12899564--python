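"""Woody-salient-keypoint detection: candidate ranking + spatial NMS.

Candidates are the ROI points sorted ascending by wood-structure significance
(lower = more salient); the top ``Nr`` fraction is kept. A single greedy
sweep over that sorted list then enforces spatial non-maximum suppression:
each surviving point suppresses every not-yet-visited candidate within the
suppression radius, so the final keypoints are pairwise at least that radius
apart and each is the WSS minimum of its own neighborhood at its turn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .features import EigenFeatureTable, compute_features, segment_roi
from .params import MethodParams
from .pointcloud import PointCloud, voxel_downsample

__all__ = ["KeypointSet", "select_candidates", "nms", "detect_wsk"]


@dataclass
class KeypointSet:
    """Keypoint indices into a cloud with their WSS saliency values."""

    cloud: PointCloud
    indices: np.ndarray   # indices into cloud.points
    wss: np.ndarray       # matching WSS values, ascending for both stages
    stage: str            # "candidate" | "final"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.wss = np.asarray(self.wss, dtype=float)
        if self.indices.shape != self.wss.shape:
            raise ValueError("indices and wss must be parallel arrays")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("keypoint indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def points(self) -> np.ndarray:
        return self.cloud.points[self.indices]


def select_candidates(roi_indices: np.ndarray, features: EigenFeatureTable,
                      ratio: float, cloud: PointCloud) -> KeypointSet:
    """Top ``ceil(ratio * |ROI|)`` ROI points in ascending-WSS order.

    Ties in WSS break toward the lower original index, which makes the
    ordering (and everything downstream) fully deterministic.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    roi_indices = np.asarray(roi_indices, dtype=np.int64)
    if roi_indices.size == 0:
        warnings.warn("empty ROI: no keypoint candidates")
        return KeypointSet(cloud, np.empty(0, np.int64), np.empty(0), "candidate")
    wss = features.WSS[roi_indices]
    order = np.lexsort((roi_indices, wss))
    keep = order[: ceil(ratio * len(roi_indices))]
    return KeypointSet(cloud, roi_indices[keep], wss[keep], "candidate")


def nms(candidates: KeypointSet, radius: float) -> KeypointSet:
    """Greedy non-maximum suppression over the ascending-WSS candidate list.

    Sweeping in saliency order, an unsuppressed candidate is kept and every
    unsuppressed candidate within ``radius`` of it is suppressed, so kept
    keypoints end up pairwise >= ``radius`` apart.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(candidates)
    if n == 0:
        return KeypointSet(candidates.cloud, np.empty(0, np.int64), np.empty(0), "final")
    if np.any(np.diff(candidates.wss) < 0):
        raise ValueError("candidates must be sorted ascending by WSS")
    pts = candidates.points
    tree = cKDTree(pts)
    suppressed = np.zeros(n, dtype=bool)
    kept: list[int] = []
    for i in range(n):
        if suppressed[i]:
            continue
        kept.append(i)
        for j in tree.query_ball_point(pts[i], radius):
            if j != i:
                suppressed[j] = True
    kept_arr = np.array(kept, dtype=np.int64)
    return KeypointSet(candidates.cloud, candidates.indices[kept_arr],
                       candidates.wss[kept_arr], "final")


def detect_wsk(cloud: PointCloud, params: Optional[MethodParams] = None,
               features: Optional[EigenFeatureTable] = None,
               downsample: bool = False) -> KeypointSet:
    """Full detector: ROI segmentation -> WSS ranking -> NMS.

    The cloud is expected to be voxel-downsampled already (pass
    ``downsample=True`` to do it here). Raises if fewer than 3 keypoints
    survive, since registration is impossible downstream.
    """
    params = params or MethodParams()
    if downsample:
        cloud = voxel_downsample(cloud, params.voxel_size)
    if features is None:
        features = compute_features(cloud, params.feature_radius)
    roi = segment_roi(cloud, params, features)
    candidates = select_candidates(roi, features, params.keypoint_ratio, cloud)
    keypoints = nms(candidates, params.nms_radius)
    if len(keypoints) < 3:
        raise RuntimeError(
            f"keypoint detection produced {len(keypoints)} keypoints (< 3); "
            f"ROI had {len(roi)} points — registration is impossible")
    return keypoints
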