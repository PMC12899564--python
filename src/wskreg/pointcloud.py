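"""Point-cloud container, semantic labels, and voxel-grid downsampling."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np

from .transforms import RigidTransform

__all__ = ["Label", "PointCloud", "voxel_downsample", "apply_transform"]


class Label(IntEnum):
    """Per-point semantic category of a plantation scene."""

    TRUNK = 0
    BRANCH = 1
    LEAF = 2
    GROUND = 3
    UNKNOWN = 4


_LABEL_NAMES = {lbl.name.lower(): lbl for lbl in Label}


def _coerce_labels(labels, n: int) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        try:
            arr = np.array([_LABEL_NAMES[str(s).lower()] for s in arr], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"unknown label name {exc}") from None
    else:
        arr = arr.astype(np.int8)
    if arr.shape != (n,):
        raise ValueError(f"labels must have one entry per point ({n}), got shape {arr.shape}")
    return arr


@dataclass
class PointCloud:
    """An ordered set of 3D points in meters.

    Parameters
    ----------
    points : (n, 3) float array
        Coordinates in meters, right-handed, z up.
    labels : (n,) int array, optional
        Per-point semantic category (:class:`Label` codes, or names on input).
    source : str
        Provenance tag: ``"ULS"``, ``"HLS"``, ``"synthetic"`` or ``"other"``.
    ids : (n,) int array, optional
        Provenance indices into a parent cloud (used by the simulator to keep
        point identity across platform samplings for index-matched RMSE).
    """

    points: np.ndarray
    labels: Optional[np.ndarray] = None
    source: str = "other"
    ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            bad = int(np.flatnonzero(~np.isfinite(pts).all(axis=1))[0])
            raise ValueError(f"non-finite coordinates at point {bad}")
        self.points = pts
        if self.labels is not None:
            self.labels = _coerce_labels(self.labels, len(pts))
        if self.ids is not None:
            self.ids = np.asarray(self.ids, dtype=np.int64)
            if self.ids.shape != (len(pts),):
                raise ValueError("ids must have one entry per point")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index) -> "PointCloud":
        """Sub-cloud at the given indices / boolean mask (order preserved)."""
        return PointCloud(
            self.points[index],
            None if self.labels is None else self.labels[index],
            self.source,
            None if self.ids is None else self.ids[index],
        )

    def transformed(self, T: RigidTransform) -> "PointCloud":
        return PointCloud(T.apply(self.points), self.labels, self.source, self.ids)


def apply_transform(cloud: PointCloud, T: RigidTransform) -> PointCloud:
    """Map every point through ``T``; labels and ids are preserved."""
    return cloud.transformed(T)


def voxel_downsample(cloud: PointCloud, cell: float) -> PointCloud:
    """Uniform-grid downsampling: one centroid per occupied cubic cell.

    The grid is anchored at ``floor(min / cell)`` of the cloud itself, which
    makes the result independent of point order but (deliberately) not of a
    rigid motion applied beforehand. Labels are carried over by per-cell
    majority vote (ties to the smallest label code); ids are dropped.
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    if len(cloud) == 0:
        return PointCloud(np.empty((0, 3)), source=cloud.source)
    pts = cloud.points
    anchor = np.floor(pts.min(axis=0) / cell) * cell
    idx3 = np.floor((pts - anchor) / cell).astype(np.int64)
    # lexicographic cell key -> stable deterministic output order
    order = np.lexsort((idx3[:, 2], idx3[:, 1], idx3[:, 0]))
    keys, inverse = np.unique(idx3[order], axis=0, return_inverse=True)
    n_cells = len(keys)
    sums = np.zeros((n_cells, 3))
    counts = np.bincount(inverse, minlength=n_cells).astype(float)
    for k in range(3):
        sums[:, k] = np.bincount(inverse, weights=pts[order, k], minlength=n_cells)
    centroids = sums / counts[:, None]
    labels = None
    if cloud.labels is not None:
        lab = cloud.labels[order].astype(np.int64)
        n_lab = int(lab.max()) + 1
        votes = np.zeros((n_cells, n_lab), dtype=np.int64)
        np.add.at(votes, (inverse, lab), 1)
        labels = votes.argmax(axis=1).astype(np.int8)
    return PointCloud(centroids, labels, cloud.source)
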