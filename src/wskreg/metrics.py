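"""Registration accuracy metrics and keypoint-quality statistics.

Global alignment between a reference cloud and a transformed cloud is
summarized by three numbers: the angles between rank-paired principal
(PCA) axes of the two clouds (per-axis rotational error, sign-folded to
<= 90 degrees), the Euclidean distance between the centroids (translational
error), and the RMSE over valid corresponding point pairs. Keypoint sets
are additionally characterized by repeatability under a known ground-truth
transform and by the average nearest-neighbor distance (ANND).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud import PointCloud
from .transforms import RigidTransform

__all__ = ["EvaluationReport", "principal_axis_angles", "centroid_distance",
           "rmse", "keypoint_repeatability", "annd", "evaluate_alignment"]


@dataclass
class EvaluationReport:
    """Alignment metrics between a reference and a transformed cloud."""

    axis_angles_deg: tuple      # (theta1, theta2, theta3), each in [0, 90]
    centroid_distance_m: float
    rmse_m: float
    pairing_mode: str           # "index" | "nn"
    n_pairs: int

    def to_dict(self) -> dict:
        return {"theta_deg": list(self.axis_angles_deg),
                "centroid_distance_m": self.centroid_distance_m,
                "rmse_m": self.rmse_m, "pairing_mode": self.pairing_mode,
                "n_pairs": self.n_pairs}


def _principal_axes(points: np.ndarray) -> np.ndarray:
    """Columns = unit principal axes in descending eigenvalue order."""
    d = points - points.mean(axis=0)
    C = d.T @ d / len(points)
    lam, vecs = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    if lam[1] <= max(lam[0], 0.0) * 1e-12:
        raise ValueError("degenerate covariance: axis 2 undefined (cloud is collinear)")
    return vecs[:, order]


def principal_axis_angles(P_star: PointCloud, P_prime: PointCloud):
    """Angles (degrees) between rank-paired principal axes of the two clouds.

    Axis sign is arbitrary in PCA, so each angle is folded through |dot| to
    [0, 90] degrees.
    """
    for name, c in (("reference", P_star), ("transformed", P_prime)):
        if len(c) < 3:
            raise ValueError(f"{name} cloud needs >= 3 points")
    V1 = _principal_axes(P_star.points)
    V2 = _principal_axes(P_prime.points)
    angles = []
    for k in range(3):
        a, b = V1[:, k], V2[:, k]
        if a @ b < 0:
            b = -b
        # atan2 form is stable near 0 where arccos loses ~1e-8 of precision
        angles.append(np.degrees(np.arctan2(np.linalg.norm(np.cross(a, b)), a @ b)))
    return tuple(angles)


def centroid_distance(P_star: PointCloud, P_prime: PointCloud) -> float:
    """Euclidean distance between the cloud centroids, meters."""
    if len(P_star) == 0 or len(P_prime) == 0:
        raise ValueError("centroid distance of an empty cloud is undefined")
    return float(np.linalg.norm(P_star.points.mean(axis=0) - P_prime.points.mean(axis=0)))


def rmse(P_star: PointCloud, P_prime: PointCloud, pairing: str = "index",
         cutoff: float = 0.45):
    """Root-mean-square pair distance over valid corresponding points.

    ``pairing="index"`` assumes shared point identity (equal counts);
    ``pairing="nn"`` pairs each transformed point with its nearest reference
    point within ``cutoff`` (default 3x the 0.15 m voxel size). Returns
    ``(rmse, n_pairs)``.
    """
    if pairing == "index":
        if len(P_star) != len(P_prime):
            raise ValueError("index pairing requires equal point counts")
        if len(P_star) == 0:
            raise ValueError("no valid pairs")
        d2 = np.sum((P_star.points - P_prime.points) ** 2, axis=1)
        return float(np.sqrt(d2.mean())), len(d2)
    if pairing == "nn":
        tree = cKDTree(P_star.points)
        d, _ = tree.query(P_prime.points, distance_upper_bound=cutoff)
        d = d[np.isfinite(d)]
        if len(d) == 0:
            raise ValueError(f"no valid pairs within cutoff {cutoff} m")
        return float(np.sqrt(np.mean(d ** 2))), len(d)
    raise ValueError(f"unknown pairing mode {pairing!r}")


def keypoint_repeatability(K_src: np.ndarray, K_tgt: np.ndarray,
                           T_gt: RigidTransform,
                           thresholds=(0.15, 0.3, 0.45, 0.6)) -> dict:
    """Fraction of source keypoints with a target keypoint within each threshold
    after ground-truth alignment. Keys are the thresholds in meters."""
    K_src = np.asarray(K_src, float).reshape(-1, 3)
    K_tgt = np.asarray(K_tgt, float).reshape(-1, 3)
    if len(K_src) == 0 or len(K_tgt) == 0:
        raise ValueError("keypoint sets must be non-empty")
    moved = T_gt.apply(K_src)
    d, _ = cKDTree(K_tgt).query(moved)
    return {float(thr): float(np.mean(d <= thr)) for thr in thresholds}


def annd(points: np.ndarray) -> float:
    """Average distance from each keypoint to its nearest fellow keypoint."""
    points = np.asarray(points, float).reshape(-1, 3)
    if len(points) < 2:
        raise ValueError("ANND needs >= 2 keypoints")
    d, _ = cKDTree(points).query(points, k=2)
    return float(d[:, 1].mean())


def evaluate_alignment(P_star: PointCloud, P_prime: PointCloud,
                       pairing: str = "nn", cutoff: float = 0.45) -> EvaluationReport:
    """All three global metrics in one report."""
    err, n = rmse(P_star, P_prime, pairing=pairing, cutoff=cutoff)
    return EvaluationReport(principal_axis_angles(P_star, P_prime),
                            centroid_distance(P_star, P_prime), err, pairing, n)
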