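"""Per-point eigenvalue geometry, saliency scores, and ROI segmentation.

Each point gets a local covariance over its fixed-radius neighborhood (the
query point included). The sorted eigenvalues l1 >= l2 >= l3 yield the
dimensionality features

    L    = (l1 - l2) / l1          linearity
    PCA1 = l1 / (l1 + l2 + l3)     first principal component share
    Sv   = l3 / (l1 + l2 + l3)     surface variation
    P    = (l2 - l3) / l1          planarity
    S    = l3 / l1                 scatter (sphericity)

from which the two saliency scores are built:

    SSS = L + PCA1 - Sv                       higher = more woody (line-like)
    WSS = (L + (1 - Sv)) / (1 + ln(1 + P + S))   lower = more locally unique

The region of interest keeps points with SSS above a threshold tau; woody
trunks and branches (line-like, SSS -> 2) pass while isotropic foliage
(SSS -> 1/3) is rejected. S is the bounded ratio l3/l1, which keeps WSS
finite on perfect lines and preserves the "lower = bifurcation-like"
ordering of the score.

Points whose neighborhood is too small (N < 5) or degenerate (l1 ~ 0) are
invalid and carry sentinel scores: SSS = -inf (never in the ROI) and
WSS = +inf (never salient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .params import MethodParams
from .pointcloud import PointCloud

__all__ = [
    "EigenFeatureTable", "compute_features", "local_covariance",
    "eigen_features", "sss_score", "wss_score", "segment_roi",
]

MIN_NEIGHBORS = 5
EIGEN_FLOOR = 1e-12  # m^2; below this the neighborhood is degenerate


@dataclass
class EigenFeatureTable:
    """Per-point eigen-features and saliency scores for one cloud."""

    neighbor_count: np.ndarray  # (n,) int
    eigenvalues: np.ndarray     # (n, 3) descending, clamped at 0
    L: np.ndarray
    PCA1: np.ndarray
    Sv: np.ndarray
    P: np.ndarray
    S: np.ndarray
    SSS: np.ndarray
    WSS: np.ndarray
    valid: np.ndarray           # (n,) bool

    def __len__(self) -> int:
        return len(self.valid)

    def to_dataframe(self):
        """Feature dump as a pandas DataFrame (index, N, eigenvalues, scores)."""
        import pandas as pd

        return pd.DataFrame({
            "index": np.arange(len(self)), "N": self.neighbor_count,
            "lambda1": self.eigenvalues[:, 0], "lambda2": self.eigenvalues[:, 1],
            "lambda3": self.eigenvalues[:, 2], "L": self.L, "PCA1": self.PCA1,
            "Sv": self.Sv, "P": self.P, "S": self.S, "SSS": self.SSS, "WSS": self.WSS,
            "valid": self.valid,
        })


def local_covariance(cloud: PointCloud, index: int, radius: float):
    """Covariance ``C = (1/N) sum (p_i - mu)(p_i - mu)^T`` over the radius ball.

    Returns ``(C, N)``; the query point is part of its own neighborhood.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(cloud.points)
    idx = tree.query_ball_point(cloud.points[index], radius)
    nbrs = cloud.points[idx]
    mu = nbrs.mean(axis=0)
    d = nbrs - mu
    return d.T @ d / len(nbrs), len(nbrs)


def _features_from_eigenvalues(lam: np.ndarray, valid: np.ndarray):
    """Vectorized feature formulas on (n, 3) descending eigenvalues."""
    n = len(lam)
    L = np.zeros(n)
    PCA1 = np.zeros(n)
    Sv = np.zeros(n)
    P = np.zeros(n)
    S = np.zeros(n)
    v = valid
    l1, l2, l3 = lam[v, 0], lam[v, 1], lam[v, 2]
    tot = l1 + l2 + l3
    L[v] = (l1 - l2) / l1
    PCA1[v] = l1 / tot
    Sv[v] = l3 / tot
    P[v] = (l2 - l3) / l1
    S[v] = l3 / l1
    SSS = np.where(v, L + PCA1 - Sv, -np.inf)
    with np.errstate(invalid="ignore"):
        WSS = np.where(v, (L + (1.0 - Sv)) / (1.0 + np.log1p(P + S)), np.inf)
    return L, PCA1, Sv, P, S, SSS, WSS


def eigen_features(C: np.ndarray, N: int) -> dict:
    """Features for a single covariance matrix; see the module formulas."""
    lam = np.linalg.eigvalsh(np.asarray(C, float))[::-1]
    lam = np.clip(lam, 0.0, None)
    valid = bool(N >= MIN_NEIGHBORS and lam[0] > EIGEN_FLOOR)
    L, PCA1, Sv, P, S, SSS, WSS = _features_from_eigenvalues(
        lam[None, :], np.array([valid]))
    return {"eigenvalues": lam, "N": N, "valid": valid,
            "L": L[0], "PCA1": PCA1[0], "Sv": Sv[0], "P": P[0], "S": S[0],
            "SSS": SSS[0], "WSS": WSS[0]}


def sss_score(features: dict) -> float:
    """Structural significance ``L + PCA1 - Sv`` (-inf for invalid records)."""
    return float(features["SSS"])


def wss_score(features: dict) -> float:
    """Wood-structure significance ``(L + (1 - Sv)) / (1 + ln(1 + P + S))``.

    Lower values mark locally unique woody structure (branch bifurcations);
    invalid records carry +inf.
    """
    return float(features["WSS"])


def compute_features(cloud: PointCloud, radius: float) -> EigenFeatureTable:
    """Eigen-features for every point of the cloud at one support radius.

    Covariances are accumulated over all radius-neighborhoods at once via the
    flattened neighbor-pair list, then diagonalized with a batched symmetric
    eigendecomposition — O(total pairs) memory, no per-point Python loop.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = cloud.points
    n = len(pts)
    if n == 0:
        z = np.zeros(0)
        return EigenFeatureTable(np.zeros(0, int), np.zeros((0, 3)), z, z, z, z, z,
                                 z.copy(), z.copy(), np.zeros(0, bool))
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")  # i < j, no self-pairs
    qi = np.concatenate([pairs[:, 0], pairs[:, 1]])
    ni = np.concatenate([pairs[:, 1], pairs[:, 0]])
    counts = np.bincount(qi, minlength=n) + 1  # + the point itself
    sums = np.zeros((n, 3))
    outer = np.zeros((n, 3, 3))
    nbr = pts[ni]
    for k in range(3):
        sums[:, k] = np.bincount(qi, weights=nbr[:, k], minlength=n)
        for m in range(k, 3):
            acc = np.bincount(qi, weights=nbr[:, k] * nbr[:, m], minlength=n)
            outer[:, k, m] = acc
            outer[:, m, k] = acc
    sums += pts
    outer += pts[:, :, None] * pts[:, None, :]
    mu = sums / counts[:, None]
    C = outer / counts[:, None, None] - mu[:, :, None] * mu[:, None, :]
    C = 0.5 * (C + np.transpose(C, (0, 2, 1)))
    lam = np.linalg.eigvalsh(C)[:, ::-1]
    lam = np.clip(lam, 0.0, None)
    valid = (counts >= MIN_NEIGHBORS) & (lam[:, 0] > EIGEN_FLOOR)
    L, PCA1, Sv, P, S, SSS, WSS = _features_from_eigenvalues(lam, valid)
    return EigenFeatureTable(counts, lam, L, PCA1, Sv, P, S, SSS, WSS, valid)


def segment_roi(cloud: PointCloud, params: MethodParams,
                features: EigenFeatureTable | None = None) -> np.ndarray:
    """Indices of the region of interest: points with ``SSS > tau``.

    Invalid points are never part of the ROI. An empty result triggers a
    warning but is returned as-is for the caller to handle.
    """
    if features is None:
        features = compute_features(cloud, params.feature_radius)
    roi = np.flatnonzero(features.SSS > params.roi_tau)
    if roi.size == 0:
        warnings.warn("ROI segmentation produced an empty set "
                      f"(tau={params.roi_tau}); no woody structure found")
    return roi
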