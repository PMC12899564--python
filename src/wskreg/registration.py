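"""Robust global rigid-transform estimation and the end-to-end pipeline.

The transform is estimated from the filtered keypoint correspondences with a
fast-global-registration style solver: the scaled Geman-McClure cost
``sum_i mu * r_i^2 / (mu + r_i^2)`` is minimized over SE(3) by graduated
non-convexity — the control parameter mu starts at the squared diameter of
the correspondence span and is divided by 1.4 every 4 of 64 Gauss-Newton
iterations on a linearized motion, with the rotation re-projected onto SO(3)
each step. Correspondences therefore need no inlier pre-selection; gross
outliers are progressively down-weighted as mu shrinks.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .detector import detect_wsk
from .matching import (CorrespondenceSet, nearest_descriptor_matches,
                       reciprocity_wss_filter, tuple_test)
from .params import MethodParams
from .pointcloud import PointCloud, voxel_downsample
from .shot import compute_descriptors, estimate_normals
from .transforms import RigidTransform

__all__ = ["RegistrationResult", "estimate_transform_fgr", "register", "icp_refine"]

FGR_ITERATIONS = 64        # minimum Gauss-Newton iterations
FGR_MU_DECAY = 1.4
FGR_MU_EVERY = 4
FGR_MU_FLOOR = 1e-4        # m^2: anneal mu down to the ~1 cm inlier scale
FGR_MAX_ITERATIONS = 400


@dataclass
class RegistrationResult:
    """Outcome of the registration pipeline with per-stage diagnostics."""

    transform: RigidTransform
    counts: dict = field(default_factory=dict)      # per-stage correspondence/keypoint counts
    timings: dict = field(default_factory=dict)     # per-stage wall-times, seconds
    trace: list = field(default_factory=list)       # FGR objective per iteration

    def summary(self) -> str:
        lines = ["registration summary", "--------------------"]
        for k, v in self.counts.items():
            lines.append(f"{k:>24}: {v}")
        for k, v in self.timings.items():
            lines.append(f"{k:>24}: {v:.3f} s")
        return "\n".join(lines)


def _project_rotation(M: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


def estimate_transform_fgr(pairs: np.ndarray, source_coords: np.ndarray,
                           target_coords: np.ndarray,
                           iterations: int | None = None,
                           mu_floor: float = FGR_MU_FLOOR):
    """Estimate the rigid motion mapping source onto target from index pairs.

    ``pairs`` is (m, 2) of (source slot, target slot) into the coordinate
    arrays. Returns ``(RigidTransform, trace)`` where the trace records the
    robust objective per iteration. Raises on fewer than 3 pairs or a
    collinear correspondence support.

    With ``iterations=None`` (default) the solver runs at least the published
    64 iterations and keeps annealing until mu reaches ``mu_floor`` — on
    plot-scale scenes (tens of meters) the graduated schedule needs more than
    64 steps to bring mu from the squared span diameter down to the inlier
    scale.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 correspondence pairs, got {len(pairs)}")
    p = np.asarray(source_coords, float)[pairs[:, 0]]
    q = np.asarray(target_coords, float)[pairs[:, 1]]
    centered = p - p.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("correspondence support is collinear; transform is ill-posed")
    span = np.vstack([p, q])
    mu = float(np.sum((span.max(axis=0) - span.min(axis=0)) ** 2))
    if mu <= 0:
        mu = 1.0
    R = np.eye(3)
    t = np.zeros(3)
    trace = []
    if iterations is None:
        n_anneal = int(np.ceil(np.log(mu / max(mu_floor, 1e-300)) / np.log(FGR_MU_DECAY)))
        iterations = min(FGR_MAX_ITERATIONS,
                         max(FGR_ITERATIONS, FGR_MU_EVERY * (n_anneal + 1)))
    for it in range(iterations):
        if it > 0 and it % FGR_MU_EVERY == 0:
            mu = max(mu / FGR_MU_DECAY, mu_floor)
        a = p @ R.T + t
        e = a - q
        r2 = np.einsum("ij,ij->i", e, e)
        obj = float(np.sum(mu * r2 / (mu + r2)))
        if not np.isfinite(obj):
            raise RuntimeError("non-finite FGR objective; check input coordinates")
        w = (mu / (mu + r2)) ** 2
        # J_i = [-[a_i]x | I]; solve (sum w J^T J) xi = -(sum w J^T e)
        A = np.zeros((6, 6))
        b = np.zeros(6)
        ax = np.zeros((len(a), 3, 3))
        ax[:, 0, 1], ax[:, 0, 2] = -a[:, 2], a[:, 1]
        ax[:, 1, 0], ax[:, 1, 2] = a[:, 2], -a[:, 0]
        ax[:, 2, 0], ax[:, 2, 1] = -a[:, 1], a[:, 0]
        Jw = -ax  # d e / d omega = -[a]x ... sign: omega x a = -[a]x omega -> J_omega = -[a]x
        A[:3, :3] = np.einsum("n,nki,nkj->ij", w, Jw, Jw)
        A[:3, 3:] = np.einsum("n,nki->ik", w, Jw)
        A[3:, :3] = A[:3, 3:].T
        A[3:, 3:] = np.eye(3) * w.sum()
        b[:3] = np.einsum("n,nki,nk->i", w, Jw, e)
        b[3:] = np.einsum("n,nk->k", w, e)
        try:
            xi = np.linalg.solve(A + 1e-12 * np.eye(6), -b)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular normal equations in FGR update") from None
        # step halving keeps the objective non-increasing within a mu block
        scale = 1.0
        for _ in range(12):
            dR = Rotation.from_rotvec(xi[:3] * scale).as_matrix()
            R_new = _project_rotation(dR @ R)
            t_new = dR @ t + xi[3:] * scale
            e_new = p @ R_new.T + t_new - q
            r2_new = np.einsum("ij,ij->i", e_new, e_new)
            if np.sum(mu * r2_new / (mu + r2_new)) <= obj + 1e-15:
                R, t = R_new, t_new
                break
            scale *= 0.5
        trace.append(obj)
    return RigidTransform(R, t), trace


def register(source: PointCloud, target: PointCloud,
             params: MethodParams | None = None) -> RegistrationResult:
    """End-to-end registration: returns the transform mapping source -> target.

    Pipeline: voxel downsample both clouds, detect woody salient keypoints,
    describe them, match descriptors, filter by reciprocity + saliency and
    by tuple consistency, then estimate the transform robustly.
    """
    params = params or MethodParams()
    if len(source) == 0 or len(target) == 0:
        raise ValueError("cannot register empty point clouds")
    counts: dict = {}
    timings: dict = {}

    def _stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"registration stage '{name}' failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        return out

    src = _stage("downsample_source", voxel_downsample, source, params.voxel_size)
    tgt = _stage("downsample_target", voxel_downsample, target, params.voxel_size)
    counts["source_points"] = len(src)
    counts["target_points"] = len(tgt)
    kp_src = _stage("keypoints_source", detect_wsk, src, params)
    kp_tgt = _stage("keypoints_target", detect_wsk, tgt, params)
    counts["source_keypoints"] = len(kp_src)
    counts["target_keypoints"] = len(kp_tgt)

    def _describe(cloud, kps):
        normals, nvalid = estimate_normals(cloud, params.feature_radius)
        return compute_descriptors(cloud, kps.indices, params.descriptor_radius,
                                   normals=normals, normal_valid=nvalid)

    ds_src = _stage("describe_source", _describe, src, kp_src)
    ds_tgt = _stage("describe_target", _describe, tgt, kp_tgt)
    C_P, C_Q = _stage("nearest_matches", nearest_descriptor_matches, ds_src, ds_tgt)
    counts["initial_matches"] = len(C_P)
    K_II = _stage("reciprocity_wss", reciprocity_wss_filter, C_P, C_Q,
                  kp_src.wss, kp_tgt.wss, params.wss_delta)
    counts["reciprocal_matches"] = len(K_II)
    K_III = _stage("tuple_test", tuple_test, K_II, kp_src.points, kp_tgt.points,
                   params.tuple_alpha, params.max_tuples, params.seed)
    counts["tuple_matches"] = len(K_III)
    # anneal mu down to the preprocessing resolution: keypoint correspondences
    # carry voxel-scale noise, so a deeper anneal would overfit a tight subset
    T, trace = _stage("fgr", estimate_transform_fgr, K_III.pairs,
                      kp_src.points, kp_tgt.points,
                      mu_floor=params.voxel_size ** 2)
    return RegistrationResult(T, counts, timings, trace)


def icp_refine(source: PointCloud, target: PointCloud, T0: RigidTransform,
               max_corr_dist: float = 0.45, max_iter: int = 50) -> RigidTransform:
    """Point-to-point ICP from the initial transform ``T0``.

    Stops on ``max_iter`` or a relative inlier-RMSE change below 1e-6, and
    never returns a transform whose inlier RMSE exceeds that of ``T0``. With
    no correspondences within ``max_corr_dist``, ``T0`` is returned with a
    warning.
    """
    tree = cKDTree(target.points)

    def _inlier_rmse(T):
        d, _ = tree.query(T.apply(source.points),
                          distance_upper_bound=max_corr_dist)
        d = d[np.isfinite(d)]
        return (np.sqrt(np.mean(d ** 2)), len(d)) if len(d) else (np.inf, 0)

    best_T = T0
    best_rmse, n0 = _inlier_rmse(T0)
    if n0 == 0:
        warnings.warn("ICP found no correspondences within "
                      f"{max_corr_dist} m; returning the initial transform")
        return T0
    T = T0
    prev = best_rmse
    for _ in range(max_iter):
        moved = T.apply(source.points)
        d, j = tree.query(moved, distance_upper_bound=max_corr_dist)
        mask = np.isfinite(d)
        if mask.sum() < 3:
            break
        src = source.points[mask]
        tgt = target.points[j[mask]]
        mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
        H = (src - mu_s).T @ (tgt - mu_t)
        R = _project_rotation(H.T)  # note: H^T gives U V^T mapping src->tgt
        t = mu_t - R @ mu_s
        T = RigidTransform(R, t)
        rmse, n = _inlier_rmse(T)
        if rmse < best_rmse:
            best_rmse, best_T = rmse, T
        if prev > 0 and abs(prev - rmse) / max(prev, 1e-300) < 1e-6:
            break
        prev = rmse
    return best_T
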