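"""Surface normals, local reference frames, and the 352-D SHOT descriptor.

The descriptor follows the published signature-of-histograms-of-orientations
layout: the support sphere is split into 32 volumes (2 radial shells x
2 elevation bands x 8 azimuth sectors) in a sign-disambiguated local
reference frame, and each volume holds an 11-bin histogram of the cosine
between the support-point normal and the keypoint normal. Contributions are
soft-assigned quadrilinearly across the radial / elevation / azimuth /
cosine boundaries (each support point distributes exactly unit mass), and
the final 352-vector is L2-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud import PointCloud

__all__ = ["DescriptorSet", "estimate_normals", "local_reference_frame",
           "shot_descriptor", "compute_descriptors"]

N_RADIAL, N_ELEV, N_AZIMUTH, N_COS = 2, 2, 8, 11
DESCRIPTOR_DIM = N_RADIAL * N_ELEV * N_AZIMUTH * N_COS  # 352


@dataclass
class DescriptorSet:
    """SHOT descriptors for a set of keypoints (zero rows = invalid support)."""

    indices: np.ndarray        # keypoint indices into the cloud
    descriptors: np.ndarray    # (k, 352), unit norm or all-zero
    valid: np.ndarray          # (k,) bool
    support_radius: float

    def to_dataframe(self):
        """Inspection dump: keypoint index + the 352 descriptor components."""
        import pandas as pd

        df = pd.DataFrame(self.descriptors,
                          columns=[f"d{i}" for i in range(self.descriptors.shape[1])])
        df.insert(0, "keypoint", self.indices)
        return df


def estimate_normals(cloud: PointCloud, radius: float):
    """Smallest-eigenvector surface normals over fixed-radius neighborhoods.

    The sign is disambiguated by the summed projection of neighbor
    displacements onto the normal (flip when negative), which is invariant
    under rigid motion. Points with fewer than 3 neighbors (including
    themselves) are flagged invalid.

    Returns ``(normals, valid)``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = cloud.points
    n = len(pts)
    if n == 0:
        return np.zeros((0, 3)), np.zeros(0, bool)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    qi = np.concatenate([pairs[:, 0], pairs[:, 1]])
    ni = np.concatenate([pairs[:, 1], pairs[:, 0]])
    counts = np.bincount(qi, minlength=n) + 1
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
    _, vecs = np.linalg.eigh(C)          # ascending eigenvalues
    normals = vecs[:, :, 0]              # smallest-eigenvalue eigenvector
    # summed neighbor displacement: sum_j (p_j - p_i) = sums - counts * p_i
    disp_sum = sums - counts[:, None] * pts
    flip = np.einsum("ij,ij->i", disp_sum, normals) < 0
    normals[flip] *= -1.0
    valid = counts >= 3
    norms = np.linalg.norm(normals, axis=1)
    normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    return normals, valid


def _lrf_from_support(disp: np.ndarray, Rf: float):
    """Local reference frame rows (x, y, z) from keypoint-centered support.

    Distance-weighted covariance with (Rf - d) weights; x and z axes are the
    largest/smallest eigenvectors, sign-disambiguated by the weighted summed
    projection of the support, and y = z cross x (right-handed).
    Returns ``(frame, valid)``.
    """
    d = np.linalg.norm(disp, axis=1)
    w = Rf - d
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if len(disp) < 5 or total <= 0:
        return np.eye(3), False
    C = (disp * w[:, None]).T @ disp / total
    lam, vecs = np.linalg.eigh(C)
    if lam[1] <= max(lam[2], 0.0) * 1e-9 + 1e-300 or lam[2] <= 1e-24:
        return np.eye(3), False  # rank-deficient (collinear/degenerate) support
    x = vecs[:, 2]
    z = vecs[:, 0]
    if (w * (disp @ x)).sum() < 0:
        x = -x
    if (w * (disp @ z)).sum() < 0:
        z = -z
    y = np.cross(z, x)
    return np.vstack([x, y, z]), True


def local_reference_frame(cloud: PointCloud, keypoint: int, Rf: float):
    """LRF at one cloud point; see :func:`_lrf_from_support`. Support is the
    radius-``Rf`` ball around the keypoint, the keypoint itself excluded."""
    tree = cKDTree(cloud.points)
    center = cloud.points[keypoint]
    idx = [i for i in tree.query_ball_point(center, Rf) if i != keypoint]
    return _lrf_from_support(cloud.points[idx] - center, Rf)


def _soft_bins(u: np.ndarray, nbins: int, wrap: bool):
    """Linear soft assignment of coordinates ``u`` (in bin units, in [0, nbins])
    to the two adjacent bins; returns (bin0, w0, bin1, w1) with w0+w1 = 1."""
    d = u - 0.5
    i0 = np.floor(d).astype(np.int64)
    f = d - i0
    i1 = i0 + 1
    if wrap:
        i0 %= nbins
        i1 %= nbins
    else:
        i0 = np.clip(i0, 0, nbins - 1)
        i1 = np.clip(i1, 0, nbins - 1)
    return i0, 1.0 - f, i1, f


def _accumulate_descriptors(kidx, local, cosang, n_key, Rf):
    """Scatter quadrilinear contributions of all (keypoint, support) pairs."""
    H = np.zeros((n_key, DESCRIPTOR_DIM))
    r = np.linalg.norm(local, axis=1)
    r = np.where(r > 0, r, 1e-300)
    u_rad = r / Rf * N_RADIAL
    u_elev = (local[:, 2] / r + 1.0) / 2.0 * N_ELEV
    azim = np.arctan2(local[:, 1], local[:, 0])          # [-pi, pi]
    u_azim = (azim + np.pi) / (2.0 * np.pi) * N_AZIMUTH
    u_cos = (np.clip(cosang, -1.0, 1.0) + 1.0) / 2.0 * N_COS
    bins = [
        _soft_bins(u_rad, N_RADIAL, wrap=False),
        _soft_bins(u_elev, N_ELEV, wrap=False),
        _soft_bins(u_azim, N_AZIMUTH, wrap=True),
        _soft_bins(u_cos, N_COS, wrap=False),
    ]
    for cr in range(2):
        ir, wr = bins[0][2 * cr], bins[0][2 * cr + 1]
        for ce in range(2):
            ie, we = bins[1][2 * ce], bins[1][2 * ce + 1]
            for ca in range(2):
                ia, wa = bins[2][2 * ca], bins[2][2 * ca + 1]
                for cc in range(2):
                    ic, wc = bins[3][2 * cc], bins[3][2 * cc + 1]
                    flat = ((ir * N_ELEV + ie) * N_AZIMUTH + ia) * N_COS + ic
                    np.add.at(H, (kidx, flat), wr * we * wa * wc)
    return H


def shot_descriptor(cloud: PointCloud, normals: np.ndarray, keypoint: int,
                    Rf: float, normal_valid: np.ndarray | None = None):
    """352-D descriptor at a single keypoint; returns ``(vector, valid)``."""
    ds = compute_descriptors(cloud, np.array([keypoint]), Rf,
                             normals=normals, normal_valid=normal_valid)
    return ds.descriptors[0], bool(ds.valid[0])


def compute_descriptors(cloud: PointCloud, keypoint_indices: np.ndarray, Rf: float,
                        normals: np.ndarray | None = None,
                        normal_valid: np.ndarray | None = None,
                        normal_radius: float = 0.5,
                        chunk_pairs: int = 4_000_000) -> DescriptorSet:
    """SHOT descriptors at the given cloud indices.

    Normals default to :func:`estimate_normals` at ``normal_radius`` (the
    eigen-feature radius is reused; no separate normal scale is introduced).
    Keypoints with a rank-deficient frame, an invalid normal, or empty
    support yield a zero descriptor flagged invalid.
    """
    keypoint_indices = np.asarray(keypoint_indices, dtype=np.int64)
    if normals is None:
        normals, normal_valid = estimate_normals(cloud, normal_radius)
    if normal_valid is None:
        normal_valid = np.ones(len(cloud), bool)
    pts = cloud.points
    k = len(keypoint_indices)
    desc = np.zeros((k, DESCRIPTOR_DIM))
    valid = np.zeros(k, bool)
    tree = cKDTree(pts)
    centers = pts[keypoint_indices]
    neighborhoods = tree.query_ball_point(centers, Rf)
    # frames (sequentially; cheap relative to binning)
    frames = np.zeros((k, 3, 3))
    frame_ok = np.zeros(k, bool)
    supports: list[np.ndarray] = []
    for s, (kp, idx) in enumerate(zip(keypoint_indices, neighborhoods)):
        idx = np.asarray(idx, dtype=np.int64)
        idx = idx[(idx != kp) & normal_valid[idx] & normal_valid[kp]]
        supports.append(idx)
        if idx.size:
            frames[s], frame_ok[s] = _lrf_from_support(pts[idx] - centers[s], Rf)
    sizes = np.array([len(s) for s in supports])
    usable = frame_ok & (sizes > 0)
    slots = np.flatnonzero(usable)
    # chunk the flattened (keypoint, support) pairs to bound memory
    start = 0
    while start < len(slots):
        end = start
        total = 0
        while end < len(slots) and (total == 0 or total + sizes[slots[end]] <= chunk_pairs):
            total += sizes[slots[end]]
            end += 1
        chunk = slots[start:end]
        kidx = np.repeat(np.arange(len(chunk)), sizes[chunk])
        sup = np.concatenate([supports[s] for s in chunk])
        disp = pts[sup] - centers[chunk][kidx]
        local = np.einsum("pij,pj->pi", frames[chunk][kidx], disp)
        # reference normal: keypoint normal, sign-aligned with the frame z-axis
        # (the frame's weighted disambiguation is far more stable than the
        # point normal's own, and a flipped reference inverts every cosine)
        kn = normals[keypoint_indices[chunk]].copy()
        zdot = np.einsum("ij,ij->i", kn, frames[chunk][:, 2, :])
        kn[zdot < 0] *= -1.0
        cosang = np.einsum("ij,ij->i", normals[sup], kn[kidx])
        H = _accumulate_descriptors(kidx, local, cosang, len(chunk), Rf)
        norms = np.linalg.norm(H, axis=1)
        nz = norms > 0
        H[nz] /= norms[nz, None]
        desc[chunk] = H
        valid[chunk] = nz
        start = end
    return DescriptorSet(keypoint_indices, desc, valid, Rf)
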