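"""Descriptor matching and correspondence filtering.

Three stages: exact nearest-neighbor matching in descriptor space (both
directions), a reciprocity test additionally gated by the saliency
constraint |WSS(p) - WSS(q)| < delta, and a seeded tuple-consistency test
that keeps pairs belonging to at least one sampled triplet whose three
cross-cloud distance ratios all lie in [alpha, 1/alpha].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .shot import DescriptorSet

__all__ = ["CorrespondenceSet", "nearest_descriptor_matches",
           "reciprocity_wss_filter", "tuple_test"]


@dataclass
class CorrespondenceSet:
    """Index pairs across two keypoint sets at one filtering stage."""

    pairs: np.ndarray  # (m, 2) — (source slot, target slot)
    stage: str         # "initial" | "reciprocal" | "tuple"

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_dataframe(self):
        """Export as (src_idx, tgt_idx, stage) rows."""
        import pandas as pd

        return pd.DataFrame({"src_idx": self.pairs[:, 0],
                             "tgt_idx": self.pairs[:, 1], "stage": self.stage})


def _descriptor_matrix(ds: DescriptorSet) -> np.ndarray:
    return np.asarray(ds.descriptors, dtype=float)


def nearest_descriptor_matches(F_P: DescriptorSet, F_Q: DescriptorSet):
    """Exact nearest neighbors in both directions.

    Returns ``(C_P, C_Q)``: C_P maps every valid source slot to its nearest
    valid target slot, and symmetrically for C_Q. Distances are Euclidean on
    the unit descriptors (monotone in cosine distance); invalid (all-zero)
    descriptors are excluded.
    """
    A, B = _descriptor_matrix(F_P), _descriptor_matrix(F_Q)
    va = np.flatnonzero(np.asarray(F_P.valid))
    vb = np.flatnonzero(np.asarray(F_Q.valid))
    if va.size == 0 or vb.size == 0:
        raise ValueError("all descriptors invalid on one side; cannot match")
    # unit vectors: argmin ||a-b|| == argmax a.b
    sim = A[va] @ B[vb].T
    cp = vb[np.argmax(sim, axis=1)]
    cq = va[np.argmax(sim, axis=0)]
    C_P = CorrespondenceSet(np.column_stack([va, cp]), "initial")
    C_Q = CorrespondenceSet(np.column_stack([cq, vb]), "initial")
    return C_P, C_Q


def reciprocity_wss_filter(C_P: CorrespondenceSet, C_Q: CorrespondenceSet,
                           wss_source: np.ndarray, wss_target: np.ndarray,
                           delta: float) -> CorrespondenceSet:
    """Mutual-nearest-neighbor pairs with |WSS(p) - WSS(q)| < delta."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    back = {int(q): int(p) for p, q in C_Q.pairs}
    kept = []
    for p, q in C_P.pairs:
        if back.get(int(q), -1) != int(p):
            continue
        if abs(wss_source[p] - wss_target[q]) < delta:
            kept.append((p, q))
    if not kept:
        warnings.warn("reciprocity + WSS filtering removed every correspondence")
    return CorrespondenceSet(np.array(kept, dtype=np.int64).reshape(-1, 2), "reciprocal")


def tuple_test(K_II: CorrespondenceSet, source_coords: np.ndarray,
               target_coords: np.ndarray, alpha: float = 0.9,
               max_tuples: int = 1000, seed: int = 0) -> CorrespondenceSet:
    """Geometric-consistency filter over randomly sampled correspondence triplets.

    ``source_coords[s]`` / ``target_coords[t]`` give the 3D position of slot
    ``s`` / ``t``. A triplet passes when all three distance ratios
    ``|p_i - p_j| / |q_i - q_j|`` lie in [alpha, 1/alpha]; the union of
    pairs of passing triplets (deduplicated, in first-pass order) is K_III.
    Triplets containing coincident points are discarded, not failed.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = len(K_II)
    if m < 3:
        raise ValueError(f"tuple test needs >= 3 correspondences, got {m}")
    rng = np.random.default_rng(seed)
    p = source_coords[K_II.pairs[:, 0]]
    q = target_coords[K_II.pairs[:, 1]]
    keep = np.zeros(m, dtype=bool)
    order: list[int] = []
    n_pass = 0
    for _ in range(max_tuples):
        i, j, k = rng.choice(m, size=3, replace=False)
        ok = True
        degenerate = False
        for a, b in ((i, j), (i, k), (j, k)):
            dp = np.linalg.norm(p[a] - p[b])
            dq = np.linalg.norm(q[a] - q[b])
            if dq <= 0 or dp <= 0:
                degenerate = True
                break
            r = dp / dq
            if not (alpha <= r <= 1.0 / alpha):
                ok = False
                break
        if degenerate or not ok:
            continue
        n_pass += 1
        for a in (i, j, k):
            if not keep[a]:
                keep[a] = True
                order.append(int(a))
    if n_pass == 0:
        raise RuntimeError(
            f"no tuple passed the consistency test (alpha={alpha}, "
            f"{max_tuples} samples over {m} correspondences); the "
            "correspondence set is likely dominated by outliers")
    return CorrespondenceSet(K_II.pairs[np.array(order, dtype=np.int64)], "tuple")
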