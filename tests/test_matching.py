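"""Descriptor matching, reciprocity + saliency filtering, tuple test."""

import numpy as np
import pytest

from wskreg import (CorrespondenceSet, nearest_descriptor_matches,
                    reciprocity_wss_filter, tuple_test)
from wskreg.shot import DescriptorSet

from conftest import random_transform


def _ds(vectors, valid=None):
    vectors = np.asarray(vectors, float)
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    vectors = np.divide(vectors, norms, out=np.zeros_like(vectors), where=norms > 0)
    if valid is None:
        valid = norms.ravel() > 0
    return DescriptorSet(np.arange(len(vectors)), vectors, np.asarray(valid), 2.0)


def _random_unit(rng, n, d=16):
    v = rng.normal(size=(n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestNearestMatches:
    def test_identical_sets_identity_mapping(self, rng):
        F = _ds(_random_unit(rng, 20))
        C_P, C_Q = nearest_descriptor_matches(F, F)
        assert np.array_equal(C_P.pairs[:, 0], C_P.pairs[:, 1])

    def test_duplicate_matched_to_duplicate(self, rng):
        A = _random_unit(rng, 5)
        B = np.vstack([_random_unit(rng, 3), A[2]])
        C_P, _ = nearest_descriptor_matches(_ds(A), _ds(B))
        assert C_P.pairs[2, 1] == 3

    def test_matches_brute_force_argmin(self, rng):
        A, B = _random_unit(rng, 100), _random_unit(rng, 100)
        C_P, C_Q = nearest_descriptor_matches(_ds(A), _ds(B))
        d = np.linalg.norm(A[:, None] - B[None, :], axis=-1)
        assert np.array_equal(C_P.pairs[:, 1], d.argmin(axis=1))
        assert np.array_equal(C_Q.pairs[:, 0], d.argmin(axis=0))

    def test_invalid_descriptors_excluded(self, rng):
        A = _random_unit(rng, 4)
        A[1] = 0.0
        C_P, _ = nearest_descriptor_matches(_ds(A), _ds(_random_unit(rng, 4)))
        assert 1 not in C_P.pairs[:, 0]

    def test_all_invalid_raises(self):
        Z = _ds(np.zeros((3, 16)))
        with pytest.raises(ValueError, match="invalid"):
            nearest_descriptor_matches(Z, Z)


class TestReciprocityWss:
    def _sets(self, cp, cq):
        return (CorrespondenceSet(np.array(cp), "initial"),
                CorrespondenceSet(np.array(cq), "initial"))

    def test_mutual_pair_equal_wss_kept(self):
        C_P, C_Q = self._sets([[0, 1]], [[0, 1]])
        out = reciprocity_wss_filter(C_P, C_Q, np.array([1.0, 9]), np.array([9, 1.0]), 0.3)
        assert np.array_equal(out.pairs, [[0, 1]])

    def test_wss_gap_above_delta_rejected(self):
        C_P, C_Q = self._sets([[0, 0]], [[0, 0]])
        with pytest.warns(UserWarning):
            out = reciprocity_wss_filter(C_P, C_Q, np.array([1.0]),
                                         np.array([1.31]), 0.3)
        assert len(out) == 0

    def test_non_mutual_rejected(self):
        C_P, C_Q = self._sets([[0, 0]], [[1, 0]])  # 0->0 but 0 maps back to 1
        with pytest.warns(UserWarning):
            out = reciprocity_wss_filter(C_P, C_Q, np.zeros(2), np.zeros(2), 0.3)
        assert len(out) == 0

    def test_symmetric_under_swap(self, rng):
        A, B = _random_unit(rng, 40), _random_unit(rng, 40)
        wa, wb = rng.uniform(0, 2, 40), rng.uniform(0, 2, 40)
        C_P, C_Q = nearest_descriptor_matches(_ds(A), _ds(B))
        K = reciprocity_wss_filter(C_P, C_Q, wa, wb, 0.3)
        D_P, D_Q = nearest_descriptor_matches(_ds(B), _ds(A))
        K_swap = reciprocity_wss_filter(D_P, D_Q, wb, wa, 0.3)
        fwd = {(int(p), int(q)) for p, q in K.pairs}
        rev = {(int(q), int(p)) for p, q in K_swap.pairs}
        assert fwd == rev


class TestTupleTest:
    def _rigid_pairs(self, rng, n=20):
        src = rng.uniform(0, 10, (n, 3))
        T = random_transform(rng)
        tgt = T.apply(src)
        K = CorrespondenceSet(np.column_stack([np.arange(n), np.arange(n)]),
                              "reciprocal")
        return K, src, tgt

    def test_exact_rigid_correspondence_all_kept(self, rng):
        K, src, tgt = self._rigid_pairs(rng)
        out = tuple_test(K, src, tgt, alpha=0.9, max_tuples=3000, seed=0)
        assert sorted(map(tuple, out.pairs.tolist())) == \
            sorted(map(tuple, K.pairs.tolist()))

    def test_distance_mismatch_rejected(self, rng):
        K, src, tgt = self._rigid_pairs(rng, n=10)
        tgt = tgt.copy()
        tgt[3] = tgt[3] + 40.0  # all its pair distances off by far more than 2x
        out = tuple_test(K, src, tgt, alpha=0.9, max_tuples=3000, seed=0)
        assert 3 not in out.pairs[:, 0]

    def test_subset_of_input(self, rng):
        K, src, tgt = self._rigid_pairs(rng, n=15)
        tgt = tgt + rng.normal(0, 1.0, tgt.shape)
        out = tuple_test(K, src, tgt, alpha=0.95, max_tuples=500, seed=1)
        in_pairs = {tuple(p) for p in K.pairs.tolist()}
        assert all(tuple(p) in in_pairs for p in out.pairs.tolist())

    def test_rigid_motion_invariance(self, rng):
        K, src, tgt = self._rigid_pairs(rng)
        T = random_transform(rng)
        a = tuple_test(K, src, tgt, seed=3)
        b = tuple_test(K, T.apply(src), tgt, seed=3)
        assert np.array_equal(a.pairs, b.pairs)

    def test_too_few_pairs_raises(self, rng):
        K = CorrespondenceSet(np.array([[0, 0], [1, 1]]), "reciprocal")
        with pytest.raises(ValueError, match=">= 3"):
            tuple_test(K, rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))

    def test_no_passing_tuple_raises(self, rng):
        n = 10
        src = rng.uniform(0, 10, (n, 3))
        tgt = src * 5.0  # uniform scale far outside [alpha, 1/alpha]
        K = CorrespondenceSet(np.column_stack([np.arange(n), np.arange(n)]),
                              "reciprocal")
        with pytest.raises(RuntimeError, match="no tuple passed"):
            tuple_test(K, src, tgt, alpha=0.9, max_tuples=200, seed=0)

    def test_seeded_determinism(self, rng):
        K, src, tgt = self._rigid_pairs(rng)
        tgt = tgt + rng.normal(0, 0.5, tgt.shape)
        a = tuple_test(K, src, tgt, max_tuples=100, seed=42)
        b = tuple_test(K, src, tgt, max_tuples=100, seed=42)
        assert np.array_equal(a.pairs, b.pairs)

    def test_inlier_pass_rate_statistics(self):
        # with inlier fraction f, a sampled triplet is all-inlier w.p. ~ f^3;
        # pass rate over many draws should not fall far below that bound
        rng = np.random.default_rng(7)
        n, f = 30, 0.5
        src = rng.uniform(0, 10, (n, 3))
        tgt = src.copy()
        n_out = int(n * (1 - f))
        tgt[:n_out] = rng.uniform(0, 10, (n_out, 3))
        K = CorrespondenceSet(np.column_stack([np.arange(n), np.arange(n)]),
                              "reciprocal")
        rates = []
        for seed in range(5):
            out = tuple_test(K, src, tgt, alpha=0.9, max_tuples=2000, seed=seed)
            inliers = set(range(n_out, n))
            got = {int(p) for p in out.pairs[:, 0]}
            rates.append(len(got & inliers) / len(inliers))
        assert np.mean(rates) > 0.9  # nearly all true inliers recovered
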