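"""Alignment metrics: principal-axis angles, centroid distance, RMSE,
keypoint repeatability, and average nearest-neighbor distance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wskreg import (PointCloud, RigidTransform, annd, centroid_distance,
                    evaluate_alignment, keypoint_repeatability,
                    principal_axis_angles, rmse)

from conftest import random_transform


@pytest.fixture
def elongated_cloud(rng):
    # distinct principal axes: 10 x 2 x 0.5 m extent
    return PointCloud(rng.uniform(0, 1, (500, 3)) * [10.0, 2.0, 0.5])


class TestPrincipalAxisAngles:
    def test_identical_clouds_zero(self, elongated_cloud):
        assert max(principal_axis_angles(elongated_cloud, elongated_cloud)) < 1e-9

    def test_known_z_rotation_recovered_on_major_axis(self, elongated_cloud):
        R = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        rotated = PointCloud(elongated_cloud.points @ R.T)
        th = principal_axis_angles(elongated_cloud, rotated)
        # eigendecomposition backward error leaves ~1e-7 rad on the axes
        assert abs(th[0] - 10.0) < 1e-4

    def test_axis_sign_flip_folds_to_zero(self, elongated_cloud):
        flipped = PointCloud(-elongated_cloud.points)
        th = principal_axis_angles(elongated_cloud, flipped)
        assert max(th) < 1e-9

    def test_collinear_cloud_rejected(self):
        line = PointCloud(np.column_stack([np.linspace(0, 1, 10),
                                           np.zeros(10), np.zeros(10)]))
        with pytest.raises(ValueError, match="axis"):
            principal_axis_angles(line, line)

    def test_angles_bounded_by_90(self, rng, elongated_cloud):
        T = random_transform(rng)
        th = principal_axis_angles(elongated_cloud, elongated_cloud.transformed(T))
        assert all(0 <= t <= 90 for t in th)


class TestCentroidDistance:
    def test_identical_zero(self, random_cloud):
        assert centroid_distance(random_cloud, random_cloud) == 0

    def test_translated_copy(self, random_cloud):
        moved = PointCloud(random_cloud.points + [0.3, 0.4, 0.0])
        assert abs(centroid_distance(random_cloud, moved) - 0.5) < 1e-12

    def test_matches_direct_computation(self, rng, random_cloud):
        T = random_transform(rng)
        moved = random_cloud.transformed(T)
        expected = np.linalg.norm(moved.points.mean(0) - random_cloud.points.mean(0))
        assert abs(centroid_distance(random_cloud, moved) - expected) < 1e-12

    def test_empty_rejected(self, random_cloud):
        with pytest.raises(ValueError):
            centroid_distance(PointCloud(np.empty((0, 3))), random_cloud)


class TestRMSE:
    def test_identical_index_zero(self, random_cloud):
        err, n = rmse(random_cloud, random_cloud, pairing="index")
        assert err == 0 and n == len(random_cloud)

    def test_uniform_shift(self, random_cloud):
        moved = PointCloud(random_cloud.points + [0.1, 0, 0])
        err, _ = rmse(random_cloud, moved, pairing="index")
        assert abs(err - 0.1) < 1e-12

    def test_matches_direct_formula(self, rng, random_cloud):
        moved = PointCloud(random_cloud.points + rng.normal(0, 0.05, (200, 3)))
        err, _ = rmse(random_cloud, moved, pairing="index")
        direct = np.sqrt(np.mean(np.sum(
            (random_cloud.points - moved.points) ** 2, axis=1)))
        assert abs(err - direct) < 1e-12

    def test_nn_pairing_with_cutoff(self, rng):
        ref = PointCloud(rng.uniform(0, 5, (100, 3)))
        # half the points close to the reference, half far away
        close = ref.points[:50] + rng.normal(0, 0.01, (50, 3))
        far = rng.uniform(50, 60, (50, 3))
        moved = PointCloud(np.vstack([close, far]))
        err, n = rmse(ref, moved, pairing="nn", cutoff=0.45)
        assert n == 50
        assert err < 0.05

    def test_count_mismatch_rejected(self, random_cloud):
        with pytest.raises(ValueError, match="equal point counts"):
            rmse(random_cloud, PointCloud(random_cloud.points[:-1]), pairing="index")

    def test_no_pairs_within_cutoff_rejected(self, rng):
        a = PointCloud(rng.uniform(0, 1, (20, 3)))
        b = PointCloud(rng.uniform(100, 101, (20, 3)))
        with pytest.raises(ValueError, match="no valid pairs"):
            rmse(a, b, pairing="nn", cutoff=0.45)


class TestRepeatability:
    def test_exact_transformed_copy_is_100pct(self, rng):
        kp = rng.uniform(0, 10, (40, 3))
        T = random_transform(rng)
        rates = keypoint_repeatability(kp, T.apply(kp), T)
        assert all(r == 1.0 for r in rates.values())

    def test_uniform_offset_thresholds(self, rng):
        kp = rng.uniform(0, 100, (30, 3))  # sparse: 0.2 m offset stays nearest
        T = RigidTransform.identity()
        tgt = kp + [0.2, 0, 0]
        rates = keypoint_repeatability(kp, tgt, T, thresholds=(0.15, 0.3))
        assert rates[0.15] == 0.0 and rates[0.3] == 1.0

    def test_matches_brute_force(self, rng):
        src = rng.uniform(0, 5, (50, 3))
        tgt = rng.uniform(0, 5, (60, 3))
        T = random_transform(rng)
        rates = keypoint_repeatability(src, tgt, T, thresholds=(0.3,))
        moved = T.apply(src)
        d = np.linalg.norm(moved[:, None] - tgt[None, :], axis=-1).min(axis=1)
        assert rates[0.3] == np.mean(d <= 0.3)

    def test_monotone_in_threshold(self, rng):
        src, tgt = rng.uniform(0, 5, (50, 3)), rng.uniform(0, 5, (50, 3))
        rates = keypoint_repeatability(src, tgt, random_transform(rng))
        vals = [rates[t] for t in sorted(rates)]
        assert vals == sorted(vals)


class TestANND:
    def test_two_points(self):
        assert annd(np.array([[0, 0, 0], [0.4, 0, 0]])) == pytest.approx(0.4)

    def test_unit_grid(self):
        g = np.stack(np.meshgrid(range(4), range(4), [0]), -1).reshape(-1, 3)
        assert annd(g.astype(float)) == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 3, (80, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert annd(pts) == pytest.approx(d.min(axis=1).mean(), abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            annd(np.zeros((1, 3)))


class TestCommonMotionInvariance:
    def test_all_metrics_invariant_under_common_rigid_motion(self, rng, elongated_cloud):
        moved = PointCloud(elongated_cloud.points + rng.normal(0, 0.1, (500, 3)))
        T = random_transform(rng)
        a_theta = principal_axis_angles(elongated_cloud, moved)
        a_cent = centroid_distance(elongated_cloud, moved)
        a_rmse, _ = rmse(elongated_cloud, moved, pairing="index")
        A, B = elongated_cloud.transformed(T), moved.transformed(T)
        b_theta = principal_axis_angles(A, B)
        assert np.abs(np.array(a_theta) - b_theta).max() < 1e-6
        assert abs(a_cent - centroid_distance(A, B)) < 1e-9
        assert abs(a_rmse - rmse(A, B, pairing="index")[0]) < 1e-9

    def test_report_fields(self, rng, elongated_cloud):
        report = evaluate_alignment(elongated_cloud, elongated_cloud, pairing="index")
        assert report.rmse_m == 0
        assert report.n_pairs == len(elongated_cloud)
        assert max(report.axis_angles_deg) < 1e-9
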