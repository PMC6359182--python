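"""Euclidean clustering and sphere-based fruit centre estimation."""

import numpy as np
import pytest

from fruitpose3d import (
    ClusterParams,
    DegenerateFitError,
    LabeledPointCloud,
    RansacFailure,
    center_bounding_box,
    detect_fruits,
    euclidean_cluster,
    fit_sphere_lsq,
    fit_sphere_ransac,
)
from tests.conftest import sample_sphere_surface


def brute_force_components(points, threshold):
    """Independent oracle: BFS over the O(n^2) adjacency matrix."""
    pts = np.asarray(points, float)
    n = len(pts)
    adj = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1) <= threshold
    seen = np.zeros(n, bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(adj[i] & ~seen)[0]:
                seen[j] = True
                stack.append(int(j))
        comps.append(frozenset(comp))
    return frozenset(comps)


class TestEuclideanCluster:
    def test_two_points_within_threshold_join(self):
        pts = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        out = euclidean_cluster(pts, ClusterParams(4.0, 1))
        assert len(out) == 1 and len(out[0]) == 2

    def test_collinear_chain_with_gap_splits(self):
        pts = np.array([[x, 0.0, 0.0] for x in (0.0, 3.0, 6.0, 20.0)])
        out = euclidean_cluster(pts, ClusterParams(4.0, 1))
        parts = {frozenset(map(int, c)) for c in out}
        assert parts == {frozenset({0, 1, 2}), frozenset({3})}

    def test_empty_cloud_gives_empty_list(self):
        assert euclidean_cluster(np.empty((0, 3)), ClusterParams(4.0, 1)) == []

    def test_min_cluster_size_filters_small_clusters(self):
        pts = np.random.default_rng(0).normal(scale=1.0, size=(10, 3))
        assert euclidean_cluster(pts, ClusterParams(50.0, 30)) == []

    def test_output_sorted_by_descending_size(self):
        big = np.random.default_rng(1).uniform(0, 3, size=(20, 3))
        small = np.random.default_rng(2).uniform(100, 102, size=(5, 3))
        out = euclidean_cluster(np.vstack([big, small]), ClusterParams(5.0, 1))
        sizes = [len(c) for c in out]
        assert sizes == sorted(sizes, reverse=True)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 300))
        scale = rng.choice([1.0, 5.0, 50.0])
        pts = rng.uniform(0, scale, size=(n, 3))
        ours = {frozenset(map(int, c)) for c in euclidean_cluster(pts, ClusterParams(4.0, 1))}
        assert ours == brute_force_components(pts, 4.0)

    def test_raising_threshold_never_splits_clusters(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 30, size=(120, 3))
        counts = [
            len(euclidean_cluster(pts, ClusterParams(t, 1))) for t in (2.0, 4.0, 8.0, 16.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCenterBoundingBox:
    def test_single_point_and_midpoint(self):
        p = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(center_bounding_box(p), p[0])
        two = np.array([[0.0, 0.0, 0.0], [2.0, 4.0, 6.0]])
        np.testing.assert_allclose(center_bounding_box(two), [1.0, 2.0, 3.0])

    def test_symmetric_cloud_centre(self):
        offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 2, 0], [0, -2, 0], [0, 0, 3], [0, 0, -3]])
        pts = np.array([5.0, 5.0, 5.0]) + offsets
        np.testing.assert_allclose(center_bounding_box(pts), [5.0, 5.0, 5.0])

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            center_bounding_box(np.empty((0, 3)))


class TestFitSphereLsq:
    def test_recovers_exact_axis_aligned_samples(self):
        c = np.array([10.0, 20.0, 30.0])
        offsets = 40.0 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        )
        sphere = fit_sphere_lsq(c + offsets)
        np.testing.assert_allclose(sphere.center, c, atol=1e-9)
        assert sphere.radius == pytest.approx(40.0, abs=1e-9)

    def test_coplanar_points_are_degenerate(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(DegenerateFitError):
            fit_sphere_lsq(pts)

    def test_fewer_than_four_points_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_sphere_lsq(np.zeros((3, 3)))

    def test_noisy_samples_recover_centre_within_a_millimetre(self):
        rng = np.random.default_rng(21)
        c, r = np.array([50.0, -30.0, 800.0]), 35.0
        pts = sample_sphere_surface(c, r, 200, rng) + rng.normal(0, 1.0, size=(200, 3))
        sphere = fit_sphere_lsq(pts)
        assert np.linalg.norm(sphere.center_array - c) < 1.0


class TestFitSphereRansac:
    def test_robust_to_thirty_percent_outliers(self):
        rng = np.random.default_rng(42)
        c, r = np.array([0.0, 10.0, 700.0]), 40.0
        inliers = sample_sphere_surface(c, r, 140, rng)
        outliers = rng.uniform(-200, 200, size=(60, 3)) + [0, 0, 700]
        pts = np.vstack([inliers, outliers])
        sphere = fit_sphere_ransac(pts, seed=7)
        assert np.linalg.norm(sphere.center_array - c) < 1.0

    def test_outlier_free_input_matches_lsq(self):
        rng = np.random.default_rng(3)
        pts = sample_sphere_surface([5.0, 5.0, 600.0], 30.0, 80, rng)
        robust = fit_sphere_ransac(pts, seed=1)
        direct = fit_sphere_lsq(pts)
        np.testing.assert_allclose(robust.center, direct.center, atol=1e-6)
        assert robust.radius == pytest.approx(direct.radius, abs=1e-6)

    def test_structureless_cloud_fails_under_radius_prior(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 500, size=(40, 3))
        with pytest.raises(RansacFailure):
            fit_sphere_ransac(pts, inlier_threshold=1.0, seed=2, radius_bounds=(20.0, 60.0))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        pts = np.vstack(
            [sample_sphere_surface([0, 0, 700], 35.0, 100, rng), rng.uniform(0, 100, (30, 3))]
        )
        a = fit_sphere_ransac(pts, seed=5)
        b = fit_sphere_ransac(pts, seed=5)
        assert a == b


class TestDetectFruits:
    @staticmethod
    def _cloud_from_points(points, label=1):
        pix = np.zeros((len(points), 2), dtype=int)
        return LabeledPointCloud(points, pix, np.full(len(points), label))

    def test_two_separated_fruits_found_with_accurate_centres(self):
        rng = np.random.default_rng(17)
        c1, c2 = np.array([0.0, 0.0, 700.0]), np.array([150.0, 0.0, 700.0])
        pts = np.vstack(
            [sample_sphere_surface(c1, 30.0, 400, rng), sample_sphere_surface(c2, 35.0, 400, rng)]
        )
        cloud = self._cloud_from_points(pts)
        dets = detect_fruits(cloud, ClusterParams(12.0, 30), center_method="sphere_fit")
        assert len(dets) == 2
        found = sorted((np.asarray(d.center) for d in dets), key=lambda c: c[0])
        np.testing.assert_allclose(found[0], c1, atol=2.0)
        np.testing.assert_allclose(found[1], c2, atol=2.0)

    def test_empty_fruit_mask_gives_no_detections(self):
        pts = np.array([[0.0, 0.0, 700.0]])
        cloud = self._cloud_from_points(pts, label=2)  # branch only
        assert detect_fruits(cloud) == []

    def test_cluster_below_min_size_is_dropped(self):
        rng = np.random.default_rng(2)
        pts = sample_sphere_surface([0, 0, 700], 30.0, 10, rng)
        cloud = self._cloud_from_points(pts)
        assert detect_fruits(cloud, ClusterParams(500.0, 30)) == []

    def test_degenerate_sphere_fit_falls_back_to_mean(self):
        # collinear points cannot define a sphere
        pts = np.array([[x, 0.0, 700.0] for x in np.linspace(0, 10, 40)])
        cloud = self._cloud_from_points(pts)
        dets = detect_fruits(cloud, ClusterParams(4.0, 30), center_method="sphere_fit")
        assert len(dets) == 1
        assert dets[0].fallback
        np.testing.assert_allclose(dets[0].center, pts.mean(axis=0))
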