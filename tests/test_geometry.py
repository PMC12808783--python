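"""Sampler laws and geodesic metric identities on the model manifolds."""

import numpy as np
import pytest

from bettisig.geometry import (
    PointCloud,
    distance_matrix,
    sample_euclidean,
    sample_hyperbolic,
    sample_sphere,
)


class TestEuclidean:
    def test_range_and_shape(self):
        cloud = sample_euclidean(5, 3, seed=0)
        assert cloud.points.shape == (5, 3)
        assert np.all(cloud.points >= 0) and np.all(cloud.points <= 1)

    def test_seeded_determinism(self):
        a = sample_euclidean(50, 4, seed=42)
        b = sample_euclidean(50, 4, seed=42)
        assert np.array_equal(a.points, b.points)

    def test_uniform_moments(self):
        # per-coordinate mean within 4 sigma/sqrt(n) of 1/2, sigma^2 = 1/12
        cloud = sample_euclidean(10000, 2, seed=1)
        tol = 4 * np.sqrt(1 / 12) / np.sqrt(10000)
        assert np.all(np.abs(cloud.points.mean(axis=0) - 0.5) < tol)

    @pytest.mark.parametrize("n,dim", [(0, 3), (5, 0), (-1, 2)])
    def test_bad_arguments(self, n, dim):
        with pytest.raises(ValueError):
            sample_euclidean(n, dim, seed=0)


class TestSphere:
    def test_unit_norms_high_dim(self):
        cloud = sample_sphere(20, 400, seed=0)
        assert cloud.points.shape == (20, 400)
        assert np.allclose(np.linalg.norm(cloud.points, axis=1), 1.0, atol=1e-12)

    def test_isotropy(self):
        cloud = sample_sphere(100000, 3, seed=0)
        assert np.linalg.norm(cloud.points.mean(axis=0)) < 0.02

    def test_single_point_on_circle(self):
        cloud = sample_sphere(1, 2, seed=7)
        assert np.isclose(np.linalg.norm(cloud.points[0]), 1.0)

    def test_ambient_dim_below_two_rejected(self):
        with pytest.raises(ValueError):
            sample_sphere(5, 1, seed=0)


class TestHyperbolic:
    def test_small_radius_norm_bound(self):
        bound = (np.cosh(0.01) - 1) / (2 + np.cosh(0.01))  # ~1.67e-5
        cloud = sample_hyperbolic(10, 3, R=0.01, seed=0)
        norms = np.linalg.norm(cloud.points, axis=1)
        assert np.all(norms <= bound + 1e-15)

    def test_origin_is_fixed_point(self):
        # (cosh 0 - 1)/(2 + cosh 0) == 0: radial map sends the origin to itself
        assert (np.cosh(0.0) - 1) / (2 + np.cosh(0.0)) == 0.0

    def test_large_radius_stays_inside_ball(self):
        bound = (np.cosh(10.0) - 1) / (2 + np.cosh(10.0))  # ~0.99973
        cloud = sample_hyperbolic(200, 5, R=10.0, seed=3)
        norms = np.linalg.norm(cloud.points, axis=1)
        assert np.all(norms <= bound + 1e-12)
        assert np.all(norms < 1.0)

    @pytest.mark.parametrize("law", ["quasi_uniform", "ball", "uniform", "sinh_n"])
    def test_radial_laws_all_bounded(self, law):
        cloud = sample_hyperbolic(100, 4, R=2.0, seed=5, radial_law=law)
        bound = (np.cosh(2.0) - 1) / (2 + np.cosh(2.0))
        assert np.all(np.linalg.norm(cloud.points, axis=1) <= bound + 1e-12)

    def test_unknown_radial_law_rejected(self):
        with pytest.raises(ValueError, match="radial_law"):
            sample_hyperbolic(5, 3, R=1.0, seed=0, radial_law="bogus")

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sample_hyperbolic(5, 3, R=0.0, seed=0)


class TestDistanceMatrix:
    def test_sphere_right_angle_and_chordal(self):
        e1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        cloud = PointCloud(e1, "sphere", seed=0)
        geo = distance_matrix(cloud, metric="geodesic").values
        cho = distance_matrix(cloud, metric="chordal").values
        assert np.isclose(geo[0, 1], np.pi / 2)
        assert np.isclose(cho[0, 1], np.sqrt(2))

    def test_sphere_antipodal(self):
        x = np.array([0.6, 0.8])
        cloud = PointCloud(np.vstack([x, -x]), "sphere", seed=0)
        assert np.isclose(distance_matrix(cloud).values[0, 1], np.pi)

    def test_hyperbolic_closed_form(self):
        # d(0, v) with |v| = 0.5 is arccosh(5/3) = ln 3
        pts = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        cloud = PointCloud(pts, "hyperbolic", seed=0)
        assert np.isclose(distance_matrix(cloud).values[0, 1], np.log(3.0))

    def test_chordal_geodesic_relation_on_sphere(self):
        cloud = sample_sphere(40, 5, seed=2)
        geo = distance_matrix(cloud, "geodesic").values
        cho = distance_matrix(cloud, "chordal").values
        assert np.allclose(cho, 2 * np.sin(geo / 2), atol=1e-10)

    @pytest.mark.parametrize(
        "cloud",
        [
            sample_euclidean(30, 3, seed=4),
            sample_sphere(30, 4, seed=4),
            sample_hyperbolic(30, 3, R=1.0, seed=4),
        ],
        ids=["euclidean", "sphere", "hyperbolic"],
    )
    def test_triangle_inequality_exhaustive(self, cloud):
        d = distance_matrix(cloud).values
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-10

    def test_permutation_equivariance(self):
        cloud = sample_sphere(12, 6, seed=9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(12)
        d = distance_matrix(cloud).values
        dp = distance_matrix(PointCloud(cloud.points[perm], "sphere", seed=9)).values
        assert np.allclose(dp, d[np.ix_(perm, perm)], atol=1e-12)

    def test_flat_limit_small_radius(self):
        # at R = 0.01 curvature is invisible: geodesic ~ 2 * chordal within 1%
        cloud = sample_hyperbolic(25, 3, R=0.01, seed=1)
        geo = distance_matrix(cloud, "geodesic").values
        cho = distance_matrix(cloud, "chordal").values
        iu = np.triu_indices(25, 1)
        ratio = geo[iu] / (2 * cho[iu])
        assert np.all(np.abs(ratio - 1.0) < 0.01)

    def test_norm_outside_ball_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="norms"):
            distance_matrix(PointCloud(pts, "hyperbolic", seed=0))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(PointCloud(np.zeros((1, 2)), "euclidean", seed=0))
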