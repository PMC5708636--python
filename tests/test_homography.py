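"""Homography fitting (DLT) and RANSAC verification."""

import numpy as np
import pytest

from lpm.homography import Homography, fit_homography_dlt, verify
from lpm.matching import MatchCandidate


def apply_h(H, pts):
    ph = np.hstack([pts, np.ones((len(pts), 1))]) @ np.asarray(H).T
    return ph[:, :2] / ph[:, 2:3]


@pytest.fixture(scope="module")
def general_h():
    return np.array([[0.95, -0.22, 14.0], [0.20, 1.05, -8.0], [3e-5, -2e-5, 1.0]])


class TestHomography:
    def test_normalized_to_unit_h22(self):
        H = Homography(2.0 * np.eye(3))
        assert H.matrix[2, 2] == 1.0
        np.testing.assert_allclose(H.matrix, np.eye(3))

    def test_apply_and_inverse(self, general_h):
        H = Homography(general_h)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 500, (20, 2))
        there = H.apply(pts)
        back = H.inverse().apply(there)
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_singular_rejected(self):
        M = np.eye(3)
        M[1] = M[0]  # rank 2
        with pytest.raises(ValueError):
            Homography(M)

    def test_scale_insensitive_singularity_check(self):
        # a well-conditioned map with a large overall scale is not singular
        Homography(1e-8 * np.array([[1.0, 0, 5], [0, 1.0, -3], [0, 0, 1.0]]))

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            Homography(np.eye(2))


class TestDLT:
    def test_exact_recovery_minimal(self, general_h):
        src = np.array([[0.0, 0], [400, 0], [400, 400], [0, 400]])
        dst = apply_h(general_h, src)
        H = fit_homography_dlt(src, dst)
        np.testing.assert_allclose(H.matrix, general_h, rtol=1e-8, atol=1e-10)

    def test_exact_recovery_overdetermined(self, general_h):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 500, (40, 2))
        dst = apply_h(general_h, src)
        H = fit_homography_dlt(src, dst)
        np.testing.assert_allclose(H.matrix, general_h, rtol=1e-8, atol=1e-10)

    def test_least_squares_under_noise(self, general_h):
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 500, (200, 2))
        dst = apply_h(general_h, src) + rng.normal(0, 0.3, (200, 2))
        H = fit_homography_dlt(src, dst)
        pred = H.apply(src)
        rms = np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1)))
        assert rms < 0.5

    def test_degenerate_collinear_rejected(self):
        src = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        dst = src * 2
        with pytest.raises(ValueError):
            fit_homography_dlt(src, dst)

    def test_too_few_points_rejected(self):
        src = np.zeros((3, 2))
        with pytest.raises(ValueError):
            fit_homography_dlt(src, src)

    def test_conditioning_with_large_offsets(self, general_h):
        # Hartley normalization keeps far-from-origin data well conditioned
        rng = np.random.default_rng(3)
        src = rng.uniform(1e5, 1e5 + 500, (30, 2))
        dst = apply_h(general_h, src)
        H = fit_homography_dlt(src, dst)
        np.testing.assert_allclose(H.apply(src), dst, atol=1e-5)


def planted_problem(n_in=20, n_out=20, noise=0.5, data_seed=7):
    rng = np.random.default_rng(data_seed)
    Hg = np.array([[0.9, -0.2, 30.0], [0.2, 0.9, -10.0], [1e-5, 0.0, 1.0]])
    pa = rng.uniform(0, 1000, (n_in, 2))
    pb = apply_h(Hg, pa) + rng.normal(0, noise, (n_in, 2))
    oa = rng.uniform(0, 1000, (n_out, 2))
    ob = rng.uniform(0, 1000, (n_out, 2))
    coords_a = np.vstack([pa, oa])
    coords_b = np.vstack([pb, ob])
    cands = [MatchCandidate(i, i, 0.01, 0.5) for i in range(n_in + n_out)]
    return Hg, cands, coords_a, coords_b


class TestVerify:
    def test_planted_recovery(self):
        Hg, cands, ca, cb = planted_problem()
        res = verify(cands, ca, cb, pixel_tol=3.0, seed=5)
        assert res.success
        idx = sorted(m.index_a for m in res.inliers)
        planted = sum(1 for i in idx if i < 20)
        extra = len(idx) - planted
        assert planted >= 19 and extra <= 1
        # fitted homography close to ground truth on the field corners
        corners = np.array([[0.0, 0], [1000, 0], [1000, 1000], [0, 1000]])
        err = np.hypot(
            *(res.homography.apply(corners) - apply_h(Hg, corners)).T
        )
        assert err.max() < 2.0

    def test_deterministic_per_seed(self):
        _, cands, ca, cb = planted_problem()
        r1 = verify(cands, ca, cb, seed=5)
        r2 = verify(cands, ca, cb, seed=5)
        assert [m.index_a for m in r1.inliers] == [m.index_a for m in r2.inliers]
        np.testing.assert_array_equal(r1.homography.matrix, r2.homography.matrix)

    def test_input_order_does_not_matter(self):
        _, cands, ca, cb = planted_problem()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cands))
        shuffled = [cands[i] for i in perm]
        r1 = verify(cands, ca, cb, seed=5)
        r2 = verify(shuffled, ca, cb, seed=5)
        assert sorted(m.index_a for m in r1.inliers) == sorted(
            m.index_a for m in r2.inliers
        )

    def test_inliers_consistent_with_homography(self):
        _, cands, ca, cb = planted_problem()
        res = verify(cands, ca, cb, pixel_tol=3.0, seed=5)
        from lpm.homography import _symmetric_errors

        idx = np.array([m.index_a for m in res.inliers])
        errs = _symmetric_errors(res.homography, ca[idx], cb[idx])
        assert errs.max() <= 3.0 + 1e-9

    def test_too_few_matches_fails(self):
        _, cands, ca, cb = planted_problem(n_in=3, n_out=0)
        res = verify(cands[:3], ca[:3], cb[:3], seed=0)
        assert not res.success

    def test_pure_noise_rejected_or_small(self):
        rng = np.random.default_rng(9)
        ca = rng.uniform(0, 1000, (30, 2))
        cb = rng.uniform(0, 1000, (30, 2))
        cands = [MatchCandidate(i, i, 0.01, 0.5) for i in range(30)]
        res = verify(cands, ca, cb, pixel_tol=3.0, seed=0)
        # random correspondences admit at most a tiny accidental consensus
        assert (not res.success) or len(res.inliers) <= 6

    def test_all_exact_inliers(self):
        Hg, cands, ca, cb = planted_problem(n_in=12, n_out=0, noise=0.0)
        res = verify(cands, ca, cb, pixel_tol=3.0, seed=1)
        assert res.success and len(res.inliers) == 12
        np.testing.assert_allclose(res.homography.matrix, Hg, rtol=1e-6, atol=1e-8)
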