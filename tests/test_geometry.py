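"""Projective-geometry core: projection, homographies, triangulation, PnP."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msmcal.exceptions import (
    CheiralityError,
    DecompositionError,
    DegenerateGeometryError,
    IllConditionedError,
    InsufficientDataError,
)
from msmcal.geometry import (
    CameraIntrinsics,
    CameraPose,
    Homography,
    decompose_homography,
    estimate_homography_ransac,
    homography_dlt,
    pnp_ransac,
    project,
    rank_decompositions,
    rodrigues,
    scaling_homography,
    select_decomposition,
    so3_log,
    triangulate,
    umeyama_sim3,
)

from conftest import make_ring_rig


class TestProjection:
    def test_principal_point(self, pinhole):
        assert np.allclose(project(pinhole, CameraPose.identity(), [0, 0, 1]), [500, 500])

    def test_pinhole_arithmetic(self, pinhole):
        assert np.allclose(
            project(pinhole, CameraPose.identity(), [0.1, 0, 1]), [600, 500]
        )

    def test_matches_stepwise_composition(self, gopro_like):
        """project == distort ∘ normalize ∘ rigid-transform, step by step."""
        rng = np.random.default_rng(0)
        K = gopro_like
        for _ in range(50):
            P = CameraPose(rodrigues(rng.normal(size=3) * 0.3), rng.normal(size=3) * 0.1)
            X = rng.normal(size=3) * 0.5 + np.array([0, 0, 3.0])
            Xc = P.R @ X + P.t
            if Xc[2] <= 0.1:
                continue
            xn = Xc[:2] / Xc[2]
            x, y = xn
            k1, k2, p1, p2, k3 = K.dist
            r2 = x * x + y * y
            rad = 1 + k1 * r2 + k2 * r2**2 + k3 * r2**3
            xd = x * rad + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
            yd = y * rad + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
            expected = [K.fx * xd + K.cx, K.fy * yd + K.cy]
            assert np.allclose(project(K, P, X), expected, atol=1e-9)

    def test_behind_camera_raises(self, pinhole):
        with pytest.raises(CheiralityError):
            project(pinhole, CameraPose.identity(), [0, 0, -1])

    def test_distort_undistort_roundtrip(self, gopro_like):
        rng = np.random.default_rng(1)
        px = rng.uniform([100, 100], [1820, 980], size=(200, 2))
        xn = gopro_like.pixel_to_normalized(px)
        back = gopro_like.normalized_to_pixel(xn)
        assert np.abs(back - px).max() < 1e-8

    def test_undistorted_equals_ideal_pinhole(self, gopro_like):
        """undistort(project(X)) equals the ideal projection K [R|t] X."""
        rng = np.random.default_rng(2)
        P = CameraPose.look_at(np.array([2.0, 1.0, 2.0]), np.zeros(3))
        X = np.column_stack([rng.uniform(-1, 1, 50), rng.uniform(-1, 1, 50), np.zeros(50)])
        px = project(gopro_like, P, X)
        ideal = gopro_like.undistort_pixel(px)
        Xc = P.transform(X)
        expected = gopro_like.normalized_to_pixel(Xc[:, :2] / Xc[:, 2:], distort=False)
        assert np.abs(ideal - expected).max() < 1e-8


class TestScalingHomography:
    def test_identity_at_unit_scale(self):
        H = scaling_homography([3.0, 4.0], 1.0)
        x = np.array([[7.0, -2.0], [0.1, 0.2]])
        assert np.allclose(H(x), x)

    @pytest.mark.parametrize("lam", [0.5, 2.0, 8.0])
    def test_center_is_fixed_point(self, lam):
        p = np.array([123.4, 56.7])
        assert np.allclose(scaling_homography(p, lam)(p), p, atol=1e-12)

    def test_scaling_arithmetic(self):
        assert np.allclose(scaling_homography([0, 0], 2.0)([1.0, 1.0]), [2, 2])

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            scaling_homography([0, 0], 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        px=st.floats(-1000, 1000), py=st.floats(-1000, 1000),
        lam=st.floats(0.01, 100),
        qx=st.floats(-1000, 1000), qy=st.floats(-1000, 1000),
    )
    def test_scaling_law(self, px, py, lam, qx, qy):
        p = np.array([px, py])
        q = np.array([qx, qy])
        got = scaling_homography(p, lam)(q)
        assert np.allclose(got, lam * (q - p) + p, atol=1e-6 * (1 + abs(lam)))


class TestHomographyRansac:
    def _make_corr(self, n, seed, outlier_frac=0.0):
        rng = np.random.default_rng(seed)
        H = np.array([[1.1, 0.05, 0.02], [-0.04, 0.95, -0.03], [0.1, -0.08, 1.0]])
        src = rng.uniform(-0.5, 0.5, size=(n, 2))
        ph = np.hstack([src, np.ones((n, 1))]) @ H.T
        dst = ph[:, :2] / ph[:, 2:]
        n_out = int(n * outlier_frac)
        if n_out:
            dst[:n_out] = rng.uniform(-0.5, 0.5, size=(n_out, 2))
        return H, src, dst, n_out

    def test_noiseless_recovery(self, pinhole):
        H, src, dst, _ = self._make_corr(20, 3)
        Hest, mask = estimate_homography_ransac(src, dst, 3.0, pinhole, pinhole, seed=0)
        Hn = Homography(H).matrix
        assert np.linalg.norm(Hest.matrix - Hn) < 1e-8
        assert mask.all()

    def test_outlier_identification(self, pinhole):
        H, src, dst, n_out = self._make_corr(20, 4, outlier_frac=0.3)
        Hest, mask = estimate_homography_ransac(src, dst, 3.0, pinhole, pinhole, seed=1)
        assert n_out == 6
        assert not mask[:n_out].any()
        assert mask[n_out:].all()

    def test_collinear_minimal_sample_degenerate(self, pinhole):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.0, 1.0]])
        dst = src.copy()
        with pytest.raises((DegenerateGeometryError, InsufficientDataError)):
            estimate_homography_ransac(src, dst, 3.0, pinhole, pinhole, seed=0)

    def test_too_few_correspondences(self, pinhole):
        with pytest.raises(InsufficientDataError):
            estimate_homography_ransac(
                np.zeros((3, 2)), np.zeros((3, 2)), 3.0, pinhole, pinhole, seed=0
            )

    def test_seeded_reproducibility(self, pinhole):
        _, src, dst, _ = self._make_corr(40, 5, outlier_frac=0.2)
        a = estimate_homography_ransac(src, dst, 3.0, pinhole, pinhole, seed=9)
        b = estimate_homography_ransac(src, dst, 3.0, pinhole, pinhole, seed=9)
        assert np.array_equal(a[0].matrix, b[0].matrix)
        assert np.array_equal(a[1], b[1])


class TestDecomposition:
    def test_identity_homography(self):
        cands = decompose_homography(np.eye(3))
        best = min(cands, key=lambda c: np.linalg.norm(c.R - np.eye(3)))
        assert np.linalg.norm(best.R - np.eye(3)) < 1e-9
        assert np.linalg.norm(best.t_over_d) < 1e-9

    def test_pure_rotation(self):
        R = rodrigues(np.array([0.1, -0.2, 0.3]))
        cands = decompose_homography(R)
        best = min(cands, key=lambda c: np.linalg.norm(c.R - R))
        assert np.linalg.norm(best.R - R) < 1e-8
        assert np.linalg.norm(best.t_over_d) < 1e-8

    def test_singular_homography_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            decompose_homography(np.diag([1.0, 1.0, 0.0]))

    def test_forward_construction_recovered(self):
        rng = np.random.default_rng(6)
        R = rodrigues(rng.normal(size=3) * 0.4)
        t = rng.normal(size=3)
        t /= np.linalg.norm(t)
        n = np.array([0.1, -0.2, 0.97])
        n /= np.linalg.norm(n)
        H = R + np.outer(t / 2.5, n)
        cands = decompose_homography(H)
        best = min(
            np.linalg.norm(c.R - R) + np.linalg.norm(c.t_unit - t) for c in cands
        )
        assert best < 1e-6

    def test_roundtrip_1000_random_scenes(self):
        """Decomposition contains the generating (R, t/||t||, n) for 1000
        random plane-induced homographies within 1e-6."""
        rng = np.random.default_rng(7)
        failures = 0
        for _ in range(1000):
            R = rodrigues(rng.normal(size=3) * 0.3)
            t = rng.normal(size=3)
            t /= np.linalg.norm(t)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            d = rng.uniform(0.5, 5.0)
            cands = decompose_homography(R + np.outer(t / d, n))
            err = min(
                np.linalg.norm(c.R - R)
                + np.linalg.norm(c.t_unit - t)
                + np.linalg.norm(c.n - n)
                for c in cands
            )
            failures += err > 1e-6
        assert failures == 0

    def test_each_candidate_reconstructs_homography(self):
        rng = np.random.default_rng(8)
        R = rodrigues(rng.normal(size=3) * 0.2)
        t = rng.normal(size=3)
        n = np.array([0.0, 0.0, 1.0])
        H = R + np.outer(t / 3.0, n)
        Hn = H / np.linalg.svd(H, compute_uv=False)[1]
        for c in decompose_homography(H):
            recon = c.R + np.outer(c.t_over_d, c.n)
            err = min(
                np.linalg.norm(recon - Hn), np.linalg.norm(recon + Hn)
            )
            assert err < 1e-8


class TestSelectDecomposition:
    def _scene(self, rng):
        az = rng.uniform(0, 2 * np.pi, 2)
        r = rng.uniform(1.2, 2.8, 2)
        h = rng.uniform(1.4, 2.8, 2)
        P1 = CameraPose.look_at(
            np.array([r[0] * np.cos(az[0]), r[0] * np.sin(az[0]), h[0]]), np.zeros(3)
        )
        P2 = CameraPose.look_at(
            np.array([r[1] * np.cos(az[1]), r[1] * np.sin(az[1]), h[1]]), np.zeros(3)
        )
        ang = rng.uniform(0, 2 * np.pi, 100)
        rad = np.sqrt(rng.uniform(0, 1, 100)) * 2.0
        X = np.column_stack([rad * np.cos(ang), rad * np.sin(ang), np.zeros(100)])
        q1, q2 = P1.transform(X), P2.transform(X)
        if np.any(q1[:, 2] <= 0.1) or np.any(q2[:, 2] <= 0.1):
            return None
        x1 = q1[:, :2] / q1[:, 2:]
        x2 = q2[:, :2] / q2[:, 2:]
        Rrel = P2.R @ P1.R.T
        trel = P2.t - Rrel @ P1.t
        return x1, x2, Rrel, trel / np.linalg.norm(trel)

    def test_selection_on_random_rig_scenes(self):
        """On 100 random floor-viewing scenes the cheirality rule picks the
        generating pose whenever it is the unique fully-consistent
        candidate; the rare exactly-ambiguous scenes (two consistent
        decompositions of one homography) are excluded from the exactness
        claim but must still return one of the consistent poses."""
        rng = np.random.default_rng(9)
        n_checked = unique_correct = unique_total = 0
        while n_checked < 100:
            scene = self._scene(rng)
            if scene is None:
                continue
            n_checked += 1
            x1, x2, Rgt, tgt = scene
            H = homography_dlt(x1, x2)
            cands = decompose_homography(H)
            ranked = rank_decompositions(cands, x1, x2)
            full = [r for r in ranked if r[1] >= 1.0 - 1e-12]
            sel = select_decomposition(cands, x1, x2)
            err = np.linalg.norm(sel.R - Rgt) + np.linalg.norm(sel.t_unit - tgt)
            if len(full) == 1:
                unique_total += 1
                unique_correct += err < 1e-6
            else:
                # ambiguous: selection must still be fully consistent
                sel_frac = [r[1] for r in ranked if r[0] is sel][0]
                assert sel_frac >= 1.0 - 1e-12
        assert unique_total > 80
        assert unique_correct == unique_total

    def test_singleton_candidate_returned(self):
        cands = decompose_homography(np.eye(3))
        assert len(cands) == 1
        sel = select_decomposition(cands, np.zeros((5, 2)), np.zeros((5, 2)))
        assert sel is cands[0]

    def test_all_points_behind_fails(self):
        """Candidates whose pose puts the scene behind the cameras are
        rejected with a failure signal, not silently returned."""
        rng = np.random.default_rng(10)
        scene = None
        while scene is None:
            scene = self._scene(rng)
        x1, x2, Rgt, tgt = scene
        n_cam1 = np.array([0.0, 0.0, 1.0])
        from msmcal.geometry import HomographyCandidate

        wrong = [
            # sign-flipped true pose: triangulates the scene behind both views
            HomographyCandidate(Rgt, -tgt, -n_cam1),
            HomographyCandidate(
                rodrigues(np.array([0.0, np.pi * 0.9, 0.0])) @ Rgt, -tgt, -n_cam1
            ),
        ]
        with pytest.raises(DecompositionError):
            select_decomposition(wrong, x1, x2)


class TestTriangulate:
    def test_two_view_exact(self, pinhole):
        Ks, poses = make_ring_rig(2, seed=3)
        X = np.array([0.3, -0.2, 0.1])
        obs = np.stack([project(K, P, X) for K, P in zip(Ks, poses)])
        got = triangulate(poses, Ks, obs)
        assert np.linalg.norm(got - X) < 1e-8

    def test_zero_baseline_ill_conditioned(self, pinhole):
        P = CameraPose.look_at(np.array([2, 0, 2]), np.zeros(3))
        with pytest.raises(IllConditionedError):
            triangulate([P, P], [pinhole, pinhole], np.array([[500, 500], [500, 500]]))

    def test_six_view_matches_two_view(self):
        Ks, poses = make_ring_rig(6, seed=4)
        X = np.array([-0.4, 0.5, 0.2])
        obs = np.stack([project(K, P, X) for K, P in zip(Ks, poses)])
        x2 = triangulate(poses[:2], Ks[:2], obs[:2])
        x6 = triangulate(poses, Ks, obs)
        assert np.linalg.norm(x2 - x6) < 1e-8
        assert np.linalg.norm(x6 - X) < 1e-8


class TestPnP:
    def test_noiseless_grid_recovery(self):
        rng = np.random.default_rng(11)
        K = CameraIntrinsics(915, 915, 960, 540, np.zeros(5), 1920, 1080)
        P = CameraPose.look_at(np.array([2.0, 1.5, 2.5]), np.zeros(3))
        X = np.column_stack(
            [rng.uniform(-1, 1, 40), rng.uniform(-1, 1, 40), rng.uniform(0, 1, 40)]
        )
        px = project(K, P, X)
        pose, mask = pnp_ransac(K, X, px, threshold_px=3.0, seed=0)
        assert mask.all()
        assert np.degrees(np.linalg.norm(so3_log(pose.R @ P.R.T))) < 1e-6 * 57.3
        assert np.linalg.norm(pose.t - P.t) < 1e-6

    def test_coplanar_floor_recovery(self):
        rng = np.random.default_rng(12)
        K = CameraIntrinsics(915, 915, 960, 540, np.zeros(5), 1920, 1080)
        P = CameraPose.look_at(np.array([2.0, -1.0, 2.5]), np.zeros(3))
        X = np.column_stack([rng.uniform(-1, 1, 40), rng.uniform(-1, 1, 40), np.zeros(40)])
        px = project(K, P, X)
        pose, mask = pnp_ransac(K, X, px, threshold_px=3.0, seed=0)
        assert mask.all()
        assert np.linalg.norm(so3_log(pose.R @ P.R.T)) < 1e-6
        assert np.linalg.norm(pose.t - P.t) < 1e-6

    def test_outlier_excluded(self):
        rng = np.random.default_rng(13)
        K = CameraIntrinsics(915, 915, 960, 540, np.zeros(5), 1920, 1080)
        P = CameraPose.look_at(np.array([1.5, 1.0, 2.0]), np.zeros(3))
        X = np.column_stack([rng.uniform(-1, 1, 20), rng.uniform(-1, 1, 20), np.zeros(20)])
        px = project(K, P, X)
        px[7] += np.array([80.0, -60.0])
        pose, mask = pnp_ransac(K, X, px, threshold_px=3.0, seed=0)
        assert not mask[7]
        assert mask.sum() == 19

    def test_too_few_points(self):
        K = CameraIntrinsics(915, 915, 960, 540, np.zeros(5), 1920, 1080)
        with pytest.raises(InsufficientDataError):
            pnp_ransac(K, np.zeros((3, 3)), np.zeros((3, 2)), 3.0, seed=0)


class TestUmeyama:
    def test_identity(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(10, 3))
        sim = umeyama_sim3(X, X)
        assert abs(sim.scale - 1) < 1e-12
        assert np.linalg.norm(sim.R - np.eye(3)) < 1e-10
        assert np.linalg.norm(sim.t) < 1e-10

    def test_forward_transform_recovered(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(20, 3))
        R = rodrigues(np.array([0.3, -0.5, 0.2]))
        s, t = 2.7, np.array([1.0, -2.0, 0.5])
        Y = s * X @ R.T + t
        sim = umeyama_sim3(X, Y)
        assert abs(sim.scale - s) < 1e-10
        assert np.linalg.norm(sim.R - R) < 1e-10
        assert np.linalg.norm(sim.t - t) < 1e-10
        assert np.abs(sim.apply(X) - Y).max() < 1e-9

    def test_reflection_gets_proper_rotation(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(15, 3))
        Y = X.copy()
        Y[:, 2] = -Y[:, 2]
        sim = umeyama_sim3(X, Y)
        assert np.linalg.det(sim.R) > 0
        assert np.linalg.norm(sim.apply(X) - Y) > 0

    def test_collinear_degenerate(self):
        X = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateGeometryError):
            umeyama_sim3(X, X + 1.0)

    def test_global_minimum_against_twists(self):
        """Perturbing the optimal rotation by random 0.1-rad twists never
        decreases the objective (checked on 100 random clouds)."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            X = rng.normal(size=(8, 3))
            R = rodrigues(rng.normal(size=3))
            s = rng.uniform(0.5, 2)
            t = rng.normal(size=3)
            Y = s * X @ R.T + t + rng.normal(scale=0.05, size=(8, 3))
            sim = umeyama_sim3(X, Y)
            base = ((sim.apply(X) - Y) ** 2).sum()
            w = rng.normal(size=3)
            w = 0.1 * w / np.linalg.norm(w)
            Rp = rodrigues(w) @ sim.R
            # re-optimal scale/translation for the twisted rotation
            Xr = X @ Rp.T
            var = ((X - X.mean(0)) ** 2).sum() / len(X)
            sp = np.trace(((Y - Y.mean(0)).T @ (Xr - Xr.mean(0))) / len(X)) / var
            tp = Y.mean(0) - sp * Rp @ X.mean(0)
            twisted = ((sp * Xr + tp - Y) ** 2).sum()
            assert twisted >= base - 1e-9
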