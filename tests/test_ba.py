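"""Bundle-adjustment engine: fixed points, recovery, constraint modes."""

import numpy as np
import pytest

from msmcal.ba import BAOptions, adjust, plane_fit_tls
from msmcal.geometry import CameraPose, project_ideal, rodrigues

from conftest import make_ring_rig


def _scene(n_cams=6, n_pts=200, seed=0, planar=True):
    rng = np.random.default_rng(seed)
    Ks, poses = make_ring_rig(n_cams, seed=seed)
    z = np.zeros(n_pts) if planar else rng.uniform(0, 1, n_pts)
    X = np.column_stack([rng.uniform(-1.5, 1.5, n_pts), rng.uniform(-1, 1, n_pts), z])
    cam_idx, blk_idx, xy = [], [], []
    for c, (K, P) in enumerate(zip(Ks, poses)):
        px, depth = project_ideal(K, P, X)
        cam_idx += [c] * n_pts
        blk_idx += list(range(n_pts))
        xy += list(px)
    return Ks, poses, X, np.array(cam_idx), np.array(blk_idx), np.array(xy)


def _perturb(poses, X, seed=1, rot=0.5, trans=0.05):
    """Perturb by `rot` degrees / `trans` meters."""
    rng = np.random.default_rng(seed)
    out = []
    for i, P in enumerate(poses):
        if i == 0:
            out.append(P)
            continue
        w = rng.normal(size=3)
        w = np.radians(rot) * w / np.linalg.norm(w)
        d = rng.normal(size=3)
        d = trans * d / np.linalg.norm(d)
        out.append(CameraPose(rodrigues(w) @ P.R, P.t + d))
    Xp = X + rng.normal(scale=trans / 5, size=X.shape)
    return out, Xp


class TestFreeMode:
    def test_ground_truth_is_fixed_point(self):
        Ks, poses, X, ci, bi, xy = _scene()
        new_poses, Xn, res = adjust(poses, Ks, ci, bi, xy, mode="free", points=X)
        assert res.cost < 1e-18
        for P, Q in zip(poses, new_poses):
            assert np.abs(P.R - Q.R).max() < 1e-10
            assert np.abs(P.t - Q.t).max() < 1e-10
        assert np.abs(X - Xn).max() < 1e-10

    def test_basin_of_attraction(self):
        """0.5 deg / 5 cm perturbation at zero noise recovers the exact
        optimum (objective below 1e-6 px^2)."""
        Ks, poses, X, ci, bi, xy = _scene()
        pp, Xp = _perturb(poses, X)
        _, _, res = adjust(pp, Ks, ci, bi, xy, mode="free", points=Xp)
        assert res.cost < 1e-6
        assert res.cost < res.initial_cost

    def test_descent_property(self):
        """The returned objective never exceeds the initial objective."""
        for seed in range(5):
            Ks, poses, X, ci, bi, xy = _scene(seed=seed)
            rng = np.random.default_rng(seed + 100)
            xy = xy + rng.normal(scale=1.0, size=xy.shape)
            pp, Xp = _perturb(poses, X, seed=seed)
            _, _, res = adjust(
                pp, Ks, ci, bi, xy, mode="free", points=Xp,
                options=BAOptions(max_iterations=15),
            )
            assert res.cost <= res.initial_cost


class TestPlaneMode:
    def test_points_exactly_coplanar_after_adjustment(self):
        Ks, poses, X, ci, bi, xy = _scene()
        pp, Xp = _perturb(poses, X)
        _, (Xn, plane), res = adjust(pp, Ks, ci, bi, xy, mode="plane", points=Xp)
        n = plane.normal / np.linalg.norm(plane.normal)
        d = (Xn - plane.origin) @ n
        assert np.abs(d).max() < 1e-9
        assert res.cost < 1e-6

    def test_plane_cost_matches_free_on_planar_scene(self):
        Ks, poses, X, ci, bi, xy = _scene(seed=3)
        rng = np.random.default_rng(3)
        xy = xy + rng.normal(scale=0.5, size=xy.shape)
        pp, Xp = _perturb(poses, X, seed=3)
        _, _, free = adjust(pp, Ks, ci, bi, xy, mode="free", points=Xp)
        _, _, plane = adjust(pp, Ks, ci, bi, xy, mode="plane", points=Xp)
        # planar truth: the constrained optimum is close to the free one
        assert plane.cost < 1.2 * free.cost + 1e-9


class TestBoardsMode:
    def _board_scene(self, seed=0, n_boards=12):
        rng = np.random.default_rng(seed)
        Ks, poses = make_ring_rig(6, seed=seed)
        gx, gy = np.meshgrid(np.linspace(-0.5, 0.5, 6), np.linspace(-0.35, 0.35, 4))
        local = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        boards = []
        for _ in range(n_boards):
            w = rng.normal(size=3) * 0.4
            t = np.array([rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(0.2, 1.0)])
            boards.append(CameraPose(rodrigues(w), t))
        ci, bi, li, xy = [], [], [], []
        for c, (K, P) in enumerate(zip(Ks, poses)):
            for b, bp in enumerate(boards):
                W = local @ bp.R.T + bp.t
                px, z = project_ideal(K, P, W)
                ok = (z > 0) & K.in_image(px)
                for l in np.where(ok)[0]:
                    ci.append(c)
                    bi.append(b)
                    li.append(l)
                    xy.append(px[l])
        return Ks, poses, boards, local, map(np.array, (ci, bi, li)), np.array(xy)

    def test_noiseless_zero_objective_at_truth(self):
        Ks, poses, boards, local, (ci, bi, li), xy = self._board_scene()
        _, _, res = adjust(
            poses, Ks, ci, bi, xy, mode="boards",
            board_poses=boards, board_locals=local, local_idx=li,
        )
        assert res.cost < 1e-16

    def test_recovery_from_perturbation(self):
        Ks, poses, boards, local, (ci, bi, li), xy = self._board_scene(seed=2)
        rng = np.random.default_rng(5)
        pb = [CameraPose(rodrigues(rng.normal(size=3) * 0.01) @ b.R, b.t + rng.normal(size=3) * 0.02) for b in boards]
        pp = [poses[0]] + [
            CameraPose(rodrigues(rng.normal(size=3) * 0.005) @ p.R, p.t + rng.normal(size=3) * 0.01)
            for p in poses[1:]
        ]
        new_poses, new_boards, res = adjust(
            pp, Ks, ci, bi, xy, mode="boards",
            board_poses=pb, board_locals=local, local_idx=li,
        )
        assert res.cost < 1e-10
        for P, Q in zip(poses[1:], new_poses[1:]):
            assert np.abs(P.center - Q.center).max() < 1e-6

    def test_parameter_count_bookkeeping(self):
        """Gauge-fixed dof = 6(n_cams-1) + 6 n_boards, with no residual
        gauge freedom: the numeric Jacobian of the residual at the
        solution has exactly that rank (board geometry fixes the scale)."""
        Ks, poses, boards, local, (ci, bi, li), xy = self._board_scene(
            seed=4, n_boards=4
        )
        n_cams, n_boards = len(poses), len(boards)

        def residual(theta):
            # theta = [cam 1..C-1 (rotvec, t)] + [board 0..B-1 (rotvec, t)]
            off = 0
            ps = [poses[0]]
            for i in range(1, n_cams):
                w, t = theta[off:off + 3], theta[off + 3:off + 6]
                ps.append(CameraPose(rodrigues(w) @ poses[i].R, poses[i].t + t))
                off += 6
            bs = []
            for b in range(n_boards):
                w, t = theta[off:off + 3], theta[off + 3:off + 6]
                bs.append(CameraPose(rodrigues(w) @ boards[b].R, boards[b].t + t))
                off += 6
            out = []
            for c, b, l, obs in zip(ci, bi, li, xy):
                W = bs[b].R @ local[l] + bs[b].t
                px, _ = project_ideal(Ks[c], ps[c], W)
                out.append(px[0] - obs)
            return np.concatenate(out)

        n_par = 6 * (n_cams - 1) + 6 * n_boards
        theta0 = np.zeros(n_par)
        J = np.empty((len(ci) * 2, n_par))
        h = 1e-6
        for k in range(n_par):
            tp = theta0.copy()
            tm = theta0.copy()
            tp[k] += h
            tm[k] -= h
            J[:, k] = (residual(tp) - residual(tm)) / (2 * h)
        sv = np.linalg.svd(J, compute_uv=False)
        rank = int((sv > 1e-6 * sv[0]).sum())
        assert rank == n_par
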