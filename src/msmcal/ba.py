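"""Sparse bundle adjustment: Levenberg-Marquardt with Schur complement.

Minimizes the summed squared reprojection error

    sum_c sum_k v_ck || pi(K_c, P_c, X_k) - x_ck ||^2

over camera poses and structure. Structure comes in three flavours:

* ``free``   — each point is an unconstrained 3-vector (3x3 Schur blocks);
* ``plane``  — points are 2D coordinates in a jointly-estimated floor plane
               (2x2 blocks plus 3 global plane parameters), the hard
               coplanarity constraint;
* ``boards`` — points are rigid boards of known local geometry posed by 6
               parameters each (6x6 blocks), the gold-standard
               moving-board model.

Rotations update by left-multiplied axis-angle increments. Cameras listed
in ``fixed_cameras`` are frozen (gauge). Observations are ideal
(undistorted) pixels; intrinsics enter only through fx, fy, cx, cy.

The normal equations are reduced by the Schur complement onto the camera
(+ plane) parameters; the camera system is tiny (6 per camera) while
structure blocks invert in closed form, vectorized. All heavy products are
batched einsums over flat observation arrays, which keeps a 10-camera,
3200-point, ~25k-observation adjustment at a few tens of milliseconds per
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CameraIntrinsics, CameraPose, rodrigues

__all__ = ["BAOptions", "BAResult", "adjust", "PlaneModel", "plane_fit_tls"]

_ZMIN = 1e-6


@dataclass
class BAOptions:
    max_iterations: int = 100
    ftol: float = 1e-12
    init_lambda: float = 1e-6
    max_trial_steps: int = 12


@dataclass
class BAResult:
    cost: float  # final summed squared reprojection error (px^2)
    initial_cost: float
    iterations: int
    converged: bool
    residuals: np.ndarray  # (N,) final per-observation reprojection error (px)


@dataclass
class PlaneModel:
    """Plane as origin + two in-plane axes; normal is e1 x e2."""

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.e1, self.e2)

    def lift(self, uv: np.ndarray) -> np.ndarray:
        """2D plane coordinates -> 3D world points."""
        return self.origin[None, :] + uv[:, [0]] * self.e1[None, :] + uv[:, [1]] * self.e2[None, :]

    def drop(self, X: np.ndarray) -> np.ndarray:
        """3D points -> 2D plane coordinates (orthogonal projection)."""
        d = X - self.origin[None, :]
        return np.stack([d @ self.e1, d @ self.e2], axis=1)


def plane_fit_tls(X: np.ndarray) -> PlaneModel:
    """Total-least-squares plane through a point cloud."""
    c = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - c, full_matrices=False)
    e1, e2 = Vt[0], Vt[1]
    return PlaneModel(origin=c, e1=e1, e2=e2)


def _skew(v: np.ndarray) -> np.ndarray:
    S = np.zeros(v.shape[:-1] + (3, 3))
    S[..., 0, 1], S[..., 0, 2] = -v[..., 2], v[..., 1]
    S[..., 1, 0], S[..., 1, 2] = v[..., 2], -v[..., 0]
    S[..., 2, 0], S[..., 2, 1] = -v[..., 1], v[..., 0]
    return S


def _segsum(keys: np.ndarray, vals: np.ndarray, nseg: int) -> np.ndarray:
    """Sum rows of ``vals`` by integer key (bincount per column)."""
    flat = vals.reshape(len(vals), -1)
    out = np.empty((nseg, flat.shape[1]))
    for q in range(flat.shape[1]):
        out[:, q] = np.bincount(keys, weights=flat[:, q], minlength=nseg)
    return out.reshape((nseg,) + vals.shape[1:])


def _plane_axes(n: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e1 = ref - (ref @ n) * n
    e1 = e1 / np.linalg.norm(e1)
    return e1, np.cross(n, e1)


class _State:
    """Mutable optimization state for one adjustment."""

    def __init__(self, R, t, blocks, plane_xi=None):
        self.R = R  # (C,3,3)
        self.t = t  # (C,3)
        self.blocks = blocks  # (T,nb) structure parameters
        self.plane_xi = plane_xi  # (3,) or None

    def copy(self):
        return _State(
            self.R.copy(), self.t.copy(), self.blocks.copy(),
            None if self.plane_xi is None else self.plane_xi.copy(),
        )


def adjust(
    poses: list[CameraPose],
    intrinsics: list[CameraIntrinsics],
    cam_idx: np.ndarray,
    blk_idx: np.ndarray,
    obs_xy: np.ndarray,
    mode: str = "free",
    points: np.ndarray | None = None,
    plane: PlaneModel | None = None,
    board_poses: list[CameraPose] | None = None,
    board_locals: np.ndarray | None = None,
    local_idx: np.ndarray | None = None,
    fixed_cameras: tuple[int, ...] = (0,),
    options: BAOptions | None = None,
):
    """Run one bundle adjustment. Returns (poses, structure, BAResult).

    ``structure`` is: points (T,3) for ``free``; (points, PlaneModel) for
    ``plane``; list of board CameraPose for ``boards``. Inputs are not
    modified.

    For ``boards``, ``blk_idx`` indexes boards and ``local_idx`` the row of
    ``board_locals`` (board-frame coordinates of the observed corner).
    """
    options = options or BAOptions()
    C = len(poses)
    R = np.stack([p.R for p in poses])
    t = np.stack([p.t for p in poses])
    fx = np.array([K.fx for K in intrinsics])
    fy = np.array([K.fy for K in intrinsics])
    cx = np.array([K.cx for K in intrinsics])
    cy = np.array([K.cy for K in intrinsics])
    cam_idx = np.asarray(cam_idx, dtype=np.int64)
    blk_idx = np.asarray(blk_idx, dtype=np.int64)
    obs_xy = np.asarray(obs_xy, dtype=float)
    N = len(cam_idx)

    if mode == "free":
        nb = 3
        T = len(points)
        blocks = np.asarray(points, dtype=float).copy()
        plane_xi = None
        ref = None
        n0 = None
        plane0 = None
    elif mode == "plane":
        nb = 2
        if plane is None:
            plane = plane_fit_tls(points)
        plane0 = plane
        n0 = plane.normal / np.linalg.norm(plane.normal)
        ref = plane.e1
        T = len(points)
        blocks = plane.drop(np.asarray(points, dtype=float))
        plane_xi = np.array([0.0, 0.0, 0.0])  # (rot about e1, rot about e2, offset)
    elif mode == "boards":
        nb = 6
        T = len(board_poses)
        blocks = np.zeros((T, 6))  # local increments; poses kept separately
        bR = np.stack([p.R for p in board_poses])
        bt = np.stack([p.t for p in board_poses])
        local_idx = np.asarray(local_idx, dtype=np.int64)
        board_locals = np.asarray(board_locals, dtype=float)
        plane_xi = None
        ref = None
        n0 = None
        plane0 = None
    else:
        raise ValueError(f"unknown BA mode {mode!r}")

    free_cams = np.array([c for c in range(C) if c not in fixed_cameras], dtype=np.int64)
    cam_slot = -np.ones(C, dtype=np.int64)
    cam_slot[free_cams] = np.arange(len(free_cams))
    n_cam_params = 6 * len(free_cams)
    n_extra = 3 if mode == "plane" else 0
    n_glob = n_cam_params + n_extra

    # key for per-(block, camera) aggregation; the Schur cross product
    # factorizes through these sums, so no pair enumeration is needed
    bc_key = blk_idx * C + cam_idx

    def current_plane(xi) -> PlaneModel:
        # xi = (tilt about e1, tilt about e2, offset along the tilted normal)
        dn = rodrigues(xi[0] * plane0.e1 + xi[1] * plane0.e2)
        n = dn @ n0
        e1, e2 = _plane_axes(n, ref)
        return PlaneModel(origin=plane0.origin + xi[2] * n, e1=e1, e2=e2)

    def world_points(st: _State):
        if mode == "free":
            return st.blocks[blk_idx]
        if mode == "plane":
            pl = current_plane(st.plane_xi)
            return pl.lift(st.blocks[blk_idx])
        # boards
        Rb = st.R_boards
        tb = st.t_boards
        L = board_locals[local_idx]
        return np.einsum("nij,nj->ni", Rb[blk_idx], L, optimize=True) + tb[blk_idx]

    def residuals(st: _State):
        Xw = world_points(st)
        Rc = st.R[cam_idx]
        v = np.einsum("nij,nj->ni", Rc, Xw, optimize=True)
        Xc = v + st.t[cam_idx]
        z = np.maximum(Xc[:, 2], _ZMIN)
        u = fx[cam_idx] * Xc[:, 0] / z + cx[cam_idx]
        w = fy[cam_idx] * Xc[:, 1] / z + cy[cam_idx]
        r = np.stack([u, w], axis=1) - obs_xy
        return r, Xc, v, z

    def cost_of(st: _State) -> float:
        r, _, _, _ = residuals(st)
        return float((r * r).sum())

    state = _State(R, t, blocks, plane_xi)
    if mode == "boards":
        state.R_boards = bR.copy()
        state.t_boards = bt.copy()

    def copy_state(st):
        s2 = st.copy()
        if mode == "boards":
            s2.R_boards = st.R_boards.copy()
            s2.t_boards = st.t_boards.copy()
        return s2

    cost = cost_of(state)
    initial_cost = cost
    lam = options.init_lambda
    it = 0
    converged = False
    slot6 = cam_slot[cam_idx]  # -1 for fixed cameras

    while it < options.max_iterations:
        it += 1
        r, Xc, v, z = residuals(state)
        zi = 1.0 / z
        f1 = fx[cam_idx]
        f2 = fy[cam_idx]
        Jp = np.zeros((N, 2, 3))  # d(residual)/d(Xc)
        Jp[:, 0, 0] = f1 * zi
        Jp[:, 0, 2] = -f1 * Xc[:, 0] * zi * zi
        Jp[:, 1, 1] = f2 * zi
        Jp[:, 1, 2] = -f2 * Xc[:, 1] * zi * zi
        # camera jacobian: [d/d(rot increment), d/dt]
        A = np.empty((N, 2, 6))
        A[:, :, :3] = np.einsum("nab,nbc->nac", Jp, -_skew(v), optimize=True)
        A[:, :, 3:] = Jp
        Jw = np.einsum("nab,nbc->nac", Jp, state.R[cam_idx], optimize=True)  # d/d(world point)
        if mode == "free":
            B = Jw
        elif mode == "plane":
            pl = current_plane(state.plane_xi)
            B = np.stack([Jw @ pl.e1, Jw @ pl.e2], axis=2)
            # numeric jacobian of world point wrt the 3 plane parameters
            E = np.empty((N, 2, 3))
            h = 1e-6
            for q in range(3):
                xi_p = state.plane_xi.copy()
                xi_m = state.plane_xi.copy()
                xi_p[q] += h
                xi_m[q] -= h
                Xp = current_plane(xi_p).lift(state.blocks[blk_idx])
                Xm = current_plane(xi_m).lift(state.blocks[blk_idx])
                dX = (Xp - Xm) / (2 * h)
                E[:, :, q] = np.einsum("nab,nb->na", Jw, dX, optimize=True)
        else:  # boards
            L = board_locals[local_idx]
            rotated = np.einsum("nij,nj->ni", state.R_boards[blk_idx], L, optimize=True)
            B = np.empty((N, 2, 6))
            B[:, :, :3] = np.einsum("nab,nbc->nac", Jw, -_skew(rotated), optimize=True)
            B[:, :, 3:] = Jw

        # normal-equation pieces; scatter-sums use bincount (fast segsum)
        V = _segsum(blk_idx, np.einsum("nai,naj->nij", B, B, optimize=True), T)
        pb = _segsum(blk_idx, np.einsum("nai,na->ni", B, r, optimize=True), T)
        UA = _segsum(cam_idx, np.einsum("nai,naj->nij", A, A, optimize=True), C)  # (C,6,6)
        gcam = _segsum(cam_idx, np.einsum("nai,na->ni", A, r, optimize=True), C)
        U = np.zeros((n_glob, n_glob))
        g = np.zeros(n_glob)
        for s, c in enumerate(free_cams):
            U[s * 6:(s + 1) * 6, s * 6:(s + 1) * 6] = UA[c]
            g[s * 6:(s + 1) * 6] = gcam[c]
        # per-(block, camera) sums of Y = A^T B; the Schur product factorizes
        # through these, so per-pair enumeration is never needed
        Y = np.einsum("nai,naj->nij", A, B, optimize=True)  # (N,6,nb)
        YS = _segsum(bc_key, Y.reshape(N, -1), T * C).reshape(T, C, 6, nb)
        if mode == "plane":
            ex0 = n_cam_params
            U[ex0:, ex0:] += np.einsum("nai,naj->ij", E, E, optimize=True)
            g[ex0:] += np.einsum("nai,na->i", E, r, optimize=True)
            UC = _segsum(cam_idx, np.einsum("nai,naj->nij", A, E, optimize=True), C)  # (C,6,3)
            for s, c in enumerate(free_cams):
                U[s * 6:(s + 1) * 6, ex0:] += UC[c]
                U[ex0:, s * 6:(s + 1) * 6] += UC[c].T
            YE = np.einsum("nai,naj->nij", E, B, optimize=True)  # (N,3,nb)
            YEs = _segsum(blk_idx, YE.reshape(N, -1), T).reshape(T, 3, nb)

        accepted = False
        for _ in range(options.max_trial_steps):
            Vd = V.copy()
            dgn = np.arange(nb)
            Vd[:, dgn, dgn] += lam * Vd[:, dgn, dgn] + 1e-14
            try:
                Vinv = np.linalg.inv(Vd)
            except np.linalg.LinAlgError:
                Vinv = np.linalg.pinv(Vd)
            Ud = U.copy()
            dgg = np.arange(n_glob)
            Ud[dgg, dgg] += lam * Ud[dgg, dgg] + 1e-14

            # Schur: S = Ud - sum_b W_b Vinv_b W_b^T on the camera(+plane) system
            ZS = np.einsum("tcik,tkl->tcil", YS, Vinv, optimize=True)  # (T,C,6,nb)
            S = Ud.copy()
            rhs = g.copy()
            Scam = np.einsum("tcik,tdjk->cdij", ZS, YS, optimize=True)  # (C,C,6,6)
            Sblk = (
                Scam[np.ix_(free_cams, free_cams)]
                .transpose(0, 2, 1, 3)
                .reshape(n_cam_params, n_cam_params)
            )
            S[:n_cam_params, :n_cam_params] -= Sblk
            zp_cam = np.einsum("tcik,tk->ci", ZS, pb, optimize=True)  # (C,6)
            rhs[:n_cam_params] -= zp_cam[free_cams].reshape(-1)
            if mode == "plane":
                ZEs = np.einsum("tik,tkl->til", YEs, Vinv, optimize=True)  # (T,3,nb)
                Sec = np.einsum("tik,tdjk->dij", ZEs, YS, optimize=True)  # (C,3,6)
                Sce = np.einsum("tcik,tjk->cij", ZS, YEs, optimize=True)  # (C,6,3)
                for s, c in enumerate(free_cams):
                    S[ex0:, s * 6:(s + 1) * 6] -= Sec[c]
                    S[s * 6:(s + 1) * 6, ex0:] -= Sce[c]
                S[ex0:, ex0:] -= np.einsum("tik,tjk->ij", ZEs, YEs, optimize=True)
                rhs[ex0:] -= np.einsum("tik,tk->i", ZEs, pb, optimize=True)

            try:
                dg_full = np.linalg.solve(S, -rhs)
            except np.linalg.LinAlgError:
                lam *= 5.0
                continue
            # back-substitute structure updates
            dcam = np.zeros((C, 6))
            if len(free_cams):
                dcam[free_cams] = dg_full[:n_cam_params].reshape(-1, 6)
            acc = np.einsum("tcik,ci->tk", YS, dcam, optimize=True)  # (T,nb)
            if mode == "plane":
                acc += np.einsum("tik,i->tk", YEs, dg_full[ex0:], optimize=True)
            dblocks = np.einsum("tij,tj->ti", Vinv, -pb - acc, optimize=True)

            trial = copy_state(state)
            if len(free_cams):
                dw = dg_full[:n_cam_params].reshape(-1, 6)
                trial.R[free_cams] = rodrigues(dw[:, :3]) @ state.R[free_cams]
                trial.t[free_cams] = state.t[free_cams] + dw[:, 3:]
            if mode == "boards":
                trial.R_boards = rodrigues(dblocks[:, :3]) @ state.R_boards
                trial.t_boards = state.t_boards + dblocks[:, 3:]
            else:
                trial.blocks = state.blocks + dblocks
            if mode == "plane":
                trial.plane_xi = state.plane_xi + dg_full[ex0:]
            new_cost = cost_of(trial)
            if np.isfinite(new_cost) and new_cost < cost:
                state = trial
                rel = (cost - new_cost) / max(cost, 1e-300)
                cost = new_cost
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                if rel < options.ftol:
                    converged = True
                break
            lam *= 5.0
        if not accepted:
            converged = True  # cannot improve further at any damping
            break
        if converged:
            break

    r, _, _, _ = residuals(state)
    res = BAResult(
        cost=cost,
        initial_cost=initial_cost,
        iterations=it,
        converged=converged,
        residuals=np.linalg.norm(r, axis=1),
    )
    out_poses = [CameraPose(state.R[c], state.t[c]) for c in range(C)]
    if mode == "free":
        return out_poses, state.blocks, res
    if mode == "plane":
        pl = current_plane(state.plane_xi)
        return out_poses, (pl.lift(state.blocks), pl), res
    boards = [CameraPose(state.R_boards[b], state.t_boards[b]) for b in range(T)]
    return out_poses, boards, res
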