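"""Pose-accuracy metrics, held-out reprojection evaluation, success rates.

Calibration from images alone leaves a global similarity (gauge) free, so
estimated and reference poses are compared only after removing it: a
Sim(3) is fitted to the camera centers by the closed-form least-squares
(Umeyama) alignment, translation errors are aligned-center distances and
rotation errors geodesic angles after applying the fitted rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import ObservationTrack
from .exceptions import InsufficientDataError
from .geometry import (
    CameraIntrinsics,
    CameraPose,
    Sim3,
    project_ideal,
    umeyama_sim3,
)

__all__ = [
    "PoseErrorReport",
    "SuccessReport",
    "pose_error",
    "evaluate_on_heldout",
    "compare_point_clouds",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.5, 2.0, 5.0)


@dataclass
class PoseErrorReport:
    rotation_rmse_deg: float
    translation_rmse_m: float
    per_camera_rotation_deg: dict[str, float]
    per_camera_translation_m: dict[str, float]
    alignment: Sim3


@dataclass
class SuccessReport:
    thresholds_px: tuple[float, ...]
    success_rates_pct: tuple[float, ...]
    per_camera_mean_reproj: dict[str, float]
    n_points_used: int
    n_points_skipped: int
    mean_point_error: float | None = None


def pose_error(
    estimated: dict[str, CameraPose],
    ground_truth: dict[str, CameraPose],
) -> PoseErrorReport:
    """Sim(3)-aligned rotation/translation RMSE between two pose sets.

    The similarity is fitted on camera centers only; orientations are
    compared after applying its rotation. Requires >= 3 common cameras.
    """
    common = sorted(set(estimated) & set(ground_truth))
    if len(common) < 3:
        raise InsufficientDataError("pose alignment needs >= 3 common cameras")
    Ce = np.stack([estimated[c].center for c in common])
    Cg = np.stack([ground_truth[c].center for c in common])
    sim = umeyama_sim3(Ce, Cg)
    Ca = sim.apply(Ce)
    rot_err = {}
    tr_err = {}
    for c, ca in zip(common, Ca):
        # estimated world axes map through sim.R into the reference world
        Ra = estimated[c].R @ sim.R.T
        Rg = ground_truth[c].R
        cosang = (np.trace(Ra @ Rg.T) - 1.0) / 2.0
        rot_err[c] = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        tr_err[c] = float(np.linalg.norm(ca - ground_truth[c].center))
    rot = np.array(list(rot_err.values()))
    tr = np.array(list(tr_err.values()))
    return PoseErrorReport(
        rotation_rmse_deg=float(np.sqrt(np.mean(rot**2))),
        translation_rmse_m=float(np.sqrt(np.mean(tr**2))),
        per_camera_rotation_deg=rot_err,
        per_camera_translation_m=tr_err,
        alignment=sim,
    )


def _refine_points_fixed_poses(
    X: np.ndarray,
    obs_cam: np.ndarray,
    obs_tid: np.ndarray,
    obs_xy: np.ndarray,
    poses: list[CameraPose],
    intrinsics: list[CameraIntrinsics],
    iterations: int = 20,
) -> np.ndarray:
    """Point-only Gauss-Newton on reprojection error, poses frozen.

    All points are independent; the normal equations are batched 3x3
    solves. Falls back to the previous iterate for any point whose step
    does not decrease its own residual (guaranteeing overall descent).
    """
    T = len(X)
    fx = np.array([K.fx for K in intrinsics])[obs_cam]
    fy = np.array([K.fy for K in intrinsics])[obs_cam]
    Rs = np.stack([p.R for p in poses])[obs_cam]
    ts = np.stack([p.t for p in poses])[obs_cam]
    cxy = np.stack([[K.cx, K.cy] for K in intrinsics])[obs_cam]

    def residual(Xcur):
        Xc = np.einsum("nij,nj->ni", Rs, Xcur[obs_tid]) + ts
        z = np.maximum(Xc[:, 2], 1e-9)
        u = fx * Xc[:, 0] / z + cxy[:, 0]
        v = fy * Xc[:, 1] / z + cxy[:, 1]
        return np.stack([u, v], axis=1) - obs_xy, Xc, z

    def per_point_cost(r):
        c = np.zeros(T)
        np.add.at(c, obs_tid, (r**2).sum(axis=1))
        return c

    X = X.copy()
    r, Xc, z = residual(X)
    cost = per_point_cost(r)
    for _ in range(iterations):
        zi = 1.0 / z
        Jc = np.zeros((len(r), 2, 3))
        Jc[:, 0, 0] = fx * zi
        Jc[:, 0, 2] = -fx * Xc[:, 0] * zi * zi
        Jc[:, 1, 1] = fy * zi
        Jc[:, 1, 2] = -fy * Xc[:, 1] * zi * zi
        J = np.einsum("nab,nbc->nac", Jc, Rs)
        JtJ = np.zeros((T, 3, 3))
        Jtr = np.zeros((T, 3))
        np.add.at(JtJ, obs_tid, np.einsum("nai,naj->nij", J, J))
        np.add.at(Jtr, obs_tid, np.einsum("nai,na->ni", J, r))
        JtJ += 1e-12 * np.eye(3)[None]
        step = np.linalg.solve(JtJ, -Jtr[..., None])[..., 0]
        Xn = X + step
        rn, Xcn, zn = residual(Xn)
        cn = per_point_cost(rn)
        worse = cn > cost
        if np.any(worse):
            Xn[worse] = X[worse]
            rn, Xcn, zn = residual(Xn)
            cn = per_point_cost(rn)
        delta = cost.sum() - cn.sum()
        X, r, Xc, z, cost = Xn, rn, Xcn, zn, cn
        if delta < 1e-14 * max(cost.sum(), 1.0):
            break
    return X


def evaluate_on_heldout(
    poses: dict[str, CameraPose],
    intrinsics: dict[str, CameraIntrinsics],
    tracks: list[ObservationTrack],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    reference_points: dict[int, np.ndarray] | None = None,
) -> SuccessReport:
    """Independent-data evaluation of fixed poses.

    Held-out tracks are triangulated pairwise between all camera pairs
    (median over pairs), refined by point-only least squares with poses
    frozen, and scored: per-camera mean reprojection error and the share of
    cameras below each threshold. Tracks seen by < 2 posed cameras are
    skipped and counted. Cameras without a pose fail all thresholds.

    With ``reference_points`` (marker_id -> 3D) the mean Euclidean point
    error after Sim(3) alignment is reported as well.
    """
    cam_ids = sorted(poses)
    cam_index = {c: i for i, c in enumerate(cam_ids)}
    pose_list = [poses[c] for c in cam_ids]
    K_list = [intrinsics[c] for c in cam_ids]
    obs_cam, obs_tid, obs_xy, tids = [], [], [], []
    skipped = 0
    for tr in tracks:
        usable = [c for c in sorted(tr.observations) if c in cam_index]
        if len(usable) < 2:
            skipped += 1
            continue
        tid = len(tids)
        tids.append(tr.marker_id)
        for c in usable:
            o = tr.observations[c]
            obs_cam.append(cam_index[c])
            obs_tid.append(tid)
            obs_xy.append(
                intrinsics[c].undistort_pixel(np.asarray(o.center_px))[0]
            )
    if not tids:
        raise InsufficientDataError("no held-out track is observed by >= 2 cameras")
    obs_cam = np.array(obs_cam)
    obs_tid = np.array(obs_tid)
    obs_xy = np.array(obs_xy)
    T = len(tids)

    # pairwise triangulation, median over pairs
    xn = np.empty_like(obs_xy)
    for c in range(len(cam_ids)):
        s = obs_cam == c
        K = K_list[c]
        xn[s] = (obs_xy[s] - [K.cx, K.cy]) / [K.fx, K.fy]
    M = np.stack([np.hstack([p.R, p.t.reshape(3, 1)]) for p in pose_list])
    X0 = np.zeros((T, 3))
    for t in range(T):
        s = np.where(obs_tid == t)[0]
        ests = []
        for i in range(len(s)):
            for j in range(i + 1, len(s)):
                rows = []
                for k in (s[i], s[j]):
                    P = M[obs_cam[k]]
                    rows.append(xn[k, 0] * P[2] - P[0])
                    rows.append(xn[k, 1] * P[2] - P[1])
                A = np.stack(rows)
                _, _, Vt = np.linalg.svd(A)
                Xh = Vt[-1]
                if abs(Xh[3]) > 1e-12:
                    ests.append(Xh[:3] / Xh[3])
        if ests:
            X0[t] = np.median(np.stack(ests), axis=0)
    X = _refine_points_fixed_poses(X0, obs_cam, obs_tid, obs_xy, pose_list, K_list)

    per_cam = {}
    for c, cid in enumerate(cam_ids):
        s = obs_cam == c
        if not np.any(s):
            per_cam[cid] = np.nan
            continue
        px, _ = project_ideal(K_list[c], pose_list[c], X[obs_tid[s]])
        per_cam[cid] = float(np.linalg.norm(px - obs_xy[s], axis=1).mean())
    # cameras lacking a pose (never registered) fail every threshold
    all_cams = sorted(intrinsics)
    errs = np.array([per_cam.get(c, np.inf) for c in all_cams])
    rates = tuple(
        float(100.0 * np.mean(errs < th)) for th in thresholds
    )
    mean_pt_err = None
    if reference_points is not None:
        common = [i for i, mid in enumerate(tids) if mid in reference_points]
        if len(common) >= 3:
            A = X[common]
            B = np.stack([reference_points[tids[i]] for i in common])
            sim = umeyama_sim3(A, B)
            mean_pt_err = float(np.linalg.norm(sim.apply(A) - B, axis=1).mean())
    return SuccessReport(
        thresholds_px=tuple(thresholds),
        success_rates_pct=rates,
        per_camera_mean_reproj=per_cam,
        n_points_used=T,
        n_points_skipped=skipped,
        mean_point_error=mean_pt_err,
    )


def compare_point_clouds(
    points_a: dict[int, np.ndarray],
    points_b: dict[int, np.ndarray],
    percentiles: tuple[float, ...] = (50.0, 90.0),
) -> dict:
    """Euclidean errors between matched clouds after Sim(3) alignment."""
    common = sorted(set(points_a) & set(points_b))
    if len(common) < 3:
        raise InsufficientDataError("cloud comparison needs >= 3 common points")
    A = np.stack([points_a[k] for k in common])
    B = np.stack([points_b[k] for k in common])
    sim = umeyama_sim3(A, B)
    err = np.linalg.norm(sim.apply(A) - B, axis=1)
    out = {
        "n_common": len(common),
        "mean_error": float(err.mean()),
        "alignment": sim,
    }
    for p in percentiles:
        out[f"p{p:g}_error"] = float(np.percentile(err, p))
    return out
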