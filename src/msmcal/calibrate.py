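"""Incremental external calibration from cross-view marker tracks.

The pipeline mirrors an incremental structure-from-motion reconstruction,
with one decisive difference: all scene points lie on (or near) the floor
plane, which makes essential-matrix initialization degenerate. The initial
camera pair is therefore recovered by decomposing the inter-image
homography, the rigorous approach for coplanar points. After that:

1. pick the initial pair maximizing the pairwise view score (count and
   spatial distribution of shared correspondences);
2. homography RANSAC (3 px threshold on normalized correspondences),
   analytic decomposition, cheirality disambiguation — with a third-view
   PnP check when two decompositions are exactly consistent;
3. repeatedly register the best unregistered camera by PnP on triangulated
   points, triangulate newly covered tracks, run intermediate bundle
   adjustment;
4. final bundle adjustment, residual-based outlier removal, final bundle
   adjustment again — optionally with the hard coplanarity constraint
   (points parametrized in a jointly refined floor plane).

Gauge: the first camera of the initial pair is frozen at identity and the
reconstruction is rescaled after every adjustment so the initial-pair
baseline is exactly 1 (metric scale is unobservable without a known
length; accuracy is evaluated after Sim(3) alignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ba import BAOptions, PlaneModel, adjust, plane_fit_tls
from .detection import ObservationTrack
from .exceptions import (
    CalibrationError,
    DecompositionError,
    DegenerateGeometryError,
    InsufficientDataError,
    RegistrationError,
)
from .geometry import (
    CameraIntrinsics,
    CameraPose,
    decompose_homography,
    estimate_homography_ransac,
    pnp_ransac,
    project_ideal,
    rank_decompositions,
    triangulate_batch,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationOptions",
    "CalibrationResult",
    "Reconstruction",
    "ViewScore",
    "ScenePoint",
    "view_score",
    "select_initial_pair",
    "rank_initial_pairs",
    "initialize_pair",
    "register_next",
    "bundle_adjust",
    "calibrate",
]


@dataclass
class CalibrationOptions:
    coplanar: bool = False
    seed: int = 0
    ransac_threshold_px: float = 3.0
    pnp_threshold_px: float = 6.0
    min_pnp_inlier_ratio: float = 0.1
    min_shared_correspondences: int = 50
    min_pnp_points: int = 6
    min_triangulation_angle_deg: float = 1.0
    max_new_point_reproj_px: float = 4.0
    outlier_robust_sigmas: float = 4.0
    score_levels: int = 6
    retriangulate_every: int = 3
    intermediate_ba_iterations: int = 25
    final_ba_iterations: int = 100


@dataclass(frozen=True)
class ViewScore:
    camera_id: str
    score: float
    n_correspondences: int


@dataclass(frozen=True)
class ScenePoint:
    marker_id: int
    position: np.ndarray
    on_floor: bool = False


@dataclass
class CalibrationResult:
    poses: dict[str, CameraPose]
    points: list[ScenePoint]
    residuals_px: np.ndarray
    per_camera_mean_reproj: dict[str, float]
    registered: list[str]
    unregistered: list[str]
    registration_order: list[str]
    gauge: str
    plane: PlaneModel | None = None
    mean_reproj_px: float = 0.0
    n_observations_used: int = 0


@dataclass
class Reconstruction:
    """Flat-array working state of the incremental reconstruction."""

    camera_ids: list[str]
    intrinsics: list[CameraIntrinsics]
    obs_cam: np.ndarray  # (N,) camera index per observation
    obs_tid: np.ndarray  # (N,) track index per observation
    obs_xy: np.ndarray  # (N,2) ideal (undistorted) pixel observation
    marker_ids: np.ndarray  # (T,) marker id per track index
    poses: dict[int, CameraPose] = field(default_factory=dict)
    points: dict[int, np.ndarray] = field(default_factory=dict)
    gauge_pair: tuple[int, int] | None = None
    obs_active: np.ndarray | None = None  # outlier mask (True = used)
    registration_order: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.obs_active is None:
            self.obs_active = np.ones(len(self.obs_cam), dtype=bool)

    @property
    def n_cameras(self) -> int:
        return len(self.camera_ids)

    def normalized(self, obs_indices: np.ndarray) -> np.ndarray:
        """Ideal pixels -> normalized camera coordinates for given obs."""
        out = np.empty((len(obs_indices), 2))
        for c in np.unique(self.obs_cam[obs_indices]):
            K = self.intrinsics[c]
            sel = self.obs_cam[obs_indices] == c
            px = self.obs_xy[obs_indices][sel]
            out[sel] = (px - [K.cx, K.cy]) / [K.fx, K.fy]
        return out


def build_reconstruction(
    tracks: list[ObservationTrack],
    intrinsics: dict[str, CameraIntrinsics],
) -> Reconstruction:
    """Flatten tracks into observation arrays; undistorts observations."""
    camera_ids = sorted(intrinsics)
    cam_index = {cid: i for i, cid in enumerate(camera_ids)}
    usable = [t for t in tracks if t.usable]
    marker_ids = np.array([t.marker_id for t in usable], dtype=np.int64)
    cam_l, tid_l, xy_l = [], [], []
    for tid, tr in enumerate(usable):
        for cid in sorted(tr.observations):
            if cid not in cam_index:
                raise CalibrationError(f"no intrinsics for camera {cid!r}")
            o = tr.observations[cid]
            cam_l.append(cam_index[cid])
            tid_l.append(tid)
            xy_l.append(np.asarray(o.center_px, dtype=float))
    obs_cam = np.array(cam_l, dtype=np.int64)
    obs_tid = np.array(tid_l, dtype=np.int64)
    obs_xy = np.array(xy_l) if xy_l else np.zeros((0, 2))
    # undistort once; everything downstream works on ideal pixels
    for c in range(len(camera_ids)):
        sel = obs_cam == c
        if np.any(sel):
            obs_xy[sel] = intrinsics[camera_ids[c]].undistort_pixel(obs_xy[sel])
    return Reconstruction(
        camera_ids=camera_ids,
        intrinsics=[intrinsics[c] for c in camera_ids],
        obs_cam=obs_cam,
        obs_tid=obs_tid,
        obs_xy=obs_xy,
        marker_ids=marker_ids,
    )


# ---------------------------------------------------------------------------
# view score


def _occupancy_score(xy: np.ndarray, width: int, height: int, levels: int) -> float:
    """Multi-level occupancy: each occupied cell at level l adds 2^l."""
    if len(xy) == 0:
        return 0.0
    score = 0.0
    fx = np.clip(xy[:, 0] / width, 0, 1 - 1e-12)
    fy = np.clip(xy[:, 1] / height, 0, 1 - 1e-12)
    for l in range(1, levels + 1):
        n = 1 << l
        cells = (fx * n).astype(int) * n + (fy * n).astype(int)
        score += (1 << l) * len(np.unique(cells))
    return score


def view_score(
    camera_id: str,
    tracks: list[ObservationTrack],
    image_size: tuple[int, int],
    levels: int = 6,
) -> ViewScore:
    """Score the number and spatial distribution of a camera's observations."""
    xy = np.array(
        [t.observations[camera_id].center_px for t in tracks if camera_id in t.observations]
    )
    n = len(xy)
    s = _occupancy_score(xy.reshape(n, 2), image_size[0], image_size[1], levels)
    return ViewScore(camera_id=camera_id, score=s, n_correspondences=n)


def rank_initial_pairs(
    tracks: list[ObservationTrack],
    intrinsics: dict[str, CameraIntrinsics],
    min_shared: int = 50,
    levels: int = 6,
) -> list[tuple[str, str]]:
    """Camera pairs ordered by min(pair-restricted score_a, score_b).

    Scores are computed only on correspondences shared by the pair;
    deterministic tie-break by lexicographic camera ids. The caller walks
    the list because the top-scoring pair can still fail initialization
    (e.g. two nearly coincident cameras share everything but have no
    baseline).
    """
    cams = sorted(intrinsics)
    if len(cams) < 2:
        raise CalibrationError("need at least 2 cameras")
    per_cam = {c: {} for c in cams}
    for t in tracks:
        if not t.usable:
            continue
        for cid, o in t.observations.items():
            per_cam[cid][t.marker_id] = o.center_px
    scored = []
    for i, a in enumerate(cams):
        for b in cams[i + 1:]:
            shared = sorted(set(per_cam[a]) & set(per_cam[b]))
            if len(shared) < min_shared:
                continue
            Ka, Kb = intrinsics[a], intrinsics[b]
            sa = _occupancy_score(
                np.array([per_cam[a][m] for m in shared]), Ka.width, Ka.height, levels
            )
            sb = _occupancy_score(
                np.array([per_cam[b][m] for m in shared]), Kb.width, Kb.height, levels
            )
            scored.append((min(sa, sb), (a, b)))
    if not scored:
        raise CalibrationError(
            f"no camera pair shares >= {min_shared} correspondences"
        )
    scored.sort(key=lambda s: (-s[0], s[1]))
    return [p for _, p in scored]


def select_initial_pair(
    tracks: list[ObservationTrack],
    intrinsics: dict[str, CameraIntrinsics],
    min_shared: int = 50,
    levels: int = 6,
) -> tuple[str, str]:
    """The top-ranked initial pair (see :func:`rank_initial_pairs`)."""
    return rank_initial_pairs(tracks, intrinsics, min_shared, levels)[0]


# ---------------------------------------------------------------------------
# initialization


def _triangulate_tracks(
    rec: Reconstruction,
    tids: np.ndarray,
    options: CalibrationOptions,
) -> int:
    """Triangulate the given tracks from currently registered cameras.

    Applies the new-point filters: >= 2 registered views, minimum
    triangulation angle, positive depths, bounded reprojection error.
    Returns the number of points added.
    """
    reg = sorted(rec.poses)
    reg_set = set(reg)
    reg_slot = {c: i for i, c in enumerate(reg)}
    sel = (
        np.isin(rec.obs_tid, tids)
        & np.isin(rec.obs_cam, reg)
        & rec.obs_active
    )
    idx = np.where(sel)[0]
    if len(idx) == 0:
        return 0
    xn = rec.normalized(idx)
    tid_arr = rec.obs_tid[idx]
    cam_arr = np.array([reg_slot[c] for c in rec.obs_cam[idx]])
    poses = [rec.poses[c] for c in reg]
    # compact track indexing
    utids, tinv = np.unique(tid_arr, return_inverse=True)
    X, ok = triangulate_batch(cam_arr, tinv, xn, poses, len(utids))
    centers = np.stack([p.center for p in poses])
    added = 0
    # vectorized filters
    pxs = np.empty((len(idx), 2))
    zs = np.empty(len(idx))
    for s, c in enumerate(reg):
        m = cam_arr == s
        if not np.any(m):
            continue
        px, z = project_ideal(rec.intrinsics[c], rec.poses[c], X[tinv[m]])
        pxs[m] = px
        zs[m] = z
    reproj = np.linalg.norm(pxs - rec.obs_xy[idx], axis=1)
    min_ang = np.radians(options.min_triangulation_angle_deg)
    for k, tid in enumerate(utids):
        if not ok[k] or tid in rec.points:
            continue
        m = tinv == k
        if np.any(zs[m] <= 0) or np.any(reproj[m] > options.max_new_point_reproj_px):
            continue
        rays = X[k][None, :] - centers[cam_arr[m]]
        rays = rays / np.linalg.norm(rays, axis=1, keepdims=True)
        cosmax = -1.0
        dots = rays @ rays.T
        iu = np.triu_indices(len(rays), 1)
        if len(iu[0]) == 0:
            continue
        ang = np.arccos(np.clip(dots[iu], -1, 1)).max()
        if ang < min_ang:
            continue
        rec.points[int(tid)] = X[k]
        added += 1
    return added


def initialize_pair(
    rec: Reconstruction,
    cam_a: int,
    cam_b: int,
    options: CalibrationOptions,
) -> None:
    """Bootstrap the reconstruction from one camera pair.

    Camera a is fixed at identity; camera b comes from homography RANSAC on
    normalized correspondences, analytic decomposition and cheirality
    selection, with unit-baseline gauge. Inlier tracks are triangulated.
    When two decompositions are exactly consistent (the planar two-solution
    ambiguity) a third camera disambiguates via PnP inlier support.
    """
    sel_a = (rec.obs_cam == cam_a) & rec.obs_active
    sel_b = (rec.obs_cam == cam_b) & rec.obs_active
    tids_a = dict(zip(rec.obs_tid[sel_a], np.where(sel_a)[0]))
    tids_b = dict(zip(rec.obs_tid[sel_b], np.where(sel_b)[0]))
    shared = sorted(set(tids_a) & set(tids_b))
    if len(shared) < 4:
        raise InsufficientDataError("initial pair shares < 4 correspondences")
    ia = np.array([tids_a[t] for t in shared])
    ib = np.array([tids_b[t] for t in shared])
    xa = rec.normalized(ia)
    xb = rec.normalized(ib)
    Ka, Kb = rec.intrinsics[cam_a], rec.intrinsics[cam_b]
    H, inliers = estimate_homography_ransac(
        xa, xb, options.ransac_threshold_px, Ka, Kb, seed=options.seed * 7919 + 1
    )
    cands = decompose_homography(H)
    ranked = rank_decompositions(cands, xa[inliers], xb[inliers])
    top = [r for r in ranked if r[1] > 0.5]
    if not top:
        raise DecompositionError("no decomposition passes cheirality")
    chosen = top[0][0]
    strong = [r for r in top if top[0][1] - r[1] < 0.02]
    if len(strong) > 1:
        chosen = _disambiguate_with_third_view(
            rec, cam_a, cam_b, [s[0] for s in strong], shared, inliers, xa, xb, options
        )
    if np.linalg.norm(chosen.t_over_d) < 1e-9:
        raise DegenerateGeometryError(
            "initial pair has no parallax (pure rotation); cannot triangulate"
        )
    rec.poses[cam_a] = CameraPose.identity()
    rec.poses[cam_b] = CameraPose(chosen.R, chosen.t_unit)
    rec.gauge_pair = (cam_a, cam_b)
    rec.registration_order = [cam_a, cam_b]
    in_tids = np.array([t for t, keep in zip(shared, inliers) if keep])
    _triangulate_tracks(rec, in_tids, options)
    if len(rec.points) < 4:
        raise DegenerateGeometryError("initialization triangulated < 4 points")
    logger.info(
        "initialized pair (%s, %s): %d inliers, %d points",
        rec.camera_ids[cam_a], rec.camera_ids[cam_b], int(inliers.sum()), len(rec.points),
    )


def _disambiguate_with_third_view(
    rec, cam_a, cam_b, candidates, shared, inliers, xa, xb, options
):
    """Pick among exactly-consistent decompositions using another camera."""
    others = [c for c in range(rec.n_cameras) if c not in (cam_a, cam_b)]
    in_tids = np.array([t for t, keep in zip(shared, inliers) if keep])
    best_cand, best_support = candidates[0], -1
    for cand in candidates:
        if np.linalg.norm(cand.t_over_d) < 1e-9:
            continue
        # provisional triangulation under this hypothesis
        trial = Reconstruction(
            camera_ids=rec.camera_ids,
            intrinsics=rec.intrinsics,
            obs_cam=rec.obs_cam,
            obs_tid=rec.obs_tid,
            obs_xy=rec.obs_xy,
            marker_ids=rec.marker_ids,
        )
        trial.poses[cam_a] = CameraPose.identity()
        trial.poses[cam_b] = CameraPose(cand.R, cand.t_unit)
        _triangulate_tracks(trial, in_tids, options)
        if len(trial.points) < options.min_pnp_points:
            continue
        support = len(trial.points)
        pnp_support = 0
        for c in others:
            selc = (rec.obs_cam == c) & rec.obs_active
            have = [t for t in np.unique(rec.obs_tid[selc]) if t in trial.points]
            if len(have) < options.min_pnp_points:
                continue
            idxc = np.where(selc & np.isin(rec.obs_tid, have))[0]
            pts3d = np.stack([trial.points[t] for t in rec.obs_tid[idxc]])
            try:
                _, mask = pnp_ransac(
                    rec.intrinsics[c], pts3d, rec.obs_xy[idxc],
                    options.pnp_threshold_px, seed=options.seed * 104729 + c,
                )
                pnp_support += int(mask.sum())
            except (RegistrationError, InsufficientDataError):
                continue
            break  # one third view is enough
        total = support + 10 * pnp_support
        if total > best_support:
            best_support, best_cand = total, cand
    return best_cand


# ---------------------------------------------------------------------------
# incremental loop


def _registered_obs(rec: Reconstruction) -> np.ndarray:
    reg = np.array(sorted(rec.poses), dtype=np.int64)
    have_pt = np.isin(rec.obs_tid, np.array(sorted(rec.points), dtype=np.int64))
    return np.isin(rec.obs_cam, reg) & have_pt & rec.obs_active


def register_next(rec: Reconstruction, options: CalibrationOptions) -> int | None:
    """Register the best unregistered camera by PnP; triangulate; BA.

    Returns the camera index registered, or None when no camera is
    eligible (the caller then reports the remainder as unregistered).
    """
    tri = np.array(sorted(rec.points), dtype=np.int64)
    unreg = [c for c in range(rec.n_cameras) if c not in rec.poses]
    scored = []
    for c in unreg:
        sel = (rec.obs_cam == c) & np.isin(rec.obs_tid, tri) & rec.obs_active
        n = int(sel.sum())
        if n < max(4, options.min_pnp_points):
            continue
        K = rec.intrinsics[c]
        s = _occupancy_score(rec.obs_xy[sel], K.width, K.height, options.score_levels)
        scored.append((s, c))
    if not scored:
        return None
    scored.sort(key=lambda sc: (-sc[0], sc[1]))
    # early structure can be too rough for a strict fit in some views;
    # fall through to the next-best camera instead of aborting the loop
    pose = mask = None
    for best_score, c in scored:
        sel = np.where(
            (rec.obs_cam == c) & np.isin(rec.obs_tid, tri) & rec.obs_active
        )[0]
        pts3d = np.stack([rec.points[t] for t in rec.obs_tid[sel]])
        try:
            pose, mask = pnp_ransac(
                rec.intrinsics[c], pts3d, rec.obs_xy[sel],
                options.pnp_threshold_px, seed=options.seed * 15485863 + c,
                min_inlier_ratio=options.min_pnp_inlier_ratio,
            )
            break
        except (RegistrationError, InsufficientDataError) as e:
            logger.info("deferring camera %s: %s", rec.camera_ids[c], e)
            pose = None
    if pose is None:
        raise RegistrationError("no remaining camera can be registered")
    rec.poses[c] = pose
    rec.registration_order.append(c)
    # triangulate tracks newly covered by >= 2 registered cameras
    reg = np.array(sorted(rec.poses), dtype=np.int64)
    cand = np.unique(
        rec.obs_tid[(rec.obs_cam == c) & rec.obs_active]
    )
    cand = np.array([t for t in cand if t not in rec.points], dtype=np.int64)
    n_new = _triangulate_tracks(rec, cand, options) if len(cand) else 0
    logger.info(
        "registered %s (%d/%d PnP inliers, score %.0f), %d new points",
        rec.camera_ids[c], int(mask.sum()), len(sel), best_score, n_new,
    )
    n_done = len(rec.registration_order)
    if options.retriangulate_every and (n_done % options.retriangulate_every == 0):
        remaining = np.array(
            [t for t in np.unique(rec.obs_tid) if t not in rec.points], dtype=np.int64
        )
        if len(remaining):
            _triangulate_tracks(rec, remaining, options)
    bundle_adjust(
        rec, coplanar=False,
        ba_options=BAOptions(max_iterations=options.intermediate_ba_iterations),
    )
    return c


def bundle_adjust(
    rec: Reconstruction,
    coplanar: bool = False,
    ba_options: BAOptions | None = None,
):
    """Adjust all registered poses and triangulated points in place.

    Holds intrinsics fixed, freezes the first gauge camera, renormalizes the
    initial-pair baseline to 1 afterwards. With ``coplanar`` the points are
    reparametrized in a jointly-estimated floor plane (hard constraint).
    Returns the BAResult (and the PlaneModel when coplanar).
    """
    reg = sorted(rec.poses)
    tri = sorted(rec.points)
    if len(reg) < 2 or len(tri) == 0:
        raise CalibrationError("bundle adjustment needs >= 2 cameras with points")
    slot = {c: i for i, c in enumerate(reg)}
    tslot = {t: i for i, t in enumerate(tri)}
    sel = np.where(_registered_obs(rec))[0]
    cam_idx = np.array([slot[c] for c in rec.obs_cam[sel]])
    blk_idx = np.array([tslot[t] for t in rec.obs_tid[sel]])
    xy = rec.obs_xy[sel]
    poses = [rec.poses[c] for c in reg]
    pts = np.stack([rec.points[t] for t in tri])
    anchor = rec.gauge_pair[0] if rec.gauge_pair else reg[0]
    fixed = (slot[anchor],)
    Ks = [rec.intrinsics[c] for c in reg]
    if coplanar:
        new_poses, (new_pts, plane), res = adjust(
            poses, Ks, cam_idx, blk_idx, xy, mode="plane", points=pts,
            fixed_cameras=fixed, options=ba_options,
        )
    else:
        new_poses, new_pts, res = adjust(
            poses, Ks, cam_idx, blk_idx, xy, mode="free", points=pts,
            fixed_cameras=fixed, options=ba_options,
        )
        plane = None
    for c, p in zip(reg, new_poses):
        rec.poses[c] = p
    for t, X in zip(tri, new_pts):
        rec.points[t] = X
    s = _renormalize_gauge(rec)
    if plane is not None and s is not None:
        plane = PlaneModel(origin=plane.origin * s, e1=plane.e1, e2=plane.e2)
    return res, plane


def _renormalize_gauge(rec: Reconstruction) -> float | None:
    """Rescale so the initial-pair baseline is 1; returns the scale used."""
    if rec.gauge_pair is None:
        return None
    a, b = rec.gauge_pair
    if a not in rec.poses or b not in rec.poses:
        return None
    base = np.linalg.norm(rec.poses[b].center - rec.poses[a].center)
    if base < 1e-12:
        return None
    s = 1.0 / base
    for c in rec.poses:
        p = rec.poses[c]
        rec.poses[c] = CameraPose(p.R, p.t * s)
    for t in rec.points:
        rec.points[t] = rec.points[t] * s
    return s


def _drop_outliers(rec: Reconstruction, options: CalibrationOptions) -> int:
    """Deactivate observations with residual > k * robust sigma."""
    sel = np.where(_registered_obs(rec))[0]
    if len(sel) == 0:
        return 0
    res = np.empty(len(sel))
    for c in sorted(rec.poses):
        m = rec.obs_cam[sel] == c
        if not np.any(m):
            continue
        X = np.stack([rec.points[t] for t in rec.obs_tid[sel[m]]])
        px, _ = project_ideal(rec.intrinsics[c], rec.poses[c], X)
        res[m] = np.linalg.norm(px - rec.obs_xy[sel[m]], axis=1)
    scale = 1.4826 * np.median(np.abs(res - np.median(res))) + 1e-12
    bad = res > np.median(res) + options.outlier_robust_sigmas * scale
    rec.obs_active[sel[bad]] = False
    # drop points that lost 2-view support
    counts = {}
    for i in np.where(_registered_obs(rec))[0]:
        t = rec.obs_tid[i]
        if t in rec.points:
            counts[t] = counts.get(t, 0) + 1
    for t in list(rec.points):
        if counts.get(t, 0) < 2:
            del rec.points[t]
    return int(bad.sum())


def calibrate(
    tracks: list[ObservationTrack],
    intrinsics: dict[str, CameraIntrinsics],
    options: CalibrationOptions | None = None,
) -> CalibrationResult:
    """Full incremental calibration from observation tracks.

    initialize -> repeat register_next -> final BA -> outlier pass ->
    final BA. Partial results (unregistered cameras listed) are returned
    rather than raised when some cameras cannot be registered.
    """
    options = options or CalibrationOptions()
    rec = build_reconstruction(tracks, intrinsics)
    if rec.n_cameras < 2:
        raise CalibrationError("calibration needs >= 2 cameras")
    pairs = rank_initial_pairs(
        tracks, intrinsics, options.min_shared_correspondences, options.score_levels
    )
    cam_index = {cid: i for i, cid in enumerate(rec.camera_ids)}
    init_error = None
    for a_id, b_id in pairs[:10]:
        try:
            initialize_pair(rec, cam_index[a_id], cam_index[b_id], options)
            init_error = None
            break
        except (DegenerateGeometryError, DecompositionError, InsufficientDataError) as e:
            logger.info("initial pair (%s, %s) rejected: %s", a_id, b_id, e)
            init_error = e
            rec.poses.clear()
            rec.points.clear()
            rec.gauge_pair = None
            rec.registration_order = []
    if init_error is not None:
        raise CalibrationError(f"no viable initial pair: {init_error}")
    bundle_adjust(
        rec, coplanar=False,
        ba_options=BAOptions(max_iterations=options.intermediate_ba_iterations),
    )
    while True:
        try:
            c = register_next(rec, options)
        except (RegistrationError, InsufficientDataError) as e:
            logger.warning("registration stopped: %s", e)
            break
        if c is None:
            break
    ba_opts = BAOptions(max_iterations=options.final_ba_iterations)
    res, plane = bundle_adjust(rec, coplanar=options.coplanar, ba_options=ba_opts)
    n_bad = _drop_outliers(rec, options)
    if n_bad:
        logger.info("outlier pass removed %d observations", n_bad)
    res, plane = bundle_adjust(rec, coplanar=options.coplanar, ba_options=ba_opts)
    return _finalize(rec, options, res, plane)


def _finalize(rec, options, ba_res, plane) -> CalibrationResult:
    sel = np.where(_registered_obs(rec))[0]
    res = np.empty(len(sel))
    for c in sorted(rec.poses):
        m = rec.obs_cam[sel] == c
        if not np.any(m):
            continue
        X = np.stack([rec.points[t] for t in rec.obs_tid[sel[m]]])
        px, _ = project_ideal(rec.intrinsics[c], rec.poses[c], X)
        res[m] = np.linalg.norm(px - rec.obs_xy[sel[m]], axis=1)
    per_cam = {}
    for c in sorted(rec.poses):
        m = rec.obs_cam[sel] == c
        per_cam[rec.camera_ids[c]] = float(res[m].mean()) if np.any(m) else np.nan
    if plane is not None:
        n = plane.normal / np.linalg.norm(plane.normal)
        on_floor = {
            t: abs((rec.points[t] - plane.origin) @ n) < 1e-9 for t in rec.points
        }
    else:
        on_floor = {t: False for t in rec.points}
    points = [
        ScenePoint(
            marker_id=int(rec.marker_ids[t]),
            position=rec.points[t],
            on_floor=on_floor[t],
        )
        for t in sorted(rec.points)
    ]
    registered = [rec.camera_ids[c] for c in sorted(rec.poses)]
    unregistered = [c for c in rec.camera_ids if c not in registered]
    return CalibrationResult(
        poses={rec.camera_ids[c]: rec.poses[c] for c in sorted(rec.poses)},
        points=points,
        residuals_px=res,
        per_camera_mean_reproj=per_cam,
        registered=registered,
        unregistered=unregistered,
        registration_order=[rec.camera_ids[c] for c in rec.registration_order],
        gauge=(
            "world-to-camera poses; first initial-pair camera at identity; "
            "initial-pair baseline = 1"
        ),
        plane=plane,
        mean_reproj_px=float(res.mean()) if len(res) else np.nan,
        n_observations_used=int(len(sel)),
    )
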