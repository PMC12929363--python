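"""Projective geometry core: camera model, homographies, triangulation, PnP.

Conventions used throughout the package:

* Poses are world-to-camera: ``x_cam = R @ X + t``. The camera center in
  world coordinates is ``-R.T @ t``.
* Pixel coordinates are 0-based and refer to pixel centers, x right, y down.
* "Normalized" image coordinates are intrinsics-free: ``(x - c) / f`` after
  undistortion, i.e. the ideal pinhole ray with unit focal length.
* Distortion is the standard radial (k1, k2, k3) + tangential (p1, p2) model
  in the coefficient order ``[k1, k2, p1, p2, k3]``. All multi-view geometry
  operates on undistorted points; distortion is applied/removed only at the
  image interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation as _Rot

from .exceptions import (
    CheiralityError,
    DecompositionError,
    DegenerateGeometryError,
    IllConditionedError,
    InsufficientDataError,
    RegistrationError,
)

__all__ = [
    "CameraIntrinsics",
    "CameraPose",
    "Homography",
    "HomographyCandidate",
    "Sim3",
    "project",
    "scaling_homography",
    "homography_dlt",
    "apply_homography",
    "estimate_homography_ransac",
    "decompose_homography",
    "select_decomposition",
    "triangulate",
    "triangulate_batch",
    "pnp_ransac",
    "umeyama_sim3",
    "rodrigues",
    "so3_log",
]


# ---------------------------------------------------------------------------
# rotation helpers


def rodrigues(w: np.ndarray) -> np.ndarray:
    """Axis-angle vector(s) -> rotation matrix/matrices (vectorized)."""
    w = np.asarray(w, dtype=float)
    single = w.ndim == 1
    w = np.atleast_2d(w)
    theta = np.linalg.norm(w, axis=1, keepdims=True)
    small = theta[:, 0] < 1e-12
    axis = np.where(theta > 1e-12, w / np.where(theta == 0, 1.0, theta), 0.0)
    K = np.zeros((len(w), 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    s = np.sin(theta)[..., None]
    c = np.cos(theta)[..., None]
    R = np.eye(3)[None] + s * K + (1.0 - c) * (K @ K)
    # first-order fallback for tiny angles
    Wx = np.zeros_like(K)
    Wx[:, 0, 1], Wx[:, 0, 2] = -w[:, 2], w[:, 1]
    Wx[:, 1, 0], Wx[:, 1, 2] = w[:, 2], -w[:, 0]
    Wx[:, 2, 0], Wx[:, 2, 1] = -w[:, 1], w[:, 0]
    R[small] = np.eye(3)[None] + Wx[small]
    return R[0] if single else R


def so3_log(R: np.ndarray) -> np.ndarray:
    """Rotation matrix -> axis-angle vector."""
    return _Rot.from_matrix(R).as_rotvec()


def rotation_geodesic_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic angle between two rotations in degrees."""
    c = (np.trace(Ra.T @ Rb) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _closest_rotation(M: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics with radial/tangential distortion.

    ``dist`` is ``[k1, k2, p1, p2, k3]``; shorter vectors are zero-padded.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    dist: np.ndarray = field(default_factory=lambda: np.zeros(5))
    width: int = 1920
    height: int = 1080
    camera_id: str = ""

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError(f"focal lengths must be positive (camera {self.camera_id!r})")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError(f"principal point outside image (camera {self.camera_id!r})")
        d = np.zeros(5)
        dv = np.asarray(self.dist, dtype=float).ravel()
        d[: len(dv)] = dv
        object.__setattr__(self, "dist", d)

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def distort_normalized(self, xn: np.ndarray) -> np.ndarray:
        """Apply the lens model to ideal normalized points."""
        xn = np.atleast_2d(np.asarray(xn, dtype=float))
        k1, k2, p1, p2, k3 = self.dist
        x, y = xn[:, 0], xn[:, 1]
        r2 = x * x + y * y
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        return np.stack([xd, yd], axis=1)

    def undistort_normalized(self, xd: np.ndarray) -> np.ndarray:
        """Invert the lens model by fixed-point/Newton iteration."""
        xd = np.atleast_2d(np.asarray(xd, dtype=float))
        if not np.any(self.dist):
            return xd.copy()
        x = xd.copy()
        for _ in range(50):
            d = self.distort_normalized(x)
            err = d - xd
            if np.max(np.abs(err)) < 1e-14:
                break
            x = x - err
        return x

    def pixel_to_normalized(self, px: np.ndarray, undistort: bool = True) -> np.ndarray:
        px = np.atleast_2d(np.asarray(px, dtype=float))
        xn = (px - [self.cx, self.cy]) / [self.fx, self.fy]
        return self.undistort_normalized(xn) if undistort else xn

    def normalized_to_pixel(self, xn: np.ndarray, distort: bool = True) -> np.ndarray:
        xn = np.atleast_2d(np.asarray(xn, dtype=float))
        if distort:
            xn = self.distort_normalized(xn)
        return xn * [self.fx, self.fy] + [self.cx, self.cy]

    def undistort_pixel(self, px: np.ndarray) -> np.ndarray:
        """Distorted pixel -> ideal (pinhole) pixel coordinates."""
        return self.normalized_to_pixel(self.pixel_to_normalized(px), distort=False)

    def distort_pixel(self, px: np.ndarray) -> np.ndarray:
        """Ideal (pinhole) pixel -> distorted pixel coordinates."""
        return self.normalized_to_pixel(
            self.pixel_to_normalized(px, undistort=False), distort=True
        )

    def in_image(self, px: np.ndarray, margin: float = 0.0) -> np.ndarray:
        px = np.atleast_2d(px)
        return (
            (px[:, 0] >= -0.5 + margin)
            & (px[:, 0] <= self.width - 0.5 - margin)
            & (px[:, 1] >= -0.5 + margin)
            & (px[:, 1] <= self.height - 0.5 - margin)
        )


@dataclass
class CameraPose:
    """Rigid world-to-camera transform: ``x_cam = R @ X + t``."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if np.max(np.abs(self.R.T @ self.R - np.eye(3))) > 1e-8:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("rotation is improper (det < 0)")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return -self.R.T @ self.t

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.R.T + self.t

    def inverse(self) -> "CameraPose":
        return CameraPose(self.R.T, -self.R.T @ self.t)

    def compose(self, other: "CameraPose") -> "CameraPose":
        """self ∘ other: apply ``other`` first."""
        return CameraPose(self.R @ other.R, self.R @ other.t + self.t)

    @classmethod
    def identity(cls) -> "CameraPose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def look_at(cls, center: np.ndarray, target: np.ndarray, up: np.ndarray = None) -> "CameraPose":
        """Camera at ``center`` with optical axis through ``target``.

        The camera up-vector is the world +z axis projected into the image
        plane (no roll); if the axis is parallel to z, +y is used.
        """
        center = np.asarray(center, dtype=float)
        target = np.asarray(target, dtype=float)
        z = target - center
        nz = np.linalg.norm(z)
        if nz < 1e-12:
            raise ValueError("camera center coincides with target")
        z = z / nz
        if up is None:
            up = np.array([0.0, 0.0, 1.0])
        up = np.asarray(up, dtype=float)
        if np.linalg.norm(np.cross(up, z)) < 1e-8:
            up = np.array([0.0, 1.0, 0.0])
        x = np.cross(-up, z)  # image x right, y down with world-z up
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        R = np.stack([x, y, z], axis=0)
        return cls(R, -R @ center)


@dataclass(frozen=True)
class Homography:
    """3x3 projective map stored with unit Frobenius norm and a fixed sign.

    The sign convention makes the last nonzero element (scanning h33, h32,
    ...) positive, so that equal maps compare equal elementwise.
    """

    matrix: np.ndarray

    def __post_init__(self):
        H = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        n = np.linalg.norm(H)
        if not np.isfinite(n) or n < 1e-15:
            raise ValueError("homography matrix is zero or non-finite")
        H = H / n
        flat = H.ravel()[::-1]
        nz = flat[np.abs(flat) > 1e-12]
        if len(nz) and nz[0] < 0:
            H = -H
        object.__setattr__(self, "matrix", H)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return apply_homography(self.matrix, pts)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))


@dataclass(frozen=True)
class Sim3:
    """Similarity transform ``y = scale * R @ x + t``."""

    scale: float
    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("Sim3 scale must be positive")
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float).reshape(3, 3))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.scale * X @ self.R.T + self.t


# ---------------------------------------------------------------------------
# projection


def project(K: CameraIntrinsics, P: CameraPose, X: np.ndarray, strict: bool = True):
    """Project world point(s) to distorted pixel coordinates.

    With ``strict`` a non-positive depth raises :class:`CheiralityError`;
    otherwise a visibility mask is returned alongside the pixels.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    Xc = P.transform(np.atleast_2d(X))
    z = Xc[:, 2]
    ok = z > 1e-12
    if strict and not np.all(ok):
        raise CheiralityError("point at or behind the camera plane")
    zsafe = np.where(ok, z, 1.0)
    xn = Xc[:, :2] / zsafe[:, None]
    px = K.normalized_to_pixel(xn, distort=True)
    if single:
        return px[0] if strict else (px[0], bool(ok[0]))
    return px if strict else (px, ok)


def project_ideal(K: CameraIntrinsics, P: CameraPose, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project to ideal (undistorted) pixels, returning (pixels, depth)."""
    Xc = P.transform(np.atleast_2d(np.asarray(X, dtype=float)))
    z = Xc[:, 2]
    zsafe = np.where(np.abs(z) < 1e-12, 1e-12, z)
    xn = Xc[:, :2] / zsafe[:, None]
    return K.normalized_to_pixel(xn, distort=False), z


# ---------------------------------------------------------------------------
# homographies


def scaling_homography(p: np.ndarray, lam: float) -> Homography:
    """Planar scaling about fixed point ``p``: ``s(x) = lam*(x - p) + p``."""
    if lam <= 0:
        raise ValueError("scale factor must be positive")
    p = np.asarray(p, dtype=float).reshape(2)
    H = np.array(
        [
            [lam, 0.0, (1.0 - lam) * p[0]],
            [0.0, lam, (1.0 - lam) * p[1]],
            [0.0, 0.0, 1.0],
        ]
    )
    return Homography(H)


def apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    H = np.asarray(H, dtype=float)
    pts = np.asarray(pts, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    ph = np.hstack([pts, np.ones((len(pts), 1))]) @ H.T
    w = ph[:, 2]
    if np.any(np.abs(w) < 1e-15):
        raise DegenerateGeometryError("point maps to the line at infinity")
    out = ph[:, :2] / w[:, None]
    return out[0] if single else out


def _hartley_normalize(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = pts.mean(axis=0)
    d = np.sqrt(((pts - c) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2.0) / max(d, 1e-15)
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    return (pts - c) * s, T


def homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalized DLT homography from >= 4 correspondences."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) < 4:
        raise InsufficientDataError("homography needs >= 4 correspondences")
    s, Ts = _hartley_normalize(src)
    d, Td = _hartley_normalize(dst)
    n = len(src)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = -s
    A[0::2, 2] = -1.0
    A[0::2, 6:8] = s * d[:, [0]]
    A[0::2, 8] = d[:, 0]
    A[1::2, 3:5] = -s
    A[1::2, 5] = -1.0
    A[1::2, 6:8] = s * d[:, [1]]
    A[1::2, 8] = d[:, 1]
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-12 * max(sv[0], 1e-300):
        raise DegenerateGeometryError("degenerate correspondence configuration")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return H / np.linalg.norm(H)


def _sample_noncollinear(rng, n, src, tries=100, k=4):
    for _ in range(tries):
        idx = rng.choice(n, size=k, replace=False)
        p = src[idx]
        ok = True
        for drop in range(k):
            q = np.delete(p, drop, axis=0)
            area = abs(
                (q[1, 0] - q[0, 0]) * (q[2, 1] - q[0, 1])
                - (q[2, 0] - q[0, 0]) * (q[1, 1] - q[0, 1])
            )
            scale2 = max(np.ptp(q[:, 0]), np.ptp(q[:, 1]), 1e-12) ** 2
            if area < 1e-9 * scale2:
                ok = False
                break
        if ok:
            return idx
    return None


def estimate_homography_ransac(
    src: np.ndarray,
    dst: np.ndarray,
    threshold_px: float,
    K_src: CameraIntrinsics,
    K_dst: CameraIntrinsics,
    seed: int,
    confidence: float = 0.999,
    max_iters: int = 10000,
) -> tuple[Homography, np.ndarray]:
    """RANSAC homography on normalized correspondences.

    The pixel-domain threshold is converted to the normalized domain as
    ``threshold_px / sqrt(fx*fy)`` using the longer-focal (more conservative)
    of the two cameras. The error is the one-sided transfer error in the
    destination image. The final model is refit on all inliers by DLT.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = len(src)
    if n < 4:
        raise InsufficientDataError("RANSAC homography needs >= 4 correspondences")
    f = max(np.sqrt(K_src.fx * K_src.fy), np.sqrt(K_dst.fx * K_dst.fy))
    thr = threshold_px / f
    rng = np.random.default_rng(seed)
    best_mask = None
    best_count = 0
    best_H = None
    it = 0
    needed = max_iters
    while it < min(needed, max_iters):
        it += 1
        idx = _sample_noncollinear(rng, n, src)
        if idx is None:
            raise DegenerateGeometryError("all minimal samples are degenerate")
        try:
            H = homography_dlt(src[idx], dst[idx])
        except DegenerateGeometryError:
            continue
        ph = np.hstack([src, np.ones((n, 1))]) @ H.T
        w = ph[:, 2]
        bad = np.abs(w) < 1e-15
        proj = ph[:, :2] / np.where(bad, 1.0, w)[:, None]
        err = np.linalg.norm(proj - dst, axis=1)
        mask = (err < thr) & ~bad
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask, best_H = count, mask, H
            ratio = count / n
            if ratio >= 1.0:
                break
            denom = np.log(max(1.0 - ratio**4, 1e-15))
            needed = (
                max_iters
                if denom >= -1e-300
                else int(min(np.ceil(np.log(1.0 - confidence) / denom), max_iters))
            )
    if best_mask is None or best_count < 4:
        raise DegenerateGeometryError("RANSAC failed to find a valid homography")
    H = homography_dlt(src[best_mask], dst[best_mask])
    # final inlier set against the refit model
    ph = np.hstack([src, np.ones((n, 1))]) @ H.T
    w = ph[:, 2]
    bad = np.abs(w) < 1e-15
    proj = ph[:, :2] / np.where(bad, 1.0, w)[:, None]
    err = np.linalg.norm(proj - dst, axis=1)
    mask = (err < thr) & ~bad
    if mask.sum() >= 4:
        H = homography_dlt(src[mask], dst[mask])
    else:
        mask = best_mask
    return Homography(H), mask


# ---------------------------------------------------------------------------
# homography decomposition (plane-induced relative pose)


@dataclass(frozen=True)
class HomographyCandidate:
    """One solution of ``H ∝ R + (t/d) nᵀ``: rotation, translation, normal."""

    R: np.ndarray
    t_over_d: np.ndarray
    n: np.ndarray

    @property
    def t_unit(self) -> np.ndarray:
        nt = np.linalg.norm(self.t_over_d)
        return self.t_over_d / nt if nt > 1e-9 else np.zeros(3)


def decompose_homography(H: Homography | np.ndarray) -> list[HomographyCandidate]:
    """Analytic decomposition of a normalized-coordinate plane homography.

    Returns the up-to-eight (sign-ambiguous) analytic solutions
    ``{R, t/d, n}``; cheirality-based disambiguation is done by
    :func:`select_decomposition`. A (near) pure-rotation homography yields a
    single zero-translation candidate.
    """
    Hm = H.matrix if isinstance(H, Homography) else np.asarray(H, dtype=float)
    sv = np.linalg.svd(Hm, compute_uv=False)
    if sv[-1] < 1e-12 * sv[0]:
        raise DegenerateGeometryError("homography is singular")
    Hn = Hm / sv[1]

    A = Hn.T @ Hn
    evals, evecs = np.linalg.eigh(A)  # ascending
    s3sq, _, s1sq = evals
    v3, v2, v1 = evecs[:, 0], evecs[:, 1], evecs[:, 2]

    if s1sq - s3sq < 1e-9:
        # pure rotation (plane at infinity limit): H is orthogonal up to scale
        R = _closest_rotation(Hn)
        return [HomographyCandidate(R, np.zeros(3), np.array([0.0, 0.0, 1.0]))]

    a = np.sqrt(max(1.0 - s3sq, 0.0))
    b = np.sqrt(max(s1sq - 1.0, 0.0))
    denom = np.sqrt(s1sq - s3sq)
    u1 = (a * v1 + b * v3) / denom
    u2 = (a * v1 - b * v3) / denom

    cands: list[HomographyCandidate] = []
    for Hs in (Hn, -Hn):
        for u in (u1, u2):
            U = np.stack([v2, u, np.cross(v2, u)], axis=1)
            W = np.stack(
                [Hs @ v2, Hs @ u, np.cross(Hs @ v2, Hs @ u)], axis=1
            )
            R = W @ U.T
            R = _closest_rotation(R)
            nvec = np.cross(v2, u)
            nn = np.linalg.norm(nvec)
            if nn < 1e-12:
                continue
            nvec = nvec / nn
            t_over_d = (Hs - R) @ nvec
            resid = np.linalg.norm(Hs - (R + np.outer(t_over_d, nvec)))
            if resid < 1e-6:
                cands.append(HomographyCandidate(R, t_over_d, nvec))
                # (R, -t/d, -n) generates the same homography
                cands.append(HomographyCandidate(R, -t_over_d, -nvec))
    # deduplicate (sign pairs can coincide for special geometries)
    unique: list[HomographyCandidate] = []
    for c in cands:
        dup = any(
            np.allclose(c.R, u.R, atol=1e-9)
            and np.allclose(c.t_over_d, u.t_over_d, atol=1e-9)
            and np.allclose(c.n, u.n, atol=1e-9)
            for u in unique
        )
        if not dup:
            unique.append(c)
    if not unique:
        raise DecompositionError("no analytic decomposition satisfies the residual bound")
    return unique


def _triangulate_two_view_normalized(R, t, x1, x2):
    """Midpoint-free linear two-view triangulation, vectorized over points.

    Camera 1 at identity, camera 2 at (R, t); x1, x2 are (N, 2) normalized.
    Returns (X (N,3), z1, z2).
    """
    n = len(x1)
    # DLT rows: x*(P3.X) - P1.X = 0 for each view
    P2 = np.hstack([R, t.reshape(3, 1)])
    A = np.zeros((n, 4, 4))
    A[:, 0, 0] = -1.0
    A[:, 0, 2] = x1[:, 0]
    A[:, 1, 1] = -1.0
    A[:, 1, 2] = x1[:, 1]
    A[:, 2] = x2[:, [0]] * P2[2] - P2[0]
    A[:, 3] = x2[:, [1]] * P2[2] - P2[1]
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[:, -1, :]
    w = Xh[:, 3]
    w = np.where(np.abs(w) < 1e-15, 1e-15, w)
    X = Xh[:, :3] / w[:, None]
    z1 = X[:, 2]
    z2 = (X @ R.T + t)[:, 2]
    return X, z1, z2


def rank_decompositions(
    candidates: Sequence[HomographyCandidate],
    src: np.ndarray,
    dst: np.ndarray,
) -> list[tuple[HomographyCandidate, float, float]]:
    """Score decomposition candidates by cheirality support.

    For each candidate returns ``(candidate, support, transfer_error)`` where
    support is the fraction of correspondences that triangulate with positive
    depth in both views and lie on the visible side of the plane
    (``nᵀ [x, 1] > 0`` in camera 1). Sorted best-first (support descending,
    transfer error ascending).
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if len(src) < 2:
        raise InsufficientDataError("need >= 2 correspondences to disambiguate")
    rays1 = np.hstack([src, np.ones((len(src), 1))])
    scored = []
    for c in candidates:
        tn = np.linalg.norm(c.t_over_d)
        if tn < 1e-9:
            scored.append((c, 0.0, np.inf))
            continue
        X, z1, z2 = _triangulate_two_view_normalized(c.R, c.t_unit, src, dst)
        front_plane = rays1 @ c.n > 0
        frac = float(np.mean((z1 > 0) & (z2 > 0) & front_plane))
        Hc = c.R + np.outer(c.t_over_d, c.n)
        ph = rays1 @ Hc.T
        w = np.where(np.abs(ph[:, 2]) < 1e-15, 1e-15, ph[:, 2])
        reproj = float(np.mean(np.linalg.norm(ph[:, :2] / w[:, None] - dst, axis=1)))
        scored.append((c, frac, reproj))
    scored.sort(key=lambda s: (-s[1], s[2]))
    return scored


def select_decomposition(
    candidates: Sequence[HomographyCandidate],
    src: np.ndarray,
    dst: np.ndarray,
    min_support: float = 0.5,
) -> HomographyCandidate:
    """Pick the physically valid decomposition by cheirality.

    Best candidate under :func:`rank_decompositions`; ties are broken by
    lower mean transfer error. Fails if no candidate passes cheirality for
    more than ``min_support`` of the correspondences.

    A single inter-image homography occasionally admits two exactly
    consistent decompositions (the classical two-solution ambiguity of
    planar relative pose); callers holding a third view should use
    :func:`rank_decompositions` and disambiguate with it.
    """
    if len(candidates) == 0:
        raise DecompositionError("no candidates supplied")
    if len(candidates) == 1:
        return candidates[0]
    scored = rank_decompositions(candidates, src, dst)
    best, frac, _ = scored[0]
    if frac <= min_support:
        raise DecompositionError(
            f"no decomposition passes cheirality for > {min_support:.0%} of points"
        )
    return best


# ---------------------------------------------------------------------------
# triangulation


def triangulate(
    poses: Sequence[CameraPose],
    intrinsics: Sequence[CameraIntrinsics],
    obs_px: np.ndarray,
    min_baseline: float = 1e-8,
    refine: bool = True,
) -> np.ndarray:
    """Multi-view triangulation of one point from >= 2 pixel observations.

    Observations are undistorted internally; linear DLT solution refined by
    Gauss-Newton on the summed squared pixel reprojection error. Raises on
    tiny baselines and on negative depths.
    """
    if len(poses) < 2:
        raise InsufficientDataError("triangulation needs >= 2 views")
    centers = np.stack([p.center for p in poses])
    dmax = max(
        np.linalg.norm(centers[i] - centers[j])
        for i in range(len(poses))
        for j in range(i + 1, len(poses))
    )
    if dmax < min_baseline:
        raise IllConditionedError("camera baseline below tolerance")
    obs_px = np.atleast_2d(np.asarray(obs_px, dtype=float))
    xn = np.stack(
        [K.pixel_to_normalized(o)[0] for K, o in zip(intrinsics, obs_px)]
    )
    rows = []
    for P, x in zip(poses, xn):
        M = np.hstack([P.R, P.t.reshape(3, 1)])
        rows.append(x[0] * M[2] - M[0])
        rows.append(x[1] * M[2] - M[1])
    A = np.stack(rows)
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[-1]
    if abs(Xh[3]) < 1e-12:
        raise IllConditionedError("triangulated point at infinity")
    X = Xh[:3] / Xh[3]
    if refine:
        X = _refine_point(X, poses, intrinsics, obs_px)
    for P in poses:
        if P.transform(X)[0, 2] <= 0:
            raise CheiralityError("triangulated point behind a camera")
    return X


def _refine_point(X, poses, intrinsics, obs_px, iters: int = 10):
    X = X.copy()
    for _ in range(iters):
        JtJ = np.zeros((3, 3))
        Jtr = np.zeros(3)
        for P, K, o in zip(poses, intrinsics, obs_px):
            Xc = P.transform(X)[0]
            z = Xc[2]
            if z <= 1e-12:
                return X
            u = K.fx * Xc[0] / z + K.cx
            v = K.fy * Xc[1] / z + K.cy
            r = np.array([u, v]) - K.undistort_pixel(o)[0]
            Jc = np.array(
                [
                    [K.fx / z, 0.0, -K.fx * Xc[0] / z**2],
                    [0.0, K.fy / z, -K.fy * Xc[1] / z**2],
                ]
            )
            J = Jc @ P.R
            JtJ += J.T @ J
            Jtr += J.T @ r
        try:
            dX = np.linalg.solve(JtJ + 1e-12 * np.eye(3), -Jtr)
        except np.linalg.LinAlgError:
            return X
        X = X + dX
        if np.linalg.norm(dX) < 1e-14:
            break
    return X


def triangulate_batch(
    cam_idx_per_obs: np.ndarray,
    track_idx_per_obs: np.ndarray,
    xn_per_obs: np.ndarray,
    poses: Sequence[CameraPose],
    n_tracks: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear DLT triangulation of many tracks at once.

    Inputs are flat observation arrays (camera index, track index, normalized
    coordinates). Returns (points (T,3), valid mask); tracks with < 2
    observations or near-singular normal equations are invalid.
    """
    M = np.stack([np.hstack([p.R, p.t.reshape(3, 1)]) for p in poses])
    Mo = M[cam_idx_per_obs]  # (N, 3, 4)
    r0 = xn_per_obs[:, [0]] * Mo[:, 2] - Mo[:, 0]  # (N, 4)
    r1 = xn_per_obs[:, [1]] * Mo[:, 2] - Mo[:, 1]
    rows = np.concatenate([r0, r1], axis=0)
    tid = np.concatenate([track_idx_per_obs, track_idx_per_obs])
    A3 = rows[:, :3]
    b = -rows[:, 3]
    AtA = np.zeros((n_tracks, 3, 3))
    Atb = np.zeros((n_tracks, 3))
    np.add.at(AtA, tid, A3[:, :, None] * A3[:, None, :])
    np.add.at(Atb, tid, A3 * b[:, None])
    counts = np.bincount(track_idx_per_obs, minlength=n_tracks)
    valid = counts >= 2
    X = np.zeros((n_tracks, 3))
    dets = np.abs(np.linalg.det(AtA))
    solvable = valid & (dets > 1e-18)
    if np.any(solvable):
        X[solvable] = np.linalg.solve(AtA[solvable], Atb[solvable][..., None])[..., 0]
    return X, solvable


# ---------------------------------------------------------------------------
# PnP


def _pose_from_planar_points(pts3d: np.ndarray, xn: np.ndarray) -> list[CameraPose]:
    """Pose hypotheses from >= 4 coplanar world points and normalized pixels.

    Builds the world-plane-to-image homography and factors it as
    ``H ∝ [r1 r2 t]`` in plane coordinates.
    """
    c = pts3d.mean(axis=0)
    Q = pts3d - c
    U, S, Vt = np.linalg.svd(Q, full_matrices=False)
    e1, e2 = Vt[0], Vt[1]
    uv = np.stack([Q @ e1, Q @ e2], axis=1)
    H = homography_dlt(uv, xn)
    poses = []
    for sgn in (1.0, -1.0):
        Hs = sgn * H
        h1, h2, h3 = Hs[:, 0], Hs[:, 1], Hs[:, 2]
        s = np.sqrt(np.linalg.norm(h1) * np.linalg.norm(h2))
        if s < 1e-15:
            continue
        r1, r2 = h1 / s, h2 / s
        R0 = np.stack([r1, r2, np.cross(r1, r2)], axis=1)
        R0 = _closest_rotation(R0)
        t0 = h3 / s
        # world rotation: columns of R0 are images of (e1, e2, n)
        Rw = R0 @ np.stack([e1, e2, np.cross(e1, e2)], axis=0)
        tw = t0 - Rw @ c
        poses.append(CameraPose(Rw, tw))
    return poses


def _pose_from_dlt(pts3d: np.ndarray, xn: np.ndarray) -> list[CameraPose]:
    """Pose from >= 6 general-position points via projective DLT."""
    n = len(pts3d)
    A = np.zeros((2 * n, 12))
    Xh = np.hstack([pts3d, np.ones((n, 1))])
    A[0::2, 0:4] = -Xh
    A[0::2, 8:12] = xn[:, [0]] * Xh
    A[1::2, 4:8] = -Xh
    A[1::2, 8:12] = xn[:, [1]] * Xh
    _, _, Vt = np.linalg.svd(A)
    M = Vt[-1].reshape(3, 4)
    if np.linalg.det(M[:, :3]) < 0:
        M = -M
    s = np.linalg.svd(M[:, :3], compute_uv=False).mean()
    if s < 1e-15:
        return []
    R = _closest_rotation(M[:, :3] / s)
    t = M[:, 3] / s
    return [CameraPose(R, t)]


def _refine_pose(pose: CameraPose, K: CameraIntrinsics, pts3d, obs_ideal_px):
    """Nonlinear pose refinement on ideal pixel reprojection error."""
    w0 = so3_log(pose.R)

    def resid(p):
        R = rodrigues(p[:3])
        Xc = pts3d @ R.T + p[3:6]
        z = np.where(Xc[:, 2] < 1e-9, 1e-9, Xc[:, 2])
        u = K.fx * Xc[:, 0] / z + K.cx
        v = K.fy * Xc[:, 1] / z + K.cy
        return np.concatenate([u - obs_ideal_px[:, 0], v - obs_ideal_px[:, 1]])

    sol = least_squares(
        resid, np.concatenate([w0, pose.t]), method="lm", xtol=1e-14, ftol=1e-14
    )
    return CameraPose(rodrigues(sol.x[:3]), sol.x[3:6])


def pnp_ransac(
    K: CameraIntrinsics,
    pts3d: np.ndarray,
    pts2d: np.ndarray,
    threshold_px: float,
    seed: int,
    confidence: float = 0.999,
    max_iters: int = 10000,
    min_inlier_ratio: float = 0.25,
) -> tuple[CameraPose, np.ndarray]:
    """Robust camera resectioning from 3D-2D correspondences.

    The minimal solver adapts to the point cloud: a plane-homography pose
    from 4-point samples when the cloud is (near) planar, a 6-point DLT
    otherwise. The winner is refined by Levenberg-Marquardt on the inliers.
    ``pts2d`` are distorted pixel observations.
    """
    pts3d = np.asarray(pts3d, dtype=float)
    pts2d = np.asarray(pts2d, dtype=float)
    n = len(pts3d)
    if n < 4:
        raise InsufficientDataError("PnP needs >= 4 correspondences")
    obs_ideal = K.undistort_pixel(pts2d)
    xn = K.pixel_to_normalized(pts2d)
    # near-planar clouds (thickness < 10% of spread) are degenerate for the
    # 6-point DLT; route them to the plane-homography minimal solver
    sv = np.linalg.svd(pts3d - pts3d.mean(axis=0), compute_uv=False)
    planar = sv[2] < 0.1 * max(sv[1], 1e-12) or n < 6
    k = 4 if planar else 6
    if n < k:
        raise InsufficientDataError(f"PnP needs >= {k} points for this configuration")
    rng = np.random.default_rng(seed)
    best = None
    best_count = 0
    it = 0
    needed = max_iters
    while it < min(needed, max_iters):
        it += 1
        idx = rng.choice(n, size=k, replace=False)
        try:
            if planar:
                hyps = _pose_from_planar_points(pts3d[idx], xn[idx])
            else:
                hyps = _pose_from_dlt(pts3d[idx], xn[idx])
        except (DegenerateGeometryError, InsufficientDataError, ValueError):
            continue
        for pose in hyps:
            px, z = project_ideal(K, pose, pts3d)
            err = np.linalg.norm(px - obs_ideal, axis=1)
            mask = (err < threshold_px) & (z > 0)
            count = int(mask.sum())
            if count > best_count:
                best_count, best = count, (pose, mask)
                ratio = count / n
                if ratio >= 1.0:
                    needed = 0
                else:
                    denom = np.log(max(1.0 - ratio**k, 1e-15))
                    needed = (
                        max_iters
                        if denom >= -1e-300
                        else int(min(np.ceil(np.log(1.0 - confidence) / denom), max_iters))
                    )
    if best is None or best_count < max(4, int(np.ceil(min_inlier_ratio * n))):
        raise RegistrationError(
            f"PnP inlier support too low ({best_count}/{n})"
        )
    pose, mask = best
    pose = _refine_pose(pose, K, pts3d[mask], obs_ideal[mask])
    px, z = project_ideal(K, pose, pts3d)
    err = np.linalg.norm(px - obs_ideal, axis=1)
    mask = (err < threshold_px) & (z > 0)
    if mask.sum() < 4:
        raise RegistrationError("PnP refinement lost its inlier support")
    pose = _refine_pose(pose, K, pts3d[mask], obs_ideal[mask])
    return pose, mask


# ---------------------------------------------------------------------------
# similarity alignment


def umeyama_sim3(source: np.ndarray, target: np.ndarray) -> Sim3:
    """Closed-form least-squares similarity aligning source onto target.

    Minimizes ``sum ||s R x + t - y||^2`` with the determinant correction
    that guarantees a proper rotation even for reflected inputs.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.shape[0] < 3:
        raise InsufficientDataError("Sim(3) alignment needs >= 3 paired points")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    var_x = (Xc**2).sum() / len(X)
    if var_x < 1e-24:
        raise DegenerateGeometryError("source points are coincident")
    C = Yc.T @ Xc / len(X)
    U, D, Vt = np.linalg.svd(C)
    if np.linalg.matrix_rank(C, tol=1e-12 * max(D[0], 1e-300)) < 2:
        raise DegenerateGeometryError("source points are collinear")
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    s = np.trace(np.diag(D) @ S) / var_x
    if s <= 0:
        raise DegenerateGeometryError("non-positive similarity scale")
    t = my - s * R @ mx
    return Sim3(float(s), R, t)
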