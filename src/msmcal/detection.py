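"""Square-fiducial detection and multi-scale observation fusion.

The detector localizes dark square markers on a bright background:
threshold, connected-component analysis, convex-quad extraction, subpixel
edge refinement, then payload decoding against the ``msq25`` dictionary.

The marker center is computed as the intersection of the imaged diagonals
of the outer quad — a projective invariant, so observations of the same
marker taken from arbitrarily different viewpoints (or at different
projected scales) refer to the same physical floor point. Per-scale centers
of one (camera, marker) pair are fused by a robust median with MAD-based
outlier rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .exceptions import DegenerateGeometryError, MsmcalError
from .geometry import CameraIntrinsics, homography_dlt, apply_homography
from .markers import MarkerDictionary, default_dictionary

__all__ = [
    "RawDetection",
    "MarkerObservation",
    "ObservationTrack",
    "detect_frame",
    "center_from_corners",
    "fuse_scales",
    "build_tracks",
]


@dataclass
class RawDetection:
    """One decoded symbol in one frame: ordered outer corners + id."""

    camera_id: str
    frame_idx: int
    symbol_id: int
    corners: np.ndarray  # (4, 2) pixel, canonical order TL,TR,BR,BL
    decode_confidence: float = 1.0

    @property
    def center(self) -> np.ndarray:
        return center_from_corners(self.corners)


@dataclass
class MarkerObservation:
    """Fused image observation of one marker in one camera (distorted px)."""

    camera_id: str
    marker_id: int
    center_px: np.ndarray
    scales_seen: tuple[float, ...] = ()
    n_frames: int = 1
    spread_px: float = 0.0


@dataclass
class ObservationTrack:
    """All observations, across cameras, of one physical marker center."""

    marker_id: int
    observations: dict[str, MarkerObservation] = field(default_factory=dict)
    floor_point_estimate: np.ndarray | None = None

    @property
    def length(self) -> int:
        return len(self.observations)

    @property
    def usable(self) -> bool:
        """Tracks seen by fewer than two cameras cannot constrain geometry."""
        return self.length >= 2


# ---------------------------------------------------------------------------
# geometric center


def center_from_corners(corners: np.ndarray) -> np.ndarray:
    """Intersection of the quad's imaged diagonals (projective invariant)."""
    c = np.asarray(corners, dtype=float)
    if c.shape != (4, 2):
        raise ValueError("need exactly 4 corner points")
    # a quad with 3 (near-)collinear corners is degenerate even when its
    # diagonals still intersect at a finite point
    scale2 = max(np.ptp(c[:, 0]), np.ptp(c[:, 1]), 1e-12) ** 2
    for i in range(4):
        a, b, d = c[i], c[(i + 1) % 4], c[(i + 2) % 4]
        area2 = abs((b[0] - a[0]) * (d[1] - a[1]) - (d[0] - a[0]) * (b[1] - a[1]))
        if area2 < 1e-9 * scale2:
            raise DegenerateGeometryError("degenerate quadrilateral (collinear corners)")
    h = np.hstack([c, np.ones((4, 1))])
    l1 = np.cross(h[0], h[2])
    l2 = np.cross(h[1], h[3])
    x = np.cross(l1, l2)
    scale = np.abs(c).max() + 1.0
    if abs(x[2]) < 1e-12 * (np.linalg.norm(l1) * np.linalg.norm(l2)) ** 0.5 or not np.isfinite(x[2]):
        raise DegenerateGeometryError("degenerate quadrilateral (collinear corners)")
    p = x[:2] / x[2]
    if not np.all(np.isfinite(p)) or np.abs(p).max() > 1e9 * scale:
        raise DegenerateGeometryError("degenerate quadrilateral (collinear corners)")
    return p


# ---------------------------------------------------------------------------
# detector internals


def _otsu(img: np.ndarray) -> float:
    hist, edges = np.histogram(img, bins=128)
    mids = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    total = w.sum()
    if total == 0:
        return 0.5
    cum = np.cumsum(w)
    cmean = np.cumsum(w * mids)
    mean_t = cmean[-1] / total
    w0 = cum / total
    w1 = 1.0 - w0
    mu0 = np.where(cum > 0, cmean / np.maximum(cum, 1e-12), 0)
    mu1 = np.where(w1 > 1e-12, (cmean[-1] - cmean) / np.maximum(total - cum, 1e-12), 0)
    var = w0 * w1 * (mu0 - mu1) ** 2
    return float(mids[np.argmax(var)])


def _hull_to_quad(hull_pts: np.ndarray) -> np.ndarray | None:
    """Reduce a convex polygon to its 4 dominant vertices.

    Iteratively removes the vertex whose removal costs the least area.
    """
    pts = hull_pts.copy()
    while len(pts) > 4:
        n = len(pts)
        costs = np.empty(n)
        for i in range(n):
            a, b, c = pts[i - 1], pts[i], pts[(i + 1) % n]
            costs[i] = abs(
                (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
            )
        pts = np.delete(pts, int(np.argmin(costs)), axis=0)
    if len(pts) < 4:
        return None
    return pts


def _order_quad(quad: np.ndarray) -> np.ndarray:
    """Order corners counterclockwise in image coords, starting top-left."""
    c = quad.mean(axis=0)
    ang = np.arctan2(quad[:, 1] - c[1], quad[:, 0] - c[0])
    quad = quad[np.argsort(ang)]
    start = int(np.argmin(quad.sum(axis=1)))
    return np.roll(quad, -start, axis=0)


def _bilinear(img: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    H, W = img.shape
    x = np.clip(x, 0, W - 1.001)
    y = np.clip(y, 0, H - 1.001)
    x0 = x.astype(int)
    y0 = y.astype(int)
    fx = x - x0
    fy = y - y0
    return (
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x0 + 1] * fx * (1 - fy)
        + img[y0 + 1, x0] * (1 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )


def _refine_edges_subpixel(
    img: np.ndarray, quad: np.ndarray, intrinsics: CameraIntrinsics | None = None
) -> np.ndarray | None:
    """Refine quad corners by fitting lines to subpixel edge crossings.

    For each side, perpendicular intensity profiles are sampled and the
    mid-level dark-to-bright crossing located by linear interpolation; a
    total-least-squares line through the crossings replaces the side, and
    refined corners are the line intersections.

    With ``intrinsics`` the crossings are undistorted before the line fit
    (lens distortion curves long edges, which biases a raw-image fit by
    several tenths of a pixel) and the corners are re-distorted on return,
    so the output stays in raw pixel coordinates.
    """
    side_len = np.linalg.norm(np.roll(quad, -1, axis=0) - quad, axis=1).mean()
    # the hull quad's edges are chords of the (distortion-curved) true
    # edges; the band must cover the chord-to-edge sagitta, which grows
    # with marker size
    reach = max(1.5, min(12.0, side_len / 12.0))
    lines = []
    for i in range(4):
        a, b = quad[i], quad[(i + 1) % 4]
        d = b - a
        L = np.linalg.norm(d)
        if L < 4:
            return None
        d = d / L
        nvec = np.array([-d[1], d[0]])  # outward if quad is CCW in image coords
        # long edges afford more crossings, which averages sampling noise
        m = int(np.clip(L / 8.0, 16, 48))
        ts = np.linspace(0.18, 0.82, m)
        base = a[None, :] + ts[:, None] * (b - a)[None, :]
        ss = np.arange(-reach, reach + 1e-9, 0.25)
        P = base[:, None, :] + ss[None, :, None] * nvec[None, None, :]
        vals = _bilinear(img, P[..., 0], P[..., 1])
        pts = []
        for j in range(m):
            v = vals[j]
            lo, hi = v.min(), v.max()
            if hi - lo < 0.15:
                continue
            mid = 0.5 * (lo + hi)
            # first crossing of mid level scanning outward
            idx = np.where((v[:-1] - mid) * (v[1:] - mid) <= 0)[0]
            if len(idx) == 0:
                continue
            k = idx[np.argmin(np.abs(ss[idx]))]
            denom = v[k + 1] - v[k]
            frac = 0.5 if abs(denom) < 1e-12 else (mid - v[k]) / denom
            s = ss[k] + frac * 0.25
            pts.append(base[j] + s * nvec)
        if len(pts) < 6:
            return None
        pts = np.array(pts)
        if intrinsics is not None:
            pts = intrinsics.undistort_pixel(pts)
        cm = pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(pts - cm)
        direction = Vt[0]
        normal = np.array([-direction[1], direction[0]])
        lines.append((normal, normal @ cm))
    corners = []
    for i in range(4):
        n1, c1 = lines[i - 1]
        n2, c2 = lines[i]
        A = np.stack([n1, n2])
        try:
            p = np.linalg.solve(A, np.array([c1, c2]))
        except np.linalg.LinAlgError:
            return None
        corners.append(p)
    q = np.array(corners)  # line i-1 ∩ line i is corner i
    if intrinsics is not None:
        q = intrinsics.distort_pixel(q)
    if np.linalg.norm(q - quad) > 4.0 * reach:
        return None
    return q


def _decode_quad(img, quad, dictionary, grid_n):
    """Sample the cell grid inside a quad and decode the payload."""
    # homography: canonical cell coords (0..grid) -> image
    canon = np.array([[0, 0], [grid_n, 0], [grid_n, grid_n], [0, grid_n]], float)
    try:
        H = homography_dlt(canon, quad)
    except MsmcalError:
        return None
    def sample(cells):
        pts = apply_homography(H, cells)
        return _bilinear(img, pts[:, 0], pts[:, 1])

    ij = np.arange(grid_n) + 0.5
    border_cells = []
    for k in range(grid_n):
        border_cells += [
            (ij[k], 0.5), (ij[k], grid_n - 0.5), (0.5, ij[k]), (grid_n - 0.5, ij[k]),
        ]
    border_vals = sample(np.array(border_cells))
    # white reference: ring just outside the quad
    out_cells = []
    for k in range(grid_n):
        out_cells += [
            (ij[k], -0.5), (ij[k], grid_n + 0.5), (-0.5, ij[k]), (grid_n + 0.5, ij[k]),
        ]
    white_vals = sample(np.array(out_cells))
    dark_ref = np.median(border_vals)
    white_ref = np.median(white_vals)
    if white_ref - dark_ref < 0.2:
        return None
    thr = 0.5 * (dark_ref + white_ref)
    if np.mean(border_vals < thr) < 0.9:
        return None
    inner = grid_n - 2
    uu, vv = np.meshgrid(np.arange(inner) + 1.5, np.arange(inner) + 1.5)
    payload_vals = sample(np.stack([uu.ravel(), vv.ravel()], axis=1))
    bits = (payload_vals > thr).astype(np.uint8).reshape(inner, inner)
    res = dictionary.decode(bits)
    if res is None:
        return None
    sid, rot = res
    margin = float(np.min(np.abs(payload_vals - thr)) / max(white_ref - dark_ref, 1e-9))
    # rotate corners so they match the canonical (unrotated) marker
    quad_canonical = np.roll(quad, rot, axis=0)
    return sid, quad_canonical, min(1.0, 2.0 * margin)


def detect_frame(
    image: np.ndarray,
    dictionary: MarkerDictionary | None = None,
    camera_id: str = "",
    frame_idx: int = 0,
    min_side_px: float = 8.0,
    intrinsics: CameraIntrinsics | None = None,
) -> list[RawDetection]:
    """Detect and decode all square fiducials in a grayscale image.

    Returns an empty list when nothing is decodable; at most one detection
    per symbol id (largest instance wins). With ``intrinsics``, subpixel
    corner refinement compensates lens distortion (corners are still
    returned in raw pixel coordinates).
    """
    dictionary = dictionary or default_dictionary()
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.5:
        img = img / 255.0
    if np.ptp(img) < 0.1:
        return []
    thr = _otsu(img)
    dark = img < thr
    labels, nlab = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
    if nlab == 0:
        return []
    objects = ndimage.find_objects(labels)
    grid_n = dictionary.grid
    min_area = (min_side_px * (grid_n - 2) / grid_n) ** 2 * 0.3
    detections: dict[int, RawDetection] = {}
    areas = ndimage.sum_labels(dark, labels, index=np.arange(1, nlab + 1))
    for lab in range(1, nlab + 1):
        if areas[lab - 1] < min_area:
            continue
        sl = objects[lab - 1]
        hgt = sl[0].stop - sl[0].start
        wdt = sl[1].stop - sl[1].start
        if hgt < min_side_px * 0.5 or wdt < min_side_px * 0.5:
            continue
        if areas[lab - 1] > 0.95 * hgt * wdt and hgt * wdt > 25:
            continue  # solid blob, not a coded marker
        ys, xs = np.nonzero(labels[sl] == lab)
        pts = np.stack([xs + sl[1].start, ys + sl[0].start], axis=1).astype(float)
        try:
            hull = ConvexHull(pts)
        except QhullError:
            continue
        hull_pts = pts[hull.vertices]
        quad = _hull_to_quad(hull_pts)
        if quad is None:
            continue
        quad = _order_quad(quad)
        sides = np.linalg.norm(np.roll(quad, -1, axis=0) - quad, axis=1)
        if sides.min() < min_side_px or sides.max() / sides.min() > 4.0:
            continue
        # a quad touching the image border is a clipped marker: its visible
        # portion can still decode but its corners are meaningless
        Him, Wim = img.shape
        if (
            quad[:, 0].min() < 2.0 or quad[:, 1].min() < 2.0
            or quad[:, 0].max() > Wim - 3.0 or quad[:, 1].max() > Him - 3.0
        ):
            continue
        # region must fill a plausible fraction of the quad (border ring + bits)
        qa = 0.5 * abs(
            np.dot(quad[:, 0], np.roll(quad[:, 1], -1))
            - np.dot(quad[:, 1], np.roll(quad[:, 0], -1))
        )
        if qa <= 0 or not 0.2 < areas[lab - 1] / qa < 1.05:
            continue
        # hull corners sit at pixel centers half a pixel inside the true edge
        refined = _refine_edges_subpixel(img, quad, intrinsics)
        quad_use = refined if refined is not None else quad
        dec = _decode_quad(img, quad_use, dictionary, grid_n)
        if dec is None:
            continue
        sid, corners, conf = dec
        prev = detections.get(sid)
        cand = RawDetection(camera_id, frame_idx, sid, corners, conf)
        if prev is None or _quad_area(cand.corners) > _quad_area(prev.corners):
            detections[sid] = cand
    return [detections[k] for k in sorted(detections)]


def _quad_area(q: np.ndarray) -> float:
    return 0.5 * abs(
        np.dot(q[:, 0], np.roll(q[:, 1], -1)) - np.dot(q[:, 1], np.roll(q[:, 0], -1))
    )


# ---------------------------------------------------------------------------
# fusion and tracks


def fuse_scales(
    raw: list[RawDetection],
    marker_id: int,
    scales_by_frame: dict[int, float] | None = None,
    mad_sigmas: float = 3.5,
    gate_px: float = 2.0,
) -> MarkerObservation | None:
    """Fuse per-scale detections of one (camera, marker) into one center.

    Coordinate-wise median of the diagonal-intersection centers with
    MAD-based rejection at ``mad_sigmas`` robust sigmas and an absolute gate
    of ``gate_px``; returns None when gating rejects everything. The result
    is permutation-invariant and deterministic.
    """
    if not raw:
        return None
    raw = sorted(raw, key=lambda r: (r.frame_idx, r.symbol_id))
    centers = np.array([r.center for r in raw])
    med = np.median(centers, axis=0)
    dev = np.linalg.norm(centers - med, axis=1)
    mad = np.median(dev)
    gate = max(gate_px, mad_sigmas * 1.4826 * mad)
    keep = dev <= gate
    if not np.any(keep):
        return None
    kept = centers[keep]
    center = np.median(kept, axis=0)
    spread = float(np.linalg.norm(kept - center, axis=1).max()) if len(kept) > 1 else 0.0
    if spread > gate_px and len(kept) > 2:
        # residual disagreement beyond the gate: drop the worst and retry
        order = np.argsort(np.linalg.norm(kept - center, axis=1))
        kept = kept[order[:-1]]
        center = np.median(kept, axis=0)
        spread = float(np.linalg.norm(kept - center, axis=1).max())
    scales = ()
    if scales_by_frame:
        scales = tuple(
            sorted({scales_by_frame[r.frame_idx] for r, k in zip(raw, keep) if k and r.frame_idx in scales_by_frame})
        )
    return MarkerObservation(
        camera_id=raw[0].camera_id,
        marker_id=marker_id,
        center_px=center,
        scales_seen=scales,
        n_frames=int(keep.sum()),
        spread_px=spread,
    )


def build_tracks(observations: list[MarkerObservation]) -> list[ObservationTrack]:
    """Group per-camera observations into per-marker correspondence tracks."""
    seen = set()
    for o in observations:
        key = (o.camera_id, o.marker_id)
        if key in seen:
            raise ValueError(f"duplicate observation for {key}")
        seen.add(key)
    tracks: dict[int, ObservationTrack] = {}
    for o in observations:
        tr = tracks.setdefault(o.marker_id, ObservationTrack(marker_id=o.marker_id))
        tr.observations[o.camera_id] = o
    return [tracks[k] for k in sorted(tracks)]


def observations_from_detections(
    detections_by_camera: dict[str, list[RawDetection]],
    schedule,
    mad_sigmas: float = 3.5,
    gate_px: float = 2.0,
) -> list[MarkerObservation]:
    """Associate raw detections to schedule slots and fuse per marker.

    The decoded symbol id identifies the marker (and hence the slot); the
    frame index maps to the projected scale as
    ``frame = array_idx * n_scales + scale_idx``. Multiple frames of one
    (camera, marker) are fused by the robust median rule.
    """
    bysym = schedule.marker_by_symbol()
    n_scales = len(schedule.scales)
    obs = []
    for cid in sorted(detections_by_camera):
        per_marker: dict[int, list[RawDetection]] = {}
        for d in detections_by_camera[cid]:
            m = bysym.get(d.symbol_id)
            if m is None:
                continue
            per_marker.setdefault(m.marker_id, []).append(d)
        for mid in sorted(per_marker):
            scales_by_frame = {
                d.frame_idx: schedule.scales[d.frame_idx % n_scales]
                for d in per_marker[mid]
            }
            o = fuse_scales(
                per_marker[mid], mid, scales_by_frame,
                mad_sigmas=mad_sigmas, gate_px=gate_px,
            )
            if o is not None:
                obs.append(o)
    return obs


def undistort_observations(
    tracks: list[ObservationTrack], intrinsics: dict[str, CameraIntrinsics]
) -> None:
    """Replace observation centers by ideal (undistorted) pixels in place."""
    for tr in tracks:
        for cid, obs in tr.observations.items():
            obs.center_px = intrinsics[cid].undistort_pixel(obs.center_px)[0]
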