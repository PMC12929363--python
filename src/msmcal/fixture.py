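"""Self-contained synthetic dataset: rendered frames for a small rig.

The fixture renders a reduced projection schedule (9 arrays x 8 markers,
3 scales) onto a 2.4 x 1.35 m floor patch and synthesizes views from a
5-camera rig: two far-field and two near-field standard cameras plus one
long-focal camera whose narrow field of view emulates the extreme scale
gap between an overview camera and a camera zoomed on the work area. It
exercises the complete pipeline — rendering, detection, multi-scale
fusion, track building, calibration — with known ground-truth poses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detection import (
    ObservationTrack,
    RawDetection,
    build_tracks,
    detect_frame,
    observations_from_detections,
)
from .geometry import CameraIntrinsics, CameraPose, project
from .markers import (
    FAST_SCALES,
    ProjectionSchedule,
    default_dictionary,
    default_floor_homography,
    floor_coordinates,
    make_schedule,
)
from .viewsynth import FloorViewRenderer

logger = logging.getLogger(__name__)

__all__ = ["FixtureData", "build_fixture", "write_fixture"]


@dataclass
class FixtureData:
    schedule: ProjectionSchedule
    g_proj: np.ndarray
    intrinsics: dict[str, CameraIntrinsics]
    gt_poses: dict[str, CameraPose]
    floor_points: dict[int, np.ndarray]
    tracks: list[ObservationTrack]
    detections: dict[str, list[RawDetection]]
    coverage: dict[str, float]  # per camera: detected / geometrically visible
    scales_seen: dict[str, set[float]]  # per camera: scales that decoded
    seed: int
    frames: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)


def _fixture_rig(seed: int) -> tuple[dict[str, CameraIntrinsics], dict[str, CameraPose]]:
    rng = np.random.default_rng(seed)
    intr: dict[str, CameraIntrinsics] = {}
    poses: dict[str, CameraPose] = {}
    specs = [
        ("far0", 915.0, 2.8, 2.8),
        ("far1", 915.0, 2.8, 2.8),
        ("near0", 915.0, 1.2, 1.4),
        ("near1", 915.0, 1.2, 1.4),
    ]
    az = rng.uniform(0, 2 * np.pi, size=len(specs))
    for (cid, f, r, h), a in zip(specs, az):
        intr[cid] = CameraIntrinsics(
            f, f, 960.0, 540.0, np.array([-0.08, 0.015, 0, 0, 0]), 1920, 1080, cid
        )
        poses[cid] = CameraPose.look_at(
            np.array([r * np.cos(a), r * np.sin(a), h]), np.zeros(3)
        )
    # long-focal camera zoomed on an off-center patch of the floor; the
    # focal length trades scale gap against how many of the reduced
    # schedule's points fall in view (too few leaves its center depth
    # nearly unobservable and poisons the center-based alignment)
    cid = "zoom0"
    intr[cid] = CameraIntrinsics(4000.0, 4000.0, 960.0, 540.0, np.zeros(5), 1920, 1080, cid)
    a = rng.uniform(0, 2 * np.pi)
    poses[cid] = CameraPose.look_at(
        np.array([1.0 * np.cos(a), 1.0 * np.sin(a), 2.6]),
        np.array([0.25, 0.15, 0.0]),
    )
    return intr, poses


def build_fixture(
    seed: int = 0,
    keep_frames: bool = False,
    n_arrays: int = 9,
    markers_per_array: int = 8,
    scales=FAST_SCALES,
) -> FixtureData:
    """Render, observe and detect the full reduced schedule.

    Detection coverage is reported against geometric visibility: a marker
    counts as visible in a camera when its center projects inside the
    image with a 10 px margin.
    """
    schedule = make_schedule(
        n_arrays=n_arrays,
        markers_per_array=markers_per_array,
        grid_shape=(4, 2),
        scales=tuple(scales),
        base_px=40.0,
        # cell height must exceed the largest marker side (8 x 40 = 320 px)
        margin_px=200.0,
    )
    g_proj = default_floor_homography(schedule, px_per_meter=800.0)
    floor = dict(floor_coordinates(schedule, g_proj))
    intr, gt = _fixture_rig(seed)
    dictionary = default_dictionary()
    n_scales = len(schedule.scales)
    detections: dict[str, list[RawDetection]] = {c: [] for c in intr}
    frames: dict[tuple[str, int], np.ndarray] = {}
    X = np.stack([floor[m] for m in sorted(floor)])
    mids = np.array(sorted(floor))
    coverage = {}
    scales_seen: dict[str, set] = {c: set() for c in intr}
    for cid in sorted(intr):
        K, P = intr[cid], gt[cid]
        renderer = FloorViewRenderer(
            K, P, g_proj, supersample=3, keep_coords=True, raster_maps=False
        )
        px, vis = project(K, P, X, strict=False)
        # a marker is geometrically visible when even its smallest-scale
        # instance fits the view: margin ~ 0.6 x that instance's size
        depth = P.transform(X)[:, 2]
        base_side = schedule.arrays[0][0].pattern.base_side
        inst_px = base_side * min(schedule.scales) * K.fx / np.maximum(depth, 1e-6)
        ok = np.zeros(len(X), dtype=bool)
        for i in np.where(vis)[0]:
            ok[i] = bool(K.in_image(px[i][None], margin=0.6 * inst_px[i])[0])
        vis = vis & ok
        visible_ids = set(int(m) for m in mids[vis])
        found_ids = set()
        for a in range(schedule.n_arrays):
            for s in range(n_scales):
                img = renderer.render_markers(schedule, a, s, dictionary)
                fidx = a * n_scales + s
                dets = detect_frame(
                    img, dictionary, camera_id=cid, frame_idx=fidx, intrinsics=K
                )
                detections[cid].extend(dets)
                bysym = schedule.marker_by_symbol()
                for d in dets:
                    m = bysym.get(d.symbol_id)
                    if m is not None:
                        found_ids.add(m.marker_id)
                        scales_seen[cid].add(schedule.scales[s])
                if keep_frames:
                    frames[(cid, fidx)] = img
        coverage[cid] = (
            len(found_ids & visible_ids) / len(visible_ids) if visible_ids else 1.0
        )
        logger.info(
            "fixture camera %s: %d/%d visible markers detected (%.1f%%), scales %s",
            cid, len(found_ids & visible_ids), len(visible_ids),
            100 * coverage[cid], sorted(scales_seen[cid]),
        )
    obs = observations_from_detections(detections, schedule)
    tracks = build_tracks(obs)
    return FixtureData(
        schedule=schedule,
        g_proj=g_proj.matrix,
        intrinsics=intr,
        gt_poses=gt,
        floor_points=floor,
        tracks=tracks,
        detections=detections,
        coverage=coverage,
        scales_seen=scales_seen,
        seed=seed,
        frames=frames,
    )


def write_fixture(fix: FixtureData, out_dir) -> Path:
    """Write frames (PNG), intrinsics, ground-truth poses and tracks."""
    import imageio.v3 as iio

    from .configio import save_intrinsics, save_poses, save_tracks

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_intrinsics(out / "intrinsics.yaml", fix.intrinsics)
    save_poses(out / "gt_poses.json", fix.gt_poses, seed=fix.seed)
    save_tracks(out / "tracks.csv", fix.tracks)
    if fix.frames:
        for (cid, fidx), img in fix.frames.items():
            d = out / "frames" / cid
            d.mkdir(parents=True, exist_ok=True)
            iio.imwrite(d / f"frame_{fidx:04d}.png", (img * 255).astype(np.uint8))
    return out
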