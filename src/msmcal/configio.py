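"""Configuration and artifact I/O: intrinsics, tracks, poses, reports.

File conventions: CSV with one header row, comma separator, '.' decimal;
pixel coordinates are 0-based pixel centers (x right, y down); pose files
state the world-to-camera convention in the payload. Every artifact embeds
the seed it was produced with.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import CalibrationResult
from .detection import MarkerObservation, ObservationTrack, RawDetection, build_tracks
from .geometry import CameraIntrinsics, CameraPose

__all__ = [
    "RunConfig",
    "load_intrinsics",
    "save_intrinsics",
    "load_tracks",
    "save_tracks",
    "save_detections",
    "load_detections",
    "save_poses",
    "load_poses",
    "save_result",
]

POSE_CONVENTION = "world_to_camera: x_cam = R @ X + t; R row-major"


@dataclass
class RunConfig:
    """Paths and options for one end-to-end pipeline run."""

    intrinsics_file: str
    tracks_file: str | None = None
    frames_dir: str | None = None
    detections_file: str | None = None
    schedule_file: str | None = None
    output_dir: str = "msmcal_out"
    coplanar: bool = False
    seed: int = 0
    ransac_threshold_px: float = 3.0
    eval_thresholds_px: tuple[float, ...] = (0.5, 2.0, 5.0)
    log_level: str = "INFO"

    def validate(self):
        if not Path(self.intrinsics_file).exists():
            raise FileNotFoundError(f"intrinsics file not found: {self.intrinsics_file}")
        sources = [self.tracks_file, self.frames_dir, self.detections_file]
        if not any(s and Path(s).exists() for s in sources):
            raise FileNotFoundError(
                "no input found: provide tracks_file, detections_file or frames_dir"
            )


# ---------------------------------------------------------------------------
# intrinsics


def load_intrinsics(path) -> dict[str, CameraIntrinsics]:
    """Read per-camera intrinsics + distortion from a YAML config.

    Schema errors name the offending camera.
    """
    with open(path) as f:
        doc = yaml.safe_load(f)
    cams = doc.get("cameras") if isinstance(doc, dict) else None
    if not cams:
        raise ValueError(f"{path}: no 'cameras' list")
    out = {}
    for rec in cams:
        cid = str(rec.get("camera_id", ""))
        try:
            K = CameraIntrinsics(
                fx=float(rec["fx"]),
                fy=float(rec["fy"]),
                cx=float(rec["cx"]),
                cy=float(rec["cy"]),
                dist=np.asarray(rec.get("dist", []), dtype=float),
                width=int(rec.get("width", 1920)),
                height=int(rec.get("height", 1080)),
                camera_id=cid,
            )
        except (KeyError, ValueError, TypeError) as e:
            raise ValueError(f"invalid intrinsics for camera {cid!r}: {e}") from e
        if cid in out:
            raise ValueError(f"duplicate camera_id {cid!r}")
        out[cid] = K
    return out


def save_intrinsics(path, intrinsics: dict[str, CameraIntrinsics]):
    doc = {
        "cameras": [
            {
                "camera_id": cid,
                "fx": float(K.fx),
                "fy": float(K.fy),
                "cx": float(K.cx),
                "cy": float(K.cy),
                "dist": [float(d) for d in K.dist],
                "width": int(K.width),
                "height": int(K.height),
            }
            for cid, K in sorted(intrinsics.items())
        ]
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


# ---------------------------------------------------------------------------
# tracks and detections


def save_tracks(path, tracks: list[ObservationTrack]):
    rows = []
    for t in sorted(tracks, key=lambda t: t.marker_id):
        for cid in sorted(t.observations):
            o = t.observations[cid]
            rows.append(
                {
                    "camera_id": cid,
                    "marker_id": t.marker_id,
                    "x": o.center_px[0],
                    "y": o.center_px[1],
                    "spread": o.spread_px,
                    "n_scales": len(o.scales_seen),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_tracks(path) -> list[ObservationTrack]:
    df = pd.read_csv(path)
    obs = [
        MarkerObservation(
            camera_id=str(r.camera_id),
            marker_id=int(r.marker_id),
            center_px=np.array([r.x, r.y]),
            spread_px=float(getattr(r, "spread", 0.0)),
        )
        for r in df.itertuples()
    ]
    return build_tracks(obs)


def save_detections(path, detections: list[RawDetection]):
    rows = []
    for d in detections:
        row = {
            "camera_id": d.camera_id,
            "frame_idx": d.frame_idx,
            "symbol_id": d.symbol_id,
            "confidence": d.decode_confidence,
        }
        for i in range(4):
            row[f"x{i}"] = d.corners[i, 0]
            row[f"y{i}"] = d.corners[i, 1]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_detections(path) -> list[RawDetection]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        corners = np.array([[getattr(r, f"x{i}"), getattr(r, f"y{i}")] for i in range(4)])
        out.append(
            RawDetection(
                camera_id=str(r.camera_id),
                frame_idx=int(r.frame_idx),
                symbol_id=int(r.symbol_id),
                corners=corners,
                decode_confidence=float(getattr(r, "confidence", 1.0)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# projection schedules


def save_schedule(path, schedule):
    """Schedule descriptor: arrays, marker ids, centers (projector px), scales."""
    doc = {
        "projector_resolution": list(schedule.projector_resolution),
        "scales": [float(s) for s in schedule.scales],
        "base_px": float(schedule.base_px),
        "slot_duration_s": float(schedule.slot_duration),
        "arrays": [
            [
                {
                    "marker_id": m.marker_id,
                    "symbol_id": m.pattern.symbol_id,
                    "center": [float(m.center_p[0]), float(m.center_p[1])],
                    "base_side_m": float(m.pattern.base_side),
                }
                for m in arr
            ]
            for arr in schedule.arrays
        ],
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def load_schedule(path):
    from .markers import MSMSpec, PatternSpec, ProjectionSchedule

    with open(path) as f:
        doc = yaml.safe_load(f)
    scales = tuple(float(s) for s in doc["scales"])
    arrays = [
        [
            MSMSpec(
                marker_id=int(m["marker_id"]),
                pattern=PatternSpec(
                    symbol_id=int(m["symbol_id"]),
                    base_side=float(m.get("base_side_m", 0.05)),
                ),
                center_p=tuple(m["center"]),
                scales=scales,
            )
            for m in arr
        ]
        for arr in doc["arrays"]
    ]
    return ProjectionSchedule(
        arrays=arrays,
        scales=scales,
        projector_resolution=tuple(doc.get("projector_resolution", (1920, 1080))),
        base_px=float(doc.get("base_px", 40.0)),
        slot_duration=float(doc.get("slot_duration_s", 0.1)),
    )


# ---------------------------------------------------------------------------
# poses and results


def save_poses(path, poses: dict[str, CameraPose], seed: int | None = None, extra: dict | None = None):
    doc = {
        "convention": POSE_CONVENTION,
        "seed": seed,
        "cameras": {
            cid: {
                "rotation": [[float(v) for v in row] for row in p.R],
                "translation": [float(v) for v in p.t],
            }
            for cid, p in sorted(poses.items())
        },
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as f:
        json.dump(doc, f, indent=1, sort_keys=True)


def load_poses(path) -> dict[str, CameraPose]:
    with open(path) as f:
        doc = json.load(f)
    return {
        cid: CameraPose(np.array(rec["rotation"]), np.array(rec["translation"]))
        for cid, rec in doc["cameras"].items()
    }


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_result(out_dir, result: CalibrationResult, seed: int, config: dict | None = None):
    """Write the pose file, points file, residuals CSV and JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_poses(
        out / "poses.json",
        result.poses,
        seed=seed,
        extra={"gauge": result.gauge},
    )
    pd.DataFrame(
        [
            {
                "marker_id": p.marker_id,
                "X": p.position[0],
                "Y": p.position[1],
                "Z": p.position[2],
                "on_floor": p.on_floor,
            }
            for p in result.points
        ]
    ).to_csv(out / "points.csv", index=False)
    pd.DataFrame({"residual_px": result.residuals_px}).to_csv(
        out / "residuals.csv", index=False
    )
    summary = {
        "seed": seed,
        "mean_reprojection_px": result.mean_reproj_px,
        "per_camera_mean_reprojection_px": result.per_camera_mean_reproj,
        "registered": result.registered,
        "unregistered": result.unregistered,
        "registration_order": result.registration_order,
        "n_points": len(result.points),
        "n_observations_used": result.n_observations_used,
        "gauge": result.gauge,
    }
    if config is not None:
        summary["config_hash"] = config_hash(config)
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=1, sort_keys=True)
    return out
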