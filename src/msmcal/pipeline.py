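"""End-to-end pipeline: detect -> tracks -> calibrate -> report.

Each stage writes its artifact under the output directory together with a
manifest (package version, seed, config hash) so a run is reproducible
from its outputs alone. Stage failures abort with the stage name; partial
artifacts are retained.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .calibrate import CalibrationOptions, CalibrationResult, calibrate
from .configio import (
    RunConfig,
    config_hash,
    load_detections,
    load_intrinsics,
    load_schedule,
    load_tracks,
    save_result,
    save_tracks,
)
from .detection import build_tracks, detect_frame, observations_from_detections
from .exceptions import MsmcalError

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _detect_stage(config: RunConfig, schedule):
    import imageio.v3 as iio

    from .markers import default_dictionary

    dets_by_cam = {}
    root = Path(config.frames_dir)
    for cam_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        cid = cam_dir.name
        dets = []
        for fpath in sorted(cam_dir.glob("*.png")):
            fidx = int("".join(ch for ch in fpath.stem if ch.isdigit()) or 0)
            img = iio.imread(fpath)
            dets.extend(
                detect_frame(img, default_dictionary(), camera_id=cid, frame_idx=fidx)
            )
        dets_by_cam[cid] = dets
        logger.info("detect: %s -> %d detections", cid, len(dets))
    obs = observations_from_detections(dets_by_cam, schedule)
    return build_tracks(obs)


def run_pipeline(config: RunConfig) -> CalibrationResult:
    """Run every configured stage and write artifacts + manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-intrinsics"
    try:
        intrinsics = load_intrinsics(config.intrinsics_file)
        if config.tracks_file and Path(config.tracks_file).exists():
            stage = "load-tracks"
            tracks = load_tracks(config.tracks_file)
        elif config.frames_dir:
            stage = "detect"
            if not config.schedule_file:
                raise MsmcalError("frames input requires a schedule file")
            schedule = load_schedule(config.schedule_file)
            tracks = _detect_stage(config, schedule)
            save_tracks(out / "tracks.csv", tracks)
        else:
            stage = "load-detections"
            if not config.schedule_file:
                raise MsmcalError("detections input requires a schedule file")
            schedule = load_schedule(config.schedule_file)
            dets = load_detections(config.detections_file)
            by_cam = {}
            for d in dets:
                by_cam.setdefault(d.camera_id, []).append(d)
            tracks = build_tracks(observations_from_detections(by_cam, schedule))
            save_tracks(out / "tracks.csv", tracks)
        stage = "calibrate"
        opts = CalibrationOptions(
            coplanar=config.coplanar,
            seed=config.seed,
            ransac_threshold_px=config.ransac_threshold_px,
        )
        result = calibrate(tracks, intrinsics, opts)
        stage = "write"
        cfg_dict = {k: getattr(config, k) for k in vars(config)}
        save_result(out, result, seed=config.seed, config=cfg_dict)
        manifest = {
            "msmcal_version": __version__,
            "seed": config.seed,
            "config": cfg_dict,
            "config_hash": config_hash(cfg_dict),
            "n_tracks": len(tracks),
            "registered": result.registered,
            "unregistered": result.unregistered,
        }
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=1, sort_keys=True, default=str)
        return result
    except Exception as e:
        raise MsmcalError(f"pipeline failed at stage {stage!r}: {e}") from e
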