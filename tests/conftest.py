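"""Shared fixtures. Heavy end-to-end artifacts are session-scoped so the
unit suite and the acceptance suite reuse one computation."""

import numpy as np
import pytest

from msmcal.geometry import CameraIntrinsics, CameraPose


@pytest.fixture
def pinhole():
    """Distortion-free camera, principal point at the image center."""
    return CameraIntrinsics(1000.0, 1000.0, 500.0, 500.0, np.zeros(5), 1000, 1000, "cam")


@pytest.fixture
def gopro_like():
    """Full-HD camera with mild radial/tangential distortion."""
    return CameraIntrinsics(
        915.0, 915.0, 960.0, 540.0,
        np.array([-0.1, 0.02, 1e-4, -2e-4, 0.003]), 1920, 1080, "gopro",
    )


def make_ring_rig(n=6, radius=2.8, height=2.8, focal=915.0, seed=0):
    """Cameras on one circle aimed at the origin (deterministic azimuths)."""
    rng = np.random.default_rng(seed)
    az = rng.uniform(0, 2 * np.pi, n)
    Ks, poses = [], []
    for i in range(n):
        c = np.array([radius * np.cos(az[i]), radius * np.sin(az[i]), height])
        poses.append(CameraPose.look_at(c, np.zeros(3)))
        Ks.append(
            CameraIntrinsics(focal, focal, 960.0, 540.0, np.zeros(5), 1920, 1080, f"c{i}")
        )
    return Ks, poses


@pytest.fixture(scope="session")
def fixture_data():
    """Rendered + detected synthetic 5-camera dataset (shared, ~2 min)."""
    from msmcal.fixture import build_fixture

    return build_fixture(seed=5)


@pytest.fixture(scope="session")
def grid_zero_run():
    """grid_floor simulation at sigma=0: ground truth + calibration result."""
    from msmcal.calibrate import CalibrationOptions, calibrate
    from msmcal.simulate import (
        RigConfig,
        ScenarioConfig,
        generate_observations,
        generate_points,
        sample_rig,
    )

    rng = np.random.default_rng(11)
    rig_config = RigConfig()
    scenario = ScenarioConfig(kind="grid_floor")
    rig = sample_rig(rig_config, rng)
    points, _ = generate_points(scenario, rng)
    tracks, info = generate_observations(rig, points, None, 0.0, rng, rig_config, scenario)
    intr = {cid: K for cid, _, K in rig}
    gt = {cid: pose for cid, pose, _ in rig}
    result = calibrate(tracks, intr, CalibrationOptions(seed=11))
    return {
        "result": result,
        "gt_poses": gt,
        "intrinsics": intr,
        "points": points,
        "tracks": tracks,
        "info": info,
    }
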