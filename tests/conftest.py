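"""Shared fixtures: programmatically built tracks and calibrated synthetic
sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from locokit import pose_io, synthetic
from locokit.pose_io import PoseTrack


def make_track(coords: dict[str, np.ndarray], fps: float = 30.0,
               likelihood: dict[str, np.ndarray] | None = None,
               units: str = "cm") -> PoseTrack:
    """Build a PoseTrack from a dict of landmark -> (N, 2) arrays."""
    names = list(coords)
    arrs = [np.asarray(coords[n], dtype=float) for n in names]
    n = arrs[0].shape[0]
    c = np.stack(arrs, axis=1)
    lik = np.ones((n, len(names)))
    if likelihood:
        for name, vals in likelihood.items():
            lik[:, names.index(name)] = vals
    return PoseTrack(names, np.arange(n) / fps, c, lik,
                     valid=np.ones((n, len(names)), dtype=bool),
                     units=units, frame_rate=fps)


CORNER_GEOMETRY = {"corner_0": (0.0, 0.0), "corner_1": (40.0, 0.0),
                   "corner_2": (40.0, 40.0), "corner_3": (0.0, 40.0)}
RULER_GEOMETRY = {f"cal_{k}": (5.0 * k, 0.0) for k in range(4)}


def calibrate_open_field(track):
    out, _ = pose_io.calibrate(track, list(CORNER_GEOMETRY), CORNER_GEOMETRY)
    return out


def calibrate_corridor(track):
    out, _ = pose_io.calibrate(track, list(RULER_GEOMETRY), RULER_GEOMETRY)
    return out


@pytest.fixture(scope="session")
def openfield_session():
    """A full-length open-field session at varied laser powers, calibrated
    and quality-filtered, with its ground truth."""
    cfg = synthetic.OpenFieldSimConfig(
        train_powers=tuple(10.0 * k for k in range(1, 11)))
    raw, truth = synthetic.simulate_open_field(cfg, seed=11)
    track = calibrate_open_field(raw)
    policy = pose_io.FilterPolicy(arena_bounds=(-5.0, 45.0, -5.0, 45.0))
    track = pose_io.apply_quality_filters(track, policy, mode="body_center")
    return track, truth, cfg


@pytest.fixture(scope="session")
def gait_session():
    """A calibrated corridor gait recording with ground truth."""
    cfg = synthetic.GaitSimConfig()
    raw, truth = synthetic.simulate_corridor_gait(cfg, seed=7)
    return calibrate_corridor(raw), truth, cfg


@pytest.fixture(scope="session")
def kinematics_session():
    """A calibrated hindlimb-kinematics recording with ground truth."""
    cfg = synthetic.GaitSimConfig(event_threshold=9.0)
    raw, truth = synthetic.simulate_hindlimb_kinematics(cfg, seed=7)
    return calibrate_corridor(raw), truth, cfg
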