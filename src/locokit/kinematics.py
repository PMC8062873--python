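"""Hindlimb joint-angle kinematics in the linear corridor.

The hindlimb is tracked as a six-landmark planar chain (iliac crest, hip,
knee, ankle, MTP, toe tip). The angle at each inner joint is the interior
angle between its two adjacent chain segments, in degrees. Stance and swing
are detected from the smoothed MTP speed (9 cm/s threshold, with a minimum
of eight consecutive frames above threshold to accept a lift-off), angle
traces are resampled onto a normalized step cycle referenced to MTP
touchdowns, and per-joint amplitudes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gait import GaitEvents, _enforce_alternation, _threshold_crossings
from .openfield import SpeedSeries
from .pose_io import PoseTrack

__all__ = [
    "CHAIN_LANDMARKS",
    "JOINTS",
    "JointAngleSeries",
    "joint_angles",
    "detect_stance_swing_mtp",
    "normalize_cycle",
    "angle_amplitude",
]

#: Proximal-to-distal landmark order of the tracked hindlimb chain.
CHAIN_LANDMARKS = ("iliac_crest", "hip", "knee", "ankle", "mtp", "toe_tip")

#: Inner joints of the chain, each with one proximal and one distal neighbor.
JOINTS = ("hip", "knee", "ankle", "mtp")


@dataclass
class JointAngleSeries:
    """Per-joint angle traces resampled onto a normalized step cycle."""

    phase: np.ndarray  # bin centers in (0, 1)
    mean: pd.DataFrame  # columns JOINTS, degrees
    sd: pd.DataFrame  # columns JOINTS, degrees
    n_cycles: int
    n_skipped: int  # cycles dropped for excess masked frames

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for joint in self.mean.columns:
            for i, ph in enumerate(self.phase):
                rows.append({"joint": joint, "phase": ph,
                             "mean_deg": self.mean[joint].iloc[i],
                             "sd_deg": self.sd[joint].iloc[i],
                             "n_cycles": self.n_cycles})
        return pd.DataFrame(rows)


def joint_angles(
    track: PoseTrack, chain: tuple[str, ...] = CHAIN_LANDMARKS
) -> pd.DataFrame:
    """Frame-by-frame interior angles at the chain's inner joints.

    The angle at joint J is measured between the segments to its two chain
    neighbors (hip: iliac crest-hip-knee; knee: hip-knee-ankle; ankle:
    knee-ankle-MTP; MTP: ankle-MTP-toe tip), in degrees in (0, 180]. Frames
    where any of the three landmarks is invalid, or where adjacent landmarks
    coincide, are NaN for that joint.
    """
    cols = {}
    for a, b, c, name in zip(chain[:-2], chain[1:-1], chain[2:], JOINTS):
        pa, pb, pc = (track.position(n) for n in (a, b, c))
        va, vb, vc = (track.landmark_valid(n) for n in (a, b, c))
        u = pa - pb
        w = pc - pb
        nu = np.hypot(u[:, 0], u[:, 1])
        nw = np.hypot(w[:, 0], w[:, 1])
        ok = va & vb & vc & (nu > 0) & (nw > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.clip((u * w).sum(axis=1) / (nu * nw), -1.0, 1.0)
            ang = np.degrees(np.arccos(cosang))
        cols[name] = np.where(ok, ang, np.nan)
    return pd.DataFrame(cols)


def detect_stance_swing_mtp(
    mtp_speed: SpeedSeries, threshold: float = 9.0, min_above: int = 8
) -> GaitEvents:
    """MTP stance/swing events: 9 cm/s threshold with an 8-frame rule.

    A lift-off (upward crossing) is accepted only when followed by at least
    ``min_above`` consecutive frames above the threshold; touchdowns are all
    downward crossings. Alternation is then enforced by dropping same-type
    repeats (keeping the first), so a suppressed lift-off also suppresses
    the touchdown ending that excursion.
    """
    crossings = _threshold_crossings(mtp_speed, threshold)
    s, m = mtp_speed.speed, mtp_speed.mask
    above = m & (s >= threshold)
    kept = []
    for tc, direction, i in crossings:
        if direction == 1:
            # frames i+1 .. i+min_above must all be valid and above threshold
            seg = above[i + 1:i + 1 + min_above]
            if seg.size < min_above or not seg.all():
                continue
        kept.append((tc, direction, i))
    kept = _enforce_alternation(kept)
    tds = np.array([t for t, d, _ in kept if d == -1])
    los = np.array([t for t, d, _ in kept if d == 1])
    return GaitEvents(tds, los)


def normalize_cycle(
    angles: pd.DataFrame,
    timestamps: np.ndarray,
    events: GaitEvents,
    n_bins: int = 100,
    max_masked_frac: float = 0.2,
) -> JointAngleSeries:
    """Resample per-frame joint angles onto a normalized step cycle.

    A cycle runs between consecutive MTP touchdowns. Each cycle's angle
    traces are linearly interpolated at ``n_bins`` phase-bin centers; cycles
    with more than ``max_masked_frac`` masked frames for a joint are skipped
    for all joints (counted in the diagnostics). Mean and SD are taken
    across cycles per bin.
    """
    tds = events.touchdowns
    if tds.size < 2:
        raise ValueError("need at least one complete touchdown-to-touchdown cycle")
    t = np.asarray(timestamps, dtype=float)
    phase = (np.arange(n_bins) + 0.5) / n_bins

    per_cycle: list[dict[str, np.ndarray]] = []
    n_skipped = 0
    for k in range(tds.size - 1):
        t0, t1 = tds[k], tds[k + 1]
        in_cycle = (t >= t0) & (t < t1)
        if not in_cycle.any():
            n_skipped += 1
            continue
        masked_frac = max(
            float(np.mean(~np.isfinite(angles[j].to_numpy()[in_cycle])))
            for j in angles.columns)
        if masked_frac > max_masked_frac:
            n_skipped += 1
            continue
        sample_t = t0 + phase * (t1 - t0)
        traces = {}
        for j in angles.columns:
            vals = angles[j].to_numpy()
            ok = np.isfinite(vals)
            traces[j] = np.interp(sample_t, t[ok], vals[ok])
        per_cycle.append(traces)

    if not per_cycle:
        raise ValueError("no usable cycle after masking rules")
    mean = {}
    sd = {}
    for j in angles.columns:
        stack = np.stack([c[j] for c in per_cycle])
        mean[j] = stack.mean(axis=0)
        sd[j] = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(n_bins)
    return JointAngleSeries(phase, pd.DataFrame(mean), pd.DataFrame(sd),
                            n_cycles=len(per_cycle), n_skipped=n_skipped)


def angle_amplitude(
    angles: pd.DataFrame,
    timestamps: np.ndarray,
    events: GaitEvents,
    n_bins: int = 100,
    method: str = "per_cycle",
) -> pd.Series:
    """Per-joint angular amplitude over the step cycle, in degrees.

    ``per_cycle`` (default): amplitude = max - min of the joint angle within
    each cycle, averaged over cycles (robust to cycle-to-cycle phase jitter).
    ``profile``: amplitude of the across-cycle mean profile.
    """
    tds = events.touchdowns
    if method == "profile":
        series = normalize_cycle(angles, timestamps, events, n_bins=n_bins)
        return series.mean.max() - series.mean.min()
    if method != "per_cycle":
        raise ValueError(f"unknown method {method!r}")
    t = np.asarray(timestamps, dtype=float)
    phase = (np.arange(n_bins) + 0.5) / n_bins
    amps: dict[str, list[float]] = {j: [] for j in angles.columns}
    for k in range(tds.size - 1):
        t0, t1 = tds[k], tds[k + 1]
        sample_t = t0 + phase * (t1 - t0)
        for j in angles.columns:
            vals = angles[j].to_numpy()
            ok = np.isfinite(vals)
            if not ok.any():
                continue
            trace = np.interp(sample_t, t[ok], vals[ok])
            amps[j].append(float(trace.max() - trace.min()))
    return pd.Series({j: float(np.mean(v)) if v else np.nan
                      for j, v in amps.items()})
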