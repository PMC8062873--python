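"""Corner-turn detection and turn-speed scaling in the open-field arena.

A turn is a traversal of a 20 cm circular region of interest (ROI) centered
on an arena corner that crosses the corner's bisector (the arena diagonal
through that corner) exactly once, starting and ending at least 5 cm from
the crossing ("turning point"). Speed along the traversal is summarized in
1-cm bins of signed Euclidean distance to the turning point (negative before
the crossing, positive after): entry, turn and exit speeds are each the mean
of exactly four bins, and traversals with fewer than four eligible occupied
bins for any summary are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import regression
from .openfield import SpeedSeries, compute_speed
from .pose_io import PoseTrack

__all__ = [
    "ArenaGeometry",
    "TurnCandidate",
    "Crossing",
    "Rejection",
    "Turn",
    "ScalingRegressions",
    "segment_roi_traversals",
    "find_turning_point",
    "classify_turn",
    "turn_angle",
    "bin_speed_by_distance",
    "summarize_turn_speeds",
    "scaling_regressions",
    "detect_turns",
]


@dataclass(frozen=True)
class ArenaGeometry:
    """Square (or convex quadrilateral) arena geometry in cm.

    ``corners`` in polygon order. The bisector of a corner is the ray from
    its vertex into the arena at 45 degrees to both adjacent walls (for a
    square, the arena diagonal).
    """

    corners: tuple[tuple[float, float], ...] = (
        (0.0, 0.0), (40.0, 0.0), (40.0, 40.0), (0.0, 40.0))
    roi_radius: float = 20.0
    turning_zone_radius: float = 2.0
    min_endpoint_distance: float = 5.0
    entry_exit_min_distance: float = 7.0  # near bin edge >= this, cm from tp
    gap_tolerance: int = 3  # frames of masked gap bridged within a traversal
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        if not (self.roi_radius > self.min_endpoint_distance
                > self.turning_zone_radius > 0):
            raise ValueError("require roi_radius > min_endpoint_distance "
                             "> turning_zone_radius > 0")

    @property
    def corner_array(self) -> np.ndarray:
        return np.asarray(self.corners, dtype=float)

    def bisector(self, corner_id: int) -> tuple[np.ndarray, np.ndarray, float]:
        """(vertex, unit direction into the arena, ray length)."""
        c = self.corner_array
        v = c[corner_id]
        prev = c[(corner_id - 1) % len(c)]
        nxt = c[(corner_id + 1) % len(c)]
        u1 = (prev - v) / np.linalg.norm(prev - v)
        u2 = (nxt - v) / np.linalg.norm(nxt - v)
        u = u1 + u2
        norm = np.linalg.norm(u)
        if norm < 1e-12:
            raise ValueError("degenerate corner: adjacent walls collinear")
        diag = float(np.max(np.linalg.norm(c - c[corner_id], axis=1)))
        return v, u / norm, diag


@dataclass
class TurnCandidate:
    """One contiguous traversal of a corner ROI."""

    corner_id: int
    frames: np.ndarray  # original frame indices (may skip short masked gaps)
    positions: np.ndarray  # (M, 2) cm
    timestamps: np.ndarray  # (M,) s
    speeds: np.ndarray  # (M,) cm/s attached per point (later-frame convention)


@dataclass(frozen=True)
class Crossing:
    point: np.ndarray
    time: float


@dataclass(frozen=True)
class Rejection:
    reason: str  # "no_crossing" | "multiple_crossings" | "endpoint_too_close"
    #             | "entry_bins" | "turn_bins" | "exit_bins"


@dataclass
class Turn:
    """One accepted corner traversal and its speed summary."""

    corner_id: int
    turning_point: np.ndarray
    angle_deg: float
    entry_speed: float
    turn_speed: float
    exit_speed: float
    profile: pd.DataFrame  # signed_bin_cm (left edge), mean_speed
    t_start: float
    t_end: float


@dataclass
class ScalingRegressions:
    """The four linear relationships characterizing braking and turning."""

    entry_vs_brake: regression.LinearFit  # x=entry, y=entry-turn
    exit_vs_accel: regression.LinearFit  # x=exit, y=exit-turn
    entry_vs_turn: regression.LinearFit  # x=entry, y=turn
    turn_vs_angle: regression.LinearFit  # x=turn speed, y=angle


def segment_roi_traversals(
    positions: np.ndarray,
    timestamps: np.ndarray,
    valid: np.ndarray,
    geometry: ArenaGeometry,
    corner_id: int,
    speeds: np.ndarray | None = None,
) -> list[TurnCandidate]:
    """Maximal runs of consecutive unmasked positions inside the ROI circle.

    Masked frames inside a run are skipped; a run is split when a masked gap
    exceeds ``geometry.gap_tolerance`` frames. Leaving the ROI always ends
    the run.
    """
    positions = np.asarray(positions, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if speeds is None:
        speeds = np.full(len(positions), np.nan)
    vertex = geometry.corner_array[corner_id]
    with np.errstate(invalid="ignore"):
        dist = np.hypot(*(positions - vertex).T)
        inside = valid & (dist <= geometry.roi_radius)
    outside = valid & ~inside

    runs: list[list[int]] = []
    current: list[int] = []
    gap = 0
    for i in range(len(positions)):
        if inside[i]:
            if current and gap > geometry.gap_tolerance:
                runs.append(current)
                current = []
            current.append(i)
            gap = 0
        elif outside[i]:
            if current:
                runs.append(current)
                current = []
            gap = 0
        else:  # masked
            gap += 1
    if current:
        runs.append(current)

    out = []
    for run in runs:
        idx = np.asarray(run)
        out.append(TurnCandidate(corner_id, idx, positions[idx],
                                 timestamps[idx], np.asarray(speeds)[idx]))
    return out


def _ray_segment_intersection(p0, p1, v, u, length):
    """Intersection of segment p0->p1 with ray v + r*u, r in [0, length].

    Returns (s, point) with s the fraction along the segment, or None.
    Endpoints are inclusive.
    """
    d = p1 - p0
    denom = d[0] * (-u[1]) - d[1] * (-u[0])
    if abs(denom) < 1e-14:
        return None
    w = v - p0
    s = (w[0] * (-u[1]) - w[1] * (-u[0])) / denom
    r = (d[0] * w[1] - d[1] * w[0]) / denom
    if -1e-12 <= s <= 1 + 1e-12 and -1e-12 <= r <= length + 1e-12:
        s = min(max(s, 0.0), 1.0)
        return s, p0 + s * d
    return None


def find_turning_point(
    candidate: TurnCandidate, geometry: ArenaGeometry
) -> Crossing | Rejection:
    """Intersect the piecewise-linear trajectory with the corner bisector.

    Exactly one intersection yields the turning point (with its crossing
    time, linearly interpolated along the segment); zero or more than one
    yields a :class:`Rejection`.
    """
    if len(candidate.positions) < 2:
        return Rejection("no_crossing")
    v, u, length = geometry.bisector(candidate.corner_id)
    hits: list[tuple[float, np.ndarray]] = []
    for k in range(len(candidate.positions) - 1):
        hit = _ray_segment_intersection(candidate.positions[k],
                                        candidate.positions[k + 1],
                                        v, u, length)
        if hit is None:
            continue
        s, point = hit
        t = candidate.timestamps[k] + s * (candidate.timestamps[k + 1]
                                           - candidate.timestamps[k])
        # a crossing at a shared vertex appears in both segments: count once
        if hits and np.allclose(point, hits[-1][1], atol=1e-9):
            continue
        hits.append((t, point))
    if not hits:
        return Rejection("no_crossing")
    if len(hits) > 1:
        return Rejection("multiple_crossings")
    t, point = hits[0]
    return Crossing(point=point, time=float(t))


def classify_turn(
    candidate: TurnCandidate, crossing: Crossing, geometry: ArenaGeometry
) -> Rejection | None:
    """Check the endpoint rule: trajectory must start and end at least
    ``min_endpoint_distance`` (default 5 cm, boundary inclusive) from the
    turning point. Returns None when accepted."""
    d0 = float(np.linalg.norm(candidate.positions[0] - crossing.point))
    d1 = float(np.linalg.norm(candidate.positions[-1] - crossing.point))
    if d0 < geometry.min_endpoint_distance or d1 < geometry.min_endpoint_distance:
        return Rejection("endpoint_too_close")
    return None


def turn_angle(first, tp, last) -> float:
    """Interior angle (degrees, in [0, 180]) at the turning point between the
    rays toward the first and last trajectory points. A straight pass gives
    180; smaller angles are sharper turns."""
    first = np.asarray(first, dtype=float)
    tp = np.asarray(tp, dtype=float)
    last = np.asarray(last, dtype=float)
    u = first - tp
    w = last - tp
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        raise ValueError("turn_angle: point coincident with turning point")
    c = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def bin_speed_by_distance(
    candidate: TurnCandidate,
    crossing: Crossing,
    geometry: ArenaGeometry,
) -> pd.DataFrame:
    """Signed-distance speed profile of one traversal.

    Per point, d = Euclidean distance to the turning point, signed negative
    for points before the crossing time and positive at or after it (d = 0
    ties to the positive side). Speeds are averaged in 1-cm bins of signed d
    over [-roi_radius, +roi_radius); empty bins are absent (NaN).
    """
    r = geometry.roi_radius
    w = geometry.bin_width
    d = np.hypot(*(candidate.positions - crossing.point).T)
    signed = np.where(candidate.timestamps < crossing.time, -d, d)
    n_bins = int(round(2 * r / w))
    edges = -r + w * np.arange(n_bins + 1)
    idx = np.floor((signed + r) / w).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    ok = np.isfinite(candidate.speeds)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    np.add.at(sums, idx[ok], candidate.speeds[ok])
    np.add.at(counts, idx[ok], 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"signed_bin_cm": edges[:-1], "mean_speed": mean,
                         "n_points": counts})


def summarize_turn_speeds(
    profile: pd.DataFrame, geometry: ArenaGeometry
) -> tuple[float, float, float] | Rejection:
    """Entry / turn / exit speeds from a signed-distance profile.

    Turn speed: mean of the four 1-cm bins covering signed d in [-2, 2).
    Entry speed: mean of the four most distal occupied bins on the negative
    side whose near edge is at least ``entry_exit_min_distance`` (default
    7 cm) from the turning point; exit is symmetric on the positive side.
    Fewer than four occupied eligible bins for any summary rejects the turn.
    """
    edges = profile["signed_bin_cm"].to_numpy()
    vals = profile["mean_speed"].to_numpy()
    w = geometry.bin_width
    zone = geometry.turning_zone_radius
    dmin = geometry.entry_exit_min_distance

    turn_sel = (edges >= -zone) & (edges + w <= zone)
    turn_vals = vals[turn_sel]
    if np.isfinite(turn_vals).sum() < 4:
        return Rejection("turn_bins")
    turn_speed = float(np.nanmean(turn_vals))

    entry_sel = np.isfinite(vals) & (edges + w <= -dmin)
    if entry_sel.sum() < 4:
        return Rejection("entry_bins")
    entry_speed = float(vals[entry_sel][np.argsort(edges[entry_sel])[:4]].mean())

    exit_sel = np.isfinite(vals) & (edges >= dmin)
    if exit_sel.sum() < 4:
        return Rejection("exit_bins")
    exit_speed = float(vals[exit_sel][np.argsort(edges[exit_sel])[-4:]].mean())
    return entry_speed, turn_speed, exit_speed


def detect_turns(
    track: PoseTrack,
    landmark: str,
    geometry: ArenaGeometry,
) -> tuple[list[Turn], pd.DataFrame]:
    """Run the full corner-turn pipeline on a calibrated, filtered track.

    Returns the accepted :class:`Turn` objects and a per-candidate table
    (corner, tp_x, tp_y, angle_deg, entry, turn, exit, status, reason).
    """
    positions = track.position(landmark)
    valid = track.landmark_valid(landmark)
    t = track.timestamps
    # speed attached to each trajectory point: later-frame convention
    speed_series = compute_speed(track, landmark)
    speeds = np.full(track.n_frames, np.nan)
    speeds[1:] = np.where(speed_series.mask, speed_series.speed, np.nan)

    accepted: list[Turn] = []
    rows = []
    for corner_id in range(len(geometry.corners)):
        for cand in segment_roi_traversals(positions, t, valid, geometry,
                                           corner_id, speeds):
            row = {"corner": corner_id, "tp_x": np.nan, "tp_y": np.nan,
                   "angle_deg": np.nan, "entry": np.nan, "turn": np.nan,
                   "exit": np.nan, "status": "rejected", "reason": ""}
            res = find_turning_point(cand, geometry)
            if isinstance(res, Rejection):
                row["reason"] = res.reason
                rows.append(row)
                continue
            row["tp_x"], row["tp_y"] = res.point
            rej = classify_turn(cand, res, geometry)
            if rej is not None:
                row["reason"] = rej.reason
                rows.append(row)
                continue
            angle = turn_angle(cand.positions[0], res.point, cand.positions[-1])
            row["angle_deg"] = angle
            profile = bin_speed_by_distance(cand, res, geometry)
            summary = summarize_turn_speeds(profile, geometry)
            if isinstance(summary, Rejection):
                row["reason"] = summary.reason
                rows.append(row)
                continue
            entry, turn, exit_ = summary
            row.update(entry=entry, turn=turn, exit=exit_, status="accepted")
            rows.append(row)
            accepted.append(Turn(
                corner_id=corner_id, turning_point=res.point,
                angle_deg=angle, entry_speed=entry, turn_speed=turn,
                exit_speed=exit_, profile=profile,
                t_start=float(cand.timestamps[0]),
                t_end=float(cand.timestamps[-1])))
    table = pd.DataFrame(rows, columns=["corner", "tp_x", "tp_y", "angle_deg",
                                        "entry", "turn", "exit", "status",
                                        "reason"])
    return accepted, table


def scaling_regressions(turns: list[Turn]) -> ScalingRegressions:
    """The four linear fits relating entry, turn and exit speeds and angle."""
    if len(turns) < 3:
        raise ValueError("need at least three accepted turns")
    entry = np.array([t.entry_speed for t in turns])
    turn = np.array([t.turn_speed for t in turns])
    exit_ = np.array([t.exit_speed for t in turns])
    angle = np.array([t.angle_deg for t in turns])
    return ScalingRegressions(
        entry_vs_brake=regression.linear_fit(entry, entry - turn),
        exit_vs_accel=regression.linear_fit(exit_, exit_ - turn),
        entry_vs_turn=regression.linear_fit(entry, turn),
        turn_vs_angle=regression.linear_fit(turn, angle),
    )
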