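"""Pose-track ingestion, calibration, quality filtering and stimulation-epoch
detection.

The universal input of the toolkit is a :class:`PoseTrack`: per-frame (x, y)
coordinates and a detection likelihood for a set of named landmarks, as
produced by markerless tracking software. Tables are read from the de facto
three-header CSV dialect (``scorer`` / ``bodyparts`` / ``coords``, with one
``x``, ``y``, ``likelihood`` column triplet per landmark).

Coordinate convention: image coordinates, y increasing downward. All
downstream geometry (angles, bisectors) is orientation-agnostic, so no axis
flip is ever applied.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PoseTrack",
    "Calibration",
    "StimulationEpoch",
    "FilterPolicy",
    "read_pose_table",
    "write_pose_table",
    "read_timestamps",
    "read_epochs_file",
    "calibrate",
    "apply_quality_filters",
    "detect_stimulation_epochs",
]


@dataclass
class PoseTrack:
    """Per-frame landmark coordinates, likelihoods and a validity mask.

    Attributes
    ----------
    landmarks : list of str
        Landmark names, in column order of the source table.
    timestamps : (N,) float array, seconds, strictly increasing.
    coords : (N, L, 2) float array
        x, y per frame per landmark, in ``units``.
    likelihood : (N, L) float array in [0, 1].
    valid : (N, L) bool array
        False wherever a coordinate is missing or has been filtered out.
    units : {"pixel", "cm"}
    frame_rate : float
        Nominal acquisition rate in Hz.
    """

    landmarks: list[str]
    timestamps: np.ndarray
    coords: np.ndarray
    likelihood: np.ndarray
    valid: np.ndarray
    units: str = "pixel"
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n, l = self.coords.shape[:2]
        if self.coords.shape != (n, l, 2):
            raise ValueError("coords must have shape (n_frames, n_landmarks, 2)")
        if len(self.landmarks) != l:
            raise ValueError("landmark count does not match coords")
        if self.timestamps.shape != (n,) or self.likelihood.shape != (n, l):
            raise ValueError("inconsistent array shapes in PoseTrack")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        finite_lik = self.likelihood[np.isfinite(self.likelihood)]
        if finite_lik.size and (finite_lik.min() < 0 or finite_lik.max() > 1):
            raise ValueError("likelihood values must lie in [0, 1]")
        if self.units not in ("pixel", "cm"):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def index(self, landmark: str) -> int:
        try:
            return self.landmarks.index(landmark)
        except ValueError:
            raise KeyError(
                f"landmark {landmark!r} not in track; available: {self.landmarks}"
            ) from None

    def position(self, landmark: str) -> np.ndarray:
        """(N, 2) coordinates of one landmark."""
        return self.coords[:, self.index(landmark), :]

    def landmark_valid(self, landmark: str) -> np.ndarray:
        return self.valid[:, self.index(landmark)]

    def copy(self) -> "PoseTrack":
        return PoseTrack(
            landmarks=list(self.landmarks),
            timestamps=self.timestamps.copy(),
            coords=self.coords.copy(),
            likelihood=self.likelihood.copy(),
            valid=self.valid.copy(),
            units=self.units,
            frame_rate=self.frame_rate,
        )


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-cm mapping recovered from in-frame markers of known geometry."""

    scale: float  # cm per pixel
    origin: tuple[float, float] = (0.0, 0.0)  # pixel point mapped to (0, 0) cm
    y_downward: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("calibration scale must be finite and > 0")


@dataclass(frozen=True)
class StimulationEpoch:
    """One optogenetic stimulation train: onset/offset in seconds."""

    onset: float
    offset: float
    laser_power: float | None = None  # % of the session maximum
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("epoch offset must be greater than onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class FilterPolicy:
    """Quality-control thresholds for pose tracks.

    Defaults follow standard rodent open-field / corridor analysis: points
    below 0.8 tracking likelihood are unreliable; 334 cm/s is the maximum
    locomotor speed recorded in mice (body center); 400 cm/s allows a 20%
    margin for individual body parts; 2.3 cm is the mean mouse tibia length
    with a 30% margin, an upper bound on adjacent hindlimb joint spacing.
    """

    likelihood_min: float = 0.8
    body_speed_max: float = 334.0  # cm/s
    part_speed_max: float = 400.0  # cm/s
    joint_distance_max: float = 2.3  # cm
    arena_bounds: tuple[float, float, float, float] | None = None  # xmin,xmax,ymin,ymax (cm)

    def __post_init__(self) -> None:
        for name in ("likelihood_min", "body_speed_max", "part_speed_max",
                     "joint_distance_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# I/O

_HEADER_ROWS = ("scorer", "bodyparts", "coords")
_COORD_COLS = ("x", "y", "likelihood")


def read_pose_table(
    source,
    dialect: str = "dlc",
    timestamps: np.ndarray | None = None,
    frame_rate: float = 30.0,
) -> PoseTrack:
    """Read a multi-header landmark CSV into a :class:`PoseTrack`.

    Parameters
    ----------
    source : path or text buffer
        CSV with three header rows (scorer / bodyparts / coords) and one
        x, y, likelihood triplet per landmark.
    dialect : str
        Only ``"dlc"`` (the three-header dialect) is supported.
    timestamps : array, optional
        Per-frame times in seconds from a companion file; wins over the
        nominal frame rate. If absent, ``t_i = i / frame_rate``.
    frame_rate : float
        Nominal frame rate in Hz, used when no timestamps are given.
    """
    if dialect != "dlc":
        raise ValueError(f"unsupported dialect {dialect!r}")
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    header_lines = text.splitlines()[:3]
    if len(header_lines) < 3:
        raise ValueError("malformed header: expected three header rows "
                         "(scorer / bodyparts / coords)")
    parts_row = header_lines[1].split(",")[1:]
    coords_row = header_lines[2].split(",")[1:]
    seen_cols = set()
    for part, coord in zip(parts_row, coords_row):
        if (part, coord) in seen_cols:
            raise ValueError(f"duplicated column {part!r}/{coord!r}")
        seen_cols.add((part, coord))

    df = pd.read_csv(io.StringIO(text), header=[0, 1, 2], index_col=0,
                     float_precision="round_trip")
    if df.columns.nlevels != 3:
        raise ValueError("malformed header: expected three header rows "
                         "(scorer / bodyparts / coords)")

    landmarks: list[str] = []
    for _, part, _ in df.columns:
        if part not in landmarks:
            landmarks.append(part)

    scorer = df.columns[0][0]
    n = len(df)
    coords = np.full((n, len(landmarks), 2), np.nan)
    likelihood = np.zeros((n, len(landmarks)))
    for j, part in enumerate(landmarks):
        for k, c in enumerate(_COORD_COLS):
            key = (scorer, part, c)
            if key not in df.columns:
                raise ValueError(f"malformed header: missing column "
                                 f"{part!r}/{c!r}")
            vals = df[key].to_numpy(dtype=float)
            if c == "likelihood":
                likelihood[:, j] = vals
            else:
                coords[:, j, k] = vals

    valid = np.isfinite(coords).all(axis=2) & np.isfinite(likelihood)
    likelihood = np.where(np.isfinite(likelihood), likelihood, 0.0)

    if timestamps is not None:
        t = np.asarray(timestamps, dtype=float)
        if t.shape != (n,):
            raise ValueError("timestamp file length does not match table")
    else:
        t = np.arange(n, dtype=float) / frame_rate
    return PoseTrack(landmarks, t, coords, likelihood, valid,
                     units="pixel", frame_rate=frame_rate)


def write_pose_table(track: PoseTrack, target, scorer: str = "locokit") -> None:
    """Write a track back to the three-header CSV dialect (round-trip safe)."""
    cols = pd.MultiIndex.from_tuples(
        [(scorer, part, c) for part in track.landmarks for c in _COORD_COLS],
        names=list(_HEADER_ROWS),
    )
    n = track.n_frames
    data = np.empty((n, len(track.landmarks) * 3))
    for j in range(len(track.landmarks)):
        data[:, 3 * j] = track.coords[:, j, 0]
        data[:, 3 * j + 1] = track.coords[:, j, 1]
        data[:, 3 * j + 2] = track.likelihood[:, j]
    # repr gives the shortest string that round-trips each double exactly
    df = pd.DataFrame(data, columns=cols).map(repr)
    df.index.name = None
    df.to_csv(target)


def read_timestamps(source) -> np.ndarray:
    """Read a one-column timestamp file (seconds, one row per frame)."""
    return pd.read_csv(source, header=None).iloc[:, 0].to_numpy(dtype=float)


def read_epochs_file(source) -> list[StimulationEpoch]:
    """Read explicit stimulation epochs (CSV: onset_s, offset_s, power_pct)."""
    df = pd.read_csv(source)
    epochs = []
    for _, row in df.iterrows():
        power = float(row["power_pct"]) if "power_pct" in df.columns else None
        epochs.append(StimulationEpoch(float(row["onset_s"]),
                                       float(row["offset_s"]),
                                       laser_power=power))
    return sorted(epochs, key=lambda e: e.onset)


# ---------------------------------------------------------------------------
# Calibration


def calibrate(
    track: PoseTrack,
    marker_names: Sequence[str],
    known_geometry: dict[str, tuple[float, float]],
    likelihood_min: float = 0.8,
) -> tuple[PoseTrack, Calibration]:
    """Recover a cm-per-pixel scale from in-frame calibration markers.

    For every marker pair, the observed pixel distance is the median over
    frames where both markers are tracked with likelihood >= ``likelihood_min``.
    The scale is the zero-intercept least-squares fit of known cm distances
    against observed pixel distances, i.e. ``s = sum(d_cm * d_px) / sum(d_px^2)``.

    Returns a rescaled copy of the track (units ``cm``) and the
    :class:`Calibration`.
    """
    if len(marker_names) < 2:
        raise ValueError("need at least two calibration markers")
    idx = [track.index(m) for m in marker_names]
    known = np.array([known_geometry[m] for m in marker_names], dtype=float)

    d_px, d_cm = [], []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            ok = (
                track.valid[:, idx[a]] & track.valid[:, idx[b]]
                & (track.likelihood[:, idx[a]] >= likelihood_min)
                & (track.likelihood[:, idx[b]] >= likelihood_min)
            )
            if not ok.any():
                continue
            diff = track.coords[ok, idx[a], :] - track.coords[ok, idx[b], :]
            d_px.append(float(np.median(np.hypot(diff[:, 0], diff[:, 1]))))
            d_cm.append(float(np.linalg.norm(known[a] - known[b])))
    if not d_px:
        raise ValueError("no frame has two calibration markers tracked "
                         f"with likelihood >= {likelihood_min}")
    d_px = np.array(d_px)
    d_cm = np.array(d_cm)
    if np.all(d_px < 1e-9) or np.all(d_cm < 1e-12):
        raise ValueError("degenerate calibration geometry: markers coincident")
    scale = float(np.sum(d_cm * d_px) / np.sum(d_px ** 2))
    cal = Calibration(scale=scale)
    out = track.copy()
    out.coords = out.coords * scale
    out.units = "cm"
    return out, cal


# ---------------------------------------------------------------------------
# Quality filters


def _mask_speed_cap(track: PoseTrack, cols: Sequence[int], cap: float) -> None:
    """Mask the later frame of every adjacent-frame pair whose implied
    instantaneous landmark speed exceeds ``cap``.

    Only strictly adjacent frame pairs with both frames currently valid are
    checked, which makes the operation idempotent: once the later frame is
    masked the pair no longer participates.
    """
    dt = np.diff(track.timestamps)
    for j in cols:
        p = track.coords[:, j, :]
        v = track.valid[:, j]
        step = np.hypot(*(p[1:] - p[:-1]).T) / dt
        bad = v[:-1] & v[1:] & (step > cap)
        track.valid[1:, j] &= ~bad


def apply_quality_filters(
    track: PoseTrack,
    policy: FilterPolicy | None = None,
    mode: str = "body_center",
    chain: Sequence[str] | None = None,
) -> PoseTrack:
    """Update the validity mask of a calibrated track.

    Rules, by ``mode``:

    * all modes: likelihood below ``policy.likelihood_min`` invalidates the
      point; positions outside ``policy.arena_bounds`` (if set) invalidate it.
    * ``body_center``: instantaneous speed above ``policy.body_speed_max``
      masks the later frame of the violating pair.
    * ``paws``: as above with ``policy.part_speed_max``.
    * ``joints``: part-speed cap as in ``paws``; additionally any adjacent
      pair along ``chain`` (default: landmark order) farther apart than
      ``policy.joint_distance_max`` invalidates the *entire frame*.

    Filtering only masks; it never raises on bad data, and it is idempotent.
    """
    if policy is None:
        policy = FilterPolicy()
    if mode not in ("body_center", "paws", "joints"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if track.units != "cm":
        raise ValueError("apply_quality_filters requires a calibrated (cm) track")

    out = track.copy()
    out.valid &= out.likelihood >= policy.likelihood_min
    if policy.arena_bounds is not None:
        xmin, xmax, ymin, ymax = policy.arena_bounds
        inside = (
            (out.coords[:, :, 0] >= xmin) & (out.coords[:, :, 0] <= xmax)
            & (out.coords[:, :, 1] >= ymin) & (out.coords[:, :, 1] <= ymax)
        )
        out.valid &= inside

    # the joint-distance rule is anatomical, judged on tracked (likelihood-
    # valid) points before any speed masking, and invalidates the whole frame
    if mode == "joints":
        names = list(chain) if chain is not None else list(out.landmarks)
        idx = [out.index(m) for m in names]
        frame_bad = np.zeros(out.n_frames, dtype=bool)
        for a, b in zip(idx[:-1], idx[1:]):
            both = out.valid[:, a] & out.valid[:, b]
            d = np.hypot(*(out.coords[:, a, :] - out.coords[:, b, :]).T)
            frame_bad |= both & (d > policy.joint_distance_max)
        out.valid[frame_bad, :] = False

    cap = policy.body_speed_max if mode == "body_center" else policy.part_speed_max
    _mask_speed_cap(out, range(len(out.landmarks)), cap)
    return out


# ---------------------------------------------------------------------------
# Stimulation-epoch detection


def detect_stimulation_epochs(
    track: PoseTrack,
    indicator_landmark: str,
    likelihood_on: float = 0.8,
    min_gap_s: float = 0.5,
    min_duration_s: float = 1.0,
) -> list[StimulationEpoch]:
    """Detect stimulation trains from an in-frame indicator-LED landmark.

    The LED is visible to the tracker only while lit, so its likelihood
    channel binarizes the laser state: frames with likelihood >=
    ``likelihood_on`` are "on". On-runs separated by gaps shorter than
    ``min_gap_s`` are merged; runs shorter than ``min_duration_s`` are
    dropped. Offsets extend one frame period past the last on-frame so a
    train spanning k frames has duration k / frame_rate.
    """
    j = track.index(indicator_landmark)
    on = track.likelihood[:, j] >= likelihood_on
    t = track.timestamps
    if not on.any():
        return []
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0 / track.frame_rate

    # run-length segmentation of the boolean signal
    starts = np.flatnonzero(np.r_[on[0], on[1:] & ~on[:-1]])
    ends = np.flatnonzero(np.r_[on[:-1] & ~on[1:], on[-1]])
    runs = list(zip(starts.tolist(), ends.tolist()))  # inclusive frame indices

    # close gaps shorter than min_gap_s
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (t[s] - t[merged[-1][1]]) < min_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    epochs = []
    for s, e in merged:
        onset = float(t[s])
        offset = float(t[e] + dt)
        if offset - onset >= min_duration_s:
            epochs.append(StimulationEpoch(onset, offset))
    return epochs
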