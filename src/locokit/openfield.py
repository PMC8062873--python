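"""Open-field locomotor speed analysis.

Body-center speed from calibrated tracks, downsampling to a uniform 20 Hz
grid, peri-stimulus averaging across optogenetic stimulation trains,
per-epoch window means, and the normalized laser-power / speed relationship
with its sigmoid fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pose_io import PoseTrack, StimulationEpoch
from . import regression

__all__ = [
    "SpeedSeries",
    "PeriStimulusProfile",
    "PowerSpeedCurve",
    "compute_speed",
    "downsample",
    "peristimulus_average",
    "epoch_window_means",
    "power_speed_curve",
    "PAPER_WINDOWS",
]

#: The four peri-stimulation analysis windows (s relative to train onset):
#: before, during, and two 10 s windows after.
PAPER_WINDOWS: tuple[tuple[float, float], ...] = (
    (-10.0, 0.0), (0.0, 10.0), (10.0, 20.0), (20.0, 30.0))


@dataclass
class SpeedSeries:
    """A scalar speed signal (cm/s) with timestamps and a validity mask."""

    timestamps: np.ndarray
    speed: np.ndarray
    mask: np.ndarray  # True where valid

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.timestamps.shape == self.speed.shape == self.mask.shape):
            raise ValueError("SpeedSeries arrays must share one shape")

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def rate(self) -> float:
        dt = np.diff(self.timestamps)
        return 1.0 / float(np.median(dt)) if dt.size else np.nan


@dataclass
class PeriStimulusProfile:
    """Speed aligned to stimulation onset, averaged across trains."""

    rel_time: np.ndarray  # s, onset at 0
    mean: np.ndarray  # cm/s
    sem: np.ndarray  # cm/s, across epochs
    n_epochs: np.ndarray  # contributing epochs per grid point

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_rel_s": self.rel_time, "mean_cm_s": self.mean,
                             "sem_cm_s": self.sem, "n": self.n_epochs})


@dataclass
class PowerSpeedCurve:
    """Max-normalized laser-power vs speed relationship with sigmoid fit."""

    pairs: pd.DataFrame  # columns: animal, power_pct, speed_pct
    bin_centers: np.ndarray
    bin_mean: np.ndarray
    bin_sem: np.ndarray
    bin_n: np.ndarray
    fit: regression.SigmoidFit


def compute_speed(track: PoseTrack, landmark: str) -> SpeedSeries:
    """Instantaneous landmark speed from consecutive frames.

    speed_i = ||p_{i+1} - p_i|| / (t_{i+1} - t_i), assigned to the later
    timestamp; masked wherever either endpoint frame is invalid. Length N-1.
    """
    if track.units != "cm":
        raise ValueError("compute_speed requires a calibrated (cm) track")
    p = track.position(landmark)
    v = track.landmark_valid(landmark)
    t = track.timestamps
    if track.n_frames < 2:
        return SpeedSeries(t[1:], np.zeros(0), np.zeros(0, dtype=bool))
    dt = np.diff(t)
    disp = np.hypot(*(p[1:] - p[:-1]).T)
    speed = disp / dt
    mask = v[:-1] & v[1:]
    speed = np.where(mask, speed, np.nan)
    return SpeedSeries(t[1:], speed, mask)


def downsample(series: SpeedSeries, target_rate: float = 20.0) -> SpeedSeries:
    """Resample onto a uniform grid by linear interpolation of valid samples.

    Grid points that fall inside a masked gap longer than one native frame
    (i.e. two or more consecutive masked samples), or outside the span of
    valid samples, are masked.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    t = series.timestamps
    if len(series) == 0:
        return SpeedSeries(t, series.speed, series.mask)
    native_dt = float(np.median(np.diff(t))) if len(series) > 1 else 0.0
    if native_dt and target_rate > 1.0 / native_dt + 1e-9:
        raise ValueError("target_rate exceeds native rate")

    step = 1.0 / target_rate
    grid = np.arange(t[0], t[-1] + 1e-12, step)
    tv = t[series.mask]
    sv = series.speed[series.mask]
    if tv.size == 0:
        return SpeedSeries(grid, np.full(grid.shape, np.nan),
                           np.zeros(grid.shape, dtype=bool))
    vals = np.interp(grid, tv, sv)
    mask = (grid >= tv[0]) & (grid <= tv[-1])
    if tv.size > 1 and native_dt:
        # spacing between the valid samples bracketing each grid point
        hi = np.searchsorted(tv, grid, side="left").clip(1, tv.size - 1)
        spacing = tv[hi] - tv[hi - 1]
        n_missing = np.round(spacing / native_dt) - 1
        mask &= n_missing <= 1
    vals = np.where(mask, vals, np.nan)
    return SpeedSeries(grid, vals, mask)


def peristimulus_average(
    series: SpeedSeries,
    epochs: list[StimulationEpoch],
    window: tuple[float, float] = (10.0, 30.0),
) -> PeriStimulusProfile:
    """Average speed across stimulation trains, aligned at train onset.

    The series must already sit on a uniform grid (see :func:`downsample`);
    each epoch onset is snapped to the nearest grid point. Mean and SEM are
    computed pointwise over epochs from unmasked values; epochs whose window
    extends past the recording contribute only in-bounds points.
    """
    if not epochs:
        raise ValueError("need at least one stimulation epoch")
    pre_s, post_s = window
    t = series.timestamps
    dt = 1.0 / series.rate
    k_pre = int(round(pre_s / dt))
    k_post = int(round(post_s / dt))
    offsets = np.arange(-k_pre, k_post + 1)
    rel = offsets * dt

    stacks = np.full((len(epochs), offsets.size), np.nan)
    for e, ep in enumerate(epochs):
        i0 = int(np.argmin(np.abs(t - ep.onset)))
        idx = i0 + offsets
        ok = (idx >= 0) & (idx < len(series))
        vals = np.full(offsets.size, np.nan)
        vals[ok] = np.where(series.mask[idx[ok]], series.speed[idx[ok]], np.nan)
        stacks[e] = vals

    finite = np.isfinite(stacks)
    n = finite.sum(axis=0)
    mean = np.where(n > 0,
                    np.where(finite, stacks, 0.0).sum(axis=0)
                    / np.maximum(n, 1), np.nan)
    sd = np.zeros(offsets.size)
    for i in range(offsets.size):
        col = stacks[finite[:, i], i]
        sd[i] = np.std(col, ddof=1) if col.size > 1 else 0.0
    sem = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    mean = np.where(n > 0, mean, np.nan)
    return PeriStimulusProfile(rel, mean, sem, n)


def epoch_window_means(
    series: SpeedSeries,
    epochs: list[StimulationEpoch],
    windows: tuple[tuple[float, float], ...] = PAPER_WINDOWS,
) -> pd.DataFrame:
    """Mean speed per (epoch, window), windows in seconds relative to onset.

    Each cell is the mean over unmasked samples with
    onset + start <= t < onset + end; empty cells are NaN. Overlapping
    windows are permitted; zero-length windows are an error.
    """
    for w in windows:
        if not w[1] > w[0]:
            raise ValueError(f"zero-length or inverted window {w}")
    cols = [f"{a:g}_{b:g}s" for a, b in windows]
    rows = []
    for ep in epochs:
        row = {}
        for (a, b), name in zip(windows, cols):
            sel = ((series.timestamps >= ep.onset + a)
                   & (series.timestamps < ep.onset + b) & series.mask)
            row[name] = float(np.mean(series.speed[sel])) if sel.any() else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out.insert(0, "onset_s", [ep.onset for ep in epochs])
    return out


def power_speed_curve(
    trials: pd.DataFrame,
    bin_width: float = 10.0,
) -> PowerSpeedCurve:
    """Normalized laser-power / speed relationship across animals.

    ``trials`` needs columns ``animal``, ``power`` (laser power, any unit
    consistent within animal) and ``speed`` (mean stimulation-window speed,
    cm/s). Per animal, power and speed are expressed as % of that animal's
    maxima; pooled pairs are binned by normalized power (default bin width
    10% of max), and a 3-parameter logistic is fitted to the binned means.
    """
    df = trials.copy()
    if df["power"].nunique() < 3:
        raise ValueError("need at least three distinct power levels")
    df["power_pct"] = df.groupby("animal")["power"].transform(
        lambda s: 100.0 * s / s.max())
    df["speed_pct"] = df.groupby("animal")["speed"].transform(
        lambda s: 100.0 * s / s.max())

    # bins partition (0, 100]: (0,10], (10,20], ..., (90,100]
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    which = np.digitize(df["power_pct"].to_numpy(), edges, right=True) - 1
    which = np.clip(which, 0, edges.size - 2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bmean = np.full(centers.size, np.nan)
    bsem = np.full(centers.size, np.nan)
    bn = np.zeros(centers.size, dtype=int)
    sp = df["speed_pct"].to_numpy()
    for k in range(centers.size):
        vals = sp[which == k]
        bn[k] = vals.size
        if vals.size:
            bmean[k] = vals.mean()
            bsem[k] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0

    occupied = np.isfinite(bmean)
    fit = regression.sigmoid_fit(centers[occupied], bmean[occupied])
    keep = df[["animal", "power_pct", "speed_pct"]].reset_index(drop=True)
    return PowerSpeedCurve(keep, centers, bmean, bsem, bn, fit)
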