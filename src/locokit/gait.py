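"""Footfall-pattern analysis in the linear corridor.

Paw (MTP) speeds are smoothed with a 5-frame centered moving average;
touchdown and lift-off are the instants the smoothed speed falls below or
rises above 15 cm/s. Events of all four limbs are normalized to the step
cycle of a reference limb (left hindlimb) to form gait diagrams, and stride
metrics (cycle, stance, swing durations, stride length) are computed per
complete cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .openfield import SpeedSeries

__all__ = [
    "LIMBS",
    "GaitEvents",
    "StrideMetrics",
    "smooth_speed",
    "detect_gait_events",
    "build_gait_diagram",
    "stride_metrics",
]

#: Conventional limb labels: left/right fore, left/right hind.
LIMBS = ("LF", "RF", "LH", "RH")


@dataclass
class GaitEvents:
    """Touchdown and lift-off times (s) for one limb.

    After alternation enforcement the merged event sequence strictly
    alternates in time; ``leading_liftoff`` / ``trailing_touchdown`` flag
    partial phases at the recording boundaries.
    """

    touchdowns: np.ndarray
    liftoffs: np.ndarray

    def __post_init__(self) -> None:
        self.touchdowns = np.asarray(self.touchdowns, dtype=float)
        self.liftoffs = np.asarray(self.liftoffs, dtype=float)

    @property
    def leading_liftoff(self) -> bool:
        """True when the recording opens mid-stance (first event is a lift-off)."""
        return (self.liftoffs.size > 0
                and (self.touchdowns.size == 0
                     or self.liftoffs[0] < self.touchdowns[0]))

    @property
    def trailing_touchdown(self) -> bool:
        """True when the recording ends mid-stance (last event is a touchdown)."""
        return (self.touchdowns.size > 0
                and (self.liftoffs.size == 0
                     or self.touchdowns[-1] > self.liftoffs[-1]))

    def stance_intervals(self) -> list[tuple[float, float]]:
        """(touchdown, lift-off) pairs with both boundary events present."""
        out = []
        for td in self.touchdowns:
            later = self.liftoffs[self.liftoffs > td]
            if later.size:
                out.append((float(td), float(later[0])))
        return out


@dataclass
class StrideMetrics:
    """Per-cycle stride metrics and their bout means."""

    per_cycle: pd.DataFrame  # cycle_s, stance_s, swing_s, stride_cm
    n_incomplete: int

    @property
    def means(self) -> pd.Series:
        return self.per_cycle[["cycle_s", "stance_s", "swing_s",
                               "stride_cm"]].mean()


def smooth_speed(series: SpeedSeries, window: int = 5) -> SpeedSeries:
    """Centered moving average over ``window`` frames.

    Masked frames are excluded from each window mean; edges average over the
    samples available. Frames masked on input stay masked on output.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = len(series)
    if window > n:
        warnings.warn("smoothing window longer than series; returned unchanged")
        return SpeedSeries(series.timestamps.copy(), series.speed.copy(),
                           series.mask.copy())
    vals = np.where(series.mask, series.speed, 0.0)
    cnt = series.mask.astype(float)
    kernel = np.ones(window)
    sums = np.convolve(vals, kernel, mode="same")
    counts = np.convolve(cnt, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(counts > 0, sums / counts, np.nan)
    mask = series.mask & (counts > 0)
    sm = np.where(mask, sm, np.nan)
    return SpeedSeries(series.timestamps.copy(), sm, mask)


def _threshold_crossings(series: SpeedSeries, threshold: float):
    """(time, direction) of linear-interpolated threshold crossings.

    direction +1 for upward (rise above), -1 for downward (fall below).
    Only strictly adjacent valid sample pairs are considered. A sample equal
    to the threshold counts as being at/above it.
    """
    t = series.timestamps
    s = series.speed
    m = series.mask
    above = s >= threshold
    events = []
    for i in range(len(series) - 1):
        if not (m[i] and m[i + 1]) or above[i] == above[i + 1]:
            continue
        frac = (threshold - s[i]) / (s[i + 1] - s[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        events.append((float(tc), 1 if above[i + 1] else -1, i))
    return events


def _enforce_alternation(events):
    """Drop same-type repeats, keeping the first of each run."""
    out = []
    for ev in events:
        if out and out[-1][1] == ev[1]:
            continue
        out.append(ev)
    return out


def detect_gait_events(
    paw_speed: SpeedSeries, threshold: float = 15.0,
    debounce_s: float = 0.0,
) -> GaitEvents:
    """Touchdowns (speed falls below) and lift-offs (speed rises above) at
    the given threshold, with sub-frame timing by linear interpolation.

    ``debounce_s`` optionally drops any crossing followed by a return
    crossing within that time (default off; the standard rule uses none).
    Alternation is enforced by dropping same-type repeats (keeping the
    first). Leading/trailing partial phases are retained and flagged on the
    returned :class:`GaitEvents`.
    """
    events = _threshold_crossings(paw_speed, threshold)
    if debounce_s > 0:
        kept = []
        i = 0
        while i < len(events):
            if (i + 1 < len(events)
                    and events[i + 1][0] - events[i][0] < debounce_s
                    and events[i + 1][1] == -events[i][1]):
                i += 2  # a bounce: skip the crossing and its return
                continue
            kept.append(events[i])
            i += 1
        events = kept
    events = _enforce_alternation(events)
    tds = np.array([t for t, d, _ in events if d == -1])
    los = np.array([t for t, d, _ in events if d == 1])
    return GaitEvents(tds, los)


def build_gait_diagram(
    events: dict[str, GaitEvents], reference: str = "LH"
) -> pd.DataFrame:
    """Normalize every limb's stance intervals to the reference-limb cycle.

    A step cycle runs between two consecutive touchdowns of the reference
    limb (left hindlimb by default). Each limb's stance intervals (pairs with
    both touchdown and lift-off present) overlapping a cycle are mapped to
    phase (t - td_k) / (td_{k+1} - td_k); the start phase is clipped at 0,
    the end phase may exceed 1 for stances running past the cycle.

    Returns a table (cycle_idx, limb, stance_start_phase, stance_end_phase);
    empty when the reference limb has fewer than two touchdowns.
    """
    ref = events[reference]
    cols = ["cycle_idx", "limb", "stance_start_phase", "stance_end_phase"]
    if ref.touchdowns.size < 2:
        return pd.DataFrame(columns=cols)
    rows = []
    stances = {limb: ev.stance_intervals() for limb, ev in events.items()}
    for k in range(ref.touchdowns.size - 1):
        t0, t1 = ref.touchdowns[k], ref.touchdowns[k + 1]
        dur = t1 - t0
        for limb, ivals in stances.items():
            for td, lo in ivals:
                if lo <= t0 or td >= t1:
                    continue
                start = max((td - t0) / dur, 0.0)
                end = (lo - t0) / dur
                rows.append((k, limb, start, end))
    return pd.DataFrame(rows, columns=cols)


def stride_metrics(
    events: GaitEvents,
    paw_positions: np.ndarray | None = None,
    position_times: np.ndarray | None = None,
) -> StrideMetrics:
    """Cycle, stance and swing durations and stride length per complete cycle.

    For each pair of consecutive touchdowns (td_k, td_{k+1}) containing
    exactly one lift-off lo_k: cycle = td_{k+1} - td_k, stance = lo_k - td_k,
    swing = td_{k+1} - lo_k (so stance + swing = cycle by construction).
    Stride length is the planar displacement of the paw between the two
    touchdowns (positions linearly interpolated at event times); NaN when no
    positions are supplied. Cycles missing a lift-off are skipped and counted.
    """
    tds = events.touchdowns
    rows = []
    n_incomplete = 0
    for k in range(tds.size - 1):
        t0, t1 = tds[k], tds[k + 1]
        los = events.liftoffs[(events.liftoffs > t0) & (events.liftoffs < t1)]
        if los.size != 1:
            n_incomplete += 1
            continue
        lo = float(los[0])
        stride = np.nan
        if paw_positions is not None and position_times is not None:
            px = np.interp([t0, t1], position_times, paw_positions[:, 0])
            py = np.interp([t0, t1], position_times, paw_positions[:, 1])
            stride = float(np.hypot(px[1] - px[0], py[1] - py[0]))
        rows.append({"cycle_s": t1 - t0, "stance_s": lo - t0,
                     "swing_s": t1 - lo, "stride_cm": stride})
    return StrideMetrics(pd.DataFrame(rows, columns=["cycle_s", "stance_s",
                                                     "swing_s", "stride_cm"]),
                         n_incomplete)
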