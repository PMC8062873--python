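"""Synthetic pose-track generators with exact ground truth.

Every analysis stage of the toolkit is verifiable against these generators
without any recorded video:

* :func:`simulate_open_field` — a 30 fps body-center track in a 40 x 40 cm
  arena. A kinematic wall-following agent runs a loop whose corner pivots
  lie exactly on the arena diagonals, braking at each corner according to a
  programmed linear law (turn speed = alpha * entry speed + beta + noise)
  and turning by an angle coupled to turn speed. Stimulation trains (10 s
  every 80 s by default) drive commanded speed through a logistic function
  of laser power, and an in-frame indicator-LED landmark is "lit" (high
  tracking likelihood) during trains.
* :func:`simulate_corridor_gait` — a 300 fps track of the four paw (MTP)
  markers in a linear corridor, with per-limb phase offsets and a half-sine
  swing speed profile.
* :func:`simulate_hindlimb_kinematics` — a 300 fps six-landmark hindlimb
  chain (iliac crest, hip, knee, ankle, MTP, toe tip) animated by programmed
  sinusoidal joint-angle waveforms phase-locked to the step cycle.

Tracks are emitted in pixel units with in-frame calibration landmarks, so
the full ingestion path (reading, calibration, filtering) is exercised.

Ground-truth convention for gait generators: the programmed duty factor and
cycle are referenced to the event-detection threshold. The half-sine swing
profile is stretched so that its threshold crossings fall exactly at the
programmed stance/swing boundaries; the recorded ground-truth event times
are therefore what an ideal threshold-crossing detector measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .gait import GaitEvents, LIMBS
from .kinematics import CHAIN_LANDMARKS, JOINTS
from .pose_io import PoseTrack, StimulationEpoch
from .regression import logistic3

__all__ = [
    "OpenFieldSimConfig",
    "GaitSimConfig",
    "OpenFieldTruth",
    "GaitTruth",
    "KinematicsTruth",
    "simulate_open_field",
    "simulate_corridor_gait",
    "simulate_hindlimb_kinematics",
    "inject_low_likelihood",
    "inject_outlier",
    "inject_joint_stretch",
]


# ---------------------------------------------------------------------------
# Configurations


@dataclass(frozen=True)
class OpenFieldSimConfig:
    """Conditions of an open-field session.

    Defaults reproduce the study conditions: 40 x 40 cm arena filmed at
    30 fps for 15 min with ten 10 s stimulation trains delivered every 80 s.
    The braking and angle laws are linear-with-noise by design so that the
    scaling regressions have known ground truth; they are a model choice,
    not a claim about mouse behavior.
    """

    arena_cm: float = 40.0
    fps: float = 30.0
    duration_s: float = 900.0
    n_trains: int = 10
    train_duration_s: float = 10.0
    train_period_s: float = 80.0
    first_onset_s: float = 40.0
    train_powers: tuple[float, ...] | None = None  # % of max; None -> all 100
    baseline_speed: float = 8.0  # cm/s, commanded speed between trains
    speed_sigmoid: tuple[float, float, float] = (40.0, 50.0, 15.0)  # a, x0, b
    braking_alpha: float = 0.3
    braking_beta: float = 0.0
    braking_noise_sd: float = 0.5  # cm/s
    angle_coupling: float = 0.15  # cm of pivot displacement per cm/s turn speed
    angle_ref_speed: float = 5.0  # cm/s
    pivot_jitter_sd: float = 0.5  # cm, along-diagonal pivot jitter
    wall_margin: float = 5.0  # cm, inset of the wall-following loop
    noise_sd: float = 0.02  # cm, tracking jitter (~0.2 px at 10 px/cm)
    dropout_prob: float = 0.01
    outlier_prob: float = 0.002
    px_per_cm: float = 10.0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.arena_cm <= 0 or self.duration_s <= 0:
            raise ValueError("fps, arena size and duration must be positive")
        for p in (self.dropout_prob, self.outlier_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < self.braking_alpha < 1:
            raise ValueError("braking_alpha must lie in (0, 1)")

    def train_schedule(self) -> list[StimulationEpoch]:
        powers = (self.train_powers if self.train_powers is not None
                  else (100.0,) * self.n_trains)
        if len(powers) != self.n_trains:
            raise ValueError("train_powers length must equal n_trains")
        out = []
        for k in range(self.n_trains):
            onset = self.first_onset_s + k * self.train_period_s
            offset = onset + self.train_duration_s
            if offset <= self.duration_s:
                out.append(StimulationEpoch(onset, offset,
                                            laser_power=float(powers[k])))
        return out


@dataclass(frozen=True)
class GaitSimConfig:
    """Conditions of a corridor recording (300 fps)."""

    fps: float = 300.0
    duration_s: float = 4.0
    cycle_s: float = 0.3
    duty_factor: float = 0.6  # threshold-referenced stance fraction
    phase_offsets: tuple[float, float, float, float] = (0.0, 0.5, 0.5, 0.0)
    stride_cm: float = 6.0
    event_threshold: float = 15.0  # cm/s; 15 for paws, 9 for MTP kinematics
    corridor_width_cm: float = 8.0
    noise_sd: float = 0.005  # cm
    px_per_cm: float = 12.0
    # hindlimb chain parameters (used by simulate_hindlimb_kinematics)
    joint_means_deg: tuple[float, float, float, float] = (120.0, 110.0, 100.0, 125.0)
    joint_amplitudes_deg: tuple[float, float, float, float] = (25.0, 40.0, 35.0, 30.0)
    joint_phases: tuple[float, float, float, float] = (0.0, 0.15, 0.3, 0.45)
    segment_lengths_cm: tuple[float, ...] = (1.0, 1.5, 1.5, 1.2, 0.6)

    def __post_init__(self) -> None:
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty_factor must lie in (0, 1)")
        if any(not 0 <= p < 1 for p in self.phase_offsets):
            raise ValueError("phase offsets must lie in [0, 1)")
        if any(l <= 0 or l >= 2.3 for l in self.segment_lengths_cm):
            raise ValueError("segment lengths must be positive and < 2.3 cm")


# ---------------------------------------------------------------------------
# Ground-truth records


@dataclass
class OpenFieldTruth:
    epochs: list[StimulationEpoch]
    turns: pd.DataFrame  # corner, tp_x, tp_y, angle_deg, entry, turn, exit, t_cross
    px_per_cm: float


@dataclass
class GaitTruth:
    events: dict[str, GaitEvents]
    cycle_s: float
    duty_factor: float
    stride_cm: float
    phase_offsets: dict[str, float]
    swing_peak_speed: float
    px_per_cm: float


@dataclass
class KinematicsTruth:
    events: GaitEvents
    angles: pd.DataFrame  # per-frame true joint angles (degrees)
    amplitudes: dict[str, float]
    cycle_s: float
    duty_factor: float
    px_per_cm: float


# ---------------------------------------------------------------------------
# Open field


def _commanded_speed(t: float, epochs: list[StimulationEpoch],
                     cfg: OpenFieldSimConfig) -> float:
    for ep in epochs:
        if ep.onset <= t < ep.offset:
            a, x0, b = cfg.speed_sigmoid
            return max(cfg.baseline_speed, logistic3(ep.laser_power, a, x0, b))
    return cfg.baseline_speed


def simulate_open_field(
    config: OpenFieldSimConfig | None = None, seed: int = 0
) -> tuple[PoseTrack, OpenFieldTruth]:
    """Simulate one open-field session; see the module docstring.

    Returns a pixel-unit :class:`PoseTrack` with landmarks ``body_center``,
    ``led`` and ``corner_0..3``, and the :class:`OpenFieldTruth` (programmed
    epochs and per-turn ground truth in cm).
    """
    cfg = config if config is not None else OpenFieldSimConfig()
    rng = np.random.default_rng(seed)
    epochs = cfg.train_schedule()
    A = cfg.arena_cm
    m = cfg.wall_margin
    corners = np.array([(0.0, 0.0), (A, 0.0), (A, A), (0.0, A)])
    base_pivots = np.array([(m, m), (A - m, m), (A - m, A - m), (m, A - m)])
    bisector_u = np.array([(1, 1), (-1, 1), (-1, -1), (1, -1)]) / np.sqrt(2)

    dt = 1.0 / cfg.fps
    n = int(round(cfg.duration_s * cfg.fps))
    pos = np.empty((n, 2))

    def make_pivot(corner: int, v_turn_pred: float) -> np.ndarray:
        e = (cfg.angle_coupling * (v_turn_pred - cfg.angle_ref_speed)
             + rng.normal(0.0, cfg.pivot_jitter_sd))
        e = float(np.clip(e, -2.0, 2.0))
        return base_pivots[corner] + e * bisector_u[corner]

    # state: walking leg from P_cur (corner cur) to P_next (corner nxt)
    cur = 0
    P_cur = base_pivots[0].copy()
    v_turn_prev = _commanded_speed(0.0, epochs, cfg)
    pivots: list[tuple[int, np.ndarray]] = [(0, P_cur.copy())]
    visits: list[dict] = []

    def start_leg(t: float):
        nonlocal cur
        nxt = (cur + 1) % 4
        v_pred = cfg.braking_alpha * _commanded_speed(t, epochs, cfg) + cfg.braking_beta
        P_next = make_pivot(nxt, v_pred)
        d = P_next - P_cur
        L = float(np.linalg.norm(d))
        return nxt, P_next, d / L, L

    nxt, P_next, d_unit, L = start_leg(0.0)
    s = 0.0
    u_entry: float | None = None
    v_turn: float | None = None
    decel, zone = 7.0, 2.5

    for i in range(n):
        t = i * dt
        pos[i] = P_cur + min(s, L) * d_unit
        to_end = L - s
        cmd = _commanded_speed(t, epochs, cfg)
        if to_end <= decel and u_entry is None:
            u_entry = cmd
            v_turn = max(0.5, cfg.braking_alpha * u_entry + cfg.braking_beta
                         + rng.normal(0.0, cfg.braking_noise_sd))
        if to_end <= zone:
            v = v_turn
        elif to_end <= decel:
            v = v_turn + (u_entry - v_turn) * (to_end - zone) / (decel - zone)
        elif s <= zone:
            v = v_turn_prev
        elif s <= decel:
            v = v_turn_prev + (cmd - v_turn_prev) * (s - zone) / (decel - zone)
        else:
            v = cmd
        s_new = s + v * dt
        if s_new >= L:
            t_cross = t + (L - s) / v
            visits.append({
                "corner": nxt, "tp_x": P_next[0], "tp_y": P_next[1],
                "entry": u_entry, "turn": v_turn,
                "exit": _commanded_speed(t_cross, epochs, cfg),
                "t_cross": t_cross,
            })
            pivots.append((nxt, P_next.copy()))
            v_turn_prev = v_turn
            P_cur, cur = P_next, nxt
            overshoot = s_new - L
            nxt, P_next, d_unit, L = start_leg(t_cross)
            s = overshoot
            u_entry = None
            v_turn = None
        else:
            s = s_new

    # backfill true turn angles from the realized pivot sequence; the legs
    # are straight, so the angle at pivot k between the rays toward its
    # neighbors equals the measured first/tp/last angle
    for k, visit in enumerate(visits):
        prev_p = pivots[k][1]  # pivot before visit k is pivots[k]
        this_p = pivots[k + 1][1]
        # after the last crossing the next pivot is the in-progress leg target
        next_p = pivots[k + 2][1] if k + 2 < len(pivots) else P_next
        u = prev_p - this_p
        w = next_p - this_p
        c = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
        visit["angle_deg"] = float(np.degrees(np.arccos(np.clip(c, -1, 1))))

    # a visit is complete once the agent has advanced far enough past the
    # pivot that all exit summary bins (near edge >= 7 cm) can be occupied
    if visits and s < 12.0:
        visits = visits[:-1]
    truth_turns = pd.DataFrame(
        visits, columns=["corner", "tp_x", "tp_y", "entry", "turn", "exit",
                         "t_cross", "angle_deg"])

    # assemble the pose table ------------------------------------------------
    t_arr = np.arange(n) * dt
    landmarks = ["body_center", "led", "corner_0", "corner_1", "corner_2",
                 "corner_3"]
    coords = np.empty((n, len(landmarks), 2))
    lik = np.empty((n, len(landmarks)))

    body = pos + rng.normal(0.0, cfg.noise_sd, size=pos.shape)
    lik_body = rng.uniform(0.9, 1.0, size=n)
    drop = rng.random(n) < cfg.dropout_prob
    lik_body[drop] = rng.uniform(0.0, 0.5, size=int(drop.sum()))
    # coordinate outliers model gross tracking jumps; their displacement is
    # made large enough that the implied frame speed always violates the
    # physiological cap, honoring the contract that every injected artifact
    # is removed by quality filtering
    outl = rng.random(n) < cfg.outlier_prob
    if outl.any():
        k = int(outl.sum())
        ang = rng.uniform(0, 2 * np.pi, size=k)
        r = rng.uniform(15.0, 25.0, size=k)
        body[outl] += np.c_[r * np.cos(ang), r * np.sin(ang)]
    coords[:, 0, :] = body
    lik[:, 0] = lik_body

    led_on = np.zeros(n, dtype=bool)
    for ep in epochs:
        led_on |= (t_arr >= ep.onset) & (t_arr < ep.offset)
    led_pos = np.array([-2.0, -2.0])
    coords[:, 1, :] = led_pos + rng.normal(0.0, cfg.noise_sd, size=(n, 2))
    lik[:, 1] = np.where(led_on, rng.uniform(0.9, 1.0, size=n),
                         rng.uniform(0.0, 0.5, size=n))

    for c in range(4):
        coords[:, 2 + c, :] = corners[c] + rng.normal(0.0, cfg.noise_sd,
                                                      size=(n, 2))
        lik[:, 2 + c] = rng.uniform(0.95, 1.0, size=n)

    coords *= cfg.px_per_cm
    track = PoseTrack(landmarks, t_arr, coords, lik,
                      valid=np.ones((n, len(landmarks)), dtype=bool),
                      units="pixel", frame_rate=cfg.fps)
    return track, OpenFieldTruth(epochs, truth_turns, cfg.px_per_cm)


# ---------------------------------------------------------------------------
# Corridor gait


def _solve_swing_profile(stride: float, t_fast: float, threshold: float):
    """Peak speed and half-sine span such that the profile's threshold
    crossings are exactly ``t_fast`` apart and its displacement is ``stride``.

    The half-sine v(tau) = v_pk sin(pi tau / t_sw) crosses ``threshold`` at
    tau1 = (t_sw/pi) asin(thr/v_pk) and t_sw - tau1; requiring their spacing
    to be t_fast fixes t_sw given v_pk, and the stride 2 v_pk t_sw / pi then
    determines v_pk.
    """

    def stride_of(v_pk):
        t_sw = t_fast / (1.0 - 2.0 * np.arcsin(threshold / v_pk) / np.pi)
        return 2.0 * v_pk * t_sw / np.pi - stride

    # stride(v_pk) is U-shaped (diverges as v_pk -> threshold and as
    # v_pk -> inf); take the fast-swing branch right of the minimum
    res = optimize.minimize_scalar(stride_of, bounds=(threshold * 1.0001,
                                                      threshold * 1e3),
                                   method="bounded")
    if res.fun > 0:
        raise ValueError("stride too short for this duty factor and threshold")
    hi = max(10.0 * threshold, 4.0 * stride / t_fast, 2.0 * res.x)
    while stride_of(hi) < 0:
        hi *= 2
    v_pk = float(optimize.brentq(stride_of, res.x, hi, xtol=1e-12))
    t_sw = t_fast / (1.0 - 2.0 * np.arcsin(threshold / v_pk) / np.pi)
    tau1 = (t_sw / np.pi) * np.arcsin(threshold / v_pk)
    return v_pk, t_sw, tau1


def _paw_x(t: np.ndarray, offset: float, cfg: GaitSimConfig,
           v_pk: float, t_sw: float, tau1: float) -> np.ndarray:
    """Horizontal paw position under the foothold/half-sine swing model.

    Cycle phase 0 is a touchdown (threshold down-crossing); the swing-sine of
    cycle m starts at phase duty - tau1/T and advances the foothold by one
    stride.
    """
    T = cfg.cycle_s
    S = cfg.stride_cm
    a = t / T + offset  # absolute phase
    s0 = cfg.duty_factor - tau1 / T  # swing-sine start within the cycle
    b = a - s0
    mcyc = np.floor(b)
    g = (b - mcyc) * T  # time since latest swing-sine start
    disp = np.where(g <= t_sw,
                    (v_pk * t_sw / np.pi) * (1 - np.cos(np.pi * np.minimum(g, t_sw) / t_sw)),
                    S)
    return mcyc * S + disp


def _true_events(offset: float, cfg: GaitSimConfig) -> GaitEvents:
    """Threshold-referenced ground-truth touchdowns and lift-offs."""
    T = cfg.cycle_s
    # touchdowns at absolute phase integer n, lift-offs at n + duty
    tds, los = [], []
    k = int(np.ceil(offset - 1))
    while True:
        td = (k - offset) * T
        lo = (k + cfg.duty_factor - offset) * T
        if td > cfg.duration_s and lo > cfg.duration_s:
            break
        if 0 <= td <= cfg.duration_s:
            tds.append(td)
        if 0 <= lo <= cfg.duration_s:
            los.append(lo)
        k += 1
    return GaitEvents(np.array(tds), np.array(los))


def simulate_corridor_gait(
    config: GaitSimConfig | None = None, seed: int = 0
) -> tuple[PoseTrack, GaitTruth]:
    """Simulate the four paw (MTP) markers in the corridor, viewed from below.

    Returns a pixel-unit :class:`PoseTrack` with landmarks ``LF, RF, LH, RH``
    and four calibration markers 5 cm apart (``cal_0..3``), plus the
    ground-truth events and cycle metrics.
    """
    cfg = config if config is not None else GaitSimConfig()
    rng = np.random.default_rng(seed)
    t_fast = (1.0 - cfg.duty_factor) * cfg.cycle_s
    if cfg.stride_cm > 0:
        v_pk, t_sw, tau1 = _solve_swing_profile(cfg.stride_cm, t_fast,
                                                cfg.event_threshold)
    else:  # degenerate standing "gait": paws never move, no events
        v_pk = t_sw = tau1 = 0.0
    n = int(round(cfg.duration_s * cfg.fps))
    t = np.arange(n) / cfg.fps

    lateral = {"LF": 1.5, "RF": cfg.corridor_width_cm - 1.5,
               "LH": 2.0, "RH": cfg.corridor_width_cm - 2.0}
    fore_lead = 3.0  # cm, forelimbs ahead of hindlimbs
    offsets = dict(zip(LIMBS, cfg.phase_offsets))

    landmarks = list(LIMBS) + [f"cal_{k}" for k in range(4)]
    coords = np.empty((n, len(landmarks), 2))
    lik = np.empty((n, len(landmarks)))
    events: dict[str, GaitEvents] = {}
    for j, limb in enumerate(LIMBS):
        if cfg.stride_cm > 0:
            x = _paw_x(t, offsets[limb], cfg, v_pk, t_sw, tau1)
        else:
            x = np.full(n, 20.0)
        if limb in ("LF", "RF"):
            x = x + fore_lead
        y = np.full(n, lateral[limb])
        coords[:, j, 0] = x + rng.normal(0.0, cfg.noise_sd, size=n)
        coords[:, j, 1] = y + rng.normal(0.0, cfg.noise_sd, size=n)
        lik[:, j] = rng.uniform(0.9, 1.0, size=n)
        events[limb] = (_true_events(offsets[limb], cfg) if cfg.stride_cm > 0
                        else GaitEvents(np.array([]), np.array([])))

    for k in range(4):
        coords[:, 4 + k, 0] = 10.0 + 5.0 * k + rng.normal(0.0, cfg.noise_sd, n)
        coords[:, 4 + k, 1] = 0.5 + rng.normal(0.0, cfg.noise_sd, n)
        lik[:, 4 + k] = rng.uniform(0.95, 1.0, size=n)

    coords *= cfg.px_per_cm
    track = PoseTrack(landmarks, t, coords, lik,
                      valid=np.ones((n, len(landmarks)), dtype=bool),
                      units="pixel", frame_rate=cfg.fps)
    truth = GaitTruth(events, cfg.cycle_s, cfg.duty_factor, cfg.stride_cm,
                      offsets, v_pk, cfg.px_per_cm)
    return track, truth


# ---------------------------------------------------------------------------
# Hindlimb kinematics


def _rot(u: np.ndarray, deg: np.ndarray) -> np.ndarray:
    """Rotate rows of (N, 2) vectors by per-row angles in degrees."""
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.stack([c * u[:, 0] - s * u[:, 1],
                     s * u[:, 0] + c * u[:, 1]], axis=1)


def simulate_hindlimb_kinematics(
    config: GaitSimConfig | None = None, seed: int = 0
) -> tuple[PoseTrack, KinematicsTruth]:
    """Simulate the six-landmark hindlimb chain, viewed from the side.

    The MTP follows the foothold/half-sine swing model (threshold-referenced
    duty factor, ``event_threshold`` default 9 cm/s for this view); interior
    joint angles are programmed sinusoids of the cycle phase, and the chain
    is built from the MTP outward/upward so both the MTP events and the
    joint angles are exact ground truth. Adjacent landmark distances equal
    the configured segment lengths (< 2.3 cm) on every frame.
    """
    cfg = config if config is not None else GaitSimConfig(event_threshold=9.0)
    rng = np.random.default_rng(seed)
    t_fast = (1.0 - cfg.duty_factor) * cfg.cycle_s
    v_pk, t_sw, tau1 = _solve_swing_profile(cfg.stride_cm, t_fast,
                                            cfg.event_threshold)
    n = int(round(cfg.duration_s * cfg.fps))
    t = np.arange(n) / cfg.fps
    phase = np.mod(t / cfg.cycle_s, 1.0)

    mtp = np.empty((n, 2))
    mtp[:, 0] = _paw_x(t, 0.0, cfg, v_pk, t_sw, tau1)
    mtp[:, 1] = 4.0  # ground height in the side view (y down = toward floor)

    means = dict(zip(JOINTS, cfg.joint_means_deg))
    amps = dict(zip(JOINTS, cfg.joint_amplitudes_deg))
    phs = dict(zip(JOINTS, cfg.joint_phases))
    ang = {j: means[j] + 0.5 * amps[j] * np.sin(2 * np.pi * (phase - phs[j]))
           for j in JOINTS}

    l_ic, l_hip, l_knee, l_ankle, l_toe = cfg.segment_lengths_cm
    u_foot = np.tile(np.array([np.cos(np.radians(-20.0)),
                               np.sin(np.radians(-20.0))]), (n, 1))
    toe = mtp + l_toe * u_foot
    # interior angle at a joint is preserved under either rotation sign;
    # alternate signs to produce a leg-like zigzag
    u_ankle = _rot(u_foot, ang["mtp"])
    ankle = mtp + l_ankle * u_ankle
    u_knee = _rot(-u_ankle, -ang["ankle"])
    knee = ankle + l_knee * u_knee
    u_hip = _rot(-u_knee, ang["knee"])
    hip = knee + l_hip * u_hip
    u_ic = _rot(-u_hip, -ang["hip"])
    ic = hip + l_ic * u_ic

    chain = {"iliac_crest": ic, "hip": hip, "knee": knee, "ankle": ankle,
             "mtp": mtp, "toe_tip": toe}
    landmarks = list(CHAIN_LANDMARKS) + [f"cal_{k}" for k in range(4)]
    coords = np.empty((n, len(landmarks), 2))
    lik = np.empty((n, len(landmarks)))
    for j, name in enumerate(CHAIN_LANDMARKS):
        coords[:, j, :] = chain[name] + rng.normal(0.0, cfg.noise_sd, (n, 2))
        lik[:, j] = rng.uniform(0.9, 1.0, size=n)
    for k in range(4):
        coords[:, 6 + k, 0] = 10.0 + 5.0 * k + rng.normal(0.0, cfg.noise_sd, n)
        coords[:, 6 + k, 1] = 8.0 + rng.normal(0.0, cfg.noise_sd, n)
        lik[:, 6 + k] = rng.uniform(0.95, 1.0, size=n)

    coords *= cfg.px_per_cm
    track = PoseTrack(landmarks, t, coords, lik,
                      valid=np.ones((n, len(landmarks)), dtype=bool),
                      units="pixel", frame_rate=cfg.fps)
    truth = KinematicsTruth(
        events=_true_events(0.0, cfg),
        angles=pd.DataFrame(ang),
        amplitudes={j: float(amps[j]) for j in JOINTS},
        cycle_s=cfg.cycle_s, duty_factor=cfg.duty_factor,
        px_per_cm=cfg.px_per_cm)
    return track, truth


# ---------------------------------------------------------------------------
# Artifact injection (filter-stress fixtures)


def inject_low_likelihood(track: PoseTrack, frame: int, landmark: str,
                          value: float = 0.5) -> PoseTrack:
    """Return a copy with one landmark's likelihood lowered at one frame."""
    out = track.copy()
    out.likelihood[frame, out.index(landmark)] = value
    return out


def inject_outlier(track: PoseTrack, frame: int, landmark: str,
                   offset: tuple[float, float]) -> PoseTrack:
    """Return a copy with one landmark displaced at one frame (track units)."""
    out = track.copy()
    out.coords[frame, out.index(landmark), :] += np.asarray(offset, dtype=float)
    return out


def inject_joint_stretch(track: PoseTrack, frame: int, landmark: str,
                         distance: float) -> PoseTrack:
    """Return a copy with one chain landmark pulled ``distance`` units away
    from its position along +x at one frame (violating the adjacent-joint
    distance cap when large enough)."""
    return inject_outlier(track, frame, landmark, (distance, 0.0))
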