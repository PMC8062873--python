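"""Corner-turn geometry, speed profiles, summaries and scaling regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locokit import turns as T
from locokit.turns import (ArenaGeometry, Crossing, Rejection, TurnCandidate,
                           bin_speed_by_distance, classify_turn,
                           find_turning_point, scaling_regressions,
                           segment_roi_traversals, summarize_turn_speeds,
                           turn_angle)

GEOM = ArenaGeometry()


def candidate(points, speeds=None, corner=0, fps=30.0):
    points = np.asarray(points, dtype=float)
    n = len(points)
    if speeds is None:
        speeds = np.full(n, 10.0)
    return TurnCandidate(corner, np.arange(n), points,
                         np.arange(n) / fps, np.asarray(speeds, dtype=float))


class TestTurningPoint:
    def test_symmetric_crossing_midpoint(self):
        cand = candidate([(5.0, 15.0), (15.0, 5.0)])
        res = find_turning_point(cand, GEOM)
        assert isinstance(res, Crossing)
        np.testing.assert_allclose(res.point, (10.0, 10.0))

    def test_zigzag_double_crossing_rejected(self):
        pts = [(2.0, 10.0), (10.0, 2.0), (4.0, 12.0), (14.0, 6.0)]
        res = find_turning_point(candidate(pts), GEOM)
        assert isinstance(res, Rejection)
        assert res.reason == "multiple_crossings"

    def test_no_crossing_rejected(self):
        pts = [(2.0, 10.0), (4.0, 12.0), (6.0, 15.0)]
        res = find_turning_point(candidate(pts), GEOM)
        assert isinstance(res, Rejection)
        assert res.reason == "no_crossing"

    def test_crossing_at_shared_vertex_counted_once(self):
        pts = [(5.0, 15.0), (10.0, 10.0), (15.0, 5.0)]
        res = find_turning_point(candidate(pts), GEOM)
        assert isinstance(res, Crossing)
        np.testing.assert_allclose(res.point, (10.0, 10.0))


class TestClassify:
    def _crossing(self):
        return Crossing(point=np.array([10.0, 10.0]), time=0.5)

    def test_endpoint_below_5cm_rejected(self):
        tp = self._crossing()
        d = 4.9 / np.sqrt(2)
        cand = candidate([(10.0 - d, 10.0 + d), (15.0, 5.0)])
        rej = classify_turn(cand, tp, GEOM)
        assert rej is not None and rej.reason == "endpoint_too_close"

    def test_far_endpoints_accepted(self):
        cand = candidate([(3.0, 17.0), (17.0, 3.0)])
        assert classify_turn(cand, self._crossing(), GEOM) is None

    def test_exactly_5cm_boundary_inclusive(self):
        d = 5.0 / np.sqrt(2)
        cand = candidate([(10.0 - d, 10.0 + d), (10.0 + d, 10.0 - d)])
        assert classify_turn(cand, self._crossing(), GEOM) is None


class TestTurnAngle:
    def test_perpendicular(self):
        assert turn_angle((0, 1), (0, 0), (1, 0)) == pytest.approx(90.0)

    def test_collinear_straight_pass(self):
        assert turn_angle((0, 0), (1, 0), (2, 0)) == pytest.approx(180.0)

    def test_law_of_cosines_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, tp, b = rng.uniform(-10, 10, (3, 2))
            if min(np.linalg.norm(a - tp), np.linalg.norm(b - tp)) < 1e-6:
                continue
            la = np.linalg.norm(a - tp)
            lb = np.linalg.norm(b - tp)
            lc = np.linalg.norm(a - b)
            oracle = np.degrees(np.arccos(
                np.clip((la**2 + lb**2 - lc**2) / (2 * la * lb), -1, 1)))
            assert turn_angle(a, tp, b) == pytest.approx(oracle, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, tp, b = rng.uniform(-5, 5, (3, 2))
        if min(np.linalg.norm(a - tp), np.linalg.norm(b - tp)) < 1e-6:
            return
        assert turn_angle(a, tp, b) == pytest.approx(turn_angle(b, tp, a))

    def test_coincident_errors(self):
        with pytest.raises(ValueError):
            turn_angle((1, 1), (1, 1), (2, 2))


class TestSegmentTraversals:
    def test_far_path_empty(self):
        t = np.linspace(0, 1, 50)
        pts = np.c_[20 + 0 * t, np.linspace(25, 25, 50)]  # 25+ cm from corners
        pts[:, 0] = 20.0
        out = segment_roi_traversals(pts, t, np.ones(50, bool), GEOM, 0)
        assert out == []

    def test_two_visits_two_candidates(self):
        xs = np.r_[np.linspace(5, 30, 30), np.linspace(30, 5, 30)]
        pts = np.c_[xs, np.full(60, 5.0)]
        t = np.arange(60) / 30.0
        out = segment_roi_traversals(pts, t, np.ones(60, bool), GEOM, 0)
        assert len(out) == 2

    def test_long_masked_gap_splits(self):
        pts = np.c_[np.linspace(2, 18, 40), np.full(40, 5.0)]
        t = np.arange(40) / 30.0
        valid = np.ones(40, bool)
        valid[18:24] = False  # 6-frame gap > gap_tolerance=3
        out = segment_roi_traversals(pts, t, valid, GEOM, 0)
        assert len(out) == 2

    def test_short_masked_gap_bridged(self):
        pts = np.c_[np.linspace(2, 18, 40), np.full(40, 5.0)]
        t = np.arange(40) / 30.0
        valid = np.ones(40, bool)
        valid[20:22] = False  # 2-frame gap <= tolerance
        out = segment_roi_traversals(pts, t, valid, GEOM, 0)
        assert len(out) == 1
        assert len(out[0].frames) == 38


class TestBinSpeed:
    def _traversal(self, speed=20.0):
        """Straight diagonal-crossing path from (2,12) to (12,2)."""
        n = 101
        s = np.linspace(0, 1, n)
        pts = np.c_[2 + 10 * s, 12 - 10 * s]
        return candidate(pts, speeds=np.full(n, speed))

    def test_constant_speed_all_bins(self):
        cand = self._traversal(20.0)
        cr = find_turning_point(cand, GEOM)
        prof = bin_speed_by_distance(cand, cr, GEOM)
        occupied = prof["mean_speed"].dropna().to_numpy()
        np.testing.assert_allclose(occupied, 20.0)

    def test_matches_per_bin_averaging_oracle(self):
        rng = np.random.default_rng(1)
        cand = self._traversal()
        cand.speeds = rng.uniform(5, 30, len(cand.speeds))
        cr = find_turning_point(cand, GEOM)
        prof = bin_speed_by_distance(cand, cr, GEOM)
        d = np.linalg.norm(cand.positions - cr.point, axis=1)
        signed = np.where(cand.timestamps < cr.time, -d, d)
        for edge, val in zip(prof["signed_bin_cm"], prof["mean_speed"]):
            sel = (signed >= edge) & (signed < edge + 1.0)
            if sel.any():
                assert val == pytest.approx(cand.speeds[sel].mean(),
                                            abs=1e-12)
            else:
                assert np.isnan(val)

    def test_point_at_crossing_positive_side(self):
        # three points: before, exactly at, after the crossing
        pts = [(5.0, 15.0), (10.0, 10.0), (15.0, 5.0)]
        cand = candidate(pts, speeds=[1.0, 2.0, 3.0])
        cr = find_turning_point(cand, GEOM)
        prof = bin_speed_by_distance(cand, cr, GEOM)
        first_pos = prof[(prof["signed_bin_cm"] == 0.0)]
        assert first_pos["mean_speed"].iloc[0] == pytest.approx(2.0)


class TestSummarize:
    def _profile(self, values):
        edges = -20.0 + np.arange(40)
        return pd.DataFrame({"signed_bin_cm": edges,
                             "mean_speed": np.asarray(values, dtype=float),
                             "n_points": np.isfinite(values).astype(int)})

    def test_constant_everywhere(self):
        out = summarize_turn_speeds(self._profile(np.full(40, 15.0)), GEOM)
        assert out == (15.0, 15.0, 15.0)

    def test_tapering_profile(self):
        vals = np.full(40, np.nan)
        edges = -20.0 + np.arange(40)
        centers = edges + 0.5
        span = (centers >= -14) & (centers <= 14)
        vals[span] = 10.0 + (30.0 - 10.0) * (np.abs(centers[span]) - 0) / 14
        vals[np.abs(centers) < 2] = 10.0
        prof = self._profile(vals)
        entry, turn, exit_ = summarize_turn_speeds(prof, GEOM)
        assert turn == pytest.approx(np.nanmean(vals[(edges >= -2)
                                                     & (edges + 1 <= 2)]))
        eligible = np.isfinite(vals) & (edges + 1 <= -7)
        assert entry == pytest.approx(
            vals[eligible][np.argsort(edges[eligible])[:4]].mean())
        assert entry > turn and exit_ > turn

    def test_three_entry_bins_rejected(self):
        vals = np.full(40, np.nan)
        edges = -20.0 + np.arange(40)
        vals[(edges >= -2) & (edges + 1 <= 2)] = 10.0
        vals[(edges >= 7)] = 20.0  # exit side fully occupied
        vals[np.isin(edges, [-10.0, -9.0, -8.0])] = 25.0  # only 3 entry bins
        out = summarize_turn_speeds(self._profile(vals), GEOM)
        assert isinstance(out, Rejection) and out.reason == "entry_bins"

    def test_missing_turn_bin_rejected(self):
        vals = np.full(40, 12.0)
        vals[20] = np.nan  # bin [0,1) inside the turning zone
        out = summarize_turn_speeds(self._profile(vals), GEOM)
        assert isinstance(out, Rejection) and out.reason == "turn_bins"


class TestScalingRegressions:
    def _mk_turn(self, entry, turn, exit_, angle):
        return T.Turn(corner_id=0, turning_point=np.zeros(2),
                      angle_deg=angle, entry_speed=entry, turn_speed=turn,
                      exit_speed=exit_, profile=pd.DataFrame(),
                      t_start=0.0, t_end=1.0)

    def test_exact_braking_law(self):
        rng = np.random.default_rng(2)
        entries = rng.uniform(10, 40, 30)
        turns_ = [self._mk_turn(e, 0.4 * e, e, 90.0) for e in entries]
        regs = scaling_regressions(turns_)
        assert regs.entry_vs_brake.slope == pytest.approx(0.6, abs=1e-9)
        assert regs.entry_vs_brake.r == pytest.approx(1.0)
        assert regs.entry_vs_turn.slope == pytest.approx(0.4, abs=1e-9)

    def test_degenerate_entries_flagged(self):
        turns_ = [self._mk_turn(20.0, t, 20.0, 90.0) for t in (5.0, 6.0, 7.0)]
        regs = scaling_regressions(turns_)
        assert regs.entry_vs_turn.degenerate


class TestPipelineInvariance:
    def test_rotation_by_90_preserves_angles_and_speeds(self, openfield_session):
        """Rotating arena and trajectory by 90 degrees permutes corners but
        leaves every accepted turn's angle and speed summary unchanged."""
        track, truth, cfg = openfield_session
        geometry = ArenaGeometry()
        accepted, _ = T.detect_turns(track, "body_center", geometry)

        rot = track.copy()
        # rotate all coordinates by 90 degrees about the arena center
        c = np.array([20.0, 20.0])
        xy = rot.coords - c
        rot.coords = np.stack([-xy[..., 1], xy[..., 0]], axis=-1) + c
        accepted_rot, _ = T.detect_turns(rot, "body_center", geometry)

        assert len(accepted_rot) == len(accepted)
        key = lambda t: t.t_start
        for a, b in zip(sorted(accepted, key=key),
                        sorted(accepted_rot, key=key)):
            assert b.corner_id == (a.corner_id + 1) % 4
            assert b.angle_deg == pytest.approx(a.angle_deg, abs=1e-6)
            assert b.entry_speed == pytest.approx(a.entry_speed, abs=1e-6)
            assert b.turn_speed == pytest.approx(a.turn_speed, abs=1e-6)
            assert b.exit_speed == pytest.approx(a.exit_speed, abs=1e-6)

    def test_accepted_turns_satisfy_rules_post_hoc(self, openfield_session):
        track, truth, cfg = openfield_session
        geometry = ArenaGeometry()
        accepted, table = T.detect_turns(track, "body_center", geometry)
        assert len(accepted) >= 50
        for trn in accepted:
            assert 0.0 <= trn.angle_deg <= 180.0
            occupied = trn.profile["mean_speed"].notna()
            assert occupied.sum() >= 12  # 4 entry + 4 turn + 4 exit
        assert (table.loc[table.status == "accepted", "reason"] == "").all()
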