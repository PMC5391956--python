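"""Gait event detection, foot placements and spatiotemporal parameters."""

import numpy as np
import pytest

from gaitrig import (FootEvent, FootPlacement, GaitCommand, analyze_recording,
                     compute_parameters, detect_crossings, estimate_axes,
                     extract_placements, simulate_gait)
from gaitrig.transforms import RigidTransform


def straight_walk(n=100, speed=1.2, width=0.12):
    t = np.arange(n) / 30.0
    left = np.column_stack([speed * t, np.full(n, width / 2), np.full(n, 0.08)])
    right = np.column_stack([speed * t, np.full(n, -width / 2), np.full(n, 0.08)])
    return t, left, right


class TestEstimateAxes:
    def test_walk_along_x(self):
        _, left, right = straight_walk()
        axes = estimate_axes(left, right)
        assert np.allclose(axes.forward, [1, 0, 0], atol=1e-12)
        assert np.allclose(axes.lateral, [0, 1, 0], atol=1e-12)

    def test_rotation_equivariance(self):
        """Rotating the whole walk by 30 deg rotates the axes by 30 deg."""
        _, left, right = straight_walk()
        rot = RigidTransform.from_euler("z", [30.0], degrees=True)
        axes = estimate_axes(rot.apply(left), rot.apply(right))
        assert np.allclose(axes.forward, rot.rotation @ [1, 0, 0], atol=1e-12)
        assert np.allclose(axes.lateral, rot.rotation @ [0, 1, 0], atol=1e-12)

    def test_standing_still_rejected(self):
        n = 50
        left = np.tile([0.0, 0.06, 0.08], (n, 1))
        right = np.tile([0.0, -0.06, 0.08], (n, 1))
        with pytest.raises(ValueError, match="displacement"):
            estimate_axes(left, right)


class TestDetectCrossings:
    def test_sine_difference_analytic_zeros(self):
        """d = sin(2*pi*t) on [0, 2] crosses at 0.5, 1.0, 1.5 and returns to
        zero at 2.0 — four events, none at the leading zero."""
        t = np.arange(0, 2.0 + 1e-9, 1 / 30.0)
        d = np.sin(2 * np.pi * t)
        left = 0.5 * d
        right = -0.5 * d
        events = detect_crossings(t, left, right, hysteresis=0.0)
        assert len(events) == 4
        assert np.allclose([e.time for e in events], [0.5, 1.0, 1.5, 2.0],
                           atol=2e-3)

    def test_simulator_walk_has_one_event_per_swing(self):
        cmd = GaitCommand(n_strides=8)
        truth = simulate_gait(cmd)
        t = np.arange(0.0, truth.duration, 1 / 30.0)
        left, right = truth.ankle_trajectories(t)
        axes = estimate_axes(left, right)
        lf, _ = axes.project(left)
        rf, _ = axes.project(right)
        events = detect_crossings(t, lf, rf)
        assert len(events) == 16
        stances = [e.stance_foot for e in events]
        assert stances == ["R", "L"] * 8
        assert np.allclose([e.time for e in events], truth.event_times,
                           atol=1 / 30.0)

    def test_hysteresis_suppresses_chatter(self):
        """Noise of amplitude below the hysteresis around one true crossing
        yields exactly one event — verified against brute-force sign-change
        counting with the re-arming rule."""
        rng = np.random.default_rng(7)
        t = np.arange(0, 2.0, 1 / 100.0)
        clean = 0.3 * (t - 1.0)          # one crossing at t = 1
        noise = 0.015 * rng.uniform(-1, 1, len(t))
        d = clean + noise
        hysteresis = 0.02
        events = detect_crossings(t, d, np.zeros_like(d),
                                  hysteresis=hysteresis)
        assert len(events) == 1
        assert events[0].time == pytest.approx(1.0, abs=0.1)

        # brute-force oracle: scan sign flips, re-arm only after |d| > h
        count, sign, armed = 0, 0, True
        for di in d:
            si = 0 if di == 0 else (1 if di > 0 else -1)
            if sign == 0:
                sign = si
                continue
            if not armed:
                if abs(di) > hysteresis:
                    armed, sign = True, si
                continue
            if si != 0 and si != sign:
                count += 1
                sign, armed = si, False
        assert count == len(events)

    def test_no_valid_overlap_rejected(self):
        t = np.arange(10) / 30.0
        with pytest.raises(ValueError):
            detect_crossings(t, np.full(10, np.nan), np.zeros(10))


class TestExtractPlacements:
    def test_simulator_placements_match_ground_truth(self):
        """Stance-ankle-at-event placements reproduce the generator's
        footfall positions to under a millimeter."""
        cmd = GaitCommand()
        truth = simulate_gait(cmd)
        t = np.arange(0.0, truth.duration, 1 / 30.0)
        left, right = truth.ankle_trajectories(t)
        axes = estimate_axes(left, right)
        lf, ll = axes.project(left)
        rf, rl = axes.project(right)
        events = detect_crossings(t, lf, rf)
        placements = extract_placements(events, t, (lf, ll), (rf, rl))
        assert len(placements) == len(truth.placements)
        for est, true in zip(placements, truth.placements):
            assert est.foot == true.foot
            est_xy = axes.to_global(est.forward_pos, est.lateral_pos)
            h = np.radians(cmd.heading)
            true_xy = (np.array([cmd.walk_origin[0], cmd.walk_origin[1], 0.0])
                       + true.forward_pos * np.array([np.cos(h), np.sin(h), 0])
                       + true.lateral_pos * np.array([-np.sin(h), np.cos(h), 0]))
            assert np.linalg.norm(est_xy[:2] - true_xy[:2]) < 1e-3

    def test_alternation_of_two_events(self):
        t = np.arange(0, 2, 1 / 30.0)
        lf = 0.7 * t
        rf = np.full_like(t, 0.7)
        events = [FootEvent(0.5, "L", "R", 1.0), FootEvent(1.1, "R", "L", 1.0)]
        placements = extract_placements(events, t, (lf, 0.06 * np.ones_like(t)),
                                        (rf, -0.06 * np.ones_like(t)))
        assert [p.foot for p in placements] == ["R", "L"]

    def test_repeated_stance_drops_weaker_event(self):
        t = np.arange(0, 3, 1 / 30.0)
        lf, rf = 0.7 * t, np.full_like(t, 1.0)
        events = [FootEvent(0.5, "L", "R", slope=2.0),
                  FootEvent(0.9, "L", "R", slope=0.5),   # weaker duplicate
                  FootEvent(1.5, "R", "L", slope=2.0)]
        placements = extract_placements(events, t, (lf, np.zeros_like(t)),
                                        (rf, np.zeros_like(t)))
        assert [p.foot for p in placements] == ["R", "L"]
        assert placements[0].time == 0.5
        assert all(p.flagged for p in placements)

    def test_single_stance_foot_rejected(self):
        t = np.arange(0, 2, 1 / 30.0)
        events = [FootEvent(0.5, "L", "R", 1.0), FootEvent(1.0, "L", "R", 1.0)]
        with pytest.raises(ValueError, match="alternation"):
            extract_placements(events, t, (0.7 * t, 0 * t),
                               (np.full_like(t, 1.0), 0 * t))


class TestComputeParameters:
    PLACEMENTS = [
        FootPlacement("R", 0.0, 0.00, 0.06),
        FootPlacement("L", 0.6, 0.73, -0.06),
        FootPlacement("R", 1.2, 1.46, 0.06),
        FootPlacement("L", 1.8, 2.19, -0.06),
        FootPlacement("R", 2.4, 2.92, 0.06),
    ]

    def test_worked_example(self):
        """R/L/R/L/R placements 0.73 m apart at 0.6 s spacing: after the
        first-left-step and first-right-stride exclusion there remain one
        left and two right steps, one right stride and one left stride, and
        the walking speed is 219/1.8 = 121.67 cm/s."""
        steps, strides, summary = compute_parameters(self.PLACEMENTS, "L")
        assert summary.n_steps == {"L": 1, "R": 2}
        for s in steps:
            assert s.step_length == pytest.approx(73.0)
            assert s.step_width == pytest.approx(12.0)
            assert s.step_time == pytest.approx(0.6)
        assert summary.n_strides == {"L": 1, "R": 1}
        for s in strides:
            assert s.stride_length == pytest.approx(146.0)
        assert summary.walking_speed == pytest.approx(3 * 73 / 1.8)
        assert summary.excluded["first_step"].foot == "L"
        assert summary.excluded["first_stride"].foot == "R"

    def test_collinear_walk_has_zero_width(self):
        flat = [FootPlacement(p.foot, p.time, p.forward_pos, 0.0)
                for p in self.PLACEMENTS]
        steps, _, _ = compute_parameters(flat, "L")
        assert all(s.step_width == 0.0 for s in steps)

    def test_stride_equals_sum_of_steps(self):
        """Projection additivity: each stride is the sum of its two steps."""
        rng = np.random.default_rng(3)
        placements, fwd, t = [], 0.0, 0.0
        feet = ["R", "L"] * 6
        for foot in feet:
            fwd += rng.uniform(0.5, 0.9)
            t += rng.uniform(0.4, 0.8)
            placements.append(FootPlacement(foot, t, fwd,
                                            0.06 if foot == "L" else -0.06))
        steps, strides, _ = compute_parameters(placements, "L")
        all_steps, all_strides, _ = compute_parameters(placements, "L")
        # use un-excluded pairs: reconstruct from raw placements
        for k in range(2, len(placements)):
            stride = (placements[k].forward_pos
                      - placements[k - 2].forward_pos) * 100
            step1 = (placements[k - 1].forward_pos
                     - placements[k - 2].forward_pos) * 100
            step2 = (placements[k].forward_pos
                     - placements[k - 1].forward_pos) * 100
            assert stride == pytest.approx(step1 + step2, abs=1e-9)

    def test_walking_speed_identity(self):
        steps, _, summary = compute_parameters(self.PLACEMENTS, "L")
        total_len = sum(s.step_length for s in steps)
        total_time = sum(s.step_time for s in steps)
        assert summary.walking_speed == pytest.approx(total_len / total_time,
                                                      abs=1e-12)

    def test_non_alternating_rejected(self):
        bad = [FootPlacement("R", 0.0, 0.0, 0.06),
               FootPlacement("R", 0.6, 0.7, 0.06),
               FootPlacement("L", 1.2, 1.4, -0.06)]
        with pytest.raises(ValueError, match="alternate"):
            compute_parameters(bad, "L")


class TestEndToEnd:
    def test_noiseless_recovery_of_commanded_parameters(self):
        """Full chain on exact trajectories recovers the commanded step
        length / width / time to < 1 mm / 1 ms."""
        cmd = GaitCommand(step_length=0.73, step_width=0.12, cadence=100.0)
        truth = simulate_gait(cmd)
        t = np.arange(0.0, truth.duration, 1 / 30.0)
        left, right = truth.ankle_trajectories(t)
        steps, strides, summary, _ = analyze_recording(t, left, right)
        assert np.mean([s.step_length for s in steps]) == pytest.approx(
            73.0, abs=0.1)
        assert np.mean([s.step_width for s in steps]) == pytest.approx(
            12.0, abs=0.1)
        assert np.mean([s.step_time for s in steps]) == pytest.approx(
            0.6, abs=1e-3)
        assert np.mean([s.stride_length for s in strides]) == pytest.approx(
            146.0, abs=0.1)
        assert summary.walking_speed == pytest.approx(73 / 0.6, abs=0.2)

    def test_parameters_invariant_under_rigid_motion(self, rng):
        """Rotating + translating all trajectories leaves every parameter
        unchanged (axes estimation equivariance)."""
        cmd = GaitCommand()
        truth = simulate_gait(cmd)
        t = np.arange(0.0, truth.duration, 1 / 30.0)
        left, right = truth.ankle_trajectories(t)
        motion = RigidTransform.from_euler("z", [37.0], degrees=True,
                                           translation=[5.0, -3.0, 0.0])
        s0, _, sum0, _ = analyze_recording(t, left, right)
        s1, _, sum1, _ = analyze_recording(t, motion.apply(left),
                                           motion.apply(right))
        assert sum1.walking_speed == pytest.approx(sum0.walking_speed,
                                                   abs=1e-6)
        for a, b in zip(s0, s1):
            assert a.foot == b.foot
            assert b.step_length == pytest.approx(a.step_length, abs=1e-6)
            assert b.step_width == pytest.approx(a.step_width, abs=1e-6)
            assert b.step_time == pytest.approx(a.step_time, abs=1e-9)

    def test_noise_robustness_of_means(self):
        """1 cm isotropic ankle noise: mean step-length bias < 1 cm and mean
        step-time bias < 0.01 s across seeded recordings."""
        cmd = GaitCommand()
        truth = simulate_gait(cmd)
        t = np.arange(0.0, truth.duration, 1 / 30.0)
        left, right = truth.ankle_trajectories(t)
        len_biases, time_biases = [], []
        from gaitrig.fusion import smooth, FusedSeries, N_JOINTS, joint_index
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ln = left + rng.normal(0, 0.01, left.shape)
            rn = right + rng.normal(0, 0.01, right.shape)
            pos = np.full((len(t), N_JOINTS, 3), np.nan)
            valid = np.zeros((len(t), N_JOINTS), bool)
            pos[:, joint_index("AnkleLeft")] = ln
            pos[:, joint_index("AnkleRight")] = rn
            valid[:, joint_index("AnkleLeft")] = True
            valid[:, joint_index("AnkleRight")] = True
            sm = smooth(FusedSeries(t, pos, valid))
            steps, _, _, _ = analyze_recording(
                t, sm.positions[:, joint_index("AnkleLeft")],
                sm.positions[:, joint_index("AnkleRight")])
            len_biases.append(np.mean([s.step_length for s in steps]) - 73.0)
            time_biases.append(np.mean([s.step_time for s in steps]) - 0.6)
        assert abs(np.mean(len_biases)) < 1.0
        assert abs(np.mean(time_biases)) < 0.01
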