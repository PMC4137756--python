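"""Bowing coordinate geometry, stroke segmentation and the five measures,
against constructed geometries and closed forms."""

import numpy as np
import pytest

from bowfreeze.bow import (
    ReversalWindow,
    Stroke,
    bow_angle,
    bow_kinematics_from_trial,
    bowing_coordinate,
    central_fraction,
    compute_measures,
    detect_strokes,
    measure_accel_amplitude,
    measure_amplitude,
    measure_angle_sd,
    measure_between_bow_var,
    measure_within_bow_var,
    reversal_window_samples,
    select_analyzed,
)
from bowfreeze.simulate import simulate_tracking_trial


def stroke(start, end, direction="down", rate=60.0):
    return Stroke(direction, start, end, rate)


class TestBowingCoordinate:
    def test_translation_along_own_axis(self):
        """Bow sliding along its own axis at 100 mm/frame against an
        orthogonal string: |velocity| = 100 * rate."""
        n, rate = 50, 60.0
        t = np.arange(n)
        bow_point = np.stack([100.0 * t, np.zeros(n), np.zeros(n)], axis=1)
        bow_dir = np.tile([1.0, 0, 0], (n, 1))
        string_point = np.tile([2000.0, 0, 0], (n, 1))
        string_dir = np.tile([0, 1.0, 0], (n, 1))
        pos, vel, _ = bowing_coordinate(bow_point, bow_dir, string_point, string_dir, rate)
        assert np.allclose(np.abs(vel[1:-1]), 100.0 * rate, rtol=1e-9)

    def test_stationary_bow(self):
        n = 30
        bow_point = np.tile([0.0, 0, 0], (n, 1))
        bow_dir = np.tile([1.0, 0, 0], (n, 1))
        string_point = np.tile([500.0, 0, 100.0], (n, 1))
        string_dir = np.tile([0, 1.0, 0], (n, 1))
        pos, vel, acc = bowing_coordinate(bow_point, bow_dir, string_point, string_dir, 60.0)
        assert np.allclose(pos, 500.0)
        assert np.allclose(vel, 0.0) and np.allclose(acc, 0.0)

    def test_parallel_axes_flagged(self):
        n = 5
        bow_point = np.zeros((n, 3))
        d = np.tile([1.0, 0, 0], (n, 1))
        pos, _, _ = bowing_coordinate(bow_point, d, bow_point + [0, 0, 50.0], d, 60.0)
        assert np.isnan(pos).all()

    def test_programmed_contact_trajectory_recovered(self):
        trial, truth = simulate_tracking_trial(amplitude_mm=260.0, seed=0)
        kin = bow_kinematics_from_trial(trial)
        assert np.abs(kin.position - truth.contact_position).max() < 1e-6


class TestBowAngle:
    def test_orthogonal_90(self):
        a = bow_angle(np.array([[1.0, 0, 0]]), np.array([[0, 1.0, 0]]))
        assert np.isclose(a[0], 90.0)

    def test_parallel_0(self):
        a = bow_angle(np.array([[0, 2.0, 0]]), np.array([[0, 1.0, 0]]))
        assert np.isclose(a[0], 0.0)

    def test_constructed_60_degrees(self):
        u = np.array([[np.cos(np.radians(60.0)), np.sin(np.radians(60.0)), 0.0]])
        a = bow_angle(u, np.array([[1.0, 0, 0]]))
        assert abs(a[0] - 60.0) < 1e-9

    def test_acute_convention_folds(self):
        u = np.array([[-1.0, 0.02, 0]])
        v = np.array([[1.0, 0, 0]])
        assert bow_angle(u, v, "signed")[0] > 90.0
        assert bow_angle(u, v, "acute")[0] < 90.0


class TestStrokeDetection:
    def test_sinusoidal_velocity_gives_alternating_075s_strokes(self):
        rate, dur = 60.0, 30.0
        t = np.arange(int(rate * dur)) / rate
        v = np.sin(2 * np.pi * t / 1.5)
        out = detect_strokes(v, rate)
        assert 39 <= len(out.strokes) <= 40
        for s in out.strokes:
            assert abs(s.duration - 0.75) <= 0.02
        dirs = [s.direction for s in out.strokes]
        assert all(a != b for a, b in zip(dirs, dirs[1:]))

    def test_constant_velocity_no_strokes(self):
        out = detect_strokes(np.full(600, 80.0), 60.0)
        assert len(out.strokes) == 0

    def test_short_stroke_rejected(self):
        rate = 60.0
        segs = [(0.75, 1.0), (0.75, -1.0), (0.4, 1.0), (0.75, -1.0), (0.75, 1.0)]
        v = np.concatenate([np.full(int(d * rate), s * 100.0) for d, s in segs])
        out = detect_strokes(v, rate)
        durations = [round(s.duration, 2) for s in out.strokes]
        assert 0.4 not in durations
        assert durations.count(0.75) >= 2

    def test_jitter_near_zero_suppressed_by_hysteresis(self):
        rate = 60.0
        t = np.arange(int(rate * 30)) / rate
        v = 100.0 * np.sin(2 * np.pi * t / 1.5)
        rng = np.random.default_rng(0)
        v += rng.normal(0, 1.0, v.shape)  # small jitter crossing zero repeatedly
        out = detect_strokes(v, rate)
        assert 38 <= len(out.strokes) <= 41


class TestSelection:
    def test_first_ten_per_direction(self):
        rate = 60.0
        t = np.arange(int(rate * 31)) / rate - 0.5
        v = 100.0 * np.sin(2 * np.pi * t / 1.5)
        detected = detect_strokes(v, rate)
        analyzed = select_analyzed(detected, np.zeros(t.shape[0], bool), 10)
        assert len(analyzed.by_direction("up")) == 10
        assert len(analyzed.by_direction("down")) == 10
        assert all(w.inside(t.shape[0]) for w in analyzed.windows)

    def test_contaminated_stroke_skipped_and_replaced(self):
        rate = 60.0
        t = np.arange(int(rate * 31)) / rate - 0.5
        v = 100.0 * np.sin(2 * np.pi * t / 1.5)
        detected = detect_strokes(v, rate)
        third = detected.strokes[2]
        missing = np.zeros(t.shape[0], bool)
        missing[(third.start + third.end) // 2] = True
        analyzed = select_analyzed(detected, missing, 10)
        starts = {s.start for s in analyzed.strokes}
        assert third.start not in starts
        assert len(analyzed.by_direction(third.direction)) == 10

    def test_all_contaminated_empty(self):
        rate = 60.0
        t = np.arange(int(rate * 31)) / rate - 0.5
        v = 100.0 * np.sin(2 * np.pi * t / 1.5)
        detected = detect_strokes(v, rate)
        analyzed = select_analyzed(detected, np.ones(t.shape[0], bool), 10)
        assert len(analyzed) == 0


class TestCentralFraction:
    def test_45_frame_stroke_keeps_frames_4_to_40(self):
        a, b = central_fraction(stroke(0, 45))
        assert (a, b) == (4, 41)  # frames 4..40 inclusive, 37 frames

    def test_full_fraction_keeps_everything(self):
        assert central_fraction(stroke(10, 55), 1.0) == (10, 55)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            central_fraction(stroke(0, 4))


class TestMeasures:
    def test_amplitude_of_ramp(self):
        pos = np.linspace(0.0, 600.0, 45)
        assert measure_amplitude(pos, stroke(0, 45)) == pytest.approx(600.0)
        assert measure_amplitude(np.full(45, 5.0), stroke(0, 45)) == 0.0

    def test_angle_sd_alternating(self):
        angle = np.where(np.arange(100) % 2 == 0, 89.0, 91.0)
        assert measure_angle_sd(angle, stroke(0, 100)) == pytest.approx(1.0, abs=1e-9)
        assert measure_angle_sd(np.full(100, 90.0), stroke(0, 100)) == 0.0

    def test_within_bow_var_rectangular_vs_bell(self):
        n = 45
        rect = np.full(n, 100.0)
        bell = 100.0 * np.pi / 2 * np.sin(np.pi * np.arange(n) / (n - 1))
        s = [stroke(0, n)]
        assert measure_within_bow_var(rect, s) == pytest.approx(0.0)
        assert measure_within_bow_var(bell, s) > measure_within_bow_var(rect, s)

    def test_between_bow_constant_offset(self):
        n = 45
        v = np.concatenate([np.full(n, 100.0), np.full(n, 110.0)])
        strokes = [stroke(0, n), stroke(n, 2 * n)]
        assert measure_between_bow_var(v, strokes) == pytest.approx(25.0)

    def test_between_bow_identical_strokes_zero(self):
        n = 45
        seg = 100.0 * np.sin(np.pi * np.arange(n) / n)
        v = np.concatenate([seg, seg])
        assert measure_between_bow_var(v, [stroke(0, n), stroke(n, 2 * n)]) == pytest.approx(0.0)

    def test_between_bow_needs_two_strokes(self):
        with pytest.raises(ValueError, match="2 strokes"):
            measure_between_bow_var(np.zeros(45), [stroke(0, 45)])

    def test_accel_amplitude_of_cosine_reversal(self):
        rate, T, V = 60.0, 1.5, 300.0
        t = np.arange(int(rate * 6)) / rate
        v = -V * np.cos(2 * np.pi * t / T)
        a = np.gradient(v, 1.0 / rate)
        center = int(rate * T / 2)  # v crosses zero at t = T/4, 3T/4 ... pick 3T/4
        center = int(rate * 3 * T / 4)
        w = ReversalWindow(center, "up-down", rate)
        expected = V * 2 * np.pi / T
        assert measure_accel_amplitude(a, w) == pytest.approx(expected, rel=0.01)

    def test_accel_zero_for_static_bow(self):
        w = ReversalWindow(60, "up-down", 60.0)
        assert measure_accel_amplitude(np.zeros(200), w) == 0.0

    def test_sharper_reversal_larger_accel(self):
        rate = 60.0
        t = np.arange(int(rate * 3)) / rate - 1.5

        def rev(tau):
            return np.clip(t / tau, -1, 1) * 300.0

        a_soft = np.gradient(rev(0.2), 1.0 / rate)
        a_sharp = np.gradient(rev(0.08), 1.0 / rate)
        w = ReversalWindow(int(1.5 * rate), "up-down", rate)
        assert measure_accel_amplitude(a_sharp, w) > measure_accel_amplitude(a_soft, w)


class TestInvariances:
    def test_window_span_from_rate(self):
        assert reversal_window_samples(60.0) == 45
        assert reversal_window_samples(120.0) == 90

    def test_measures_invariant_under_rigid_transform(self, expert_noisy):
        from scipy.spatial.transform import Rotation

        trial, _ = expert_noisy
        kin = bow_kinematics_from_trial(trial)
        detected = detect_strokes(kin.velocity, trial.rate_hz)
        analyzed = select_analyzed(detected, trial.missing.any(axis=1), 10)
        base = compute_measures(kin, analyzed)

        moved = trial.copy()
        rot = Rotation.from_euler("xyz", [15, -40, 70], degrees=True).as_matrix()
        moved.positions = np.einsum("ij,nmj->nmi", rot, moved.positions) + [100, -50, 30]
        kin2 = bow_kinematics_from_trial(moved)
        again = compute_measures(kin2, analyzed)
        for key, val in base.items():
            assert again[key] == pytest.approx(val, rel=1e-9, abs=1e-9), key

    def test_amplitude_linear_variance_quadratic_under_scaling(self, expert_noisy):
        trial, _ = expert_noisy
        kin = bow_kinematics_from_trial(trial)
        detected = detect_strokes(kin.velocity, trial.rate_hz)
        analyzed = select_analyzed(detected, trial.missing.any(axis=1), 10)
        base = compute_measures(kin, analyzed)

        scaled = trial.copy()
        scaled.positions = scaled.positions * 2.0
        kin2 = bow_kinematics_from_trial(scaled)
        doubled = compute_measures(kin2, analyzed)
        for d in ("up", "down"):
            assert doubled[("amplitude", d)] == pytest.approx(2 * base[("amplitude", d)], rel=1e-6)
            assert doubled[("within_bow_var", d)] == pytest.approx(
                4 * base[("within_bow_var", d)], rel=1e-6
            )
        for k in ("up-down", "down-up"):
            assert doubled[("accel_amp", k)] == pytest.approx(2 * base[("accel_amp", k)], rel=1e-6)
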