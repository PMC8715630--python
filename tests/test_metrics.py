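"""Macro kinematic/kinetic metric correctness against closed forms and
independent oracles."""

import math
import warnings

import numpy as np
import pytest

from robokin import (
    ArmGeometry,
    fit_ellipse,
    forward_kinematics_2link,
    inverse_kinematics_2link,
    joint_independence,
    reach_macro_metrics,
    resistance_metrics,
    shoulder_strength,
    stabilization_metrics,
)
from robokin.metrics import MetricOptions, UndefinedMetricError
from robokin.types import DegenerateSegmentError

from conftest import minimum_jerk_segment


class TestReachMacroMetrics:
    def test_minimum_jerk_speed_shape(self, minjerk):
        t, q, target = minjerk
        m = reach_macro_metrics(t, q, target, 0.01)
        assert m.speed_shape == pytest.approx(8.0 / 15.0, abs=1e-3)

    def test_minimum_jerk_dimensionless_jerk(self, minjerk):
        t, q, target = minjerk
        m = reach_macro_metrics(t, q, target, 0.01)
        assert m.jerk_discrete == pytest.approx(720.0, rel=5e-3)

    def test_minimum_jerk_aim_and_deviation_zero(self, minjerk):
        t, q, target = minjerk
        m = reach_macro_metrics(t, q, target, 0.01)
        assert m.aim == pytest.approx(0.0, abs=1e-6)
        assert m.deviation == pytest.approx(0.0, abs=1e-9)

    def test_constant_speed_shape_is_one(self):
        t = np.linspace(0, 1, 500)
        q = np.stack([0.1 * t, np.zeros_like(t)], axis=1)
        m = reach_macro_metrics(t, q, (0.1, 0.0), 0.01, MetricOptions(smooth_window=0))
        assert m.speed_shape == pytest.approx(1.0, abs=1e-9)

    def test_jerk_invariant_to_amplitude_and_duration_scaling(self):
        t1, q1, tg1 = minimum_jerk_segment(duration=1.0, amplitude=0.1, n=2000)
        t2, q2, tg2 = minimum_jerk_segment(duration=2.5, amplitude=0.35, n=2000)
        j1 = reach_macro_metrics(t1, q1, tg1, 0.01).jerk_discrete
        j2 = reach_macro_metrics(t2, q2, tg2, 0.01).jerk_discrete
        assert j1 == pytest.approx(j2, rel=1e-6)

    def test_zero_displacement_flagged(self):
        t = np.linspace(0, 1, 100)
        q = np.zeros((100, 2))
        with pytest.raises(DegenerateSegmentError):
            reach_macro_metrics(t, q, (0.1, 0.0), 0.01)

    def test_too_few_samples_flagged(self):
        with pytest.raises(DegenerateSegmentError):
            reach_macro_metrics(
                np.array([0.0, 0.1, 0.2]), np.array([[0, 0], [0.1, 0], [0.2, 0]]),
                (0.2, 0.0), 0.01,
            )

    def test_dwell_time_of_terminal_rest(self):
        # move for 1 s then rest inside the target for exactly 0.5 s
        n_move, n_rest = 400, 200
        t = np.arange(n_move + n_rest) / 400.0
        tau = np.minimum(t[:n_move] / t[n_move - 1], 1.0)
        x = 0.14 * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        x = np.concatenate([x, np.full(n_rest, 0.14)])
        q = np.stack([x, np.zeros_like(x)], axis=1)
        m = reach_macro_metrics(t, q, (0.14, 0.0), 0.01)
        # at least the 0.5 s rest; may extend into the slow terminal approach
        assert 0.5 <= m.dwell_time <= 0.62


class TestFitEllipse:
    @staticmethod
    def _ellipse_points(a, b, theta, center=(0.0, 0.0), n=100):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x, y = a * np.cos(t), b * np.sin(t)
        ct, st = np.cos(theta), np.sin(theta)
        return np.stack([center[0] + ct * x - st * y, center[1] + st * x + ct * y], axis=1)

    def test_axis_aligned_recovery(self):
        major, minor, orient = fit_ellipse(self._ellipse_points(2.0, 1.0, 0.0))
        assert major == pytest.approx(2.0, abs=1e-9)
        assert minor == pytest.approx(1.0, abs=1e-9)
        assert orient == pytest.approx(0.0, abs=1e-9)

    def test_circle_axis_ratio_one(self):
        major, minor, _ = fit_ellipse(self._ellipse_points(1.0, 1.0, 0.3))
        assert minor / major == pytest.approx(1.0, abs=1e-9)

    def test_rotated_recovery(self):
        major, minor, orient = fit_ellipse(self._ellipse_points(2.0, 1.0, np.pi / 6))
        assert orient == pytest.approx(np.pi / 6, abs=1e-6)
        assert (major, minor) == pytest.approx((2.0, 1.0), abs=1e-6)

    def test_equivariance_under_rotation_and_translation(self):
        rng = np.random.default_rng(3)
        pts = self._ellipse_points(1.4, 0.6, 0.2, n=60)
        rot = 0.7
        ct, st = np.cos(rot), np.sin(rot)
        moved = pts @ np.array([[ct, -st], [st, ct]]).T + np.array([3.0, -1.0])
        m0 = fit_ellipse(pts)
        m1 = fit_ellipse(moved)
        assert m1[0] == pytest.approx(m0[0], abs=1e-6)
        assert m1[1] == pytest.approx(m0[1], abs=1e-6)
        expected = (m0[2] + rot + np.pi / 2) % np.pi - np.pi / 2
        assert m1[2] == pytest.approx(expected, abs=1e-6)

    def test_collinear_points_rejected(self):
        pts = np.stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)], axis=1)
        with pytest.raises(ValueError, match="collinear"):
            fit_ellipse(pts)


class TestInverseKinematics:
    def test_full_extension(self, arm):
        sx, sy = arm.shoulder_position
        reach = arm.upper_arm_m + arm.forearm_m
        _, theta_e = inverse_kinematics_2link((sx + reach, sy), arm)
        assert theta_e == pytest.approx(0.0, abs=1e-6)

    def test_fully_folded(self, arm):
        sx, sy = arm.shoulder_position
        fold = abs(arm.upper_arm_m - arm.forearm_m)
        _, theta_e = inverse_kinematics_2link((sx + fold, sy), arm)
        assert abs(theta_e) == pytest.approx(math.pi, abs=1e-6)

    def test_round_trip_on_random_reachable_points(self, arm, rng):
        r = rng.uniform(
            abs(arm.upper_arm_m - arm.forearm_m) + 1e-6,
            arm.upper_arm_m + arm.forearm_m - 1e-6,
            1000,
        )
        ang = rng.uniform(0, 2 * np.pi, 1000)
        pts = np.stack(
            [
                arm.shoulder_position[0] + r * np.cos(ang),
                arm.shoulder_position[1] + r * np.sin(ang),
            ],
            axis=1,
        )
        ts, te = inverse_kinematics_2link(pts, arm)
        back = forward_kinematics_2link(ts, te, arm)
        assert np.abs(back - pts).max() < 1e-9

    def test_unreachable_point_names_distance(self, arm):
        with pytest.raises(ValueError, match="annulus"):
            inverse_kinematics_2link((5.0, 5.0), arm)


class TestJointIndependence:
    def test_constant_elbow_flagged(self, arm):
        # shoulder-only arc: elbow angle held fixed along the whole path
        theta_s = np.linspace(0.5, 1.0, 100)
        path = forward_kinematics_2link(theta_s, np.full_like(theta_s, -0.5), arm)
        with pytest.raises(UndefinedMetricError):
            joint_independence(path, arm)

    def test_affine_joint_dependence_gives_unit_correlation(self, arm):
        theta_s = np.linspace(0.8, 1.2, 200)
        theta_e = 2.0 * theta_s - 2.8
        path = forward_kinematics_2link(theta_s, theta_e, arm)
        assert joint_independence(path, arm) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_ik_correlation_oracle(self, arm):
        ang = np.linspace(0, 2 * np.pi, 300, endpoint=False)
        path = np.stack([0.1 * np.cos(ang), 0.1 * np.sin(ang)], axis=1)
        r = joint_independence(path, arm)
        # brute-force oracle: law-of-cosines angles point by point
        l1, l2 = arm.upper_arm_m, arm.forearm_m
        sx, sy = arm.shoulder_position
        ts, te = [], []
        for x, y in path:
            dx, dy = x - sx, y - sy
            rr = math.hypot(dx, dy)
            te.append(-math.acos((rr**2 - l1**2 - l2**2) / (2 * l1 * l2)))
            ts.append(
                math.atan2(dy, dx)
                + math.acos((l1**2 + rr**2 - l2**2) / (2 * l1 * rr))
            )
        oracle = np.corrcoef(ts, te)[0, 1]
        assert r == pytest.approx(oracle, abs=1e-9)


class TestResistanceMetrics:
    @staticmethod
    def _segment(target, frac, aim_rad=0.0, n=101):
        t = np.linspace(0, 1, n)
        target = np.asarray(target, dtype=float)
        u = target / np.linalg.norm(target)
        rot = np.array(
            [[np.cos(aim_rad), -np.sin(aim_rad)], [np.sin(aim_rad), np.cos(aim_rad)]]
        )
        direction = rot @ u
        prog = frac * np.linalg.norm(target) * np.sin(np.pi * t) ** 2
        return t, np.outer(prog, direction), target

    def test_reaching_target_and_pushed_back(self):
        seg = self._segment((0.14, 0.0), frac=1.0)
        max_disp, _ = resistance_metrics([seg])
        assert max_disp == pytest.approx(0.14, rel=1e-6)

    def test_all_zero_aims(self):
        segs = [self._segment((0.14, 0.0), 0.8), self._segment((0.0, 0.14), 0.6)]
        _, aim = resistance_metrics(segs)
        assert aim == pytest.approx(0.0, abs=1e-6)

    def test_opposite_aims_cancel_in_circular_mean(self):
        segs = [
            self._segment((0.14, 0.0), 0.9, aim_rad=+0.2),
            self._segment((0.14, 0.0), 0.9, aim_rad=-0.2),
        ]
        _, aim = resistance_metrics(segs)
        assert aim == pytest.approx(0.0, abs=1e-9)

    def test_missing_force_channel_warns(self):
        with pytest.warns(UserWarning, match="force channel"):
            resistance_metrics([self._segment((0.14, 0.0), 1.0)], has_force=False)


class TestStabilization:
    def test_perfect_hold(self):
        q = np.zeros((100, 2))
        scatter, offset = stabilization_metrics(np.arange(100) / 200, q, (0, 0))
        assert scatter == 0.0 and offset == 0.0

    def test_constant_displacement(self):
        q = np.full((100, 2), [0.003, 0.004])
        scatter, offset = stabilization_metrics(np.arange(100) / 200, q, (0, 0))
        assert offset == pytest.approx(0.005, abs=1e-12)
        assert scatter == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_wander_matches_closed_form(self):
        rng = np.random.default_rng(99)
        sigma = 0.003
        q = rng.normal(0, sigma, (100_000, 2))
        scatter, _ = stabilization_metrics(np.arange(len(q)) / 200, q, (0, 0))
        assert scatter == pytest.approx(sigma * math.sqrt(2), rel=0.02)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match=">= 10"):
            stabilization_metrics(np.arange(5) / 200, np.zeros((5, 2)), (0, 0))


class TestShoulderStrength:
    def test_uniform_trials(self):
        trials = [(d, 10.0) for d in ("F", "E", "AB", "AD") for _ in range(5)]
        means = shoulder_strength(trials)
        assert all(means[d] == 10.0 for d in ("F", "E", "AB", "AD"))
        assert means["deltaz"] == 10.0

    def test_deltaz_is_mean_of_direction_means(self):
        trials = [("F", 8.0), ("E", 10.0), ("AB", 12.0), ("AD", 14.0)]
        assert shoulder_strength(trials)["deltaz"] == pytest.approx(11.0)

    def test_matches_bruteforce_group_mean(self, rng):
        dirs = ("F", "E", "AB", "AD")
        trials = [(dirs[int(rng.integers(4))], float(rng.uniform(5, 50))) for _ in range(40)]
        means = shoulder_strength(trials)
        for d in dirs:
            vals = [p for dd, p in trials if dd == d]
            assert means[d] == pytest.approx(float(np.mean(vals)), abs=1e-12)

    def test_missing_direction_warns(self):
        trials = [("F", 8.0), ("E", 10.0), ("AB", 12.0)]
        with pytest.warns(UserWarning, match="AD"):
            means = shoulder_strength(trials)
        assert means["AD"] is None
        assert means["deltaz"] == pytest.approx(10.0)
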