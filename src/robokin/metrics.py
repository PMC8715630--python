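"""Macro kinematic and kinetic metrics of the robotic evaluation tasks.

Point-to-point tasks (planar reaching, wrist pointing, forearm rotation)
yield per-attempt macro metrics — aim, duration, deviation, dwell time,
mean/peak speed, speed shape, and dimensionless jerk — which are averaged
over a session's non-degenerate attempts ("mean-aggregated").  Circle
drawing yields best-fit ellipse axes and the shoulder-elbow joint
independence (correlation of the joint angles estimated by two-link inverse
kinematics).  The resistance, isometric-stabilization and kinetic-strength
tasks yield displacement/aim, scatter/offset and per-direction shoulder
force means (deltaz).

Jerk normalization: discrete (terminated) movements use the dimensionless
squared jerk J = (integral of |d3q/dt3|^2 dt) * D^5 / A^2 with D the
attempt duration and A its path length; the rhythmic variant normalizes by
the mean speed, J_r = (integral of |d3q/dt3|^2 dt) * D / vbar^2.  For a
minimum-jerk straight reach J = 720 and the speed-shape ratio is 8/15.

Derivatives are central finite differences on the timestamp grid; an
optional Savitzky-Golay smoothing pass (default window 5) precedes
differentiation when sampling is uniform, since third derivatives of raw
measured data are noise-dominated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .types import DegenerateSegmentError

__all__ = [
    "ArmGeometry",
    "MacroMetrics",
    "MetricOptions",
    "reach_macro_metrics",
    "fit_ellipse",
    "inverse_kinematics_2link",
    "forward_kinematics_2link",
    "joint_independence",
    "resistance_metrics",
    "stabilization_metrics",
    "shoulder_strength",
    "speed_profile",
]


@dataclass(frozen=True)
class ArmGeometry:
    """Two-link planar arm model used for inverse kinematics.

    The shoulder sits behind the robot workspace centre; the elbow-down
    branch is used throughout (right-arm convention, consistent within a
    session).
    """

    upper_arm_m: float = 0.31
    forearm_m: float = 0.34
    shoulder_position: tuple = (0.0, -0.45)

    def __post_init__(self):
        if self.upper_arm_m <= 0 or self.forearm_m <= 0:
            raise ValueError("arm segment lengths must be positive")


@dataclass(frozen=True)
class MetricOptions:
    smooth_window: int = 5  # samples; <3 disables smoothing
    speed_threshold_frac: float = 0.05  # of segment peak speed, for dwell
    deviation: str = "rms"  # or "max"
    aim_at: str = "first_peak"  # aim measured at the first local speed max


@dataclass
class MacroMetrics:
    """Whole-movement summary of one point-to-point attempt."""

    aim: float  # rad, unsigned
    duration: float  # s
    deviation: float  # m or rad
    dwell_time: float  # s
    mean_speed: float
    peak_speed: float
    speed_shape: float  # mean/peak, in (0, 1]
    jerk_discrete: float  # dimensionless
    jerk_rhythmic: float  # dimensionless

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _smooth(x: np.ndarray, t: np.ndarray, window: int) -> np.ndarray:
    """Savitzky-Golay smoothing when the grid is (near) uniform."""
    n = len(x)
    if window < 3 or n < window:
        return x
    dt = np.diff(t)
    if dt.max() - dt.min() > 1e-6 * dt.mean():
        return x  # non-uniform grid: leave as measured
    return savgol_filter(x, window, polyorder=min(3, window - 1), axis=0)


def speed_profile(t: np.ndarray, q: np.ndarray, smooth_window: int = 0) -> np.ndarray:
    """Tangential speed |dq/dt| by central differences on the time grid."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if q.shape[0] == 1:
        q = q.T
    v = np.gradient(q, t, axis=0)
    speed = np.linalg.norm(v, axis=1)
    # smoothing can undershoot zero near rest phases; speed is non-negative
    return np.clip(_smooth(speed, t, smooth_window), 0.0, None)


def _first_speed_peak(speed: np.ndarray) -> int:
    for i in range(1, len(speed) - 1):
        if speed[i] > speed[i - 1] and speed[i] >= speed[i + 1]:
            return i
    return int(np.argmax(speed))


def reach_macro_metrics(
    t: np.ndarray,
    q: np.ndarray,
    target,
    target_radius: float,
    opts: MetricOptions | None = None,
) -> MacroMetrics:
    """Macro metrics of one point-to-point attempt toward ``target``.

    Raises :class:`DegenerateSegmentError` for attempts with fewer than 5
    samples or no net displacement; callers exclude those from session
    means.
    """
    opts = opts or MetricOptions()
    t = np.asarray(t, dtype=float)
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if q.shape[0] == 1:
        q = q.T
    target = np.atleast_1d(np.asarray(target, dtype=float))
    n = len(t)
    if n < 5:
        raise DegenerateSegmentError(f"segment has {n} samples, need >= 5")
    disp = q[-1] - q[0]
    if np.linalg.norm(disp) < 1e-12:
        raise DegenerateSegmentError("zero-displacement segment")

    v = np.gradient(q, t, axis=0)
    speed = _smooth(np.linalg.norm(v, axis=1), t, opts.smooth_window)
    duration = float(t[-1] - t[0])
    path_length = float(np.trapezoid(speed, t))
    mean_speed = path_length / duration
    peak_speed = float(speed.max())
    if peak_speed <= 0:
        raise DegenerateSegmentError("segment never moves")
    speed_shape = mean_speed / peak_speed

    # aim: unsigned angle between the velocity at the first local speed
    # maximum and the straight line from the start to the target
    i_peak = _first_speed_peak(speed)
    line = target - q[0]
    aim = _unsigned_angle(v[i_peak], line)

    deviation = _chord_deviation(q, q[0], target, opts.deviation)
    dwell_time = _terminal_dwell(
        t, q, speed, target, target_radius, opts.speed_threshold_frac * peak_speed
    )

    jerk = np.gradient(np.gradient(v, t, axis=0), t, axis=0)
    jerk_sq = float(np.trapezoid(np.sum(jerk**2, axis=1), t))
    jerk_discrete = jerk_sq * duration**5 / path_length**2
    jerk_rhythmic = jerk_sq * duration / mean_speed**2

    return MacroMetrics(
        aim=aim,
        duration=duration,
        deviation=deviation,
        dwell_time=dwell_time,
        mean_speed=mean_speed,
        peak_speed=peak_speed,
        speed_shape=speed_shape,
        jerk_discrete=jerk_discrete,
        jerk_rhythmic=jerk_rhythmic,
    )


def _unsigned_angle(u: np.ndarray, w: np.ndarray) -> float:
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < 1e-15 or nw < 1e-15:
        return 0.0
    c = float(np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0))
    return math.acos(c)


def signed_aim(v_peak: np.ndarray, line: np.ndarray) -> float:
    """Signed aim for planar movements (positive = counter-clockwise of the
    target line); falls back to the unsigned angle in 1-D."""
    ang = _unsigned_angle(v_peak, line)
    if len(np.atleast_1d(v_peak)) == 2:
        cross = line[0] * v_peak[1] - line[1] * v_peak[0]
        return math.copysign(ang, cross) if cross != 0 else ang
    return ang


def _chord_deviation(q, start, target, mode: str) -> float:
    d = np.atleast_1d(target - start)
    if q.shape[1] == 1:
        return 0.0  # no perpendicular direction in 1-D
    dn = np.linalg.norm(d)
    if dn < 1e-15:
        return 0.0
    u = d / dn
    rel = q - start
    along = rel @ u
    perp = rel - np.outer(along, u)
    dist = np.linalg.norm(perp, axis=1)
    return float(np.max(dist)) if mode == "max" else float(np.sqrt(np.mean(dist**2)))


def _terminal_dwell(t, q, speed, target, target_radius, thr) -> float:
    inside = (np.linalg.norm(q - target[None, :], axis=1) <= target_radius) & (
        speed <= thr
    )
    if not inside[-1]:
        return 0.0
    k = len(inside) - 1
    while k > 0 and inside[k - 1]:
        k -= 1
    return float(t[-1] - t[k])


# ---------------------------------------------------------------------------
# circle drawing


def fit_ellipse(points: np.ndarray) -> tuple[float, float, float]:
    """Least-squares ellipse fit; returns (major, minor, orientation).

    ``major``/``minor`` are the semi-axis lengths; ``orientation`` is the
    major-axis angle in (-pi/2, pi/2].  Requires >= 6 non-collinear points.
    """
    from skimage.measure import EllipseModel

    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 6:
        raise ValueError("need >= 6 planar points")
    # collinearity check: rank of centered points
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("points are collinear; no ellipse is defined")
    # centre and scale first: the direct conic solve is ill-conditioned for
    # far-from-origin data
    centroid = points.mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum((points - centroid) ** 2, axis=1))))
    model = EllipseModel.from_estimate((points - centroid) / scale)
    if not model:
        raise ValueError("ellipse fit failed (degenerate point set)")
    a, b = model.axis_lengths
    theta = float(model.theta)
    major, minor = float(a) * scale, float(b) * scale
    if minor > major:
        major, minor = minor, major
        theta += math.pi / 2.0
    theta = (theta + math.pi / 2.0) % math.pi - math.pi / 2.0
    if theta <= -math.pi / 2.0 + 1e-15:
        theta += math.pi
    return major, minor, theta


def forward_kinematics_2link(
    theta_s: np.ndarray, theta_e: np.ndarray, geometry: ArmGeometry
) -> np.ndarray:
    """Endpoint position(s) for shoulder angle(s) and signed elbow angle(s)."""
    l1, l2 = geometry.upper_arm_m, geometry.forearm_m
    sx, sy = geometry.shoulder_position
    theta_s = np.asarray(theta_s, dtype=float)
    theta_e = np.asarray(theta_e, dtype=float)
    ex = sx + l1 * np.cos(theta_s) + l2 * np.cos(theta_s + theta_e)
    ey = sy + l1 * np.sin(theta_s) + l2 * np.sin(theta_s + theta_e)
    return np.stack([ex, ey], axis=-1)


def inverse_kinematics_2link(xy, geometry: ArmGeometry):
    """Joint angles (theta_shoulder, theta_elbow) of planar endpoint(s).

    ``theta_elbow`` is the signed elbow rotation: 0 at full extension,
    magnitude pi when fully folded; the elbow-down (right-arm) branch is
    chosen consistently.  Raises for unreachable points, naming the
    violating distance.
    """
    l1, l2 = geometry.upper_arm_m, geometry.forearm_m
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    rel = xy - np.asarray(geometry.shoulder_position)
    r = np.linalg.norm(rel, axis=1)
    r_min, r_max = abs(l1 - l2), l1 + l2
    tol = 1e-9
    bad = (r > r_max + tol) | (r < r_min - tol)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"point {tuple(xy[i])} at distance {r[i]:.6f} m from the shoulder "
            f"is outside the reachable annulus [{r_min:.6f}, {r_max:.6f}] m"
        )
    r = np.clip(r, r_min, r_max)
    cos_elbow = (r**2 - l1**2 - l2**2) / (2.0 * l1 * l2)
    cos_elbow = np.clip(cos_elbow, -1.0, 1.0)
    # elbow-down branch: elbow bends clockwise (negative) for the right arm
    theta_e = -np.arccos(cos_elbow)
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    cos_alpha = np.clip((l1**2 + r**2 - l2**2) / (2.0 * l1 * r), -1.0, 1.0)
    theta_s = phi + np.arccos(cos_alpha)
    if theta_s.shape == (1,):
        return float(theta_s[0]), float(theta_e[0])
    return theta_s, theta_e


class UndefinedMetricError(ValueError):
    """Metric undefined on this input (e.g. zero-variance joint angle)."""


def joint_independence(path_xy: np.ndarray, geometry: ArmGeometry) -> float:
    """Pearson correlation between the shoulder and elbow joint-angle time
    series along a (circle-drawing) path, angles from inverse kinematics."""
    theta_s, theta_e = inverse_kinematics_2link(path_xy, geometry)
    theta_s = np.atleast_1d(theta_s)
    theta_e = np.atleast_1d(theta_e)
    if np.std(theta_s) < 1e-12 or np.std(theta_e) < 1e-12:
        raise UndefinedMetricError("constant joint-angle series; correlation undefined")
    return float(np.corrcoef(theta_s, theta_e)[0, 1])


# ---------------------------------------------------------------------------
# resistance / stabilization / strength


def resistance_metrics(
    segments: Sequence[tuple], has_force: bool = True
) -> tuple[float, float]:
    """(max_displacement, overall_aim) over resistance-task attempts.

    Each segment is ``(t, q, target)``.  ``max_displacement`` is the largest
    progression from the start toward the target over any attempt;
    ``overall_aim`` is the circular mean of the per-attempt signed aims.
    """
    if not has_force:
        warnings.warn(
            "resistance recording has no force channel; metrics computed "
            "from kinematics only",
            stacklevel=2,
        )
    if not segments:
        raise ValueError("no resistance segments")
    max_disp = 0.0
    aims = []
    for t, q, target in segments:
        t = np.asarray(t, dtype=float)
        q = np.atleast_2d(np.asarray(q, dtype=float))
        if q.shape[0] == 1:
            q = q.T
        target = np.atleast_1d(np.asarray(target, dtype=float))
        d = target - q[0]
        dn = np.linalg.norm(d)
        if dn < 1e-15:
            continue
        u = d / dn
        along = (q - q[0]) @ u
        max_disp = max(max_disp, float(along.max()))
        v = np.gradient(q, t, axis=0)
        speed = np.linalg.norm(v, axis=1)
        aims.append(signed_aim(v[_first_speed_peak(speed)], d))
    overall_aim = math.atan2(
        float(np.mean(np.sin(aims))), float(np.mean(np.cos(aims)))
    )
    return max_disp, overall_aim


def stabilization_metrics(
    t: np.ndarray, q: np.ndarray, hold_point
) -> tuple[float, float]:
    """(scatter, offset) of an isometric hold.

    ``offset`` is the norm of the mean displacement from the commanded hold
    point; ``scatter`` is the RMS excursion of the position about its own
    mean (for isotropic planar noise of per-axis sd sigma this converges to
    sigma * sqrt(2)).
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if q.shape[0] == 1:
        q = q.T
    if q.shape[0] < 10:
        raise ValueError(f"need >= 10 samples for stabilization metrics, got {q.shape[0]}")
    hold_point = np.atleast_1d(np.asarray(hold_point, dtype=float))
    mean = q.mean(axis=0)
    offset = float(np.linalg.norm(mean - hold_point))
    scatter = float(np.sqrt(np.mean(np.sum((q - mean) ** 2, axis=1))))
    return scatter, offset


DIRECTIONS = ("F", "E", "AB", "AD")


def shoulder_strength(trials: Sequence[tuple]) -> dict:
    """Per-direction mean peak force and their grand mean (deltaz).

    ``trials`` is a sequence of ``(direction, peak_force_N)`` with direction
    in F/E/AB/AD (1-5 trials each).  A direction with no trials is reported
    missing and excluded from deltaz with a warning.
    """
    by_dir: dict[str, list[float]] = {d: [] for d in DIRECTIONS}
    for direction, peak in trials:
        if direction not in by_dir:
            raise ValueError(f"unknown strength direction {direction!r}")
        by_dir[direction].append(float(peak))
    means: dict[str, Optional[float]] = {}
    for d in DIRECTIONS:
        means[d] = float(np.mean(by_dir[d])) if by_dir[d] else None
    available = [m for m in means.values() if m is not None]
    if len(available) < len(DIRECTIONS):
        missing = [d for d, m in means.items() if m is None]
        warnings.warn(
            f"no strength trials for direction(s) {missing}; deltaz computed "
            "over available directions",
            stacklevel=2,
        )
    if not available:
        raise ValueError("no strength trials at all")
    means["deltaz"] = float(np.mean(available))
    return means
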