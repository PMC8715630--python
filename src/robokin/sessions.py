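"""Session-level feature assembly: from task recordings to the analysis
dataset.

Every metric's session value is the arithmetic mean of its per-segment
values over the session's non-degenerate segments (degenerate segments are
flagged and excluded).  Metric names follow the registry in
``docs/metrics.md``; wrist/forearm variants carry a ``wrist_``/``forearm_``
prefix so both devices can coexist in one row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import metrics as mk
from .submovements import DecomposeOptions, decompose, micrometrics
from .types import (
    ClinicalScores,
    DegenerateSegmentError,
    SessionFeatureRow,
    TaskGeometry,
    TaskRecording,
)

__all__ = ["session_features", "SessionOptions", "METRIC_REGISTRY"]

_MACRO = (
    "aim",
    "duration",
    "deviation",
    "dwell_time",
    "mean_speed",
    "peak_speed",
    "speed_shape",
    "jerk_discrete",
    "jerk_rhythmic",
)
_MICRO = ("sub_number", "sub_duration", "sub_overlap", "sub_peak", "sub_interpeak")

#: (name, unit, device, task) of every implemented metric
METRIC_REGISTRY: list[tuple] = (
    [(m, "rad|s|m|-", "shoulder_elbow", "reach8") for m in _MACRO + _MICRO]
    + [
        ("circle_major", "m", "shoulder_elbow", "circle_draw"),
        ("circle_minor", "m", "shoulder_elbow", "circle_draw"),
        ("circle_axis_ratio", "-", "shoulder_elbow", "circle_draw"),
        ("circle_orientation", "rad", "shoulder_elbow", "circle_draw"),
        ("circle_joint_independence", "-", "shoulder_elbow", "circle_draw"),
        ("horizontal_axes", "m", "shoulder_elbow", "circle_draw"),
        ("max_displacement", "m", "shoulder_elbow", "resistance"),
        ("overall_aim", "rad", "shoulder_elbow", "resistance"),
        ("scatter", "m", "shoulder_elbow", "isometric_hold"),
        ("offset", "m", "shoulder_elbow", "isometric_hold"),
        ("deltaz", "N", "shoulder_elbow", "kinetic_strength"),
        ("shoulder_f", "N", "shoulder_elbow", "kinetic_strength"),
        ("shoulder_e", "N", "shoulder_elbow", "kinetic_strength"),
        ("shoulder_ab", "N", "shoulder_elbow", "kinetic_strength"),
        ("shoulder_ad", "N", "shoulder_elbow", "kinetic_strength"),
    ]
    + [(f"wrist_{m}", "rad|s|-", "wrist_forearm", "wrist_point8") for m in _MACRO + _MICRO]
    + [(f"forearm_{m}", "rad|s|-", "wrist_forearm", "forearm_ps") for m in _MACRO + _MICRO]
    + [
        ("wrist_max_displacement", "rad", "wrist_forearm", "resistance"),
        ("wrist_overall_aim", "rad", "wrist_forearm", "resistance"),
        ("wrist_scatter", "rad", "wrist_forearm", "isometric_hold"),
        ("wrist_offset", "rad", "wrist_forearm", "isometric_hold"),
    ]
)

#: features derived from force-loaded tasks (resistance, isometric hold,
#: force transducer) — the "kinematic force metrics" family
FORCE_DERIVED = (
    "max_displacement",
    "overall_aim",
    "scatter",
    "offset",
    "wrist_max_displacement",
    "wrist_overall_aim",
    "wrist_scatter",
    "wrist_offset",
)
KINETIC = ("deltaz", "shoulder_f", "shoulder_e", "shoulder_ab", "shoulder_ad")


@dataclass(frozen=True)
class SessionOptions:
    metric_opts: mk.MetricOptions = mk.MetricOptions()
    arm: mk.ArmGeometry = mk.ArmGeometry()
    micrometrics: bool = True
    decompose_opts: DecomposeOptions = DecomposeOptions()
    reach_geometry: TaskGeometry = None  # defaults set in __post_init__

    def __post_init__(self):
        if self.reach_geometry is None:
            object.__setattr__(self, "reach_geometry", TaskGeometry.reach())


def _prefix(device: str, task: str) -> str:
    if device != "wrist_forearm":
        return ""
    return "forearm_" if task == "forearm_ps" else "wrist_"


def _target_lookup(rec: TaskRecording, geometry: TaskGeometry) -> dict:
    return {str(i): np.atleast_1d(np.asarray(t, dtype=float)) for i, t in enumerate(geometry.targets)}


def _mean(values: list) -> float:
    values = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(values)) if values else np.nan


def _pointing_features(rec: TaskRecording, geometry: TaskGeometry, opts: SessionOptions) -> dict:
    targets = _target_lookup(rec, geometry)
    per_seg: dict[str, list] = {m: [] for m in _MACRO + _MICRO}
    n_flagged = 0
    for seg in rec.segments:
        t, q, _ = rec.segment_arrays(seg)
        target = targets.get(seg.target_id)
        if target is None:
            target = q[-1]
        try:
            macro = mk.reach_macro_metrics(t, q, target, geometry.target_radius, opts.metric_opts)
        except DegenerateSegmentError:
            n_flagged += 1
            continue
        for m in _MACRO:
            per_seg[m].append(getattr(macro, m))
        if opts.micrometrics:
            speed = mk.speed_profile(t, q, opts.metric_opts.smooth_window)
            dec = decompose(speed, t, opts.decompose_opts)
            micro = micrometrics(dec)
            for m, v in micro.as_dict().items():
                per_seg[m].append(v)
    if n_flagged:
        warnings.warn(
            f"{rec.patient_id}/{rec.session_label} {rec.task}: "
            f"{n_flagged} degenerate segment(s) excluded",
            stacklevel=2,
        )
    prefix = _prefix(rec.device, rec.task)
    keys = _MACRO + (_MICRO if opts.micrometrics else ())
    return {prefix + m: _mean(per_seg[m]) for m in keys}


def _circle_features(rec: TaskRecording, opts: SessionOptions) -> dict:
    majors, minors, ratios, orients, independences = [], [], [], [], []
    horiz = []
    for seg in rec.segments:
        _, q, _ = rec.segment_arrays(seg)
        try:
            major, minor, orient = mk.fit_ellipse(q)
        except ValueError:
            continue
        majors.append(major)
        minors.append(minor)
        ratios.append(minor / major)
        orients.append(orient)
        # horizontal axis extent of this drawing condition
        horiz.append(q[:, 0].max() - q[:, 0].min())
        try:
            independences.append(mk.joint_independence(q, opts.arm))
        except (ValueError, mk.UndefinedMetricError):
            pass
    return {
        "circle_major": _mean(majors),
        "circle_minor": _mean(minors),
        "circle_axis_ratio": _mean(ratios),
        "circle_orientation": _mean(orients),
        "circle_joint_independence": _mean(independences),
        "horizontal_axes": _mean(horiz),
    }


def _resistance_features(rec: TaskRecording, geometry: TaskGeometry) -> dict:
    targets = _target_lookup(rec, geometry)
    segs = []
    for seg in rec.segments:
        t, q, _ = rec.segment_arrays(seg)
        target = targets.get(seg.target_id, q[-1])
        segs.append((t, q, target))
    max_disp, overall_aim = mk.resistance_metrics(segs, has_force=rec.f is not None)
    prefix = "wrist_" if rec.device == "wrist_forearm" else ""
    return {prefix + "max_displacement": max_disp, prefix + "overall_aim": overall_aim}


def _isometric_features(rec: TaskRecording) -> dict:
    hold = np.zeros(rec.q.shape[1])
    scatter, offset = mk.stabilization_metrics(rec.t, rec.q, hold)
    prefix = "wrist_" if rec.device == "wrist_forearm" else ""
    return {prefix + "scatter": scatter, prefix + "offset": offset}


def _strength_features(rec: TaskRecording) -> dict:
    trials = []
    for seg in rec.segments:
        _, _, f = rec.segment_arrays(seg)
        if f is None:
            continue
        trials.append((seg.target_id, float(np.linalg.norm(f, axis=1).max())))
    means = mk.shoulder_strength(trials)
    return {
        "deltaz": means["deltaz"],
        "shoulder_f": means["F"],
        "shoulder_e": means["E"],
        "shoulder_ab": means["AB"],
        "shoulder_ad": means["AD"],
    }


def session_features(
    recordings: Sequence[TaskRecording],
    scores: Optional[ClinicalScores] = None,
    opts: SessionOptions | None = None,
) -> SessionFeatureRow:
    """Mean-aggregated metric vector of one (patient, session).

    ``recordings`` must all belong to the same patient and session; tasks
    may span both devices.
    """
    opts = opts or SessionOptions()
    if not recordings:
        raise ValueError("no recordings for this session")
    pids = {r.patient_id for r in recordings}
    labels = {r.session_label for r in recordings}
    if len(pids) != 1 or len(labels) != 1:
        raise ValueError(f"recordings span multiple sessions: {pids} x {labels}")
    features: dict[str, float] = {}
    for rec in recordings:
        if rec.task in ("reach8", "wrist_point8", "forearm_ps"):
            geo = {
                "reach8": opts.reach_geometry,
                "wrist_point8": TaskGeometry.wrist(),
                "forearm_ps": TaskGeometry.forearm(),
            }[rec.task]
            features.update(_pointing_features(rec, geo, opts))
        elif rec.task == "circle_draw":
            features.update(_circle_features(rec, opts))
        elif rec.task == "resistance":
            geo = opts.reach_geometry if rec.device == "shoulder_elbow" else TaskGeometry.wrist()
            features.update(_resistance_features(rec, geo))
        elif rec.task == "isometric_hold":
            features.update(_isometric_features(rec))
        elif rec.task == "kinetic_strength":
            features.update(_strength_features(rec))
    features = {k: v for k, v in features.items() if np.isfinite(v)}
    return SessionFeatureRow(
        patient_id=next(iter(pids)),
        session_label=next(iter(labels)),
        features=features,
        scores=scores or ClinicalScores(),
    )
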