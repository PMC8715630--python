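"""Domain types shared by every stage of the pipeline.

The pipeline moves through three representations:

``TaskRecording``
    the raw time series of one robotic evaluation task, segmented into
    movement attempts;
``SessionFeatureRow``
    the mean-aggregated metric vector of one evaluation session together
    with the clinical scores recorded at that session;
``CVResult`` / ``CorrelationReport`` (see :mod:`robokin.models`,
:mod:`robokin.report`)
    fitted predictors and the cross-validated correlation grid.

Coordinates are SI internally: metres for the planar shoulder-elbow
endpoint, radians for wrist and forearm angles.  Degrees appear only at
file boundaries (:mod:`robokin.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

SESSION_LABELS = ("baseline1", "baseline2", "discharge", "followup")
DEVICES = ("shoulder_elbow", "wrist_forearm")
TASKS = (
    "reach8",
    "circle_draw",
    "resistance",
    "isometric_hold",
    "kinetic_strength",
    "wrist_point8",
    "forearm_ps",
)

#: tasks recorded on each robot
DEVICE_TASKS = {
    "shoulder_elbow": (
        "reach8",
        "circle_draw",
        "resistance",
        "isometric_hold",
        "kinetic_strength",
    ),
    "wrist_forearm": ("wrist_point8", "forearm_ps", "resistance", "isometric_hold"),
}

#: coordinate dimensionality of ``q`` per (device, task)
def q_dim(device: str, task: str) -> int:
    if device == "shoulder_elbow":
        return 1 if task == "kinetic_strength" else 2
    return 1 if task == "forearm_ps" else 2


SCALES = ("fma_ue", "wmft", "bi", "mrc")

#: scale maxima used for clipping/rescaling.  FMA-UE and BI maxima are the
#: instruments' fixed totals; the WMFT functional-ability sum and the summed
#: MRC grades vary by protocol and are configurable (see SimConfig).
SCALE_MAX = {"fma_ue": 66.0, "wmft": 75.0, "bi": 100.0, "mrc": 80.0}
#: granularity each scale is recorded at
SCALE_STEP = {"fma_ue": 1.0, "wmft": 1.0, "bi": 5.0, "mrc": 0.5}


class RecordingError(ValueError):
    """A trajectory file or in-memory recording violates the format contract."""


class DegenerateSegmentError(ValueError):
    """A movement segment cannot support the requested metric (flagged,
    excluded from session means)."""


class Segment(NamedTuple):
    """One movement attempt: half-open sample range [start, end) and the
    identifier of the cued target."""

    start: int
    end: int
    target_id: str


@dataclass
class TaskRecording:
    """Time series of one evaluation task.

    ``t`` is seconds, strictly increasing.  ``q`` is (n, d) with d fixed by
    (device, task); ``f`` is an optional (n, df) force channel in newtons.
    ``segments`` are non-overlapping, ordered movement attempts.
    """

    patient_id: str
    session_label: str
    device: str
    task: str
    t: np.ndarray
    q: np.ndarray
    f: Optional[np.ndarray] = None
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim == 1:
            self.q = self.q[:, None]
        if self.f is not None:
            self.f = np.asarray(self.f, dtype=float)
            if self.f.ndim == 1:
                self.f = self.f[:, None]

    def validate(self) -> "TaskRecording":
        if self.session_label not in SESSION_LABELS:
            raise RecordingError(f"unknown session label {self.session_label!r}")
        if self.device not in DEVICES:
            raise RecordingError(f"unknown device {self.device!r}")
        if self.task not in TASKS:
            raise RecordingError(f"unknown task label {self.task!r}")
        if self.task not in DEVICE_TASKS[self.device]:
            raise RecordingError(
                f"task {self.task!r} is not recorded on device {self.device!r}"
            )
        n = len(self.t)
        if self.q.shape[0] != n:
            raise RecordingError("t and q lengths differ")
        if self.f is not None and self.f.shape[0] != n:
            raise RecordingError("t and f lengths differ")
        expected = q_dim(self.device, self.task)
        if self.q.shape[1] != expected:
            raise RecordingError(
                f"q must have {expected} coordinate(s) for "
                f"({self.device}, {self.task}), got {self.q.shape[1]}"
            )
        dt = np.diff(self.t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            # report the file row of the offending sample, counting the CSV
            # column-header line as row 1
            raise RecordingError(
                f"time must be strictly increasing; violated at row {bad[0] + 3}"
            )
        prev_end = 0
        for seg in self.segments:
            if not (0 <= seg.start < seg.end <= n):
                raise RecordingError(f"segment {seg} out of bounds (n={n})")
            if seg.start < prev_end:
                raise RecordingError(f"segments overlap or are unordered at {seg}")
            prev_end = seg.end
        return self

    def segment_arrays(self, seg: Segment):
        """(t, q, f) views of one movement attempt."""
        sl = slice(seg.start, seg.end)
        return self.t[sl], self.q[sl], None if self.f is None else self.f[sl]


@dataclass(frozen=True)
class TaskGeometry:
    """Target layout of the pointing-style evaluation tasks.

    Reach targets sit equally spaced on a circle of radius ``reach_radius_m``
    around ``center``; wrist targets sit on an ellipse whose full major axis
    is ``wrist_major_deg`` (flexion/extension) and minor axis
    ``wrist_minor_deg`` (radial/ulnar deviation); forearm targets sit at
    ±``forearm_span_deg``/2 of pronation/supination.
    """

    targets: tuple
    center: tuple
    reach_radius_m: float = 0.14
    wrist_major_deg: float = 60.0
    wrist_minor_deg: float = 30.0
    forearm_span_deg: float = 60.0
    target_radius: float = 0.01

    @staticmethod
    def reach(
        n_targets: int = 8,
        reach_radius_m: float = 0.14,
        center=(0.0, 0.0),
        target_radius: float = 0.01,
    ) -> "TaskGeometry":
        ang = 2 * math.pi * np.arange(n_targets) / n_targets
        targets = tuple(
            (center[0] + reach_radius_m * math.cos(a), center[1] + reach_radius_m * math.sin(a))
            for a in ang
        )
        return TaskGeometry(
            targets=targets,
            center=tuple(center),
            reach_radius_m=reach_radius_m,
            target_radius=target_radius,
        )

    @staticmethod
    def wrist(
        n_targets: int = 8,
        major_deg: float = 60.0,
        minor_deg: float = 30.0,
        target_radius_rad: float = 0.035,
    ) -> "TaskGeometry":
        a = math.radians(major_deg) / 2.0
        b = math.radians(minor_deg) / 2.0
        ang = 2 * math.pi * np.arange(n_targets) / n_targets
        targets = tuple((a * math.cos(p), b * math.sin(p)) for p in ang)
        return TaskGeometry(
            targets=targets,
            center=(0.0, 0.0),
            wrist_major_deg=major_deg,
            wrist_minor_deg=minor_deg,
            target_radius=target_radius_rad,
        )

    @staticmethod
    def forearm(span_deg: float = 60.0, target_radius_rad: float = 0.035) -> "TaskGeometry":
        half = math.radians(span_deg) / 2.0
        return TaskGeometry(
            targets=((half,), (-half,)),
            center=(0.0,),
            forearm_span_deg=span_deg,
            target_radius=target_radius_rad,
        )

    def validate(self) -> "TaskGeometry":
        if len(self.targets) >= 2 and len(self.targets[0]) == 2:
            r = [math.hypot(t[0] - self.center[0], t[1] - self.center[1]) for t in self.targets]
            if self.target_radius >= max(r):
                raise ValueError(
                    f"target tolerance radius {self.target_radius} must be smaller "
                    f"than the reach radius {max(r)}"
                )
        return self


@dataclass
class ClinicalScores:
    """Clinical outcome scores of one evaluation session.

    ``None`` marks a score that was not administered.  FMA-UE is the 33-item
    upper-extremity Fugl-Meyer total (0-66); BI the Barthel Index (0-100);
    WMFT and MRC are non-negative sums whose maximum depends on the scoring
    variant and is therefore not hard-clipped here.
    """

    fma_ue: Optional[float] = None
    wmft: Optional[float] = None
    bi: Optional[float] = None
    mrc: Optional[float] = None

    def validate(self) -> "ClinicalScores":
        if self.fma_ue is not None and not (0 <= self.fma_ue <= 66):
            raise ValueError(f"fma_ue must be in [0, 66], got {self.fma_ue}")
        if self.bi is not None and not (0 <= self.bi <= 100):
            raise ValueError(f"bi must be in [0, 100], got {self.bi}")
        if self.wmft is not None and self.wmft < 0:
            raise ValueError(f"wmft must be >= 0, got {self.wmft}")
        if self.mrc is not None and self.mrc < 0:
            raise ValueError(f"mrc must be >= 0, got {self.mrc}")
        return self

    def as_dict(self) -> dict:
        return {s: getattr(self, s) for s in SCALES}


@dataclass
class SessionFeatureRow:
    """One analysis-dataset row: (patient, session) identity, the
    mean-aggregated metric values, and the session's clinical scores."""

    patient_id: str
    session_label: str
    features: dict
    scores: ClinicalScores
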