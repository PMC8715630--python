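"""Synthetic cohort generator.

Clinical datasets of this kind are usually access-gated, so every
downstream stage is exercised against simulated cohorts with known ground
truth.  The generator draws one latent impairment score z in [0, 1] per
patient (0 = unimpaired, 1 = maximally impaired), lets it drift slightly
across the four evaluation sessions, and derives from it both

* the clinical scores — monotone (linear or sigmoid) links from z to each
  bounded ordinal scale, plus observation noise, clipping and rounding to
  the scale's granularity; and
* the trajectory quality — movements are assembled from support-bounded
  lognormal submovements whose count grows with z (1 + Poisson(lambda z)),
  whose blending decreases with z, with path-curvature noise growing with
  z; isometric wander, resistance displacement deficits and shoulder
  strength scale with z likewise.

Defaults mirror the emulated study: 82 patients, up to 4 evaluation
sessions (two baselines, discharge, six-month follow-up), 8 reach targets
on a 14 cm circle, a 60x30 degree wrist target ellipse, +/-30 degree
forearm rotations, 20 circle-drawing repetitions, and 5 strength trials in
each of 4 directions.  Trajectories are phenomenological, not forward
dynamics.  All randomness flows from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .submovements import Submovement, synth_speed_profile
from .types import (
    SCALE_MAX,
    SCALE_STEP,
    SCALES,
    SESSION_LABELS,
    ClinicalScores,
    Segment,
    SessionFeatureRow,
    TaskGeometry,
    TaskRecording,
)

__all__ = [
    "SimConfig",
    "LinkSpec",
    "GroundTruth",
    "simulate_cohort",
    "latent_to_clinical",
    "simulate_feature_cohort",
]


@dataclass(frozen=True)
class LinkSpec:
    """Monotone link from latent impairment z to one clinical scale.

    ``linear``: score = max * (offset - slope * z) clipped to the scale;
    ``sigmoid``: score = max * logistic(slope * (offset - z)).
    Either way the noise-free score is non-increasing in z.
    """

    kind: str = "linear"  # or "sigmoid"
    slope: float = 1.0
    offset: float = 1.0

    def noise_free(self, z: float, scale_max: float) -> float:
        if self.kind == "linear":
            return scale_max * (self.offset - self.slope * z)
        if self.kind == "sigmoid":
            return scale_max / (1.0 + math.exp(-self.slope * (self.offset - z)))
        raise ValueError(f"unknown link kind {self.kind!r}")


def _default_links() -> dict:
    return {
        "fma_ue": LinkSpec("linear", 1.0, 1.0),
        "wmft": LinkSpec("linear", 1.0, 1.0),
        "bi": LinkSpec("sigmoid", 6.0, 0.55),
        "mrc": LinkSpec("linear", 1.0, 1.0),
    }


def _default_noise() -> dict:
    # observation noise, in score units
    return {"fma_ue": 3.0, "wmft": 4.0, "bi": 6.0, "mrc": 4.0}


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic cohort."""

    n_patients: int = 82
    sessions_per_patient: int = 4
    seed: int = 0
    latent_mean: float = 0.6  # population mean impairment
    latent_sd: float = 0.22
    session_drift_sd: float = 0.02  # session-to-session wobble of z
    recovery_per_session: float = 0.03  # mean improvement per later session
    links: dict = field(default_factory=_default_links)
    noise_sd: dict = field(default_factory=_default_noise)
    scale_max: dict = field(default_factory=lambda: dict(SCALE_MAX))
    sample_rate_hz: float = 200.0
    n_reaches: int = 80
    n_circle_reps: int = 20  # 4 conditions x 5 repetitions
    n_strength_trials_per_dir: int = 5
    # kinematic effect sizes (monotone dependence on z)
    submovement_rate: float = 3.0  # lambda(z) = rate * z
    blend_gap_frac: float = 0.35  # onset gap fraction grows with z
    curvature_frac: float = 0.25  # perpendicular wobble, fraction of path
    base_strength_n: dict = field(
        default_factory=lambda: {"F": 60.0, "E": 55.0, "AB": 50.0, "AD": 45.0}
    )
    strength_noise_n: float = 2.0
    hold_wander_m: float = 0.004  # isometric wander sd at z = 1
    reach_geometry: TaskGeometry = field(default_factory=TaskGeometry.reach)
    wrist_geometry: TaskGeometry = field(default_factory=TaskGeometry.wrist)
    forearm_geometry: TaskGeometry = field(default_factory=TaskGeometry.forearm)

    def validate(self) -> "SimConfig":
        if self.n_patients < 8:
            raise ValueError("need >= 8 patients for patient-wise cross-validation")
        if not (1 <= self.sessions_per_patient <= 4):
            raise ValueError("sessions_per_patient must be in 1..4")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd must be >= 0")
        self.reach_geometry.validate()
        return self


@dataclass
class GroundTruth:
    """Generator-side truth, carried alongside the observable outputs and
    never fed to the pipeline."""

    z: dict  # (patient_id, session_label) -> latent impairment
    submovements: dict  # (patient_id, session_label, device, task, seg_idx) -> [Submovement]
    noise_free_scores: dict  # (patient_id, session_label) -> {scale: score}


def latent_to_clinical(
    z: float,
    scale: str,
    link: LinkSpec,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    scale_max: Optional[float] = None,
) -> float:
    """Observed clinical score for impairment ``z``: link, noise, clip to
    the scale bounds, round to the scale granularity."""
    if not (0.0 <= z <= 1.0):
        raise ValueError(f"z must be in [0, 1], got {z}")
    smax = SCALE_MAX[scale] if scale_max is None else scale_max
    score = link.noise_free(z, smax)
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        score += rng.normal(0.0, noise_sd)
    score = min(max(score, 0.0), smax)
    step = SCALE_STEP.get(scale, 1.0)
    return round(score / step) * step


def _latent_for_patient(cfg: SimConfig, rng: np.random.Generator, n_sessions: int):
    z0 = float(np.clip(rng.normal(cfg.latent_mean, cfg.latent_sd), 0.0, 1.0))
    zs = []
    for s in range(n_sessions):
        drift = -cfg.recovery_per_session * s + rng.normal(0.0, cfg.session_drift_sd)
        zs.append(float(np.clip(z0 + drift, 0.0, 1.0)))
    return zs


def _segment_submovements(
    rng: np.random.Generator, z: float, path_len: float, cfg: SimConfig
) -> list[Submovement]:
    """Submovement plan of one point-to-point attempt.

    One primary pulse always; corrective pulses follow a Poisson(lambda z)
    count with later onsets (less blending) and growing relative amplitude
    as z grows.
    """
    n_extra = int(rng.poisson(cfg.submovement_rate * z))
    n = 1 + n_extra
    frac_corr = 0.35 * z if n > 1 else 0.0
    amps = np.full(n, (path_len * frac_corr) / max(n - 1, 1))
    amps[0] = path_len * (1.0 - frac_corr)
    d_primary = 0.6 + 0.5 * z + rng.uniform(-0.05, 0.05)
    subs = [
        Submovement(
            t0=0.05,
            D=d_primary,
            A=float(amps[0]),
            mu=rng.uniform(-0.3, 0.0),
            sigma=rng.uniform(0.35, 0.5),
        )
    ]
    t_cursor = 0.05 + d_primary
    for i in range(1, n):
        gap = cfg.blend_gap_frac * (0.3 + 0.7 * z)
        d = 0.25 + 0.15 * rng.random()
        t0 = t_cursor - (1.0 - gap) * d  # overlap shrinks as z grows
        subs.append(
            Submovement(
                t0=float(max(t0, 0.0)),
                D=d,
                A=float(max(amps[i], 1e-4 * path_len)),
                mu=rng.uniform(-0.3, 0.0),
                sigma=rng.uniform(0.35, 0.5),
            )
        )
        t_cursor = max(t_cursor, t0 + d)
    return subs


def _point_to_point_recording(
    rng: np.random.Generator,
    z: float,
    cfg: SimConfig,
    targets: list,
    start_center,
    n_moves: int,
    patient_id: str,
    session_label: str,
    device: str,
    task: str,
    truth_subs: dict,
) -> TaskRecording:
    """Assemble a pointing-task recording: for each cued target, integrate a
    submovement speed plan along the start->target line, add a smooth
    perpendicular curvature error that grows with z, and join attempts with
    short rest dwells."""
    dt = 1.0 / cfg.sample_rate_hz
    dim = len(np.atleast_1d(np.asarray(targets[0], dtype=float)))
    t_all: list[np.ndarray] = []
    q_all: list[np.ndarray] = []
    segments: list[Segment] = []
    t_off = 0.0
    pos = np.asarray(start_center, dtype=float)
    for k in range(n_moves):
        tg = np.atleast_1d(np.asarray(targets[k % len(targets)], dtype=float))
        d = tg - pos
        path_len = float(np.linalg.norm(d))
        if path_len < 1e-9:
            continue
        u = d / path_len
        subs = _segment_submovements(rng, z, path_len, cfg)
        t_end = max(s.t0 + s.D for s in subs) + 0.1
        n_samp = max(int(round(t_end / dt)) + 1, 8)
        tt = np.arange(n_samp) * dt
        speed = synth_speed_profile(subs, tt)
        progress = np.concatenate(
            [[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(tt))]
        )
        # renormalize so the attempt lands on the target
        if progress[-1] > 0:
            progress *= path_len / progress[-1]
        qq = pos[None, :] + np.outer(progress, u)
        if dim == 2:
            perp = np.array([-u[1], u[0]])
            wobble = (
                cfg.curvature_frac
                * z
                * path_len
                * rng.uniform(0.3, 1.0)
                * rng.choice([-1.0, 1.0])
            )
            qq = qq + np.outer(wobble * np.sin(np.pi * progress / path_len), perp)
        start_idx = sum(len(a) for a in q_all)
        t_all.append(t_off + tt)
        q_all.append(qq)
        segments.append(Segment(start_idx, start_idx + n_samp, str(k % len(targets))))
        truth_subs[(patient_id, session_label, device, task, len(segments) - 1)] = subs
        # brief rest at the target before the next cue
        n_rest = int(round(0.15 / dt))
        if n_rest > 0:
            t_all.append(t_off + tt[-1] + dt * np.arange(1, n_rest + 1))
            q_all.append(np.tile(qq[-1], (n_rest, 1)))
        t_off = t_all[-1][-1] + dt
        pos = qq[-1]
    rec = TaskRecording(
        patient_id=patient_id,
        session_label=session_label,
        device=device,
        task=task,
        t=np.concatenate(t_all),
        q=np.vstack(q_all),
        segments=segments,
    )
    return rec.validate()


def _circle_recording(rng, z, cfg, patient_id, session_label) -> TaskRecording:
    """Circle drawing: 4 conditions (CW/CCW x 2 starts) x reps.  Impairment
    flattens the drawn ellipse and adds radial tremor."""
    dt = 1.0 / cfg.sample_rate_hz
    radius = cfg.reach_geometry.reach_radius_m
    ratio = 1.0 - 0.45 * z  # minor/major shrinks with impairment
    tilt = rng.uniform(-0.3, 0.3)
    t_all, q_all, segments = [], [], []
    t_off = 0.0
    conds = [(dirn, start) for dirn in (1, -1) for start in (0.0, math.pi)]
    reps = max(cfg.n_circle_reps // 4, 1)
    for ci, (dirn, start) in enumerate(conds):
        for rep in range(reps):
            period = 2.0 + 1.5 * z
            n_samp = int(round(period / dt))
            tt = np.arange(n_samp) * dt
            ang = start + dirn * 2.0 * math.pi * tt / period
            a = radius * (1.0 + 0.05 * rng.standard_normal())
            b = a * ratio * (1.0 + 0.05 * rng.standard_normal())
            x = a * np.cos(ang)
            y = b * np.sin(ang)
            ct, st = math.cos(tilt), math.sin(tilt)
            qq = np.stack([ct * x - st * y, st * x + ct * y], axis=1)
            qq += 0.002 * z * rng.standard_normal(qq.shape).cumsum(axis=0) * math.sqrt(dt)
            start_idx = sum(len(aq) for aq in q_all)
            t_all.append(t_off + tt)
            q_all.append(qq)
            segments.append(Segment(start_idx, start_idx + n_samp, f"cond{ci}"))
            t_off = t_all[-1][-1] + dt
    return TaskRecording(
        patient_id=patient_id,
        session_label=session_label,
        device="shoulder_elbow",
        task="circle_draw",
        t=np.concatenate(t_all),
        q=np.vstack(q_all),
        segments=segments,
    ).validate()


def _resistance_recording(rng, z, cfg, patient_id, session_label, device) -> TaskRecording:
    """Reaching against a ramping opposing force: displacement achieved
    falls with impairment, then the arm is pushed back."""
    dt = 1.0 / cfg.sample_rate_hz
    geo = cfg.reach_geometry if device == "shoulder_elbow" else cfg.wrist_geometry
    targets = [np.asarray(tg) for tg in geo.targets]
    t_all, q_all, f_all, segments = [], [], [], []
    t_off = 0.0
    for k, tg in enumerate(targets):
        frac = float(np.clip(1.0 - 0.6 * z + rng.normal(0, 0.05), 0.05, 1.0))
        n_samp = int(round(1.5 / dt))
        tt = np.arange(n_samp) * dt
        prog = frac * np.sin(np.pi * tt / tt[-1]) ** 2  # out and pushed back
        u = tg / np.linalg.norm(tg)
        qq = np.outer(prog, tg)
        force = np.outer(20.0 * tt / tt[-1], -u)  # ramping opposing force
        start_idx = sum(len(aq) for aq in q_all)
        t_all.append(t_off + tt)
        q_all.append(qq)
        f_all.append(force)
        segments.append(Segment(start_idx, start_idx + n_samp, str(k)))
        t_off = t_all[-1][-1] + dt
    return TaskRecording(
        patient_id=patient_id,
        session_label=session_label,
        device=device,
        task="resistance",
        t=np.concatenate(t_all),
        q=np.vstack(q_all),
        f=np.vstack(f_all),
        segments=segments,
    ).validate()


def _isometric_recording(rng, z, cfg, patient_id, session_label, device) -> TaskRecording:
    dt = 1.0 / cfg.sample_rate_hz
    n_samp = int(round(5.0 / dt))
    tt = np.arange(n_samp) * dt
    sd = cfg.hold_wander_m * (0.1 + 0.9 * z)
    bias = rng.normal(0.0, sd, size=2)
    qq = bias[None, :] + rng.normal(0.0, sd, size=(n_samp, 2))
    ff = rng.normal(0.0, 1.0, size=(n_samp, 2)) + np.array([5.0, 0.0])
    return TaskRecording(
        patient_id=patient_id,
        session_label=session_label,
        device=device,
        task="isometric_hold",
        t=tt,
        q=qq,
        f=ff,
        segments=[Segment(0, n_samp, "hold")],
    ).validate()


def _strength_recording(rng, z, cfg, patient_id, session_label) -> TaskRecording:
    """Kinetic shoulder evaluation: per-direction peak force shrinks
    linearly with impairment."""
    dt = 1.0 / cfg.sample_rate_hz
    t_all, q_all, f_all, segments = [], [], [], []
    t_off = 0.0
    directions = ("F", "E", "AB", "AD")
    for d in directions:
        base = cfg.base_strength_n[d]
        for _ in range(cfg.n_strength_trials_per_dir):
            peak = max(base * (1.0 - 0.85 * z) + rng.normal(0.0, cfg.strength_noise_n), 0.5)
            n_samp = int(round(2.0 / dt))
            tt = np.arange(n_samp) * dt
            ff = peak * np.sin(np.pi * tt / tt[-1]) ** 2
            start_idx = sum(len(a) for a in f_all)
            t_all.append(t_off + tt)
            q_all.append(np.zeros((n_samp, 1)))
            f_all.append(ff[:, None])
            segments.append(Segment(start_idx, start_idx + n_samp, d))
            t_off = t_all[-1][-1] + dt
    return TaskRecording(
        patient_id=patient_id,
        session_label=session_label,
        device="shoulder_elbow",
        task="kinetic_strength",
        t=np.concatenate(t_all),
        q=np.vstack(q_all),
        f=np.vstack(f_all),
        segments=segments,
    ).validate()


def simulate_cohort(cfg: SimConfig):
    """Generate a full synthetic cohort.

    Returns ``(recordings, score_rows, truth)`` where ``recordings`` holds
    every task of every (patient, session) on both devices, ``score_rows``
    is a list of :class:`SessionFeatureRow` with empty feature maps (scores
    only; features come from the metrics stage), and ``truth`` carries the
    latent impairments, generating submovements and noise-free scores.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    recordings: list[TaskRecording] = []
    score_rows: list[SessionFeatureRow] = []
    truth = GroundTruth(z={}, submovements={}, noise_free_scores={})
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:03d}"
        zs = _latent_for_patient(cfg, rng, cfg.sessions_per_patient)
        for s, z in enumerate(zs):
            label = SESSION_LABELS[s]
            truth.z[(pid, label)] = z
            noise_free = {
                sc: min(
                    max(cfg.links[sc].noise_free(z, cfg.scale_max[sc]), 0.0),
                    cfg.scale_max[sc],
                )
                for sc in SCALES
            }
            truth.noise_free_scores[(pid, label)] = noise_free
            observed = {
                sc: latent_to_clinical(
                    z,
                    sc,
                    cfg.links[sc],
                    cfg.noise_sd[sc],
                    rng,
                    scale_max=cfg.scale_max[sc],
                )
                for sc in SCALES
            }
            score_rows.append(
                SessionFeatureRow(pid, label, {}, ClinicalScores(**observed).validate())
            )
            recordings.append(
                _point_to_point_recording(
                    rng, z, cfg, list(cfg.reach_geometry.targets),
                    cfg.reach_geometry.center, cfg.n_reaches,
                    pid, label, "shoulder_elbow", "reach8", truth.submovements,
                )
            )
            recordings.append(_circle_recording(rng, z, cfg, pid, label))
            recordings.append(
                _resistance_recording(rng, z, cfg, pid, label, "shoulder_elbow")
            )
            recordings.append(
                _isometric_recording(rng, z, cfg, pid, label, "shoulder_elbow")
            )
            recordings.append(_strength_recording(rng, z, cfg, pid, label))
            recordings.append(
                _point_to_point_recording(
                    rng, z, cfg, list(cfg.wrist_geometry.targets), (0.0, 0.0),
                    cfg.n_reaches, pid, label, "wrist_forearm", "wrist_point8",
                    truth.submovements,
                )
            )
            recordings.append(
                _point_to_point_recording(
                    rng, z, cfg, [np.atleast_1d(t) for t in cfg.forearm_geometry.targets],
                    (0.0,), cfg.n_reaches, pid, label, "wrist_forearm", "forearm_ps",
                    truth.submovements,
                )
            )
            recordings.append(
                _resistance_recording(rng, z, cfg, pid, label, "wrist_forearm")
            )
            recordings.append(
                _isometric_recording(rng, z, cfg, pid, label, "wrist_forearm")
            )
    return recordings, score_rows, truth


def simulate_feature_cohort(
    n_patients: int,
    sessions_per_patient: int,
    population_r: float,
    seed: int,
    link: str = "linear",
    target: str = "wmft",
    sigmoid_gain: float = 12.0,
    noise_sd: float = 0.05,
):
    """Single-feature cohort with a known generating relationship.

    ``linear``: (x, y) bivariate normal with correlation ``population_r``
    per row (patients group rows for fold assignment).  ``sigmoid``:
    y = logistic(gain * (x - 0.5)) + Gaussian noise, a saturating link a
    2-sigmoid-node network can represent but a line cannot.  Returns a
    DataFrame with columns patient_id, session_label, x, <target>.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        for s in range(sessions_per_patient):
            if link == "linear":
                x = rng.standard_normal()
                y = population_r * x + math.sqrt(1.0 - population_r**2) * rng.standard_normal()
                x_val = 50.0 + 10.0 * x
                y_val = 40.0 + 10.0 * y
            elif link == "sigmoid":
                x = rng.uniform(0.0, 1.0)
                y = 1.0 / (1.0 + math.exp(-sigmoid_gain * (x - 0.5)))
                y += rng.normal(0.0, noise_sd)
                x_val = x
                y_val = 66.0 * min(max(y, 0.0), 1.0)
            else:
                raise ValueError(f"unknown link {link!r}")
            rows.append(
                {
                    "patient_id": pid,
                    "session_label": SESSION_LABELS[s % len(SESSION_LABELS)],
                    "x": x_val,
                    target: y_val,
                }
            )
    return pd.DataFrame(rows)
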