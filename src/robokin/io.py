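"""Readers and writers for the trajectory and feature-table formats.

Trajectory CSV dialect
----------------------
``#``-prefixed header lines carry ``key: value`` metadata (patient_id,
session_label, device, task, units), followed by a normal CSV with columns

    ``t,q1[,q2][,f1[,f2]],target_id,segment_id``

Angles are degrees in files and radians in memory; planar positions are
metres throughout.  ``segment_id`` is optional — when absent, movement
attempts are derived from target cues with a speed-threshold convention
(onset above 5% of the recording's peak speed after a cue, offset inside the
target radius below that threshold for >= 0.1 s).

Feature-table CSV
-----------------
``patient_id,session_label,<metric...>,fma_ue,wmft,bi,mrc`` with ``NA`` for
missing values.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    SCALES,
    ClinicalScores,
    RecordingError,
    Segment,
    SessionFeatureRow,
    TaskGeometry,
    TaskRecording,
    q_dim,
)

_ANGLE_TASKS = {"wrist_point8", "forearm_ps"}

#: fraction of peak speed separating "moving" from "still"
SPEED_THRESHOLD_FRAC = 0.05
#: minimum still time (s) that terminates a movement attempt
MIN_DWELL_S = 0.1


def _is_angle_recording(device: str, task: str) -> bool:
    return device == "wrist_forearm" and task in _ANGLE_TASKS


def read_recording(path, geometry: Optional[TaskGeometry] = None) -> TaskRecording:
    """Read one trajectory CSV into a validated :class:`TaskRecording`.

    ``geometry`` is required only when segments must be derived from target
    cues (no ``segment_id`` column).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    for key in ("patient_id", "session_label", "device", "task"):
        if key not in meta:
            raise RecordingError(f"{path}: missing '# {key}:' metadata line")
    try:
        df = pd.read_csv(_io.StringIO("".join(body_lines)))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RecordingError(f"{path}: malformed CSV body ({exc})") from exc
    if "t" not in df.columns:
        raise RecordingError(f"{path}: malformed header, no 't' column")
    qcols = [c for c in df.columns if c.startswith("q")]
    fcols = [c for c in df.columns if c.startswith("f") and c != "f"]
    if not qcols:
        raise RecordingError(f"{path}: malformed header, no coordinate columns")
    t = df["t"].to_numpy(dtype=float)
    q = df[qcols].to_numpy(dtype=float)
    f = df[fcols].to_numpy(dtype=float) if fcols else None
    if _is_angle_recording(meta["device"], meta["task"]) or meta.get("units") == "deg":
        q = np.deg2rad(q)

    target_ids = (
        df["target_id"].astype(str).to_numpy() if "target_id" in df.columns else None
    )
    if "segment_id" in df.columns:
        segments = _segments_from_column(
            df["segment_id"].to_numpy(), target_ids
        )
    elif target_ids is not None:
        if geometry is None:
            raise RecordingError(
                f"{path}: no segment_id column; a TaskGeometry is required to "
                "derive segments from target cues"
            )
        segments = derive_segments(t, q, target_ids, geometry)
    else:
        segments = []

    rec = TaskRecording(
        patient_id=meta["patient_id"],
        session_label=meta["session_label"],
        device=meta["device"],
        task=meta["task"],
        t=t,
        q=q,
        f=f,
        segments=segments,
    )
    try:
        return rec.validate()
    except RecordingError as exc:
        raise RecordingError(f"{path}: {exc}") from exc


def _segments_from_column(segment_ids: np.ndarray, target_ids) -> list[Segment]:
    segments = []
    ids = pd.Series(segment_ids)
    valid = ids.notna() & (ids.astype(str) != "") & (ids.astype(str) != "-1")
    i = 0
    n = len(ids)
    while i < n:
        if not valid.iloc[i]:
            i += 1
            continue
        j = i
        while j < n and valid.iloc[j] and ids.iloc[j] == ids.iloc[i]:
            j += 1
        tid = str(target_ids[i]) if target_ids is not None else str(ids.iloc[i])
        segments.append(Segment(i, j, tid))
        i = j
    return segments


def derive_segments(
    t: np.ndarray, q: np.ndarray, target_ids: np.ndarray, geometry: TaskGeometry
) -> list[Segment]:
    """Derive movement attempts from target cues.

    Each run of a constant ``target_id`` is one cue; within it the attempt
    starts at the first sample whose speed exceeds 5% of the recording's
    peak speed and ends when the endpoint has stayed inside the target
    tolerance radius below that threshold for at least ``MIN_DWELL_S``.
    """
    v = np.gradient(q, t, axis=0)
    speed = np.linalg.norm(v, axis=1)
    thr = SPEED_THRESHOLD_FRAC * speed.max() if speed.max() > 0 else 0.0
    targets = {str(i): np.asarray(tg, dtype=float) for i, tg in enumerate(geometry.targets)}
    segments = []
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and target_ids[j] == target_ids[i]:
            j += 1
        tid = str(target_ids[i])
        tg = targets.get(tid)
        block = slice(i, j)
        sp = speed[block]
        start_rel = np.argmax(sp > thr) if (sp > thr).any() else None
        if start_rel is not None:
            start = i + int(start_rel)
            end = j
            if tg is not None:
                inside = (
                    np.linalg.norm(q[block] - tg[None, :], axis=1)
                    <= geometry.target_radius
                ) & (sp <= thr)
                # earliest sample after which the hand stays quiet >= MIN_DWELL_S
                for k in range(len(sp) - 1, -1, -1):
                    if not inside[k]:
                        break
                else:
                    k = -1
                settle = i + k + 1
                if settle < j and t[j - 1] - t[settle] >= MIN_DWELL_S:
                    end = min(j, settle + 1 + int(np.searchsorted(t[settle:j], t[settle] + MIN_DWELL_S)))
            if end - start >= 2:
                segments.append(Segment(start, end, tid))
        i = j
    return segments


def write_recording(rec: TaskRecording, path) -> None:
    """Write a :class:`TaskRecording` in the documented CSV dialect
    (inverse of :func:`read_recording`)."""
    rec.validate()
    path = Path(path)
    angles = _is_angle_recording(rec.device, rec.task)
    q = np.rad2deg(rec.q) if angles else rec.q
    units = "deg" if angles else "m"
    qcols = [f"q{i + 1}" for i in range(q.shape[1])]
    data = {"t": rec.t}
    for i, c in enumerate(qcols):
        data[c] = q[:, i]
    if rec.f is not None:
        for i in range(rec.f.shape[1]):
            data[f"f{i + 1}"] = rec.f[:, i]
    n = len(rec.t)
    target = np.full(n, "", dtype=object)
    segid = np.full(n, "", dtype=object)
    for k, seg in enumerate(rec.segments):
        target[seg.start : seg.end] = seg.target_id
        segid[seg.start : seg.end] = str(k)
    data["target_id"] = target
    data["segment_id"] = segid
    df = pd.DataFrame(data)
    with open(path, "w", newline="") as fh:
        for key in ("patient_id", "session_label", "device", "task"):
            fh.write(f"# {key}: {getattr(rec, key)}\n")
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def write_feature_table(rows: Sequence[SessionFeatureRow], path) -> None:
    """Write the analysis dataset: one CSV row per (patient, session).

    Column order is deterministic: identity, metric names sorted
    alphabetically, then the four clinical scales.  Missing values are
    written as ``NA``.
    """
    seen = set()
    for row in rows:
        key = (row.patient_id, row.session_label)
        if key in seen:
            raise ValueError(f"duplicate (patient, session) pair {key}")
        seen.add(key)
    feature_names = sorted({name for row in rows for name in row.features})
    records = []
    for row in rows:
        rec = {"patient_id": row.patient_id, "session_label": row.session_label}
        for name in feature_names:
            rec[name] = row.features.get(name, np.nan)
        rec.update(row.scores.as_dict())
        records.append(rec)
    columns = ["patient_id", "session_label", *feature_names, *SCALES]
    df = pd.DataFrame(records, columns=columns)
    df.to_csv(path, index=False, na_rep="NA", float_format="%.12g")


def read_feature_table(path) -> list[SessionFeatureRow]:
    """Read a feature table written by :func:`write_feature_table` (or any
    conforming file) back into typed rows."""
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    required = ["patient_id", "session_label"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    metric_cols = [c for c in df.columns if c not in required and c not in SCALES]
    for col in metric_cols + [s for s in SCALES if s in df.columns]:
        bad = df[col].apply(
            lambda v: not (isinstance(v, (int, float, np.floating, np.integer)) or pd.isna(v))
        )
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, row {row + 2}"
            )
    rows = []
    for _, rec in df.iterrows():
        features = {
            c: (float(rec[c]) if not pd.isna(rec[c]) else math.nan) for c in metric_cols
        }
        # drop features that are genuinely absent for this row
        features = {k: v for k, v in features.items() if not math.isnan(v)}
        scores = ClinicalScores(
            **{
                s: (None if s not in df.columns or pd.isna(rec[s]) else float(rec[s]))
                for s in SCALES
            }
        )
        rows.append(
            SessionFeatureRow(
                patient_id=str(rec["patient_id"]),
                session_label=str(rec["session_label"]),
                features=features,
                scores=scores,
            )
        )
    return rows


def rows_to_frame(rows: Sequence[SessionFeatureRow]) -> pd.DataFrame:
    """Stack typed rows into the analysis DataFrame used by the modelling
    stages (identity + feature columns + scale columns)."""
    feature_names = sorted({name for row in rows for name in row.features})
    records = []
    for row in rows:
        rec = {"patient_id": row.patient_id, "session_label": row.session_label}
        for name in feature_names:
            rec[name] = row.features.get(name, np.nan)
        rec.update(row.scores.as_dict())
        records.append(rec)
    df = pd.DataFrame(records, columns=["patient_id", "session_label", *feature_names, *SCALES])
    for c in [*feature_names, *SCALES]:
        df[c] = pd.to_numeric(df[c])
    return df


def frame_to_rows(df: pd.DataFrame) -> list[SessionFeatureRow]:
    metric_cols = [
        c for c in df.columns if c not in ("patient_id", "session_label", *SCALES)
    ]
    rows = []
    for _, rec in df.iterrows():
        features = {c: float(rec[c]) for c in metric_cols if not pd.isna(rec[c])}
        scores = ClinicalScores(
            **{
                s: (None if s not in df.columns or pd.isna(rec[s]) else float(rec[s]))
                for s in SCALES
            }
        )
        rows.append(SessionFeatureRow(str(rec["patient_id"]), str(rec["session_label"]), features, scores))
    return rows
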