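"""Publication-style outputs: correlation heatmaps, the results grid
(scale x device x model -> R, p), inter-scale correlations, qualitative
R-strength labels, and deterministic markdown/JSON rendering.

Correlation strength bins (|R|): 0-0.30 very weak, 0.31-0.50 weak,
0.51-0.70 moderate, 0.71-1.0 strong.  Values falling in the printed gaps
(e.g. 0.305) are assigned to the lower bin.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import pearson_r
from .models import CVResult, VIFReport
from .types import SCALES

__all__ = [
    "interpret_r",
    "heatmap",
    "correlation_matrix",
    "CorrelationReport",
    "build_report",
    "render_markdown",
]

#: canonical row order of the results grid
MEASURE_ORDER = [
    "FMA-UE 0-66",
    "FMA-UE 1-38",
    "FMA-UE 39-66",
    "BI",
    "WMFT",
    "MP total",
    "MP kinematic force",
    "MP force transducer (deltaz)",
    "MP force transducer (F/E/AB/AD)",
]
DEVICE_ORDER = ["shoulder_elbow", "wrist", "both"]
MODEL_ORDER = ["linear", "nonlinear"]

_BINS = [(0.71, "strong"), (0.51, "moderate"), (0.31, "weak"), (0.0, "very weak")]


def interpret_r(r: float) -> str:
    """Qualitative strength label of a correlation coefficient."""
    a = abs(r)
    if a > 1.0:
        raise ValueError(f"|R| must be <= 1, got {r}")
    for lo, label in _BINS:
        if a >= lo:
            return label
    return "very weak"


def correlation_matrix(
    df: pd.DataFrame, features: Sequence[str], scales: Sequence[str] = SCALES
) -> pd.DataFrame:
    """Pairwise Pearson R of every feature (and scale) with every scale.

    Rows are features followed by scales (the trailing square block is the
    inter-scale correlation matrix and is symmetric)."""
    scales = [s for s in scales if s in df.columns and df[s].notna().sum() >= 3]
    if df.empty or not scales:
        raise ValueError("empty table or no usable scale columns")
    rows = list(features) + list(scales)
    out = pd.DataFrame(index=rows, columns=list(scales), dtype=float)
    for r in rows:
        for c in scales:
            try:
                out.loc[r, c] = pearson_r(df[r], df[c])
            except ValueError:
                out.loc[r, c] = np.nan
    return out


def heatmap(
    df: pd.DataFrame,
    features: Sequence[str],
    scales: Sequence[str] = SCALES,
    out_path: Optional[str] = None,
) -> pd.DataFrame:
    """Correlation heatmap of features (and scales) against scales.

    Writes ``<out_path>`` as a PNG and the matrix CSV alongside it; returns
    the matrix.
    """
    mat = correlation_matrix(df, features, scales)
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(2 + 0.6 * mat.shape[1], 1.5 + 0.3 * mat.shape[0])
        )
        im = ax.imshow(mat.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
        ax.set_yticks(range(mat.shape[0]), mat.index)
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                v = mat.iat[i, j]
                if np.isfinite(v):
                    ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=7)
        fig.colorbar(im, ax=ax, label="Pearson R")
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        mat.to_csv(str(out_path).rsplit(".", 1)[0] + ".csv")
    return mat


@dataclass
class GridCell:
    measure: str
    device: str
    model: str
    r: float
    p: float
    n: int
    features: list
    strength: str


@dataclass
class CorrelationReport:
    """Assembled results grid plus diagnostics and provenance."""

    grid: list  # list[GridCell] in canonical order
    scale_intercorrelations: dict  # (scale_a, scale_b) -> R
    vif_blocks: dict  # label -> {feature: vif}
    provenance: dict = field(default_factory=dict)


def build_report(
    cv_results: Sequence[tuple],
    vif_reports: Optional[dict] = None,
    scale_corr: Optional[pd.DataFrame] = None,
    provenance: Optional[dict] = None,
) -> CorrelationReport:
    """Assemble the grid from ``(measure_label, device, model, CVResult)``
    tuples.  Duplicate (measure, device, model) cells are an error."""
    if not cv_results:
        raise ValueError("need at least one cross-validation result")
    seen = {}
    cells = []
    for measure, device, model, cv in cv_results:
        key = (measure, device, model)
        if key in seen:
            raise ValueError(f"duplicate grid cell {key}")
        seen[key] = True
        if not isinstance(cv, CVResult):
            raise TypeError("expected a CVResult")
        if not (-1.0 - 1e-9 <= cv.mean_r <= 1.0 + 1e-9):
            raise ValueError(f"R out of range in cell {key}")
        cells.append(
            GridCell(
                measure=measure,
                device=device,
                model=model,
                r=cv.mean_r,
                p=cv.p_value,
                n=cv.n_rows,
                features=list(cv.features),
                strength=interpret_r(cv.mean_r),
            )
        )

    def sort_key(c: GridCell):
        m = MEASURE_ORDER.index(c.measure) if c.measure in MEASURE_ORDER else len(MEASURE_ORDER)
        d = DEVICE_ORDER.index(c.device) if c.device in DEVICE_ORDER else len(DEVICE_ORDER)
        mo = MODEL_ORDER.index(c.model) if c.model in MODEL_ORDER else len(MODEL_ORDER)
        return (m, c.measure, d, c.device, mo, c.model)

    cells.sort(key=sort_key)
    inter = {}
    if scale_corr is not None:
        for a in scale_corr.columns:
            for b in scale_corr.columns:
                if a in scale_corr.index:
                    inter[f"{a}:{b}"] = float(scale_corr.loc[a, b])
    vif_blocks = {}
    for label, rep in (vif_reports or {}).items():
        if isinstance(rep, VIFReport):
            vif_blocks[label] = dict(rep.vif)
        else:
            vif_blocks[label] = dict(rep)
    return CorrelationReport(
        grid=cells,
        scale_intercorrelations=inter,
        vif_blocks=vif_blocks,
        provenance=provenance or {},
    )


def _fmt_p(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    if p < 0.05:
        return "<0.05"
    return f"{p:.2f}"


def render_markdown(report: CorrelationReport) -> str:
    """Deterministic markdown rendering of the results grid."""
    lines = [
        "# Correlation of kinematic and kinetic metrics with clinical measures",
        "",
        "| Measure | Device | Model | R | P | strength | n | features |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for c in report.grid:
        feats = ", ".join(c.features)
        lines.append(
            f"| {c.measure} | {c.device} | {c.model} | {c.r:.2f} | {_fmt_p(c.p)} "
            f"| {c.strength} | {c.n} | {feats} |"
        )
    if report.scale_intercorrelations:
        lines += ["", "## Inter-scale correlations", ""]
        for key in sorted(report.scale_intercorrelations):
            lines.append(f"- {key}: R = {report.scale_intercorrelations[key]:.2f}")
    if report.vif_blocks:
        lines += ["", "## Variance inflation factors", ""]
        for label in sorted(report.vif_blocks):
            block = report.vif_blocks[label]
            parts = ", ".join(f"{f}: {v:.1f}" for f, v in sorted(block.items()))
            lines.append(f"- {label}: {parts}")
    if report.provenance:
        lines += ["", "## Provenance", ""]
        for key in sorted(report.provenance):
            lines.append(f"- {key}: {report.provenance[key]}")
    return "\n".join(lines) + "\n"


def report_to_json(report: CorrelationReport) -> str:
    payload = {
        "grid": [asdict(c) for c in report.grid],
        "scale_intercorrelations": report.scale_intercorrelations,
        "vif_blocks": report.vif_blocks,
        "provenance": report.provenance,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
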