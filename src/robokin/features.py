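"""Analysis-dataset construction: correlation-based feature selection,
collinearity pruning, and max-rescaling.

Selection is a pure filter: a feature is retained when the absolute Pearson
correlation of its session values with the target clinical scale exceeds
``r_threshold`` (default 0.5).  Absolute value is used because
worse-is-larger metrics (deviation, offset, scatter) legitimately
anti-correlate with the scales; a signed variant is available.  When no
feature passes, the strongest ``top_k`` may be used as a flagged fallback.
Within each group of mutually dependent selected features (pairwise |R|
above ``dep_threshold``) one representative is kept — a configured
keep-list member if present, otherwise the feature most correlated with the
target.

Rescaling divides each feature by its training-set maximum; the target is
rescaled by its maximum for the nonlinear model only.  Scaling learned on
training folds is applied unchanged to test folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "pearson_r",
    "SelectionResult",
    "select_features",
    "prune_collinear",
    "ScalingSpec",
    "fit_scaling",
    "apply_scaling",
    "invert_scaling",
]


def pearson_r(x, y) -> float:
    """Pairwise-complete Pearson product-moment correlation.

    Rows where either input is missing are dropped; requires >= 3 complete
    pairs and nonzero variance in both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class SelectionResult:
    """Outcome of feature selection for one target scale."""

    target: str
    candidate_correlations: dict  # feature -> R with the target (all candidates)
    selected: list  # ordered by |R| descending
    pruned: dict = field(default_factory=dict)  # dropped -> (kept, dependency R)
    r_threshold: float = 0.5
    dep_threshold: Optional[float] = None
    sub_threshold: bool = False  # True when the top-k fallback was used


def select_features(
    df: pd.DataFrame,
    target: str,
    features: Optional[Sequence[str]] = None,
    r_threshold: float = 0.5,
    signed: bool = False,
    top_k: Optional[int] = None,
) -> SelectionResult:
    """Correlation-filter feature selection against one clinical scale.

    ``signed=True`` reproduces a literal one-sided R > threshold rule;
    the default thresholds |R|.  If nothing passes and ``top_k`` is given,
    the ``top_k`` strongest features are returned flagged
    ``sub_threshold``; without ``top_k`` an empty selection is returned
    with a warning.
    """
    if df[target].notna().sum() < 3:
        raise ValueError(f"need >= 3 rows with non-missing target {target!r}")
    if features is None:
        features = [
            c
            for c in df.columns
            if c not in ("patient_id", "session_label", "fma_ue", "wmft", "bi", "mrc")
        ]
    corr: dict[str, float] = {}
    for feat in features:
        try:
            corr[feat] = pearson_r(df[feat], df[target])
        except ValueError:
            corr[feat] = float("nan")
    strength = (lambda r: r) if signed else abs
    passed = [f for f, r in corr.items() if np.isfinite(r) and strength(r) > r_threshold]
    passed.sort(key=lambda f: abs(corr[f]), reverse=True)
    sub_threshold = False
    if not passed:
        ranked = sorted(
            (f for f, r in corr.items() if np.isfinite(r)),
            key=lambda f: abs(corr[f]),
            reverse=True,
        )
        if top_k:
            passed = ranked[:top_k]
            sub_threshold = True
        else:
            warnings.warn(
                f"no feature exceeded |R| > {r_threshold} for {target!r}; "
                "empty selection (set top_k for a fallback)",
                stacklevel=2,
            )
    return SelectionResult(
        target=target,
        candidate_correlations=corr,
        selected=passed,
        r_threshold=r_threshold,
        sub_threshold=sub_threshold,
    )


def prune_collinear(
    df: pd.DataFrame,
    selection: SelectionResult,
    dep_threshold: float = 0.85,
    keep_list: Optional[Sequence[str]] = None,
) -> SelectionResult:
    """Reduce each mutually dependent group of selected features to one.

    Builds the dependency graph of selected features whose pairwise |R|
    exceeds ``dep_threshold``; in every connected component the keep-list
    member (interpretability preference) or else the feature with the
    largest |R| to the target survives.
    """
    if not selection.selected:
        raise ValueError("selection is empty; nothing to prune")
    keep_list = list(keep_list or [])
    g = nx.Graph()
    g.add_nodes_from(selection.selected)
    dep: dict[tuple, float] = {}
    for i, a in enumerate(selection.selected):
        for b in selection.selected[i + 1 :]:
            try:
                r = pearson_r(df[a], df[b])
            except ValueError:
                continue
            if abs(r) > dep_threshold:
                g.add_edge(a, b)
                dep[(a, b)] = r
                dep[(b, a)] = r
    kept: list[str] = []
    pruned: dict[str, tuple] = {}
    for comp in nx.connected_components(g):
        comp = list(comp)
        preferred = [f for f in keep_list if f in comp]
        if preferred:
            winner = preferred[0]
        else:
            winner = max(comp, key=lambda f: abs(selection.candidate_correlations[f]))
        kept.append(winner)
        for f in comp:
            if f != winner:
                pruned[f] = (winner, dep.get((f, winner), float("nan")))
    kept.sort(key=lambda f: abs(selection.candidate_correlations[f]), reverse=True)
    return SelectionResult(
        target=selection.target,
        candidate_correlations=selection.candidate_correlations,
        selected=kept,
        pruned=pruned,
        r_threshold=selection.r_threshold,
        dep_threshold=dep_threshold,
        sub_threshold=selection.sub_threshold,
    )


@dataclass(frozen=True)
class ScalingSpec:
    """Max-normalization constants learned from training rows only."""

    feature_max: dict
    target: str
    target_max: Optional[float] = None  # set for the nonlinear model only


def fit_scaling(
    df: pd.DataFrame, features: Sequence[str], target: str, mode: str = "linear"
) -> ScalingSpec:
    """Learn per-feature maxima (and the target maximum when
    ``mode='nonlinear'``) from ``df``."""
    if mode not in ("linear", "nonlinear"):
        raise ValueError(f"mode must be linear|nonlinear, got {mode!r}")
    fmax = {}
    for f in features:
        m = float(np.nanmax(np.abs(df[f].to_numpy(dtype=float))))
        if not np.isfinite(m) or m == 0.0:
            raise ValueError(f"feature {f!r} has zero or undefined maximum")
        fmax[f] = m
    tmax = None
    if mode == "nonlinear":
        tmax = float(np.nanmax(np.abs(df[target].to_numpy(dtype=float))))
        if not np.isfinite(tmax) or tmax == 0.0:
            raise ValueError(f"target {target!r} has zero or undefined maximum")
    return ScalingSpec(feature_max=fmax, target=target, target_max=tmax)


def apply_scaling(df: pd.DataFrame, spec: ScalingSpec) -> pd.DataFrame:
    out = df.copy()
    for f, m in spec.feature_max.items():
        out[f] = out[f] / m
    if spec.target_max is not None:
        out[spec.target] = out[spec.target] / spec.target_max
    return out


def invert_scaling(df: pd.DataFrame, spec: ScalingSpec) -> pd.DataFrame:
    out = df.copy()
    for f, m in spec.feature_max.items():
        out[f] = out[f] * m
    if spec.target_max is not None:
        out[spec.target] = out[spec.target] * spec.target_max
    return out
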