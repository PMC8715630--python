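"""Linear and shallow-network predictors of clinical scales, evaluated by
patient-wise cross-validated correlation, with collinearity diagnostics.

The model space is deliberately small: ordinary least squares, and a
multilayer perceptron with exactly one hidden layer of 2 sigmoid units and
a linear output, trained by full-batch nonlinear least squares from
multiple seeded initializations.  Because one patient contributes several
evaluation sessions, cross-validation samples *patients*, not rows: all of
a patient's sessions stay on the same side of every split, which removes
identity leakage.  Each fold's feature scaling is learned on its training
rows only.  Per-fold correlations between predicted and observed scores
are averaged into the reported R; a Mann-Whitney rank test guards against
unbalanced train/test target distributions (the whole partition is redrawn
when any fold's two-sided p falls below 0.05).

The variance inflation factor of feature j is VIF_j = 1 / (1 - R_j^2),
with R_j^2 the coefficient of determination of feature j regressed on the
remaining features; VIF > 10 (R_j^2 > 0.9) flags strong multicollinearity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.special import expit

from .features import ScalingSpec, apply_scaling, fit_scaling, pearson_r

__all__ = [
    "LinearFit",
    "MLPFit",
    "fit_linear",
    "fit_mlp",
    "MLPOptions",
    "assign_folds",
    "patientwise_cv",
    "stratified_evaluation",
    "partition_balance_test",
    "CVResult",
    "vif",
    "VIFReport",
]


@dataclass
class LinearFit:
    """Ordinary least-squares fit: y ~ intercept + X @ coef."""

    kind: str
    features: list
    intercept: float
    coef: np.ndarray
    training_rmse: float

    def predict(self, X) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


def fit_linear(X, y, feature_names: Optional[Sequence[str]] = None) -> LinearFit:
    """OLS with an explicit rank check (raises naming dependent columns)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n < d + 2:
        raise ValueError(f"need >= {d + 2} rows for {d} features, have {n}")
    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < d + 1:
        names = list(feature_names or [f"x{i}" for i in range(d)])
        # identify columns in the span of the preceding ones
        dependent = []
        for j in range(1, d + 1):
            if np.linalg.matrix_rank(A[:, : j + 1]) == np.linalg.matrix_rank(A[:, :j]):
                dependent.append(names[j - 1])
        raise ValueError(f"design matrix is rank deficient; dependent columns: {dependent}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return LinearFit(
        kind="linear",
        features=list(feature_names or []),
        intercept=float(beta[0]),
        coef=beta[1:],
        training_rmse=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass(frozen=True)
class MLPOptions:
    restarts: int = 10
    max_iter: int = 2000
    tol: float = 1e-8
    n_hidden: int = 2


@dataclass
class MLPFit:
    """One-hidden-layer (2 sigmoid units) network with a linear output.

    Weights live on the scaled data ([0, 1] features, max-scaled target);
    ``predict`` returns values on the scaled target axis — the CV driver
    multiplies back by the target maximum.
    """

    kind: str
    features: list
    w1: np.ndarray  # (d, h)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h,)
    b2: float
    seed: int
    training_rmse: float

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        h = expit(X @ self.w1 + self.b1)
        return h @ self.w2 + self.b2


def _mlp_unpack(theta: np.ndarray, d: int, h: int):
    w1 = theta[: d * h].reshape(d, h)
    b1 = theta[d * h : d * h + h]
    w2 = theta[d * h + h : d * h + 2 * h]
    b2 = theta[-1]
    return w1, b1, w2, b2


def fit_mlp(
    X,
    y,
    seed: int = 0,
    opts: MLPOptions | None = None,
    feature_names: Optional[Sequence[str]] = None,
) -> MLPFit:
    """Least-squares training of the 2-sigmoid-node network.

    ``X`` is expected max-scaled (roughly [0, 1]) and ``y`` scaled by its
    maximum.  The best of ``opts.restarts`` seeded initializations by
    training RMSE is returned; identical seed and data give identical
    weights.
    """
    opts = opts or MLPOptions()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    h = opts.n_hidden
    rng = np.random.default_rng(seed)

    def resid(theta):
        w1, b1, w2, b2 = _mlp_unpack(theta, d, h)
        hidden = expit(X @ w1 + b1)
        return hidden @ w2 + b2 - y

    best = None
    for _ in range(opts.restarts):
        theta0 = rng.normal(0.0, 1.0, d * h + 2 * h + 1)
        try:
            fit = least_squares(
                resid,
                theta0,
                method="lm",
                max_nfev=opts.max_iter * (len(theta0) + 1),
                xtol=opts.tol,
                ftol=opts.tol,
                gtol=opts.tol,
            )
        except Exception:
            continue
        rmse = float(np.sqrt(np.mean(fit.fun**2)))
        if best is None or rmse < best[0]:
            best = (rmse, fit.x)
    if best is None:
        raise RuntimeError("MLP training failed in every restart")
    rmse, theta = best
    w1, b1, w2, b2 = _mlp_unpack(theta, d, h)
    return MLPFit(
        kind="mlp",
        features=list(feature_names or []),
        w1=w1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        seed=seed,
        training_rmse=rmse,
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    """Patient-wise cross-validated correlation of one (target, model)."""

    target: str
    model_kind: str
    features: list
    fold_assignments: dict  # patient_id -> fold index
    per_fold_r: list
    mean_r: float
    pooled_r: float  # secondary: correlation of all pooled test predictions
    p_value: float
    balance_p: list  # Mann-Whitney p per fold
    n_rows: int
    n_dropped: int
    seed: int
    redraws: int


def assign_folds(patient_ids: Sequence[str], k: int, rng: np.random.Generator) -> dict:
    """Partition patients into k folds whose sizes differ by at most one,
    in seeded shuffled order."""
    ids = sorted(set(patient_ids))
    if len(ids) < k:
        raise ValueError(f"need >= {k} patients, have {len(ids)}")
    order = list(rng.permutation(len(ids)))
    folds: dict[str, int] = {}
    for pos, idx in enumerate(order):
        folds[ids[idx]] = pos % k
    return folds


def partition_balance_test(train_y, test_y) -> float:
    """Two-sided Mann-Whitney rank-sum p-value comparing the target values
    of a train and a test partition (p < 0.05 flags imbalance)."""
    train_y = np.asarray(train_y, dtype=float)
    test_y = np.asarray(test_y, dtype=float)
    if len(train_y) < 3 or len(test_y) < 3:
        raise ValueError("both partitions need >= 3 values")
    combined = np.concatenate([train_y, test_y])
    if np.all(combined == combined[0]):
        warnings.warn("all target values tied; balance test degenerate (p = 1)", stacklevel=2)
        return 1.0
    return float(stats.mannwhitneyu(train_y, test_y, alternative="two-sided").pvalue)


def _r_p_value(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t transform at sample size n."""
    if n < 3:
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if 1.0 - r * r < 1e-15:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def patientwise_cv(
    df: pd.DataFrame,
    features: Sequence[str],
    target: str,
    kind: str = "linear",
    k: int = 4,
    seed: int = 0,
    max_redraws: int = 20,
    mlp_opts: MLPOptions | None = None,
) -> CVResult:
    """k-fold cross-validation sampling patients, not rows.

    For every fold the remaining patients' rows train a freshly scaled
    model; R is the Pearson correlation between predicted and observed
    target on the held-out rows, and the reported value is the mean of the
    per-fold Rs (pooled-prediction R is carried as a secondary).  Any fold
    whose train/test target distributions differ (Mann-Whitney p < 0.05)
    triggers a full partition redraw, up to ``max_redraws``.
    """
    features = list(features)
    work = df.dropna(subset=[*features, target]).reset_index(drop=True)
    n_dropped = len(df) - len(work)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} row(s) with missing feature/target values",
            stacklevel=2,
        )
    patients = work["patient_id"].tolist()
    rng = np.random.default_rng(seed)
    folds = None
    balance = None
    redraws = 0
    for attempt in range(max_redraws + 1):
        cand = assign_folds(patients, k, rng)
        fold_of_row = work["patient_id"].map(cand).to_numpy()
        sizes = [(fold_of_row == j).sum() for j in range(k)]
        if min(sizes) < 3:
            raise ValueError(
                f"fold with {min(sizes)} test rows (< 3); use fewer folds"
            )
        cand_balance = [
            partition_balance_test(
                work.loc[fold_of_row != j, target], work.loc[fold_of_row == j, target]
            )
            for j in range(k)
        ]
        folds, balance = cand, cand_balance
        if min(cand_balance) >= 0.05:
            break
        redraws = attempt + 1
    else:
        pass
    if min(balance) < 0.05:
        warnings.warn(
            f"partition still unbalanced after {max_redraws} redraws "
            f"(min p = {min(balance):.3g}); proceeding",
            stacklevel=2,
        )

    fold_of_row = work["patient_id"].map(folds).to_numpy()
    per_fold_r = []
    pooled_pred, pooled_obs = [], []
    for j in range(k):
        train = work[fold_of_row != j]
        test = work[fold_of_row == j]
        mode = "nonlinear" if kind == "mlp" else "linear"
        spec = fit_scaling(train, features, target, mode=mode)
        tr = apply_scaling(train, spec)
        te = apply_scaling(test, spec)
        if kind == "linear":
            model = fit_linear(tr[features].to_numpy(), tr[target].to_numpy(), features)
            pred = model.predict(te[features].to_numpy())
        elif kind == "mlp":
            model = fit_mlp(
                tr[features].to_numpy(),
                tr[target].to_numpy(),
                seed=seed + 104729 * j,
                opts=mlp_opts,
                feature_names=features,
            )
            pred = model.predict(te[features].to_numpy()) * spec.target_max
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        obs = test[target].to_numpy(dtype=float)
        per_fold_r.append(pearson_r(pred, obs))
        pooled_pred.append(pred)
        pooled_obs.append(obs)
    mean_r = float(np.mean(per_fold_r))
    pooled_r = pearson_r(np.concatenate(pooled_pred), np.concatenate(pooled_obs))
    return CVResult(
        target=target,
        model_kind=kind,
        features=features,
        fold_assignments=folds,
        per_fold_r=per_fold_r,
        mean_r=mean_r,
        pooled_r=pooled_r,
        p_value=_r_p_value(mean_r, len(work)),
        balance_p=balance,
        n_rows=len(work),
        n_dropped=n_dropped,
        seed=seed,
        redraws=redraws,
    )


def stratified_evaluation(
    df: pd.DataFrame,
    features: Sequence[str],
    target: str,
    target_range: tuple,
    **kwargs,
) -> CVResult:
    """Patient-wise CV restricted to rows whose target lies in the closed
    interval ``target_range`` (e.g. an FMA-UE severity stratum)."""
    lo, hi = target_range
    stratum = df[(df[target] >= lo) & (df[target] <= hi)]
    if stratum.empty:
        raise ValueError(
            f"no rows with {target} in [{lo}, {hi}]; empty stratum"
        )
    return patientwise_cv(stratum, features, target, **kwargs)


# ---------------------------------------------------------------------------
# multicollinearity diagnostics


@dataclass
class VIFReport:
    """Per-feature variance inflation factors."""

    features: list
    r_squared: dict  # feature -> R_j^2 against the other features
    vif: dict  # feature -> 1 / (1 - R_j^2)
    flag_high: dict  # feature -> VIF > 10
    effectively_infinite: dict  # feature -> R_j^2 at the clip bound


def vif(df: pd.DataFrame, features: Sequence[str]) -> VIFReport:
    """VIF_j = 1/(1 - R_j^2) from an OLS of feature j on the remaining
    features (with intercept).  R_j^2 is clipped just below 1; clipped
    features are flagged effectively infinite."""
    features = list(features)
    if len(features) < 2:
        raise ValueError("need >= 2 features for VIF")
    X = df[features].to_numpy(dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n = X.shape[0]
    if n <= len(features):
        raise ValueError(f"need more rows ({n}) than features ({len(features)})")
    r2: dict[str, float] = {}
    out_vif: dict[str, float] = {}
    flag: dict[str, bool] = {}
    inf: dict[str, bool] = {}
    clip = 1.0 - 1e-12
    for j, name in enumerate(features):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ beta
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0.0:
            raise ValueError(f"feature {name!r} is constant")
        rj2 = 1.0 - float(np.sum(resid**2)) / sst
        inf[name] = rj2 >= clip
        rj2 = min(max(rj2, 0.0), clip)
        r2[name] = rj2
        out_vif[name] = 1.0 / (1.0 - rj2)
        flag[name] = out_vif[name] > 10.0
    return VIFReport(
        features=features,
        r_squared=r2,
        vif=out_vif,
        flag_high=flag,
        effectively_infinite=inf,
    )
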