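"""Support-bounded lognormal submovements and speed-profile decomposition.

A movement's speed profile is modelled as a sum of brief stereotyped pulses
("submovements").  Each pulse is lognormal in the support time *ratio*: with
normalized support time tau = (t - t0)/D in (0, 1),

    v(t) = A / D * 1/(tau (1 - tau) sigma sqrt(2 pi))
               * exp(-(ln(tau / (1 - tau)) - mu)^2 / (2 sigma^2))

i.e. a logit-normal density on the support, scaled so the pulse integrates
exactly to its amplitude A (the path length travelled).  The pulse is
identically zero outside [t0, t0 + D] and — unlike a hard-truncated
lognormal — decays smoothly to zero at *both* support ends, which makes all
five parameters (t0, D, A, mu, sigma) identifiable from samples of the
profile.  For sigma < sqrt(2) the density is strictly unimodal; the fit
bounds keep sigma <= 1.2.  The mode solves
ln(tau/(1-tau)) = mu + sigma^2 (2 tau - 1) and shifts earlier as mu
decreases.

Decomposition is greedy matching pursuit with joint refitting: start with
one pulse, refit all parameters by nonlinear least squares, and add pulses
initialized at the largest residual peak until the residual RMSE falls
below ``rmse_tol`` times the profile's peak speed or ``max_n`` is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Submovement",
    "Decomposition",
    "Micrometrics",
    "lognormal_pulse",
    "synth_speed_profile",
    "decompose",
    "micrometrics",
    "DecomposeOptions",
]


@dataclass(frozen=True)
class Submovement:
    """One support-bounded lognormal speed pulse."""

    t0: float  # onset, s
    D: float  # support duration, s
    A: float  # amplitude = integral of the pulse (path length units)
    mu: float  # location of ln(tau/(1-tau)) (dimensionless)
    sigma: float  # scale of ln(tau/(1-tau)) (dimensionless)

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.A <= 0:
            raise ValueError(f"A must be > 0, got {self.A}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def peak_time(self) -> float:
        """Time of the pulse maximum."""
        return self.t0 + _mode_tau(self.mu, self.sigma) * self.D

    @property
    def peak_speed(self) -> float:
        return float(lognormal_pulse(np.array([self.peak_time]), self)[0])


def _mode_tau(mu: float, sigma: float) -> float:
    """Mode of the pulse in normalized support time.

    Unique root of ln(tau/(1-tau)) = mu + sigma^2 (2 tau - 1); uniqueness
    holds for sigma < sqrt(2) (the left side's slope is >= 4, the right
    side's is 2 sigma^2).
    """
    from scipy.optimize import brentq

    def g(tau):
        return math.log(tau / (1.0 - tau)) - mu - sigma**2 * (2.0 * tau - 1.0)

    return brentq(g, 1e-12, 1.0 - 1e-12, xtol=1e-14)


def lognormal_pulse(t, sm: Submovement) -> np.ndarray:
    """Evaluate one pulse at times ``t`` (zero outside its support)."""
    t = np.asarray(t, dtype=float)
    tau = (t - sm.t0) / sm.D
    out = np.zeros_like(tau)
    mask = (tau > 0.0) & (tau < 1.0)
    tm = tau[mask]
    logit = np.log(tm / (1.0 - tm))
    out[mask] = (
        sm.A
        / sm.D
        / (tm * (1.0 - tm) * sm.sigma * math.sqrt(2.0 * math.pi))
        * np.exp(-((logit - sm.mu) ** 2) / (2.0 * sm.sigma**2))
    )
    return out


def synth_speed_profile(submovements: Sequence[Submovement], t_grid) -> np.ndarray:
    """Pointwise sum of submovement pulses on ``t_grid`` (non-negative)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be non-empty")
    out = np.zeros_like(t_grid)
    for sm in submovements:
        out += lognormal_pulse(t_grid, sm)
    return out


@dataclass
class Decomposition:
    """Result of fitting pulses to a speed profile."""

    submovements: list[Submovement]
    residual_rmse: float
    reconstruction: np.ndarray
    #: best residual RMSE after each greedy step (non-increasing)
    rmse_history: list[float] = field(default_factory=list)

    @property
    def number(self) -> int:
        return len(self.submovements)


@dataclass
class Micrometrics:
    """Per-segment submovement summary (the micrometric family).

    Means are over the segment's submovements; ``overlap`` and
    ``interpeak_interval`` need at least two pulses and are ``None``
    (missing, not zero) otherwise.
    """

    number: int
    duration: Optional[float]
    overlap: Optional[float]
    peak: Optional[float]
    interpeak_interval: Optional[float]

    def as_dict(self) -> dict:
        return {
            "sub_number": float(self.number),
            "sub_duration": self.duration,
            "sub_overlap": self.overlap,
            "sub_peak": self.peak,
            "sub_interpeak": self.interpeak_interval,
        }


@dataclass(frozen=True)
class DecomposeOptions:
    max_n: int = 8
    rmse_tol: float = 0.02  # fraction of the profile's peak speed
    restarts: int = 5
    seed: int = 0
    mu_init: float = -0.2
    sigma_init: float = 0.4


class DecompositionError(RuntimeError):
    def __init__(self, msg: str, best_rmse: float):
        super().__init__(msg)
        self.best_rmse = best_rmse


def _pack(sms: list[Submovement]) -> np.ndarray:
    return np.array([[s.t0, s.D, s.A, s.mu, s.sigma] for s in sms]).ravel()


def _unpack(x: np.ndarray) -> list[Submovement]:
    p = x.reshape(-1, 5)
    return [Submovement(*row) for row in p]


def _bounds(n: int, t: np.ndarray, total_path: float):
    t_span = t[-1] - t[0]
    lo = np.tile([t[0] - 0.5 * t_span, 0.05, 1e-9, -2.5, 0.05], n)
    hi = np.tile([t[-1], max(t_span, 0.06), 2.0 * total_path, 2.5, 1.2], n)
    return lo, hi


def _init_pulse(residual: np.ndarray, t: np.ndarray, opts: DecomposeOptions) -> Submovement:
    """Matching-pursuit initialization at the largest residual peak."""
    i = int(np.argmax(residual))
    peak = residual[i]
    half = peak / 2.0
    j = i
    while j > 0 and residual[j] > half:
        j -= 1
    k = i
    while k < len(residual) - 1 and residual[k] > half:
        k += 1
    fwhm = max(t[k] - t[j], 2.0 * float(np.mean(np.diff(t))))
    # FWHM and mode of the default init shape, in units of D
    tau_star = _mode_tau(opts.mu_init, opts.sigma_init)
    ref = Submovement(0.0, 1.0, 1.0, opts.mu_init, opts.sigma_init)
    tau_grid = np.linspace(1e-4, 1.0 - 1e-4, 400)
    prof = lognormal_pulse(tau_grid, ref)
    above = tau_grid[prof > prof.max() / 2.0]
    fwhm_ratio = float(above[-1] - above[0])
    D = min(max(fwhm / fwhm_ratio, 0.06), t[-1] - t[0])
    t0 = t[i] - tau_star * D
    A = max(float(np.trapezoid(np.clip(residual, 0.0, None), t)), 1e-6)
    return Submovement(t0=t0, D=D, A=A, mu=opts.mu_init, sigma=opts.sigma_init)


def _refit(
    sms: list[Submovement], speed: np.ndarray, t: np.ndarray, total_path: float
) -> tuple[list[Submovement], float]:
    x0 = _pack(sms)
    lo, hi = _bounds(len(sms), t, total_path)
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    def resid(x):
        return synth_speed_profile(_unpack_safe(x), t) - speed

    fit = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    sms_out = _unpack_safe(fit.x)
    rmse = float(np.sqrt(np.mean(fit.fun**2)))
    return sms_out, rmse


def _unpack_safe(x: np.ndarray) -> list[Submovement]:
    p = x.reshape(-1, 5)
    out = []
    for t0, D, A, mu, sigma in p:
        out.append(Submovement(t0, max(D, 1e-6), max(A, 1e-12), mu, max(sigma, 1e-6)))
    return out


def decompose(speed, t, opts: DecomposeOptions | None = None) -> Decomposition:
    """Fit support-bounded lognormal pulses to a non-negative speed profile.

    Greedy add-and-refit; returns the first model whose residual RMSE is
    below ``opts.rmse_tol * max(speed)``, otherwise the best model found
    with up to ``opts.max_n`` pulses (after ``opts.restarts`` jittered
    re-runs).  Deterministic under ``opts.seed``.
    """
    opts = opts or DecomposeOptions()
    speed = np.asarray(speed, dtype=float)
    t = np.asarray(t, dtype=float)
    if speed.shape != t.shape:
        raise ValueError("speed and t must have the same length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    if np.any(speed < -1e-12):
        raise ValueError("speed must be non-negative")
    peak = float(speed.max(initial=0.0))
    if peak <= 0.0:
        return Decomposition([], 0.0, np.zeros_like(speed), [0.0])

    rng = np.random.default_rng(opts.seed)
    total_path = float(np.trapezoid(speed, t))
    target = opts.rmse_tol * peak

    best_overall: tuple[float, list[Submovement]] | None = None
    for attempt in range(opts.restarts + 1):
        sms: list[Submovement] = []
        rmse = float(np.sqrt(np.mean(speed**2)))
        history: list[float] = []
        ok = False
        for _ in range(opts.max_n):
            residual = speed - synth_speed_profile(sms, t)
            new = _init_pulse(residual, t, opts)
            if attempt > 0:
                # jittered restart: perturb the matching-pursuit init
                new = Submovement(
                    t0=new.t0 + rng.normal(0, 0.05) * new.D,
                    D=new.D * math.exp(rng.normal(0, 0.2)),
                    A=new.A * math.exp(rng.normal(0, 0.2)),
                    mu=new.mu + rng.normal(0, 0.15),
                    sigma=max(new.sigma * math.exp(rng.normal(0, 0.2)), 0.06),
                )
            cand, cand_rmse = _refit(sms + [new], speed, t, total_path)
            if cand_rmse <= rmse + 1e-15:
                sms, rmse = cand, cand_rmse
            history.append(rmse)
            if rmse <= target:
                ok = True
                break
        if best_overall is None or rmse < best_overall[0]:
            best_overall = (rmse, sms)
            best_history = history
        if ok:
            break
    rmse, sms = best_overall
    sms = sorted(sms, key=lambda s: s.t0)
    recon = synth_speed_profile(sms, t)
    return Decomposition(sms, rmse, recon, best_history)


def micrometrics(dec: Decomposition) -> Micrometrics:
    """Submovement count, mean duration/overlap/peak/interpeak-interval."""
    sms = dec.submovements
    n = len(sms)
    if n == 0:
        return Micrometrics(0, None, None, None, None)
    duration = float(np.mean([s.D for s in sms]))
    peak = float(np.mean([s.peak_speed for s in sms]))
    if n < 2:
        return Micrometrics(n, duration, None, peak, None)
    overlaps = [
        (sms[i].t0 + sms[i].D) - sms[i + 1].t0 for i in range(n - 1)
    ]  # positive when consecutive pulses overlap
    peaks = [s.peak_time for s in sms]
    interpeak = [peaks[i + 1] - peaks[i] for i in range(n - 1)]
    return Micrometrics(
        n,
        duration,
        float(np.mean(overlaps)),
        peak,
        float(np.mean(interpeak)),
    )
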