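"""Curve-fitting phase markers.

Three fitted forms, each evaluated over one ~24-h day of data:

* **F(2)/F(3)** — Fourier series with a fundamental of fixed 24-h period plus
  one or two harmonics (5 or 7 parameters), fit by linear least squares.
* **Skewed bimodal cosine** — a 6-parameter clipped-cosine pulse whose phase
  angle is warped by skew and bimodality terms (see :func:`skewed_eval`),
  fit by multistart nonlinear least squares.
* **NOSA** (non-orthogonal spectral analysis) — a fundamental plus two
  harmonics whose fundamental period is itself selected by scanning
  23.5-24.5 h; used for the fitted amplitude and the peak/trough that set the
  25% relative DLMO threshold.

Phase markers from a fitted curve are the fit maximum (earliest global
maximiser on a 1-minute grid) and the up/down crossings of half the fitted
maximum value (measured from zero), refined by bisection.  Goodness of fit is
compared across model families with the adjusted R², which penalises
parameter count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq, least_squares

from .profile_core import SampleSeries
from .threshold_markers import MarkerEstimate

__all__ = [
    "HarmonicFit",
    "SkewedFit",
    "NosaFit",
    "fit_fourier",
    "fit_skewed",
    "skewed_eval",
    "curve_markers",
    "adjusted_r2",
    "nosa_fit",
]


def adjusted_r2(residual_ss: float, total_ss: float, n: int, p: int) -> float:
    """Adjusted R² = 1 - (1 - R²)(n - 1)/(n - p - 1), R² about the mean."""
    if n <= p + 1:
        raise ValueError("adjusted R² needs n > p + 1")
    if total_ss == 0:
        return 1.0 if residual_ss == 0 else float("-inf")
    r2 = 1.0 - residual_ss / total_ss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass(frozen=True)
class HarmonicFit:
    """Least-squares Fourier fit with fixed 24-h fundamental period."""

    mesor: float
    cos_coef: np.ndarray  # a_k, k = 1..K
    sin_coef: np.ndarray  # b_k
    period_h: float
    residual_ss: float
    n_params: int
    adjusted_r2: float
    converged: bool

    @property
    def n_harmonics(self) -> int:
        return len(self.cos_coef)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.mesor)
        for k in range(1, self.n_harmonics + 1):
            w = 2.0 * math.pi * k / self.period_h
            y = y + self.cos_coef[k - 1] * np.cos(w * t) + self.sin_coef[k - 1] * np.sin(w * t)
        return y


@dataclass(frozen=True)
class SkewedFit:
    """Skewed bimodal cosine fit (6 free parameters)."""

    baseline: float
    amplitude: float
    phase_h: float
    skew: float
    bimodality: float
    shape_nu: float
    period_h: float
    residual_ss: float
    adjusted_r2: float
    converged: bool

    def predict(self, t) -> np.ndarray:
        return skewed_eval(
            t, self.baseline, self.amplitude, self.phase_h,
            self.skew, self.bimodality, self.shape_nu, self.period_h,
        )


@dataclass(frozen=True)
class NosaFit:
    """NOSA result: amplitude = (fitted max - fitted min)/2."""

    amplitude: float
    fit_peak: float
    fit_trough: float
    period_h: float
    residual_ss: float


def _fourier_design(t: np.ndarray, n_harmonics: int, period_h: float) -> np.ndarray:
    cols = [np.ones_like(t)]
    for k in range(1, n_harmonics + 1):
        w = 2.0 * math.pi * k / period_h
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    return np.column_stack(cols)


def fit_fourier(s: SampleSeries, K: int = 2, period_h: float = 24.0) -> HarmonicFit:
    """Fit mesor + K harmonics of a fixed 24-h period by linear least squares.

    K = 2 is the 5-parameter F(2) model (fundamental plus second harmonic);
    K = 3 is the 7-parameter F(3).
    """
    if K not in (2, 3):
        raise ValueError("K must be 2 or 3")
    n_params = 2 * K + 1
    if len(s) < n_params + 2:
        raise ValueError(f"F({K}) fit needs at least {n_params + 2} samples")
    if s.span_h < 20:
        raise ValueError("Fourier fit needs a span of at least 20 h")
    t, c = s.times, s.concentrations
    X = _fourier_design(t, K, period_h)
    beta, _, rank, _ = np.linalg.lstsq(X, c, rcond=None)
    converged = rank == n_params
    resid = c - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((c - c.mean()) ** 2))
    adj = adjusted_r2(rss, tss, len(c), n_params)
    return HarmonicFit(
        mesor=float(beta[0]),
        cos_coef=beta[1::2].copy(),
        sin_coef=beta[2::2].copy(),
        period_h=period_h,
        residual_ss=rss,
        n_params=n_params,
        adjusted_r2=adj,
        converged=bool(converged),
    )


def skewed_eval(t, baseline, amplitude, phase_h, skew, bimodality, nu, period_h=24.0):
    """Skewed bimodal cosine pulse:

    ``y(t) = baseline + amplitude * max(0, cos(theta~))**nu`` with
    ``theta = 2*pi*(t - phase_h)/period`` and
    ``theta~ = theta + skew*sin(theta) + bimodality*sin(2*theta)``.

    ``skew`` steepens one flank relative to the other, ``bimodality`` can
    flatten or split the peak, and ``nu`` narrows (large) or broadens (small)
    the pulse.  This is the single evaluation routine behind
    :class:`SkewedFit`; replacing the functional form means replacing only
    this function.
    """
    t = np.asarray(t, dtype=float)
    theta = 2.0 * math.pi * (t - phase_h) / period_h
    theta_w = theta + skew * np.sin(theta) + bimodality * np.sin(2.0 * theta)
    base = np.maximum(0.0, np.cos(theta_w))
    return baseline + amplitude * np.power(base, nu)


def fit_skewed(s: SampleSeries, starts: int = 8) -> SkewedFit:
    """Multistart nonlinear least-squares fit of the skewed bimodal cosine.

    The phase parameter is started on ``starts`` equispaced points across one
    period, in fixed order, so non-convergence is deterministic.  A fit where
    no start converges is returned with ``converged=False`` — a recorded
    outcome mirroring "profiles not fit" reporting, not an exception.
    """
    if len(s) < 10:
        raise ValueError("skewed fit needs at least 10 samples")
    if s.span_h < 20:
        raise ValueError("skewed fit needs a span of at least 20 h")
    t, c = s.times, s.concentrations
    cmin, cmax = float(c.min()), float(c.max())
    rng = max(cmax - cmin, 1e-12)

    def resid(x):
        b, A, phi, sk, bi, nu = x
        return skewed_eval(t, b, A, phi, sk, bi, nu) - c

    t0 = float(t[0])
    lo = [0.0, 0.0, t0 - 12.0, -1.0, -1.0, 0.5]
    hi = [max(cmax, 1e-9), 10.0 * rng, t0 + 36.0, 1.0, 1.0, 8.0]

    best = None
    for k in range(starts):
        phi0 = t0 + 24.0 * k / starts
        x0 = np.clip([cmin, rng, phi0, 0.0, 0.0, 2.0], lo, hi)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, max_nfev=300)
        except Exception:
            continue
        if not res.success:
            continue
        if best is None or res.cost < best.cost:
            best = res

    n = len(c)
    tss = float(np.sum((c - c.mean()) ** 2))
    if best is None:
        return SkewedFit(float("nan"), float("nan"), float("nan"), float("nan"),
                         float("nan"), float("nan"), 24.0, tss, float("-inf"), False)
    b, A, phi, sk, bi, nu = best.x
    rss = float(2.0 * best.cost)
    adj = adjusted_r2(rss, tss, n, 6) if n > 7 else float("-inf")
    return SkewedFit(float(b), float(A), float(phi), float(sk), float(bi),
                     float(nu), 24.0, rss, adj, True)


def curve_markers(
    fit: Union[HarmonicFit, SkewedFit],
    window: tuple[float, float],
    grid_step_h: float = 1.0 / 60.0,
) -> dict[str, MarkerEstimate]:
    """Phase markers from a fitted curve over one day window.

    Max is the earliest global maximiser on a 1-minute grid; Upcross and
    Downcross are the nearest times before/after Max where the curve crosses
    half the fitted maximum value, refined by bisection between grid points.
    Fourier fits yield {F2|F3}{Max,Upcross,Downcross}; skewed fits yield
    SkewedUpcross/SkewedDowncross only.
    """
    if not fit.converged:
        raise ValueError("curve markers need a converged fit")
    if isinstance(fit, HarmonicFit):
        prefix = f"F{fit.n_harmonics}"
        emit_max = True
    else:
        prefix = "Skewed"
        emit_max = False

    t0, t1 = window
    grid = np.arange(t0, t1 + 0.5 * grid_step_h, grid_step_h)
    y = fit.predict(grid)
    i_max = int(np.argmax(y))  # argmax returns the earliest maximiser
    t_max, y_max = float(grid[i_max]), float(y[i_max])
    level = 0.5 * y_max

    out: dict[str, MarkerEstimate] = {}
    if emit_max:
        out[f"{prefix}Max"] = MarkerEstimate(f"{prefix}Max", t_max, True)

    def cross(name: str, rising: bool) -> MarkerEstimate:
        f = lambda tt: float(fit.predict(np.array([tt]))[0]) - level
        if rising:
            idx = np.flatnonzero(y[: i_max + 1] <= level)
            if len(idx) == 0:
                return MarkerEstimate(name, None, False,
                                      "curve never below half-max before peak")
            i = int(idx[-1])
            a, bb = grid[i], grid[min(i + 1, i_max)]
        else:
            idx = np.flatnonzero(y[i_max:] <= level)
            if len(idx) == 0:
                return MarkerEstimate(name, None, False,
                                      "curve never below half-max after peak")
            i = i_max + int(idx[0])
            a, bb = grid[max(i - 1, i_max)], grid[i]
        if a == bb or f(a) * f(bb) > 0:
            # crossing sits exactly on a grid point
            tcross = a if abs(f(a)) <= abs(f(bb)) else bb
            return MarkerEstimate(name, float(tcross), True)
        return MarkerEstimate(name, float(brentq(f, a, bb, xtol=1e-10)), True)

    out[f"{prefix}Upcross"] = cross(f"{prefix}Upcross", rising=True)
    out[f"{prefix}Downcross"] = cross(f"{prefix}Downcross", rising=False)
    return out


def _refine_extremum(curve, grid, y, i, maximum: bool) -> float:
    """Polish a grid extremum of a smooth curve by bounded 1-D optimisation
    (a grid-only extremum is quantised by the evaluation step)."""
    from scipy.optimize import minimize_scalar

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        return float(y[i])
    sign = -1.0 if maximum else 1.0
    res = minimize_scalar(lambda tt: sign * curve(tt), bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-10})
    val = sign * float(res.fun)
    grid_val = float(y[i])
    return max(val, grid_val) if maximum else min(val, grid_val)


def nosa_fit(
    s: SampleSeries,
    n_harmonics: int = 3,
    period_grid: tuple[float, float, float] = (23.5, 24.5, 0.01),
) -> NosaFit:
    """Non-orthogonal spectral analysis of one calibration day.

    A mesor plus ``n_harmonics`` harmonic pairs of a common fundamental
    period is fit by linear least squares at every period on the scan grid
    (default 23.5-24.5 h in 0.01-h steps; "non-orthogonal" because sampling
    and period are incommensurate); the period with minimal residual wins.
    Amplitude is half the fitted peak-to-trough range; peak and trough feed
    the 25% relative DLMO threshold.
    """
    n_params = 2 * n_harmonics + 1
    if len(s) < n_params + 2:
        raise ValueError("NOSA needs more samples than parameters")
    t, c = s.times, s.concentrations
    lo, hi, step = period_grid
    periods = np.arange(lo, hi + 0.5 * step, step)

    best_rss, best_T, best_beta = math.inf, None, None
    for T in periods:
        X = _fourier_design(t, n_harmonics, T)
        beta, _, rank, _ = np.linalg.lstsq(X, c, rcond=None)
        if rank < n_params:
            continue
        r = c - X @ beta
        rss = float(r @ r)
        if rss < best_rss:
            best_rss, best_T, best_beta = rss, float(T), beta
    if best_T is None:
        raise ValueError("NOSA design matrix rank-deficient at every period")

    grid = np.arange(t[0], t[-1] + 1e-9, 1.0 / 60.0)
    X = _fourier_design(grid, n_harmonics, best_T)
    y = X @ best_beta

    def curve(tt):
        row = _fourier_design(np.atleast_1d(float(tt)), n_harmonics, best_T)
        return float((row @ best_beta)[0])

    peak = _refine_extremum(curve, grid, y, int(np.argmax(y)), maximum=True)
    trough = _refine_extremum(curve, grid, y, int(np.argmin(y)), maximum=False)
    return NosaFit(
        amplitude=0.5 * (peak - trough),
        fit_peak=peak,
        fit_trough=trough,
        period_h=best_T,
        residual_ss=best_rss,
    )
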