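"""Physiologically based linear differential-equation model of melatonin.

The model follows the two-compartment picture of pineal synthesis and plasma
clearance: melatonin is synthesised in the pineal (compartment H1), infused
into plasma (H2) at rate ``beta_I`` and cleared from plasma at rate
``beta_C``::

    dH1/dt = -beta_I * H1 + u(t)
    dH2/dt =  beta_I * H1 - beta_C * H2

with measured concentration ``b + H2(t)``.  The synthesis drive ``u(t)`` is
zero before onset ``t_on``, a saturating ramp ``A * (1 - exp(-alpha (t -
t_on)))`` between onset and offset, and an exponential decay at rate
``delta`` after offset ``t_off``.  Onset and offset of this drive are the
physiological phase markers Syn-on and Syn-off.

Exactly nine parameters are fit: ``t_on, t_off, A, alpha, delta, beta_I,
beta_C, b, H2_0``.  The precise ramp/decay forcing is this package's
rendering of the synthesis drive; it is isolated behind
:func:`synthesis_rate` and :func:`_segment_forcing` so a different
parameterisation can be swapped without touching the fitter.  The system is
linear, so the solution with piecewise-exponential forcing is available in
closed form (:func:`simulate_analytic`); :func:`simulate` integrates the same
system numerically and the two routes cross-check each other.  An optional
light-suppression input is deliberately absent: the intended data are
dim-light protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .profile_core import SampleSeries

__all__ = [
    "PhysioParams",
    "PhysioFit",
    "synthesis_rate",
    "simulate",
    "simulate_analytic",
    "fit_physio",
]


@dataclass(frozen=True)
class PhysioParams:
    """The nine parameters of the differential-equation model.

    Times are decimal hours on the same clock as the data; rates are 1/h;
    ``A`` is the maximal synthesis rate in concentration units per hour;
    ``b`` is the assay baseline and ``H2_0`` the plasma level at the first
    sample time.
    """

    t_on: float
    t_off: float
    A: float
    alpha: float
    delta: float
    beta_I: float
    beta_C: float
    b: float
    H2_0: float

    def __post_init__(self) -> None:
        if not self.t_on < self.t_off:
            raise ValueError("t_on must precede t_off")
        for name in ("alpha", "delta", "beta_I", "beta_C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PhysioFit:
    """Result of the nine-parameter fit.  Syn-on = t_on, Syn-off = t_off."""

    params: Optional[PhysioParams]
    converged: bool
    adjusted_r2: float
    residual_ss: float
    note: str = ""

    @property
    def syn_on(self) -> float:
        if not self.converged:
            raise ValueError("fit did not converge")
        return self.params.t_on

    @property
    def syn_off(self) -> float:
        if not self.converged:
            raise ValueError("fit did not converge")
        return self.params.t_off


def synthesis_rate(t, p: PhysioParams):
    """Pineal synthesis drive u(t): 0, saturating ramp, exponential decay.

    Continuous everywhere, non-negative, bounded by ``A``.
    """
    t = np.asarray(t, dtype=float)
    u = np.zeros_like(t)
    rising = (t >= p.t_on) & (t < p.t_off)
    u[rising] = p.A * (1.0 - np.exp(-p.alpha * (t[rising] - p.t_on)))
    u_off = p.A * (1.0 - math.exp(-p.alpha * (p.t_off - p.t_on)))
    falling = t >= p.t_off
    u[falling] = u_off * np.exp(-p.delta * (t[falling] - p.t_off))
    return u if u.ndim else float(u)


def _separate(rates: Sequence[float], eps: float = 1e-9) -> list[float]:
    """Nudge rates apart so exponential-pole denominators never vanish.

    The closed form divides by differences of rates; coincident rates are a
    measure-zero degeneracy handled by a deterministic 1e-9-relative nudge.
    """
    out = list(map(float, rates))
    for i in range(1, len(out)):
        for j in range(i):
            if abs(out[i] - out[j]) < eps * max(1.0, abs(out[j])):
                out[i] = out[j] * (1.0 + 10 * eps) + 10 * eps
    return out


def _segment_forcing(p: PhysioParams, ta: float) -> tuple[float, float, float]:
    """Forcing on the segment starting at ``ta``, as (const, coef, rate):
    u(ta + s) = const + coef * exp(-rate * s)."""
    if ta < p.t_on:
        return 0.0, 0.0, 1.0
    if ta < p.t_off:
        return p.A, -p.A * math.exp(-p.alpha * (ta - p.t_on)), p.alpha
    u_off = p.A * (1.0 - math.exp(-p.alpha * (p.t_off - p.t_on)))
    return 0.0, u_off * math.exp(-p.delta * (ta - p.t_off)), p.delta


def _breakpoints(p: PhysioParams, t0: float, t1: float) -> list[float]:
    bps = [t0]
    for tc in (p.t_on, p.t_off):
        if t0 < tc < t1:
            bps.append(tc)
    bps.append(t1)
    return bps


def simulate_analytic(p: PhysioParams, times) -> np.ndarray:
    """Closed-form solution of the model at the requested times.

    With forcing const + coef*exp(-r s) on each segment, H1 and H2 are sums
    of at most four exponentials; the segments are chained exactly.  Initial
    conditions H1 = 0, H2 = H2_0 hold at ``times[0]``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be increasing")

    h1, h2 = 0.0, p.H2_0
    out = np.empty_like(times)
    t0, t1 = float(times[0]), float(times[-1])
    bps = _breakpoints(p, t0, t1)
    for ta, tb in zip(bps[:-1], bps[1:]):
        const, coef, rate = _segment_forcing(p, ta)
        bI, bC, r = _separate([p.beta_I, p.beta_C, rate])

        # H1(s) = c0 + c1 e^{-bI s} + c2 e^{-r s}
        c0 = const / bI
        c2 = coef / (bI - r)
        c1 = h1 - c0 - c2
        # H2(s) = d0 + d1 e^{-bI s} + d2 e^{-r s} + dh e^{-bC s}
        d0 = bI * c0 / bC
        d1 = bI * c1 / (bC - bI)
        d2 = bI * c2 / (bC - r)
        dh = h2 - d0 - d1 - d2

        last = tb >= t1
        sel = (times >= ta) & ((times <= tb) if last else (times < tb))
        s = times[sel] - ta
        e_bI, e_r, e_bC = np.exp(-bI * s), np.exp(-r * s), np.exp(-bC * s)
        out[sel] = d0 + d1 * e_bI + d2 * e_r + dh * e_bC

        sL = tb - ta
        h1 = c0 + c1 * math.exp(-bI * sL) + c2 * math.exp(-r * sL)
        h2 = (
            d0
            + d1 * math.exp(-bI * sL)
            + d2 * math.exp(-r * sL)
            + dh * math.exp(-bC * sL)
        )
    return p.b + out


def simulate(
    p: PhysioParams, times, rtol: float = 1e-8, atol: float = 1e-10
) -> np.ndarray:
    """Numerically integrate the model and return ``b + H2`` at ``times``.

    Integration restarts at t_on and t_off so the adaptive solver never
    smooths across the switch points.  Output is linear in ``A`` (superposed
    on the homogeneous decay of ``H2_0``).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be increasing")

    def rhs(t, y):
        u = synthesis_rate(t, p)
        return [-p.beta_I * y[0] + u, p.beta_I * y[0] - p.beta_C * y[1]]

    t0, t1 = float(times[0]), float(times[-1])
    y = np.array([0.0, p.H2_0])
    out = np.empty_like(times)
    out[times == t0] = y[1]
    if t1 == t0:
        return p.b + out

    bps = _breakpoints(p, t0, t1)
    for ta, tb in zip(bps[:-1], bps[1:]):
        sel = (times > ta) & (times <= tb)
        # always land on tb so the next segment starts exactly at the switch
        t_eval = np.unique(np.append(times[sel], tb))
        sol = solve_ivp(
            rhs, (ta, tb), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed for params {p}: {sol.message}")
        lookup = dict(zip(sol.t, sol.y[1]))
        out[sel] = [lookup[tt] for tt in times[sel]]
        y = sol.y[:, -1]
    return p.b + out


def _rise_init(times: np.ndarray, conc: np.ndarray) -> float:
    """Scale-free onset initialiser: interpolated time at which the profile
    first rises through 20% of its own range."""
    lo, hi = float(conc.min()), float(conc.max())
    if hi <= lo:
        return float(times[0] + 0.5 * (times[-1] - times[0]))
    level = lo + 0.2 * (hi - lo)
    above = conc > level
    for i in range(len(conc) - 1):
        if not above[i] and above[i + 1]:
            frac = (level - conc[i]) / (conc[i + 1] - conc[i])
            return float(times[i] + frac * (times[i + 1] - times[i]))
    return float(times[0] + 0.5 * (times[-1] - times[0]))


def fit_physio(
    s: SampleSeries,
    starts: int = 8,
    amplitude_floor_snr: float = 4.0,
) -> PhysioFit:
    """Fit all nine model parameters by bounded nonlinear least squares.

    Multistart over onset/duration initialisations in a fixed order, so a
    failure to fit is deterministic and reproducible.  ``converged`` is False
    when no start converges or when the fitted pulse is indistinguishable
    from the residual noise (flat, low-amplitude profiles) — a recorded
    outcome, not an error.
    """
    if len(s) < 12:
        raise ValueError("physio fit needs at least 12 samples")
    if s.span_h < 20:
        raise ValueError("physio fit needs a span of at least 20 h")

    t_ref = float(s.times[0])
    t = s.times - t_ref
    c = s.concentrations
    t_end = float(t[-1])
    cmax = float(c.max())
    if cmax <= 0:
        return PhysioFit(None, False, float("-inf"), float(np.sum(c**2)),
                         note="all-zero profile")
    if np.ptp(c) == 0:
        return PhysioFit(None, False, float("-inf"), 0.0, note="constant profile")

    def unpack(x):
        t_on, dur, A, alpha, delta, bI, bC, b, h2 = x
        return PhysioParams(t_on, t_on + dur, A, alpha, delta, bI, bC, b, h2)

    def resid(x):
        return simulate_analytic(unpack(x), t) - c

    # duration bounded below at 4 h: human secretion episodes last hours, and
    # the bound stops the fit collapsing onto short noise excursions
    lo = [0.0, 4.0, 1e-6, 1e-3, 1e-3, 1e-3, 1e-3, 0.0, 0.0]
    hi = [t_end - 2.0, 18.0, 100.0 * cmax, 10.0, 10.0, 10.0, 10.0, cmax, 10.0 * cmax]

    t_on0 = _rise_init(t, c)
    b0 = float(np.percentile(c, 10))
    A0 = max(cmax - b0, 1e-3) * 0.9  # plateau ~ A/beta_C at beta_C ~ 0.9/h
    inits = []
    for d_on in (0.0, -1.0, 1.0, -2.0):
        for dur0 in (9.0, 12.0):
            inits.append([t_on0 + d_on, dur0, A0, 1.5, 1.2, 1.2, 0.9, b0, c[0]])
    inits = inits[:starts]

    best = None
    for x0 in inits:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=400)
        except Exception:
            continue
        if not res.success:
            continue
        if best is None or res.cost < best.cost:
            best = res

    n = len(c)
    tss = float(np.sum((c - c.mean()) ** 2))
    if best is None:
        return PhysioFit(None, False, float("-inf"), tss, note="no start converged")

    params = unpack(best.x)
    rss = float(2.0 * best.cost)
    model = simulate_analytic(params, t)
    pulse_amp = float(model.max() - params.b)
    noise_rms = math.sqrt(rss / max(n - 9, 1))
    # floor is relative to the data scale, so flagging is scale-equivariant:
    # a fitted pulse under 4x the residual noise or under 5% of the data
    # range is indistinguishable from baseline
    floor = max(amplitude_floor_snr * noise_rms, 0.05 * float(np.ptp(c)))
    if pulse_amp < floor:
        return PhysioFit(None, False, float("-inf"), rss,
                         note="fitted amplitude indistinguishable from noise")

    from .curvefit_markers import adjusted_r2 as _adj

    adj = _adj(rss, tss, n, 9) if n > 10 and tss > 0 else float("-inf")
    shifted = PhysioParams(
        params.t_on + t_ref, params.t_off + t_ref, params.A, params.alpha,
        params.delta, params.beta_I, params.beta_C, params.b, params.H2_0,
    )
    return PhysioFit(shifted, True, adj, rss)
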