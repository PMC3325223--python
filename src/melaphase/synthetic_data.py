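"""Synthetic multi-day melatonin profiles with known ground truth.

Real inpatient melatonin series (constant-routine and forced-desynchrony
protocols) are not redistributable, so analyses here run on generated
profiles that reproduce the statistical structure those protocols assume:

* a unimodal, asymmetric nocturnal secretion pulse produced by the
  physiological two-compartment model (onset ~2 h before habitual bedtime,
  saturating rise, slower decay after synthesis offset);
* inter-subject amplitude variation spanning roughly an order of magnitude;
* day-to-day phase drift from a non-24-h intrinsic period (population mean
  ~24.15 h): day d's synthesis onset moves by (period - 24) h per day,
  exactly linearly — zero curvature by construction;
* 30- or 60-min sampling on a 24-h day window scheduled relative to the subject's habitual onset, so each day's
  series contains one complete pulse;
* multiplicative lognormal assay noise with a configurable CV;
* injectable contiguous data gaps.

Amplitude and pulse duration are held constant across a subject's days;
slow multi-day parameter change is deliberately left unmodelled.  Light-
driven melatonin suppression is out of scope (dim-light protocols).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .profile_core import SampleSeries, PMOL_PER_L
from .physio_model import PhysioParams, simulate_analytic

__all__ = [
    "SubjectScenario",
    "GapSpec",
    "CohortRanges",
    "simulate_subject",
    "inject_gap",
    "simulate_cohort",
    "simulate_marker_phases",
    "BASELINE_LEAD_H",
]

#: Sampling for day d starts BASELINE_LEAD_H before the subject's day-1
#: synthesis onset, i.e. at 24*(d-1) + onset_clock_h - BASELINE_LEAD_H, the
#: way inpatient protocols schedule sampling relative to habitual bedtime.
#: Each 24-h window then holds one complete nocturnal pulse — daytime
#: baseline, evening rise, overnight plateau and the full morning falling
#: limb back to baseline — for every admissible onset/duration combination.
BASELINE_LEAD_H = 7.5

# Physiological defaults (rates in 1/h, A in pmol/L/h): plasma clearance
# half-life ~45 min, synthesis shutdown over ~40 min, plateau concentration
# ~109 pmol/L at amplitude_scale 1.  The full pulse (rise, plateau, fall to
# near baseline) must fit inside one 24-h day window.
_A_REF = 100.0
_ALPHA = 1.5
_DELTA = 1.4
_BETA_I = 1.2
_BETA_C = 0.92
_BASELINE = 2.5


@dataclass(frozen=True)
class SubjectScenario:
    """Everything that determines one subject's multi-day profile."""

    intrinsic_period_h: float = 24.15
    onset_clock_h: float = 21.5
    secretion_duration_h: float = 10.0
    amplitude_scale: float = 1.0
    noise_cv: float = 0.10
    sampling_interval_h: float = 0.5
    n_days: int = 3
    seed: int = 0
    subject_id: str = "S1"

    def __post_init__(self) -> None:
        if not 23.0 <= self.intrinsic_period_h <= 26.0:
            raise ValueError("intrinsic_period_h must lie in [23, 26]")
        if not 6.0 <= self.secretion_duration_h <= 14.0:
            raise ValueError("secretion_duration_h must lie in [6, 14]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.sampling_interval_h not in (0.5, 1.0):
            raise ValueError("sampling_interval_h must be 0.5 or 1.0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be > 0")


@dataclass(frozen=True)
class GapSpec:
    """A contiguous block of missing data on the study clock."""

    start_h: float
    length_h: float = 2.0

    def __post_init__(self) -> None:
        if self.length_h <= 0:
            raise ValueError("length_h must be > 0")


def _pulse_times(sc: SubjectScenario) -> list[tuple[float, float]]:
    """(t_on, t_off) per day on the continuous study clock.  Drift is uniform:
    day d's onset sits at onset_clock_h + (d-1)*(period - 24) on the local
    clock, i.e. 24*(d-1) + that on the study clock."""
    drift = sc.intrinsic_period_h - 24.0
    out = []
    for d in range(1, sc.n_days + 1):
        on = 24.0 * (d - 1) + sc.onset_clock_h + (d - 1) * drift
        out.append((on, on + sc.secretion_duration_h))
    return out


def _noiseless_concentration(sc: SubjectScenario, times: np.ndarray) -> np.ndarray:
    """Superpose per-pulse responses of the linear model (linearity makes the
    multi-day solution an exact sum of single-pulse solutions)."""
    A = _A_REF * sc.amplitude_scale
    total = np.zeros_like(times)
    for t_on, t_off in _pulse_times(sc):
        p = PhysioParams(t_on, t_off, A, _ALPHA, _DELTA, _BETA_I, _BETA_C, 0.0, 0.0)
        # evaluate from study start so every pulse shares the same origin
        eval_times = np.concatenate([[0.0], times])
        total += simulate_analytic(p, eval_times)[1:]
    return _BASELINE + total


def simulate_subject(
    sc: SubjectScenario,
) -> tuple[list[SampleSeries], dict]:
    """Generate one subject's per-day series plus the ground-truth record.

    Returns ``(series, truth)`` where ``series`` holds one
    :class:`SampleSeries` per day (bedtime-anchored windows, pmol/L) and
    ``truth`` records the true per-day synthesis onset/offset (``syn_on``,
    ``syn_off``, study clock) and the generating parameters.
    """
    rng = np.random.default_rng(sc.seed)
    pulses = _pulse_times(sc)
    series = []
    for d in range(1, sc.n_days + 1):
        start = 24.0 * (d - 1) + sc.onset_clock_h - BASELINE_LEAD_H
        times = np.arange(start, start + 24.0, sc.sampling_interval_h)
        conc = _noiseless_concentration(sc, times)
        if sc.noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + sc.noise_cv**2))
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(times))
            conc = conc * noise
        series.append(
            SampleSeries(
                subject_id=sc.subject_id,
                day_index=d,
                times=times,
                concentrations=conc,
                units=PMOL_PER_L,
            )
        )
    truth = {
        "subject_id": sc.subject_id,
        "syn_on": [on for on, _ in pulses],
        "syn_off": [off for _, off in pulses],
        "drift_h_per_day": sc.intrinsic_period_h - 24.0,
        "amplitude_scale": sc.amplitude_scale,
        "A": _A_REF * sc.amplitude_scale,
        "alpha": _ALPHA,
        "delta": _DELTA,
        "beta_I": _BETA_I,
        "beta_C": _BETA_C,
        "baseline": _BASELINE,
    }
    return series, truth


def inject_gap(s: SampleSeries, g: GapSpec) -> SampleSeries:
    """Remove all samples with time in [start_h, start_h + length_h)."""
    keep = ~((s.times >= g.start_h) & (s.times < g.start_h + g.length_h))
    if not keep.any():
        raise ValueError("gap would remove every sample")
    return replace(s, times=s.times[keep], concentrations=s.concentrations[keep])


@dataclass(frozen=True)
class CohortRanges:
    """Sampling distributions for per-subject scenario draws.

    ``onset_clock_h`` and ``secretion_duration_h`` are uniform ranges;
    ``amplitude_scale`` is lognormal with median 1 and the given sigma (a
    point mass when sigma is 0); intrinsic period is normal truncated to
    [23, 26].
    """

    onset_range_h: tuple[float, float] = (20.0, 23.0)
    duration_range_h: tuple[float, float] = (8.0, 12.0)
    amplitude_log_sigma: float = 0.5
    amplitude_median: float = 1.0
    period_mean_h: float = 24.15
    period_sd_h: float = 0.2
    noise_cv: float = 0.10
    sampling_interval_h: float = 0.5
    n_days: int = 3


def simulate_cohort(
    n_subjects: int,
    ranges: CohortRanges = CohortRanges(),
    seed: int = 0,
) -> list[tuple[list[SampleSeries], dict]]:
    """Draw ``n_subjects`` scenarios and simulate each subject.

    Deterministic under ``seed``: subject k's profile noise uses a child seed
    derived from the cohort seed, so cohorts are reproducible sample by
    sample.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_subjects):
        period = float(np.clip(rng.normal(ranges.period_mean_h, ranges.period_sd_h),
                               23.0, 26.0))
        onset = float(rng.uniform(*ranges.onset_range_h))
        dur = float(rng.uniform(*ranges.duration_range_h))
        amp = float(ranges.amplitude_median
                    * math.exp(rng.normal(0.0, ranges.amplitude_log_sigma))
                    if ranges.amplitude_log_sigma > 0 else ranges.amplitude_median)
        sc = SubjectScenario(
            intrinsic_period_h=period,
            onset_clock_h=onset,
            secretion_duration_h=dur,
            amplitude_scale=amp,
            noise_cv=ranges.noise_cv,
            sampling_interval_h=ranges.sampling_interval_h,
            n_days=ranges.n_days,
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=f"S{k + 1:03d}",
        )
        out.append(simulate_subject(sc))
    return out


def simulate_marker_phases(
    n_subjects: int,
    slope_h_per_day: float = 0.15,
    residual_sd_h: float = 0.03,
    n_days: int = 3,
    intercept_range_h: tuple[float, float] = (20.0, 23.0),
    quadratic_h_per_day2: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Phase estimates on the continuous study clock, generated directly.

    Day d's phase for subject i is
    ``24*(d-1) + c_i + slope*(d-1) + quad*(d-1)**2 + eps`` with iid normal
    residuals — the measurement model the drift-decomposition analysis
    assumes.  Used for calibration studies of the variability pipeline where
    simulating full profiles would only add cost, not structure.

    Returns an (n_subjects, n_days) array.
    """
    rng = np.random.default_rng(seed)
    c = rng.uniform(*intercept_range_h, size=n_subjects)
    d = np.arange(n_days, dtype=float)
    base = 24.0 * d + c[:, None] + slope_h_per_day * d + quadratic_h_per_day2 * d**2
    return base + rng.normal(0.0, residual_sd_h, size=(n_subjects, n_days))
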