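"""Threshold-based phase markers.

Two families:

* **DLMO** (dim light melatonin onset) against an absolute threshold — the
  conventional 10 pg/ml (43.08 pmol/L) — either as the first suprathreshold
  sample time (``DLMOpost-threshold``) or the linearly interpolated crossing
  (``DLMOinterpolated``); and against an individualised relative threshold at
  25% of the fitted peak-to-trough range (``DLMOn25%`` / ``DLMOff25%``) with
  a two-consecutive-sample sustain rule.
* **24-h mean** crossings: the profile's own 24-h mean as threshold, giving
  ``24hUpcross``, ``24hDowncross`` and their average ``24hMidpoint``.

Tie policy: "exceeds" is strict (>) everywhere; a sample exactly at the
threshold belongs to the earlier (sub-threshold) side.  This makes
``DLMOinterpolated <= DLMOpost-threshold`` hold unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .profile_core import SampleSeries, PMOL_PER_L, convert_units

__all__ = [
    "MarkerEstimate",
    "DLMO_THRESHOLD_PMOLL",
    "dlmo_post_threshold",
    "dlmo_interpolated",
    "relative_threshold",
    "dlmo_on25_off25",
    "mean24_crossings",
]

#: The conventional DLMO threshold: 10 pg/ml expressed in pmol/L.
DLMO_THRESHOLD_PMOLL = 43.08


@dataclass(frozen=True)
class MarkerEstimate:
    """One named phase-marker value on the continuous study clock."""

    marker: str
    phase_h: Optional[float]
    converged: bool
    note: str = ""

    def __post_init__(self) -> None:
        if not self.converged and self.phase_h is not None:
            raise ValueError("non-converged estimate cannot carry a phase")


def _not_fit(marker: str, note: str) -> MarkerEstimate:
    return MarkerEstimate(marker, None, False, note)


def _as_pmol(s: SampleSeries) -> SampleSeries:
    return convert_units(s, PMOL_PER_L)


def _interp_time(t0, c0, t1, c1, level) -> float:
    return float(t0 + (level - c0) / (c1 - c0) * (t1 - t0))


def dlmo_post_threshold(
    s: SampleSeries, threshold: float = DLMO_THRESHOLD_PMOLL
) -> MarkerEstimate:
    """Time of the first sample strictly above the threshold (pmol/L)."""
    s = _as_pmol(s)
    if len(s) == 0:
        raise ValueError("empty series")
    above = np.flatnonzero(s.concentrations > threshold)
    if len(above) == 0:
        return _not_fit("DLMOpost-threshold", "no sample exceeds threshold")
    return MarkerEstimate("DLMOpost-threshold", float(s.times[above[0]]), True)


def dlmo_interpolated(
    s: SampleSeries, threshold: float = DLMO_THRESHOLD_PMOLL
) -> MarkerEstimate:
    """Linearly interpolated first rising crossing of the threshold.

    The crossing is taken between the last sample <= threshold and the first
    subsequent sample > threshold.  A series already above the threshold at
    its first sample yields that sample time (no left bracket exists).
    """
    s = _as_pmol(s)
    if len(s) == 0:
        raise ValueError("empty series")
    c, t = s.concentrations, s.times
    above = c > threshold
    if not above.any():
        return _not_fit("DLMOinterpolated", "no sample exceeds threshold")
    i = int(np.flatnonzero(above)[0])
    if i == 0:
        return MarkerEstimate(
            "DLMOinterpolated", float(t[0]), True, "series starts above threshold"
        )
    phase = _interp_time(t[i - 1], c[i - 1], t[i], c[i], threshold)
    return MarkerEstimate("DLMOinterpolated", phase, True)


def relative_threshold(fit_peak: float, fit_trough: float, frac: float = 0.25) -> float:
    """Individualised threshold at ``frac`` of the fitted peak-to-trough
    range: ``trough + frac * (peak - trough)``.

    Peak and trough come from the harmonic (NOSA) fit of the designated
    calibration day.
    """
    if not fit_peak > fit_trough:
        raise ValueError("fit_peak must exceed fit_trough")
    return fit_trough + frac * (fit_peak - fit_trough)


def _sustained_rising(c: np.ndarray, thr: float, sustain: int) -> Optional[int]:
    """Index i of the first rising crossing (c[i] <= thr < c[i+1]) followed by
    ``sustain`` consecutive suprathreshold samples; None if absent."""
    for i in range(len(c) - sustain):
        if c[i] <= thr and all(c[i + 1 + k] > thr for k in range(sustain)):
            return i
    return None


def _sustained_falling(c: np.ndarray, thr: float, sustain: int) -> Optional[int]:
    """Index i of the last falling crossing (c[i] > thr >= c[i+1]) followed by
    ``sustain`` consecutive subthreshold samples; None if absent."""
    found = None
    for i in range(len(c) - sustain):
        if c[i] > thr and all(c[i + 1 + k] <= thr for k in range(sustain)):
            found = i
    return found


def dlmo_on25_off25(
    s: SampleSeries, threshold: float, sustain: int = 2
) -> tuple[MarkerEstimate, MarkerEstimate]:
    """Onset/offset crossings of a relative threshold, sustained for at least
    ``sustain`` consecutive samples (single-sample blips are rejected).

    Returns (``DLMOn25%``, ``DLMOff25%``): the interpolated first sustained
    rising crossing and last sustained falling crossing of the raw data.
    """
    s = _as_pmol(s)
    if len(s) < sustain + 1:
        raise ValueError("series too short for the sustain rule")
    t, c = s.times, s.concentrations

    i_on = _sustained_rising(c, threshold, sustain)
    if i_on is None:
        onset = _not_fit("DLMOn25%", "no sustained rising crossing")
    else:
        onset = MarkerEstimate(
            "DLMOn25%", _interp_time(t[i_on], c[i_on], t[i_on + 1], c[i_on + 1], threshold), True
        )

    i_off = _sustained_falling(c, threshold, sustain)
    if i_off is None:
        offset = _not_fit("DLMOff25%", "no sustained falling crossing")
    else:
        offset = MarkerEstimate(
            "DLMOff25%",
            _interp_time(t[i_off], c[i_off], t[i_off + 1], c[i_off + 1], threshold),
            True,
        )
    return onset, offset


def mean24_crossings(
    s: SampleSeries,
) -> tuple[MarkerEstimate, MarkerEstimate, MarkerEstimate]:
    """Crossings of the 24-h mean level: (24hUpcross, 24hMidpoint, 24hDowncross).

    The threshold is the arithmetic mean of the window's samples.  With
    multiple crossings the first rising and last falling are used; the
    midpoint is their average by construction.
    """
    s = _as_pmol(s)
    if s.span_h < 20:
        raise ValueError("24-h mean markers need a series spanning >= 20 h")
    t, c = s.times, s.concentrations
    thr = float(c.mean())

    i_up = None
    for i in range(len(c) - 1):
        if c[i] <= thr < c[i + 1]:
            i_up = i
            break
    i_dn = None
    for i in range(len(c) - 1):
        if c[i] > thr >= c[i + 1]:
            i_dn = i

    if i_up is None or i_dn is None:
        note = "no rising crossing of 24-h mean" if i_up is None else "no falling crossing of 24-h mean"
        return (
            _not_fit("24hUpcross", note),
            _not_fit("24hMidpoint", note),
            _not_fit("24hDowncross", note),
        )
    up = _interp_time(t[i_up], c[i_up], t[i_up + 1], c[i_up + 1], thr)
    dn = _interp_time(t[i_dn], c[i_dn], t[i_dn + 1], c[i_dn + 1], thr)
    return (
        MarkerEstimate("24hUpcross", up, True),
        MarkerEstimate("24hMidpoint", 0.5 * (up + dn), True),
        MarkerEstimate("24hDowncross", dn, True),
    )
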