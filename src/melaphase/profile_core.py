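"""Data model, CSV I/O, unit conversion and completeness validation.

A :class:`SampleSeries` holds one subject-day (or multi-day) melatonin time
series on a *continuous study clock*: decimal hours since study start, so
day 2 begins at 24.0 and no downstream line fit ever has to unwrap midnight.

Units are plasma conventions: pmol/L or pg/ml.  The conversion factor is
pinned at 4.308 so that the customary 10 pg/ml DLMO threshold maps to exactly
43.08 pmol/L, the pair printed in the clinical literature; recomputing the
factor from melatonin's molecular weight would move thresholds by rounding.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

PMOL_PER_L = "pmol_per_L"
PG_PER_ML = "pg_per_ml"
_UNITS = (PMOL_PER_L, PG_PER_ML)

#: pg/ml -> pmol/L.  10 pg/ml == 43.08 pmol/L exactly.
PGML_TO_PMOLL = 4.308

#: Nominal "complete" sampling schedule: one sample per hour.  Missing time is
#: accounted against this grid, so 30-min sampling never creates negative
#: missingness.
NOMINAL_INTERVAL_H = 1.0


@dataclass(frozen=True)
class SampleSeries:
    """One melatonin concentration time series.

    Parameters
    ----------
    subject_id : str
        Opaque subject label.
    day_index : int
        Study day, 1-based.
    times : ndarray
        Strictly increasing sample times, decimal hours on the continuous
        study clock.
    concentrations : ndarray
        Non-negative melatonin concentrations, same length as ``times``.
    units : str
        ``"pmol_per_L"`` or ``"pg_per_ml"``.
    """

    subject_id: str
    day_index: int
    times: np.ndarray
    concentrations: np.ndarray
    units: str = PMOL_PER_L

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if self.units not in _UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {_UNITS}")
        if t.ndim != 1 or c.ndim != 1 or len(t) != len(c):
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"times not strictly increasing at sample index {bad}")
        if np.any(c < 0):
            raise ValueError("negative concentration")
        if self.day_index < 1:
            raise ValueError("day_index must be >= 1")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span_h(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0


@dataclass(frozen=True)
class CompletenessReport:
    """Result of the complete-data-set rule.

    A series is complete when the largest consecutive run of missing data is
    under 2 h and no 24-h window is missing 6 h or more in total.
    """

    is_complete: bool
    max_consecutive_gap_h: float
    total_missing_h_per_24h: float


def convert_units(s: SampleSeries, target: str) -> SampleSeries:
    """Convert concentrations between pg/ml and pmol/L (factor 4.308)."""
    if target not in _UNITS:
        raise ValueError(f"unknown unit tag {target!r}")
    if s.units == target:
        return s
    factor = PGML_TO_PMOLL if target == PMOL_PER_L else 1.0 / PGML_TO_PMOLL
    return replace(s, concentrations=s.concentrations * factor, units=target)


def _missing_hours(times: np.ndarray) -> np.ndarray:
    """Missing time within each inter-sample interval, against the nominal
    1-sample-per-hour grid.  An interval of 2.5 h is 1.5 h missing."""
    return np.maximum(np.diff(times) - NOMINAL_INTERVAL_H, 0.0)


def check_completeness(s: SampleSeries, window_h: float = 24.0) -> CompletenessReport:
    """Apply the complete-data-set rule to one series.

    Gap accounting measures missing hours against a nominal one-sample-per-
    hour schedule: each inter-sample interval contributes
    ``max(interval - 1 h, 0)`` missing hours.  The report carries the worst
    single gap and the worst total over any sliding ``window_h`` window.
    """
    if len(s) < 2:
        raise ValueError("completeness needs at least 2 samples")
    t = s.times
    miss = _missing_hours(t)
    max_gap = float(miss.max()) if len(miss) else 0.0

    # Worst-window total: midpoints of gap intervals, swept with a window.
    mids = 0.5 * (t[:-1] + t[1:])
    worst = 0.0
    for anchor in mids:
        in_win = (mids >= anchor) & (mids < anchor + window_h)
        worst = max(worst, float(miss[in_win].sum()))
    return CompletenessReport(
        is_complete=(max_gap < 2.0 and worst < 6.0),
        max_consecutive_gap_h=max_gap,
        total_missing_h_per_24h=worst,
    )


def read_series(path: Union[str, Path, io.IOBase], units: str) -> list[SampleSeries]:
    """Read melatonin series from a CSV with columns
    ``subject,day,time_h,concentration``.

    Rows with a missing concentration are dropped: a blank cell is a gap in
    sampling, never a zero (zero is a valid low concentration).  Returns one
    :class:`SampleSeries` per (subject, day), ordered as first encountered.
    """
    if units not in _UNITS:
        raise ValueError(f"unknown unit tag {units!r}")
    # round_trip parsing: the default float parser can be 1 ulp off, which
    # breaks bit-identical write/read cycles
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"subject", "day", "time_h", "concentration"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    df["time_h"] = pd.to_numeric(df["time_h"])
    df["concentration"] = pd.to_numeric(df["concentration"])

    out: list[SampleSeries] = []
    for (subj, day), grp in df.groupby(["subject", "day"], sort=False):
        kept = grp.dropna(subset=["concentration"])
        t = kept["time_h"].to_numpy(dtype=float)
        c = kept["concentration"].to_numpy(dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
            row = int(kept.index[bad + 1]) + 2  # +2: header line + 1-based
            raise ValueError(
                f"non-monotone time for subject {subj!r} day {day}: CSV row {row}"
            )
        if np.any(c < 0):
            row = int(kept.index[np.flatnonzero(c < 0)[0]]) + 2
            raise ValueError(f"negative concentration at CSV row {row}")
        out.append(
            SampleSeries(
                subject_id=str(subj),
                day_index=int(day),
                times=t,
                concentrations=c,
                units=units,
            )
        )
    return out


def write_series(series: Iterable[SampleSeries], path: Union[str, Path]) -> None:
    """Write series to the CSV layout :func:`read_series` reads.

    Times and concentrations are written with enough digits (repr precision)
    that a read-back reproduces them bit-identically at float64.
    """
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "subject": s.subject_id,
                    "day": s.day_index,
                    "time_h": s.times,
                    "concentration": s.concentrations,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
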