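"""End-to-end orchestration: profiles -> 17 markers -> variability -> gaps.

These functions are the library behind the ``melaphase`` command line: they
take cohorts of :class:`~melaphase.profile_core.SampleSeries`, compute every
phase marker per subject-day, assemble the per-marker variability comparison
and run the gap-robustness scan.  Every non-converged fit is recorded
(subject, marker, reason) in a not-fit log rather than raised, mirroring how
method comparisons must report "profiles not fit" counts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .vocab import MARKERS
from .profile_core import SampleSeries
from .threshold_markers import (
    DLMO_THRESHOLD_PMOLL,
    MarkerEstimate,
    dlmo_interpolated,
    dlmo_post_threshold,
    dlmo_on25_off25,
    mean24_crossings,
    relative_threshold,
)
from .curvefit_markers import curve_markers, fit_fourier, fit_skewed, nosa_fit
from .physio_model import fit_physio
from .variability_pipeline import drift_removed_se

__all__ = ["estimate_day_markers", "marker_table", "variability_table", "not_fit_counts"]


def _not_fit(marker: str, note: str) -> MarkerEstimate:
    return MarkerEstimate(marker, None, False, note)


def estimate_day_markers(
    s: SampleSeries,
    threshold25: Optional[float] = None,
    abs_threshold: float = DLMO_THRESHOLD_PMOLL,
) -> dict[str, MarkerEstimate]:
    """All 17 phase markers for one subject-day series.

    ``threshold25`` is the subject's individualised 25% threshold from the
    calibration-day NOSA fit; when None, DLMOn25%/DLMOff25% are reported as
    not fit.  Fit failures become non-converged estimates, never exceptions.
    """
    out: dict[str, MarkerEstimate] = {}
    window = (float(s.times[0]), float(s.times[0]) + 24.0)

    out["DLMOpost-threshold"] = dlmo_post_threshold(s, abs_threshold)
    out["DLMOinterpolated"] = dlmo_interpolated(s, abs_threshold)

    if threshold25 is None:
        out["DLMOn25%"] = _not_fit("DLMOn25%", "no calibration-day threshold")
        out["DLMOff25%"] = _not_fit("DLMOff25%", "no calibration-day threshold")
    else:
        on, off = dlmo_on25_off25(s, threshold25)
        out["DLMOn25%"], out["DLMOff25%"] = on, off

    try:
        up, mid, down = mean24_crossings(s)
    except ValueError as e:
        up = _not_fit("24hUpcross", str(e))
        mid = _not_fit("24hMidpoint", str(e))
        down = _not_fit("24hDowncross", str(e))
    out["24hUpcross"], out["24hMidpoint"], out["24hDowncross"] = up, mid, down

    for K in (2, 3):
        names = (f"F{K}Max", f"F{K}Upcross", f"F{K}Downcross")
        try:
            fit = fit_fourier(s, K=K)
            if fit.converged:
                out.update(curve_markers(fit, window))
            else:
                for nm in names:
                    out[nm] = _not_fit(nm, "rank-deficient design")
        except ValueError as e:
            for nm in names:
                out[nm] = _not_fit(nm, str(e))

    try:
        sk = fit_skewed(s)
        if sk.converged:
            out.update(curve_markers(sk, window))
        else:
            for nm in ("SkewedUpcross", "SkewedDowncross"):
                out[nm] = _not_fit(nm, "no start converged")
    except ValueError as e:
        for nm in ("SkewedUpcross", "SkewedDowncross"):
            out[nm] = _not_fit(nm, str(e))

    try:
        pf = fit_physio(s)
        if pf.converged:
            out["Syn-on"] = MarkerEstimate("Syn-on", pf.syn_on, True)
            out["Syn-off"] = MarkerEstimate("Syn-off", pf.syn_off, True)
        else:
            out["Syn-on"] = _not_fit("Syn-on", pf.note)
            out["Syn-off"] = _not_fit("Syn-off", pf.note)
    except ValueError as e:
        out["Syn-on"] = _not_fit("Syn-on", str(e))
        out["Syn-off"] = _not_fit("Syn-off", str(e))

    return out


def marker_table(
    cohort: Sequence[Sequence[SampleSeries]],
    calibration_day: int = 1,
    abs_threshold: float = DLMO_THRESHOLD_PMOLL,
) -> pd.DataFrame:
    """Tidy table of all markers for a cohort.

    ``cohort`` is a sequence of per-subject day lists.  The 25% relative
    threshold is calibrated per subject from the NOSA fit of
    ``calibration_day`` (a config key, not inferred from the data).
    Columns: subject, day, marker, phase_h, converged, note.
    """
    rows = []
    for days in cohort:
        thr25 = None
        cal = next((d for d in days if d.day_index == calibration_day), None)
        if cal is not None:
            try:
                nf = nosa_fit(cal)
                if nf.fit_peak > nf.fit_trough:
                    thr25 = relative_threshold(nf.fit_peak, nf.fit_trough, 0.25)
            except ValueError:
                thr25 = None
        for s in days:
            ests = estimate_day_markers(s, threshold25=thr25, abs_threshold=abs_threshold)
            for m in MARKERS:
                e = ests[m]
                rows.append(
                    {
                        "subject": s.subject_id,
                        "day": s.day_index,
                        "marker": m,
                        "phase_h": e.phase_h,
                        "converged": e.converged,
                        "note": e.note,
                    }
                )
    return pd.DataFrame(rows)


def variability_table(table: pd.DataFrame, ddof: str = "n-2") -> pd.DataFrame:
    """Per subject x marker drift decomposition from a marker table.

    Subject-marker pairs missing a converged estimate on any day are
    excluded (and flagged in the returned frame's ``complete`` column as
    absent rows).  Columns: subject, marker, slope_h_per_day, with_drift_sd,
    drift_removed_se, n_days.
    """
    rows = []
    for (subj, marker), grp in table.groupby(["subject", "marker"], sort=False):
        ok = grp[grp["converged"]].sort_values("day")
        n_days_total = grp["day"].nunique()
        if len(ok) < 3 or ok["day"].nunique() < n_days_total:
            continue
        phases = ok["phase_h"].to_numpy(dtype=float)
        dec = drift_removed_se(phases, marker=marker, subject_id=str(subj), ddof=ddof)
        rows.append(
            {
                "subject": subj,
                "marker": marker,
                "slope_h_per_day": dec.slope_h_per_day,
                "with_drift_sd": dec.with_drift_sd,
                "drift_removed_se": dec.drift_removed_se,
                "n_days": len(phases),
            }
        )
    return pd.DataFrame(rows)


def not_fit_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Number (and %) of subject-days each marker failed to fit."""
    rows = []
    for marker, grp in table.groupby("marker", sort=False):
        n = len(grp)
        bad = int((~grp["converged"]).sum())
        rows.append(
            {
                "marker": marker,
                "n_profiles": n,
                "n_not_fit": bad,
                "pct_not_fit": 100.0 * bad / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
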