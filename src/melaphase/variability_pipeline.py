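"""Day-to-day variability of phase markers, with and without drift removal.

A circadian pacemaker with intrinsic period tau != 24 h makes any phase
marker drift by (tau - 24) h per day, inflating the naive day-to-day
standard deviation.  The comparison analysis therefore reports two numbers
per subject and marker over >= 3 consecutive days:

* **with-drift SD** — sample SD of the local clock hour of the estimate
  (phase mod 24);
* **drift-removed SE** — an ordinary least-squares line is fit to the
  continuous-clock phases versus day index; its slope is the drift and the
  residual standard error sqrt(SSR/(n-2)) is the variability that remains.

The uniform-drift assumption is itself testable: per subject the day-1→2
slope should equal the day-2→3 slope, checked with a paired t-test
(:func:`curvature_test`).  Variabilities are right-skewed, so cross-method
comparison log-transforms them and uses a within-subject Friedman test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DriftDecomposition",
    "CurvatureResult",
    "clock_hour_phases",
    "with_drift_sd",
    "drift_removed_se",
    "curvature_test",
    "compare_methods",
]


@dataclass(frozen=True)
class DriftDecomposition:
    """Per-subject, per-marker line fit across >= 3 consecutive days."""

    marker: str
    subject_id: str
    phases: np.ndarray  # continuous study clock, one per day
    slope_h_per_day: float
    intercept: float
    residuals: np.ndarray
    with_drift_sd: float
    drift_removed_se: float


@dataclass(frozen=True)
class CurvatureResult:
    """Paired t-test of day-1→2 vs day-2→3 slopes across subjects."""

    t: float
    df: int
    p_value: float
    n_subjects: int
    note: str = ""


def clock_hour_phases(phases: Sequence[float]) -> np.ndarray:
    """Reduce continuous-clock phases to local clock hours, unwrapped.

    Consecutive-day differences are mapped into (-12, +12] h so that an
    estimate drifting across midnight (23.9 then 24.2 -> 0.2 local) is a
    +0.3 h step, never -23.7.  The first phase anchors the sequence.
    """
    p = np.asarray(phases, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise ValueError("phases must be a non-empty 1-D sequence")
    local = np.empty_like(p)
    local[0] = p[0] % 24.0
    for i in range(1, len(p)):
        step = (p[i] - p[i - 1]) % 24.0  # expected ~0 for a daily marker
        if step > 12.0:
            step -= 24.0
        local[i] = local[i - 1] + step
    return local


def with_drift_sd(phases: Sequence[float]) -> float:
    """Sample SD (n-1) of the local clock hour of >= 3 daily estimates."""
    p = np.asarray(phases, dtype=float)
    if len(p) < 3:
        raise ValueError("with-drift SD needs >= 3 phases")
    return float(np.std(clock_hour_phases(p), ddof=1))


def drift_removed_se(
    phases: Sequence[float],
    marker: str = "",
    subject_id: str = "",
    ddof: str = "n-2",
) -> DriftDecomposition:
    """OLS line through continuous-clock phases vs day index; residual SE.

    ``ddof="n-2"`` (default) uses the regression degrees of freedom;
    ``ddof="n-1"`` is the literal standard deviation of the residuals, kept
    for fidelity comparisons.  The fitted slope is the per-day drift.
    """
    p = np.asarray(phases, dtype=float)
    n = len(p)
    if n < 3:
        raise ValueError("drift decomposition needs >= 3 phases")
    if ddof not in ("n-2", "n-1"):
        raise ValueError("ddof must be 'n-2' or 'n-1'")
    local = clock_hour_phases(p)
    days = np.arange(1, n + 1, dtype=float)
    slope, intercept = np.polyfit(days, local, 1)
    resid = local - (intercept + slope * days)
    ssr = float(resid @ resid)
    denom = n - 2 if ddof == "n-2" else n - 1
    return DriftDecomposition(
        marker=marker,
        subject_id=subject_id,
        phases=p,
        slope_h_per_day=float(slope),
        intercept=float(intercept),
        residuals=resid,
        with_drift_sd=float(np.std(local, ddof=1)),
        drift_removed_se=math.sqrt(ssr / denom),
    )


def curvature_test(decomps: Sequence[DriftDecomposition]) -> CurvatureResult:
    """Test uniformity of drift: paired t-test of s12 = phase2 - phase1
    versus s23 = phase3 - phase2 across subjects (first three days used)."""
    if len(decomps) < 2:
        raise ValueError("curvature test needs >= 2 subjects")
    s12, s23 = [], []
    for d in decomps:
        local = clock_hour_phases(d.phases)
        if len(local) < 3:
            raise ValueError(f"subject {d.subject_id}: needs 3 days")
        s12.append(local[1] - local[0])
        s23.append(local[2] - local[1])
    diffs = np.asarray(s23) - np.asarray(s12)
    n = len(diffs)
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs.std(), 0.0):
        if np.isclose(diffs[0], 0.0):
            return CurvatureResult(0.0, n - 1, 1.0, n, note="no curvature")
        return CurvatureResult(float("inf"), n - 1, 0.0, n,
                               note="constant nonzero curvature")
    t, p = stats.ttest_rel(s23, s12)
    return CurvatureResult(float(t), n - 1, float(p), n)


def compare_methods(
    variabilities: Mapping[str, Mapping[str, float]],
    min_subjects: int = 3,
) -> dict:
    """Within-subject comparison of log-variabilities across markers.

    Parameters
    ----------
    variabilities
        ``{marker: {subject_id: variability_h}}``.  Non-converged marker/
        subject pairs are simply absent; subjects are compared pairwise-
        complete (only subjects with every retained marker enter the test).
    min_subjects
        Markers converged for fewer subjects are dropped (and listed).

    Returns a dict with the Friedman test (``statistic``, ``p_value``), a
    summary DataFrame of median/IQR log10-variability with mean within-
    subject rank, and the dropped-marker list.
    """
    kept = {m: v for m, v in variabilities.items() if len(v) >= min_subjects}
    dropped = sorted(set(variabilities) - set(kept))
    if len(kept) < 2:
        raise ValueError("need at least 2 markers with enough subjects")

    common = set.intersection(*(set(v) for v in kept.values()))
    if len(common) < 2:
        raise ValueError("fewer than 2 subjects shared by all markers")
    subjects = sorted(common)
    markers = sorted(kept)
    mat = np.array([[kept[m][s] for m in markers] for s in subjects], dtype=float)
    if np.any(mat <= 0):
        # a zero variability cannot be log-transformed; clamp to float tiny
        mat = np.maximum(mat, np.finfo(float).tiny)
    logv = np.log10(mat)

    if np.allclose(logv, logv[:, [0]]):
        statistic, p_value = 0.0, 1.0
    elif len(markers) == 2:
        # Friedman needs >= 3 groups; the 2-marker contrast is the Wilcoxon
        # signed-rank test on the paired log-variabilities
        statistic, p_value = stats.wilcoxon(logv[:, 0], logv[:, 1])
    else:
        statistic, p_value = stats.friedmanchisquare(*(logv[:, j] for j in range(len(markers))))

    ranks = np.apply_along_axis(stats.rankdata, 1, logv)
    summary = pd.DataFrame(
        {
            "marker": markers,
            "n_subjects": [len(kept[m]) for m in markers],
            "median_log10_var": np.median(logv, axis=0),
            "iqr_log10_var": np.subtract(*np.percentile(logv, [75, 25], axis=0)),
            "mean_rank": ranks.mean(axis=0),
        }
    ).sort_values("mean_rank", ignore_index=True)
    return {
        "statistic": float(statistic),
        "p_value": float(p_value),
        "summary": summary,
        "n_subjects_complete": len(subjects),
        "dropped_markers": dropped,
    }
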