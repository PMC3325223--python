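# melaphase

Circadian phase estimation from melatonin time series, for sleep and
circadian researchers who need to compare — or choose between — the field's
standard phase markers.

Melatonin is the most reliable output marker of the human circadian
pacemaker, but "melatonin phase" is not one number: published studies compute
it with threshold rules, with fitted curves, or with a physiological model,
and the choices matter, especially with noisy, low-amplitude or incomplete
data. `melaphase` implements all three method families — **17 named phase
markers** — plus the two analyses used to compare them: drift-removed
day-to-day variability and robustness to systematic 2-hour data gaps.
Because raw inpatient melatonin series are rarely shareable, the package
also ships a synthetic-profile generator with known ground truth.

## The markers

| Family | Markers | How |
| --- | --- | --- |
| Absolute threshold | `DLMOpost-threshold`, `DLMOinterpolated` | first sample above / interpolated crossing of 10 pg/ml (43.08 pmol/L) |
| Relative threshold | `DLMOn25%`, `DLMOff25%` | sustained crossings of 25% of the NOSA-fitted peak-to-trough range |
| 24-h mean | `24hUpcross`, `24hMidpoint`, `24hDowncross` | interpolated crossings of the day's mean concentration |
| Fourier F(2), F(3) | `F2Max/Upcross/Downcross`, `F3…` | 5- or 7-parameter harmonic fit; peak and half-max crossings |
| Skewed bimodal cosine | `SkewedUpcross`, `SkewedDowncross` | 6-parameter warped clipped-cosine fit |
| Differential-equation model | `Syn-on`, `Syn-off` | 9-parameter two-compartment pineal/plasma model |

The physiological model is
`dH1/dt = −β_I·H1 + u(t)`, `dH2/dt = β_I·H1 − β_C·H2`, measured
concentration `b + H2`, with a saturating-ramp synthesis drive `u(t)`
switching on at `t_on` (= Syn-on) and decaying after `t_off` (= Syn-off).
Being linear with piecewise-exponential forcing it has a closed-form
solution, used both as a fast fitting engine and as an independent oracle
for the numerical integrator.

Variability over ≥3 consecutive days is decomposed per subject and marker:
the *with-drift SD* is the SD of the daily clock hour; fitting a line
against day index removes the drift caused by a non-24-h intrinsic period
(τ ≈ 24.15 h), and the residual SE (`sqrt(SSR/(n−2))`) is the
*drift-removed* variability. Uniformity of the drift is testable
(paired t-test of day-1→2 vs day-2→3 slopes), and methods are compared on
log-variabilities with a within-subject Friedman test.

## Worked example

```python
import numpy as np
import melaphase as mp
from melaphase.pipeline import estimate_day_markers
from melaphase.curvefit_markers import nosa_fit
from melaphase.threshold_markers import relative_threshold

sc = mp.SubjectScenario(onset_clock_h=21.5, secretion_duration_h=10.0,
                        intrinsic_period_h=24.15, noise_cv=0.0, seed=42)
days, truth = mp.simulate_subject(sc)

cal = nosa_fit(days[0])                      # calibration-day harmonic fit
thr25 = relative_threshold(cal.fit_peak, cal.fit_trough)

phases = []
for s in days:
    ests = estimate_day_markers(s, threshold25=thr25)
    phases.append(ests["DLMOinterpolated"].phase_h)

dec = mp.drift_removed_se(np.array(phases))
print(truth["syn_on"], phases, dec.slope_h_per_day, dec.drift_removed_se)
```

This subject's true synthesis onsets are 21.50, 45.65, 69.80 h (study
clock, i.e. 21:30 drifting 0.15 h later per day with τ = 24.15 h). The run
prints, per day:

```
day 1 DLMOinterpolated=23.37  24hUpcross=23.51  F2Upcross=24.46  Syn-on=21.50  Syn-off=31.50
day 2 DLMOinterpolated=47.52  24hUpcross=47.67  F2Upcross=48.61  Syn-on=45.65  Syn-off=55.65
day 3 DLMOinterpolated=71.67  24hUpcross=71.82  F2Upcross=72.76  Syn-on=69.80  Syn-off=79.80
DLMOinterpolated: slope=0.151 h/day, with-drift SD=0.151 h, drift-removed SE=0.0015 h
```

Read: the model recovers its own synthesis onset exactly; the threshold and
curve markers sit, as they should, on the rising limb ~2–3 h after synthesis
onset (each defines "onset" at a different height of the rise); the line fit
recovers the configured 0.15 h/day drift, and removing it collapses the
day-to-day variability by two orders of magnitude — the reason multi-day
phase studies must de-drift before comparing methods.

## Command line

```bash
melaphase simulate --n-subjects 10 --seed 1 --out sim/
melaphase markers  sim/profiles.csv --out markers.csv
melaphase compare  sim/profiles.csv --out report/      # variability + Friedman
melaphase gapscan  sim/profiles.csv --out scan.csv     # 2-h gap robustness
melaphase report   scan.csv
```

Every output file carries the seed and a config hash in its header; a rerun
with the same seed is byte-identical. Non-converged fits are reported as
"not fit" counts per marker, never silently dropped.

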