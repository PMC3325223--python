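# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## The physiological model

Plasma melatonin is modelled as a linear two-compartment cascade,

    dH1/dt = −β_I·H1 + u(t)          (pineal)
    dH2/dt =  β_I·H1 − β_C·H2        (plasma)
    y(t)   =  b + H2(t),

with nine fitted parameters: synthesis onset `t_on` (Syn-on) and offset
`t_off` (Syn-off), maximal synthesis rate `A` (pmol/L/h), onset growth rate
`α` (1/h), offset decay rate `δ` (1/h), infusion rate `β_I` (1/h), clearance
rate `β_C` (1/h), assay baseline `b`, and initial plasma level `H2_0`. The
synthesis drive is zero before `t_on`, the saturating ramp
`A·(1 − e^{−α(t−t_on)})` until `t_off`, and exponential decay at rate `δ`
afterwards — continuous everywhere. This concrete ramp/decay form is this
package's rendering of the two-compartment synthesis/clearance picture; the
literature does not pin down one canonical nine-parameter set, so the drive
is isolated behind `synthesis_rate`/`_segment_forcing` and can be swapped
without touching the fitter. A light-suppression input is deliberately out
of scope: the intended data are dim-light protocols.

**Closed form and numerics.** With piecewise-exponential forcing the system
is solvable segment by segment in closed form (`simulate_analytic`); the
numerical route (`simulate`, LSODA, rtol 1e-8, atol 1e-10) restarts
integration at `t_on`/`t_off` so the solver never smooths across a switch.
The two routes agree to ~1e-8 relative on 48-h minute grids and serve as
mutual cross-checks; tests additionally check the α, δ → ∞ limit against an
independently derived two-exponential solution for square-pulse synthesis.
Coincident rates (e.g. β_I = β_C), where the closed form's denominators
vanish, are handled by a deterministic 1e-9-relative nudge.

**Fitting.** Bounded nonlinear least squares (`scipy.optimize.least_squares`,
trf) over all nine parameters, with the analytic solution as the forward
model. Bounds: rates in [1e-3, 10]/h, onset inside the day window, duration
in [4, 18] h (secretion episodes last hours; the lower bound stops the fit
collapsing onto short noise excursions), amplitudes relative to the data
scale so the fit is concentration-scale equivariant. Multistart (8 starts)
over onset offsets {0, −1, +1, −2} h around a scale-free initialiser (the
interpolated 20%-of-range rising crossing) × durations {9, 12} h, in fixed
order, so failures are deterministic. A fit is reported **not converged**
when no start succeeds or when the fitted pulse amplitude is below
max(4 × residual RMS, 5% of the data range) — i.e. indistinguishable from
noise. Non-convergence is a recorded outcome (a "not fit" table row), never
an exception.

## Curve-fit markers

F(2)/F(3) are linear least-squares Fourier fits with the fundamental period
fixed at exactly 24 h per analysis day (standard for single-day segments;
only NOSA fits period). The skewed bimodal cosine is

    y(t) = b + A·max(0, cos θ̃)^ν,   θ = 2π(t − φ)/24,
    θ̃ = θ + s·sin θ + m·sin 2θ,

six parameters (b, A, φ, s, m, ν): `s` skews the flanks, `m` flattens or
splits the peak, `ν` sharpens/broadens the pulse. The exact functional form
of the "skewed bimodal cosine" used by earlier salivary-melatonin work is
not published to parameter-level detail; this rendering keeps the advertised
six parameters and is isolated behind `skewed_eval` so it can be replaced.
It is fit by multistart least squares (8 equispaced phase starts, fixed
order; s, m ∈ [−1, 1], ν ∈ [0.5, 8]).

Curve markers: the fit maximum is the earliest global maximiser on a
1-minute grid (ties broken to the earliest); up/down crossings are where the
fitted curve passes **half the fitted maximum measured from zero** (not from
the fitted minimum), located by bisection between grid points. The
zero-reference reading matches profiles whose baseline is near zero; it is a
documented choice, revisable at one site. Skewed fits report crossings only.

NOSA (non-orthogonal spectral analysis) fits a mesor plus three harmonic
pairs of a common fundamental period, scanning the period over 23.5–24.5 h
in 0.01-h steps and keeping the minimal-residual fit; amplitude is half the
fitted peak-to-trough range with grid extrema polished by bounded 1-D
optimisation. The NOSA peak/trough define the 25% relative DLMO threshold;
the calibration day is an explicit argument, never inferred.

## Threshold markers

"Exceeds" is strict (>) throughout; a sample exactly at a threshold belongs
to the earlier side. This makes `DLMOinterpolated ≤ DLMOpost-threshold`
unconditional. The 25% markers require the crossing to be sustained for two
consecutive samples, rejecting single-sample blips; multiple crossings
resolve to the first sustained rising and the last sustained falling. The
25% crossings are interpolated on the **raw data**, with the fitted curve
supplying only the threshold level. Unit conversion is pinned at
4.308 (pg/ml → pmol/L) so that the customary 10 pg/ml threshold is exactly
43.08 pmol/L; recomputing from molecular weight would shift thresholds by
rounding.

## Variability decomposition

Daily phases are kept on a continuous study clock (day 2 begins at 24.0);
consecutive-day differences are mapped into (−12, +12] h before any SD or
line fit, so markers drifting across midnight never produce a −23.7 h
artefact. With-drift SD is the sample SD (n−1) of local clock hours.
Drift-removed SE fits OLS phase-vs-day and reports `sqrt(SSR/(n−2))`; with 3
points and 2 fitted parameters the literal "SD of the residuals" (n−1)
systematically understates, so n−2 is the default and the literal variant is
available via `ddof="n-1"`. Curvature is tested by a paired t-test of the
day-1→2 versus day-2→3 slopes. Cross-method comparison log-transforms the
(right-skewed) variabilities and uses a within-subject Friedman test
(Wilcoxon signed-rank for a two-marker contrast); a linear mixed-effects
confirmatory analysis with study/age/sex terms is a known fidelity gap,
deliberately replaced by this simpler within-subject design plus stratified
descriptives — the machinery is off-the-shelf and orthogonal to what this
package contributes.

## The synthetic generator

The generator emulates dim-light inpatient conditions: a single asymmetric
nocturnal pulse from the physiological model; uniform day-to-day drift of
synthesis timing at (τ − 24) h/day with τ defaulting to 24.15 h (drift is
exactly linear by construction — the structural null of the curvature test);
constant amplitude and duration within subject; multiplicative lognormal
assay noise (unit mean, CV configurable, default 0.10 — typical RIA
precision); 30- or 60-min sampling. Defaults: onset ~ U[20, 23] h,
duration ~ U[8, 12] h, amplitude scale lognormal (median 1, σ = 0.5, giving
NOSA amplitudes spanning roughly 15–250 pmol/L across a 98-subject pool),
α = 1.5/h, δ = 1.4/h, β_I = 1.2/h, β_C = 0.92/h (plasma half-life ≈ 45
min), A = 100 pmol/L/h (plateau ≈ 109 pmol/L at scale 1), baseline 2.5
pmol/L. Onset/duration distributions are stand-ins chosen for physiological
plausibility; no public dataset constrains them.

Each day is sampled over a 24-h window starting 7.5 h before the subject's
day-1 synthesis onset — the way inpatient protocols schedule sampling
relative to habitual bedtime — so every window contains one complete pulse
(daytime baseline, evening rise, overnight plateau, full morning fall). A
fixed clock anchor instead clips the morning falling limb for late-onset,
long-duration subjects and makes window truncation masquerade as day-to-day
marker variability.

**What passing tests show, and don't.** The generator shares its functional
form with the fitted physiological model, so physio-fit recovery tests
establish numerical correctness of the pipeline, not robustness to model
misspecification; conversely the Fourier/skewed fits are misspecified for
these pulses, which is realistic. Real data add masking, posture/assay
artefacts, between-day shape changes and non-lognormal noise that the
generator deliberately omits — conclusions about *relative* method
performance on real recordings should not be read off these simulations.
One concrete consequence: in the gap-robustness experiment the fitted
Syn-on moves *later* when a gap removes the early rise (baseline samples
bound onset strongly from below but only weakly from above, since a later
onset can be offset by a steeper ramp), whereas the corresponding
real-data analyses report earlier shifts; the sign depends on the exact
synthesis-drive rendering and on real-data misspecification, and is a
documented divergence. The magnitude ordering — Syn-on and
DLMOpost-threshold most gap-sensitive, F2Upcross least — does reproduce.

## Study configurations

The canonical experiments (`melaphase.experiments`) fix these conditions:

- **ODE cross-check:** 48-h grid at 1-min resolution, 3 parameter draws
  around the defaults; numeric vs closed form ≤ 1e-6 relative.
- **Physio recovery:** 20 noiseless single-day scenarios (onset/duration/
  amplitude drawn around defaults); 50 replicates at 5% noise.
- **Onset-marker recovery:** 10 noiseless 3-day subjects, amplitude median
  1.5 with σ = 0.25 so every peak exceeds twice the 43.08 pmol/L threshold
  (the validity condition for absolute-threshold DLMO; low-amplitude
  behaviour is exercised by the degenerate-profile checks instead). Region
  containment — every converged onset marker inside [synthesis onset,
  true rising half-max] ± one sampling interval — is checked on the hourly
  protocol, whose tolerance absorbs each marker's intrinsic bias (a
  2-harmonic fit of an asymmetric pulse places its half-max crossing ~0.7 h
  late); drift recovery to ≤ 0.02 h/day is checked on the 30-min protocol,
  where interpolation quantisation (~dt²) is negligible at that precision.
  At a single interval the two claims cannot both hold, which is a property
  of the markers, not of the implementation.
- **Drift structure:** 200 phase-level 3-day subjects (slope 0.4 h/day,
  residual σ 0.03 h) for the with-drift/drift-removed ratio; 100
  repetitions × 20 subjects for curvature-test level (null: exactly linear
  drift) and power (quadratic drift 0.5 h/day², residual σ 0.1 h). Phases
  are generated directly at the marker level — the decomposition operates
  on phases, so profile simulation would add cost without structure. Note
  the t-test is *exactly* level 0.05 under this null, so the observed
  rejection proportion over 100 repetitions fluctuates around 5% with SD
  ≈ 2.2 points.
- **Gap experiment:** 5 subjects, one day each, default 10% noise, amplitude
  scale fixed at 1.5 (standing in for the selection of complete,
  high-amplitude profiles for this analysis); 2-h gaps tiled every 2 h from
  the window start; deltas referenced to the complete-data
  DLMOpost-threshold. Noise is required: with noiseless data an
  exactly-specified model fit is unaffected by gaps and every Syn-on delta
  is identically zero.

These sizes keep the full suite and the acceptance script in the
single-digit minutes on one CPU while leaving each comparison far from its
decision margin.

## Known limitations

- The nine-parameter drive is one plausible rendering; Syn-on/Syn-off
  semantics are tied to it.
- Saliva/urine matrices, assay QC, and light-suppression dynamics are out of
  scope.
- `DLMOpost-threshold` is grid-quantised (a sample time), so its drift and
  variability statistics are step-like by nature.
- The 24-h-mean markers depend on window content; carry-over from the
  previous night's tail slightly shifts the mean threshold on days ≥ 2.
- Input CSVs must label days explicitly (a `day` column); the package does
  not infer day boundaries from sample times.
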