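# Methods

This note records the models, conventions and numerical choices behind
`topeq`, and what the synthetic-data tests do and do not demonstrate.

## Diffusion-cell mass balance

Periodic receptor sampling with volume replacement removes drug from the
receptor, so the cumulative amount released per unit area at draw *n* is

    Q_n = (C_n · V_receptor + Σ_{i<n} C_i · V_sample) / A

with concentrations in mass/mL, volumes in mL and the diffusion area in cm².
This is the universal Franz-cell arithmetic; the correction can be disabled
(`correct_sampling=False`) for data corrected upstream, and the input
concentration unit is declared per file (µg/mL for HPLC release data,
ng/mL for HPLC-MS/MS permeation data) and propagated to the profile's
amount unit. Q is *not* forced to be monotone: analytical noise legitimately
produces small local decreases and masking them would bias the fits. A t = 0
point is used when present and never synthesized.

Default release-cell geometry: 12 mL receptor, 300 µL draws, 1.54 cm² area,
37 °C, schedule 0.5–6 h. Permeation cells: 1 cm² area, 32 °C, schedule up to
24 h; the receptor volume of skin-mounted cells is set to 7 mL (a typical
value for this format — the quantity only matters through the correction term
and all equivalence quantities are ratios, so results are insensitive to it).

## Release kinetics (IVRT)

Cumulative release from a semisolid through a membrane follows
square-root-of-time kinetics over the 6 h window: Q(t) ≈ intercept + K·√t.
`higuchi_fit` is an ordinary least-squares fit of Q on √t over all strictly
positive times (a window option excludes an early burst; a forced-zero
intercept is available but biased in the presence of burst release, hence not
the default). **Q6h is the measured/interpolated amount at 6 h**, not the
fitted line's value there — the batch tables treat Q6h as an independent
observable with its own dispersion.

Method validation follows the standard four checks:

- *linearity*: OLS of individual K and Q6h on product strength across ≥3
  strengths; pass when r² > 0.90;
- *intermediate precision*: CV% (100·SD/mean) per operator/day group and
  pooled over raw replicates; pass below 10%. Pooled statistics are always
  computed from the concatenated replicates, never from group means;
- *discriminatory power*: the ratio CI of a deliberately altered formulation
  must fall entirely outside 90–111%;
- *robustness*: one-way ANOVA of each modified operating condition against
  the standard condition (two groups), flagged at p < 0.05. The layout is
  two-group because each factor is varied one at a time against the common
  standard runs.

## Permeation (IVPT)

Skin integrity is gated on TEER strictly above 2000 Ω before any fitting.
The steady-state flux is the OLS slope of Q on t over the steady-state
window; the default window is the **trailing run of at least five points
ending at the last sample that maximizes r²** (ties resolved toward the
longer window), since the latest part of the profile is the steady state and
the window is otherwise a free choice. Lag time is −intercept/slope when the
slope is positive; non-positive slopes are reported with a warning and an
undefined lag rather than suppressed. Q24h is the cumulative amount at the
final sampling time.

Replicates are collapsed to per-donor geometric means first; all arm-level
statistics operate on the n-donor list (no mixed-effects model is fitted —
the hierarchy is fixed and shallow). Equivalence uses the classical
bioequivalence construction: a Welch two-sample 90% CI on the difference of
log-transformed donor means, exponentiated, judged against 80–125%. Swapping
test and reference exactly inverts the interval.

Mass balance per cell is 100·(receptor + skin + residual)/applied; the cohort
requirement applies to the mean, with individual cells outside 90–110%
flagged.

The permeation tables in the source study print Q24h in µg/cm² alongside
fluxes of ~15 ng·h⁻¹·cm⁻²; those magnitudes are mutually consistent only in
ng/cm², so this package treats MS-quantified permeation amounts in ng/cm².
Every equivalence quantity is a ratio and therefore unit-invariant.

## Equivalence intervals

The difference CI is the standard Welch two-sample interval. The published
ratio formula pairs a dimensionless point estimate with an absolute
standard-error term; as printed it is dimensionally inconsistent. `topeq`
adopts the reading in which the standard error is scaled by the reference
mean — equivalently, the difference CI shifted by X̄ᵣ and divided by X̄ᵣ —
because that construction exactly reproduces the published discrimination
interval (1.14–1.22) from its published summaries, under either df rule.
Welch–Satterthwaite df is the default; pooled df is available and changes
nothing at printed precision in the cases checked. α is fixed at 0.10 (90%
CI) per guideline; it is configurable for sensitivity analyses only.

Acceptance ranges are registered as *closed* intervals on the ratio scale
(0.90–1.10, 0.90–1.11, 0.80–1.25): an interval touching a boundary counts as
within, and every interval receives exactly one of
within/outside/straddles.

A nonparametric percentile bootstrap (independent resampling of each arm,
ratio of means or of geometric means, ≥1000 resamples, mandatory seed)
provides a resampling alternative when normality is in doubt; it is a check,
not the primary construction.

## Rheology

- η₃₀₀ is stress/rate at 300 s⁻¹, from the hold-segment average when a hold
  is present, else interpolated on the up ramp. Viscosity is reported in
  Pa·s; some instrument exports label the same column "Pa" — the quantity is
  stress/rate regardless.
- RTLA = 100·(S_asc − S_desc)/S_asc with trapezoidal areas in stress–shear-
  rate coordinates over the sampled points only (no extrapolation to 0 or
  300 s⁻¹). It is invariant to uniform stress rescaling, 0 for reversible
  loops, negative for anti-thixotropy, and the quadrature error is O(h²) on
  smooth curves.
- The linear viscoelastic plateau is the first run of ≥4 consecutive sweep
  points whose G′ spread is <5% of their mean, extended while the condition
  holds. G\* = √(G′²+G″²) and δ = atan(G″/G′) are averaged over the plateau.
- Yield stress is not uniquely defined in the field; the default extraction
  is the stress amplitude at which G′ first drops 10% below the plateau
  mean, log-interpolated between the bracketing points (resolution is
  therefore one log-grid step). The G′ = G″ crossover stress is provided as
  an alternative metric.

## Microstructure

Droplet diameters are consumed as measured lists (image segmentation is out
of scope). Statistics are arithmetic mean and sample SD; batch comparison
reuses the same ratio-CI engine as every other physicochemical parameter.
Because the guideline construction assumes normality and real droplet data
are typically lognormal, every droplet comparison carries an
Anderson–Darling normality result and a warning flag when either batch
rejects at p < 0.05.

The Anderson–Darling statistic uses estimated mean/SD, the small-sample
correction A\*² = A²(1 + 0.75/n + 2.25/n²) and the standard piecewise
exponential p-value approximation for the estimated-parameters case
(requiring n ≥ 8). The statistic is cross-checked against an independent
implementation in the tests; simulated type-I error is ≈5% at α = 0.05.

Diffraction peak detection: moving-average smoothing (0.1° default), a
rolling-median baseline over a 2° window (robust to the wide amorphous hump),
then prominence-filtered local maxima with a default prominence floor of
5× the robust noise scale (1.4826·MAD) of the residual. A maximum peak width
of 1° at half prominence excludes broad features — without it the hump's own
maximum can clear a prominence threshold even after baseline removal.
Classification matches detected positions against the two characteristic
position sets within ±0.2° 2θ; a set is "present" when ≥75% of its positions
match (the fraction is a package choice; the sets share some reflections, so
a perfect-match criterion would be brittle). Bragg spacings use
d = λ/(2 sin θ), Cu Kα1 = 1.5406 Å by default.

## Synthetic-data generators

The generators define the study conditions used throughout the tests:

- *release*: per-replicate K lognormal around the arm truth with CV 8%
  (default true K 28 µg·h^-1/2·cm⁻² at 0.025% strength, scaling with
  strength), additive N(0, 1 µg/cm²) noise on cumulative amounts. These
  settings give fitted-K CVs of ~8%, the single-digit intermediate-precision
  regime the method targets. Records are emitted as *concentrations* by
  inverting the sampling correction, so the correction path is always
  exercised; a noise-free run round-trips K exactly.
- *permeation*: flux = truth × lognormal donor factor (CV 55% — skin donors
  dominate the variance) × lognormal replicate factor (CV 8%);
  Q(t) = flux·max(t − lag, 0) with 5% multiplicative measurement noise;
  default truth 15 ng·h⁻¹·cm⁻² with 2 h lag. TEER draws fall above the
  cut-off except for a configurable failing fraction. At 6 donors/arm this
  reproduces the wide, frequently non-equivalent CIs characteristic of
  pilot permeation studies; doubling one arm's flux mirrors a
  double-strength negative control (ratio ≈ 50%, outside 80–125%).
- *flow curves*: Herschel–Bulkley up ramp (σ = σ_y + kγ̇ⁿ), hold at
  300 s⁻¹, down ramp = (1 − f)·up ramp so the target RTLA = 100·f holds
  exactly by linearity of integration.
- *oscillatory sweeps*: G′ plateau with power-law decay (s/s_c)^(−m) past
  the critical stress, constant phase angle; m = 0 yields a flat sweep that
  exercises the no-yield error path. The 10%-deviation extraction recovers
  s_c·0.9^(−1/m), within a few percent of s_c for the default m = 4.
- *droplets*: lognormal moment-matched to target mean/SD
  (σ² = ln(1 + (SD/mean)²)); convergence to the targets is verified at
  n = 10⁵ within 1–2%.
- *diffractograms*: Gaussian reflections (σ = 0.08°, step 0.02°) over a wide
  Gaussian hump plus additive noise.

All generators are bit-deterministic under a fixed seed.

**What passing these tests shows — and does not.** The generators reproduce
the dispersion structure the analysis assumes (tight release CVs, heavy
donor-dominated permeation variability, lognormal droplets, sharp peaks on a
hump), so the tests validate the estimators, interval constructions and
verdict logic. They do not emulate sink-condition violations, dose
depletion, skin metabolism, emulsion aging kinetics, overlapping reflections
or instrument drift; conclusions about real data quality still require the
method-validation suite on real measurements.

## Problem sizes and numerical choices

Simulation-based checks use 500 replicates for parameter-recovery and
coverage-of-K checks, 2000 simulations for log-CI coverage and
Anderson–Darling calibration, and a 200 000-draw studentized parametric
bootstrap as the interval oracle — sizes at which Monte-Carlo error is well
below the tolerances asserted. Interpolation is linear everywhere (time
profiles) except log-linear for yield-stress crossing on the log-spaced
sweep grid. Degenerate inputs are errors, not silent results: zero √t
variance, zero reference mean, non-positive values on the log scale, zero
variance in the normality test, missing plateau or yield. Two constant
identical groups give an undefined ANOVA p (reported as NaN, not
significant).

## Known limitations

- The ratio CI is the guideline's additive construction rescaled, not a
  Fieller interval; for very variable references the two can differ.
- No TOST p-values; verdicts are interval-inclusion only, per guideline.
- The steady-state window heuristic assumes the profile ends in its linear
  regime; strongly depleting (finite-dose) profiles need an explicit window.
- Pattern classification is positional only — intensities and overlapping
  type I/II reflections are not deconvolved.
- No constitutive rheological model fitting (Cross/Carreau) and no aging
  kinetics; time points are compared, not modeled.
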