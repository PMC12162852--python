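# Methods

## Measurement model

The assay captures all αSyn conformers from CSF on an antibody-
functionalized ATR crystal and reads the Amide-I band of the bound protein
by difference spectroscopy: spectra recorded during the buffer wash after
sample circulation, minus spectra recorded before sample application. The
Amide-I band position encodes the secondary-structure distribution —
α-helical/random-coil near 1650 cm⁻¹, oligomeric near 1647 cm⁻¹, β-sheet
near 1624 cm⁻¹ — so disease-associated misfolding appears as a downshift
and, in a cohort difference spectrum, as a positive lobe near 1623.5 cm⁻¹
paired with a negative lobe near 1656.0 cm⁻¹.

The primary per-subject read-out is the absorbance ratio
r = A(1656.0)/A(1623.5) of the processed difference spectrum, evaluated by
linear interpolation (the feature positions are half-wavenumber values on
a 2 cm⁻¹ grid; nearest-neighbour snapping would alias them). Low r means
β-enriched, misfolded αSyn.

## Processing chain

Canonical order, pinned by tests: average replicates → water-vapor
correction → baseline correction → difference (wash − background) →
Savitzky–Golay smoothing → (normalisation, for group-level spectra only).
Every stage appends parameters and fitted scalars to a trace in the
spectrum metadata; a processed spectrum is auditable and reproducible.

Choices where the upstream acquisition convention does not prescribe an
algorithm:

- **Water vapor.** The correction coefficient α in s − α·ref is the
  one-parameter least-squares solution on *second differences* over
  1900–1700 cm⁻¹. Second differencing isolates the sharp rotational lines
  from broad protein and baseline features; 1800–1900 cm⁻¹ is protein-free.
  On noiseless composites clean + α·ref the fit recovers α to better than
  1e-6 provided the clean spectrum has no sharp structure in the window.
- **Baseline.** A straight line through the mean absorbance of two anchor
  windows, 1800–1750 and 1490–1480 cm⁻¹ (flanking the amide region). A
  pure linear ramp is removed exactly.
- **Smoothing.** Savitzky–Golay, window 9 points, polynomial order 3 — a
  conventional mild setting for 2 cm⁻¹-spaced protein spectra. The
  acquisition convention says only that difference spectra are smoothed;
  window and order are this package's defaults and are recorded in the
  trace. S/N is always computed on unsmoothed spectra.
- **Normalisation** = unit Amide-I maximum (window 1700–1600 cm⁻¹), not
  unit area: the difference-spectrum lobes are reported relative to a
  normalized band and max-normalisation is the simplest convention
  consistent with that. Per-spectrum normalisation before group averaging
  is the default (normalising only the final group difference is a
  caller-side alternative, since `group_difference` is compositional).

## Quality gates

A subject enters the analysis only if the processed difference spectrum
passes both gates:

- Amide-I/Amide-II peak ratio (window maxima, 1700–1600 over
  1580–1500 cm⁻¹) inside the **closed** interval [1.10, 1.50];
- S/N ≥ 20, S = mean absorbance 1560–1540 cm⁻¹, N = RMS of the absorbance
  1800–1900 cm⁻¹ of the unsmoothed spectrum. The RMS is taken of the raw
  values (no mean subtraction); a mean-subtracted variant is available by
  flag. Exactly 20 passes — only S/N < 20 is excluded.

Window endpoints are closed intervals over grid points; with 2 cm⁻¹
spacing the difference from interpolated endpoints is negligible. "Peak
maxima" are taken within the fixed windows above, not as global maxima.
Both gates are invariant under a global gain, and amplitude-zero (null)
runs fail the S/N gate rather than producing a spurious feature.

## Features

- **Absolute maximum**: argmax wavenumber in 1700–1600 cm⁻¹, ties broken
  toward higher wavenumber.
- **Center-of-mass maximum**: Σν·A/ΣA over the points with A ≥ f·A*,
  f ∈ [0.80, 0.90], default 0.85 (midpoint of the recommended range; both
  endpoints are exposed because the convention gives a range, not a
  value). Robust to small signals; converges toward the absolute maximum
  as f → 1 on asymmetric bands. Reported per subject; the group value is
  the mean of per-subject values (computing it on the group-mean spectrum
  is the documented alternative).
- **Ratio** r as above, computed on the smoothed per-subject difference
  spectrum (unsmoothed variant available for sensitivity analysis). A
  nonpositive denominator marks the feature invalid and flags the subject
  explicitly — never a silent drop.
- **Band integrals** of a group difference spectrum: trapezoidal integrals
  over 1608–1640 (β lobe) and 1640–1672 cm⁻¹ (helix lobe), i.e. ±16 cm⁻¹
  around the lobe positions with the boundary at 1640 cm⁻¹; magnitudes
  reported.
- **Kinetic amplitude**: mean of the last 10 % of the binding trace minus
  mean of the first 5 % (offset-invariant plateau estimate; the first 5 %
  of a run is the pre-injection buffer hold).

## Classification

Single threshold: positive iff r < 1.093 (a value exactly at the
threshold is negative; the convention quotes no boundary rule, so the rule
is documented here). Traffic light: red iff r < 1.065, green iff r > 1.14,
yellow otherwise — the quoted inequalities are strict, so both threshold
values are yellow. Confusion metrics compare red (test-positive) against
green (test-negative) with yellow excluded; percentages are reported
rounded half-up to integers with raw fractions retained. Thresholds are
treated as fixed constants; re-derivation (e.g. Youden) is deliberately
not part of the pipeline.

## Statistics

Group location: two-sided Mann–Whitney U (the ratio is not normally
distributed), exact null distribution when the smaller group has ≤ 8
observations without ties, normal approximation with tie correction
otherwise; the reported statistic is min(U₁, U₂). Primary model: ML
logistic regression, disease ~ ratio + age + sex (F = 1, M = 0), no
regularisation; ROC and AUC from the predicted probabilities. The
trapezoidal AUC equals the normalized U statistic exactly (property-
tested). 95 % CIs by DeLong's method (the reference analysis names no CI
method; DeLong is the standard analytic choice), seeded percentile
bootstrap (2000 replicates) by flag; bounds are not clipped to [0, 1].
Under perfect separation the ML fit diverges and the scores fall back to
ranks of −ratio (low ratio ⇒ disease) with an explicit warning — monotone-
equivalent for ROC purposes. All tests are two-sided at α = 0.05.

Supporting computations: Q_Alb positivity iff the CSF/serum albumin
quotient strictly exceeds 4 + age/15; extraction efficiency
100·(c_original − c_supernatant)/c_original; thioflavin-T aggregation
confirmed iff the excitation maximum lies within ±3 nm of 450 nm and the
482 nm emission is ≥ 20× the blank.

## Synthetic data: what it emulates, and what it does not

No per-subject CSF spectra are publicly deposited for this assay, so the
package ships a forward model calibrated to the published cohort
summaries:

- **Bands**: pseudo-Voigt (η = 0.3) components — helix/rc 1650/42,
  oligomer 1647/40, β-sheet 1624/28 cm⁻¹ (center/FWHM) — plus Amide-II at
  1548/45 cm⁻¹ with amplitude 0.75× the Amide-I peak, which keeps the
  Amide-I/II QC ratio of clean runs inside [1.10, 1.50]. Grid
  1900–1480 cm⁻¹ at 2 cm⁻¹ (the instrument's nominal resolution; spacing
  configurable since acquisition settings vary).
- **Runs**: background = baseline (offset ±1e-3 AU, slope ±2e-6 AU/cm⁻¹)
  + water-vapor lines (17 Lorentzians, FWHM 1.5 cm⁻¹, spanning
  1900–1480 cm⁻¹; amplitude 1–5e-5 AU with 10 % per-spectrum fluctuation;
  the same line list is the correction reference) + white noise
  (sd 2e-5 AU per raw spectrum, a realistic FTIR floor); wash = background
  + amplitude·mixture, amplitude lognormal around 1e-3 AU (the scale of
  pg–ng/ml protein loads); 10 background and 10 wash replicates. Kinetics:
  saturating exponential, τ = 20 min over 120 min with a 6 min buffer
  hold.
- **Cohorts**: per-subject β-sheet fraction f ~ logit-normal per group;
  subject-level band-center jitter, *independent per component band*,
  sd 1.0 cm⁻¹. The logit-normal parameters are fitted **once** by
  inverting the noiseless ratio-vs-f curve at the published box
  (interquartile) limits — 1.01/1.11 for the misfolding group, 1.08/1.22
  for controls — after subtracting the jitter-induced ratio variance
  (first-order, evaluated at the group median) in quadrature, so the
  *total* simulated quartiles match the published boxes. A common rigid
  band shift of ~2 cm⁻¹ was rejected: the 1656 cm⁻¹ query point sits on
  the helix-band flank where such a shift alone moves the ratio by ~0.09,
  more than the entire published within-group IQR, which no β-fraction
  distribution could then reproduce. Demographics per group follow the
  published combined cohort: 23 % vs 53 % female, age 70 ± 9 y in both
  groups, Q_Alb (×10³) lognormal with mean ± sd 10.1 ± 5.5 vs 7.3 ± 3.5,
  diagnosis mix 57 PD/5 MSA vs 51 control/5 CBD/7 FTD/9 PSP per 62/72.
  One global seed fans out to per-subject substreams via a CRC-32 hash of
  the subject id, so cohorts are insertion-order independent and bitwise
  reproducible.

The generator reproduces the *summary* structure of the study — group
ratio quartiles and medians, QC-passing spectra, the difference-spectrum
sign pattern, demographic imbalance — under unimodal within-group
distributions. It does **not** reproduce the published discrimination
performance (AUC ≈ 0.90, extremes sensitivity/specificity 97 %/92 %):
unimodal distributions matched to the published interquartile boxes imply
more group overlap than the real, presumably heavier-tailed per-subject
data, and the simulated AUCs come out near 0.8. Passing tests therefore
demonstrate correctness of the pipeline's operations and calibration of
the generator to the published summaries — not clinical performance on
real CSF. It also omits physical optics (evanescent-field depth,
polarization), antibody-affinity kinetics, channel drift and CO₂ bands.

## Problem sizes

The default simulated study is 62 + 72 subjects with 10+10 replicate
spectra of 211 points each and runs in under a second; the test suite's
Monte-Carlo checks use up to 10⁴ permutations (Mann–Whitney type-I error),
1000 simulated cohorts of n = 200 (DeLong coverage), and n = 2000
binormal cohorts (closed-form AUC recovery). These sizes give the quoted
tolerances comfortable margins while keeping the suite fast.

## Known limitations

- JCAMP-DX support covers single-block XYPOINTS and AFFN XYDATA — the
  subset needed for spectrum exchange — not compressed (DIF/DUF) nor
  multi-block compound files; proprietary instrument binaries (e.g. OPUS)
  must be converted upstream.
- The vapor-correction fit assumes the reference line shape matches the
  contamination up to a single scale factor per spectrum.
- Thresholds and QC gates are constants of the assay convention; the
  package applies them, it does not re-derive them.
- The albumin-quotient cross-tabulation and extraction-efficiency
  operations are arithmetic on measured counts/concentrations; the package
  computes them but cannot validate the underlying assays.
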