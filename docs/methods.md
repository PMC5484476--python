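# Methods

## The calibration problem

Serum IgG concentration is inferred from the mid-infrared absorbance spectrum
of a dried serum film. Protein amide bands (amide A ≈ 3300, amide I ≈ 1650,
amide II ≈ 1550 cm⁻¹) carry the signal, but every serum protein absorbs
there, so no single wavenumber measures IgG: the problem is a multivariate
calibration of a 400-point spectrum against a reference concentration, with a
clinical decision (failure of transfer of passive immunity, IgG < 1000 mg/dL)
layered on top of the regression.

## Pipeline and its assumptions

Stages run in a fixed order: base operator (Savitzky–Golay smoothing or
derivative) → optional normalization → region selection → Dixon-Q screening →
replicate averaging → test split → Monte-Carlo cross-validation → final PLS
fit → evaluation. Choices a user may care about:

* **Savitzky–Golay**: window 9 points, polynomial order 2 (defaults;
  configurable). Derivatives are taken with respect to wavenumber on the
  descending grid, so derivative weights carry a (−1)^order factor relative
  to the array coordinate, and are scaled by the grid step so units are
  AU·cm per derivative order. Edge half-windows (4 points each end at the
  default) are dropped, never extrapolated; the analysis regions are interior
  so nothing of value is lost.
* **Normalization order**: normalization statistics are computed over the full
  edge-trimmed grid *before* region selection, and normalization follows the
  derivative (presets read left to right). The order is echoed in every run's
  `config_echo.yaml` so it is auditable. Note one algebraic fact: because the
  derivative is linear and both SNV and vector normalization are (affine)
  scalings, "normalize, differentiate, normalize again" collapses to
  "differentiate, normalize" — the order only matters when the final
  normalization is omitted.
* **Region selection**: closed intervals, defaults 3700–2600 and
  1800–1300 cm⁻¹ (402 points on the default 4 cm⁻¹ grid after edge trim).
  The excluded 2200–1900 cm⁻¹ stretch is where diamond-ATR optics absorb.
* **Dixon-Q screen**: at each retained wavenumber the r₁₀ statistic is
  computed over the whole cohort of spectra and only the two extreme owners
  are testable (one pass, no re-testing after removal — the test's
  definition). Exclusion requires flags at more than 50% of wavenumbers at
  95% two-tailed confidence. With duplicate-only acquisition a within-sample
  test is impossible (n = 2 < 3), hence the cohort scope; a
  `replicate_group` scope exists for ≥3-replicate designs and skips groups
  that are too small with a warning. Critical values are the standard
  two-tailed r₁₀ table (n ≤ 30); beyond the table a quadratic in 1/n fitted
  to the n = 10..30 entries extrapolates, clamped monotone, and the report
  marks when extrapolation was in play. The extrapolated values are
  conservative: on clean synthetic cohorts the observed flag rate is far
  below nominal, which errs toward keeping spectra.
* **Test split**: samples sorted by reference IgG (ties broken by sample id),
  every third rank held out — 58 of 175 — guaranteeing the test set spans the
  concentration range. The remaining 117 form the calibration set.
* **MCCV**: each repeat draws one uniform random split of the calibration set
  into training (default ⌈n/2⌉, i.e. 59 of 117) and validation halves; all
  factor counts 1..30 are fitted on the same split per repeat (one NIPALS
  pass to the maximum count, per-factor predictions read off incrementally).
  RMMCCV(k) is the square root of the pooled mean squared validation error
  across repeats; a per-repeat-RMSE-mean variant is available
  (`pooling="per_repeat"`) and differs negligibly at equal validation sizes.
  The minimum selects k, ties toward fewer factors. Repeats default to
  10,000; tests and examples run 100–600, where the curve is already stable
  (doubling repeats moves it by under 2% on the synthetic fixture — asserted
  in the test suite).
* **PLS1 (NIPALS)**: mean centering only, no per-wavenumber variance scaling
  (standard for spectra, where the scale is physically meaningful). For a
  single response the weight vector has a closed form per factor, so there is
  no inner iteration or convergence tolerance. Extraction stops early if the
  residual covariance norm falls below 1e-12 (rank exhausted) and the
  achieved count is recorded; Monte-Carlo pooling then carries the achieved
  model's error forward for the unreachable counts.
* **Evaluation**: Bland–Altman difference is reference minus IR prediction
  (direction recorded in the report), limits of agreement ±1.96·SD (not the
  exact-t variant). RPD bands are closed on the left: < 2 poor, 2–2.5
  screening, > 2.5 quantification, > 3 accurate (RER analogues > 10 / > 20).
  The FTPI cutoff is strict: exactly 1000 mg/dL is negative. When a cohort
  has no reference positives, sensitivity is reported as not-applicable
  rather than 0. Display rounding (integer percents, 1-decimal RPD/RER,
  integer mg/dL errors) mirrors clinical reporting; machine-readable outputs
  keep full precision.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, not
serum photophysics. Absorbance is a Beer–Lambert mixture of four components
(IgG, albumin, other globulins, a broad matrix background), each a sum of
Gaussian bands; the protein bands overlap deliberately so that the
calibration is genuinely multivariate. Instrument effects per replicate: a
path-length scale (1.0 lab, 1.3 portable — the portable unit's deeper
effective penetration), multiplicative scatter ~N(1, 0.01), an affine
baseline (offset SD 2 mAU, slope SD 1 µAU/cm⁻¹), optional non-affine slow
sinusoidal baseline wander (off by default; affine wander alone spans two
spectral directions that PLS simply absorbs, so studying baseline-sensitive
preprocessing requires the non-affine term), and white noise per point.

IgG concentrations are a truncated two-component lognormal mixture: a low-IgG
subpopulation (weight 0.12, mean 700, SD 180 mg/dL — the FTPI animals) plus a
main component whose untruncated moments are solved by fixed-point iteration
on closed-form truncated-lognormal moments so that the truncated mixture
reproduces the configured herd mean 2654 and SD 1305 mg/dL within Monte-Carlo
error. A single lognormal at those moments was rejected because it puts only
~3% of animals below 1000 mg/dL where the emulated herd has ~12%, and
truncation to [394, 6327] mg/dL would additionally shrink its realized SD by
~10%. Interferents are independent truncated normals; the reference assay is
true IgG × (1 + N(0, cv)) with cv = 0.05 by default (the reference method's
precision is a free parameter; 5% is a plausible figure for a plate-based
immunoassay run in replicates).

White-noise defaults (lab 3.0 mAU, portable 9.0 mAU per point) were set once
by scanning so that the end-to-end pipeline at default conditions yields
held-out r ≈ 0.90 for both instrument profiles — the performance regime the
workflow is designed for — and then frozen. The portable profile pairs a
longer optical path with a noisier detector, leaving the two instruments
comparable, as compact and benchtop FTIR units tend to be in practice.

What the generator does **not** emulate: water-vapor and CO₂ interference,
Mie scatter, detector nonlinearity, film-thickness heterogeneity, wavenumber
calibration drift, or any correlation between IgG and the interferents.
Passing tests therefore demonstrate the correctness and stability of the
*procedure* (preprocessing algebra, screening logic, factor selection,
metric arithmetic) under a faithful statistical facsimile — not the clinical
performance of any real instrument, which must be established on real sera.

## Numerical and design notes

* Determinism: every stochastic step derives from explicit seeds via
  counter-based substreams (`default_rng([seed, tag, counter])`), so datasets
  and whole pipeline runs are bit-reproducible and order-independent;
  replicate and repeat substreams are independent by construction.
* Degenerate inputs fail loudly: constant spectra under SNV, all-zero vectors
  under vector normalization, zero-variance responses, empty region
  selections, samples losing all replicates in QC. Zero spectral range at a
  wavenumber yields a no-outlier signal rather than a division by zero.
* Spectra CSVs are written with 17 significant digits and read with
  round-trip float parsing, so write→read is the identity (property-tested).
* Demonstration problem sizes: tests and the acceptance script use 100–600
  MCCV repeats and cohorts of 60–175 samples. These are the package's own
  demonstration choices; the RMMCCV curve and all downstream decisions are
  stable well below the 10,000-repeat default.
* Known limitations: Dixon's test applied to cohorts of hundreds of spectra
  relies on extrapolated critical values (flagged in the report); the
  cohort-scope screen assumes most spectra at a wavenumber are sound; PLS1
  only (no multi-response or kernel variants); no confidence intervals on
  sensitivity/specificity; figures are emitted as plot-ready CSV data, not
  rendered graphics.
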