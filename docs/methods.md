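# Methods

## The calibration problem

The package calibrates regression models that predict ten panel-scored
sensory attributes of dry-cured pork loin (1–9 intensity scale) from FT-NIR
absorbance spectra measured on minced samples over 4000–10,000 cm⁻¹ at
4 cm⁻¹ resolution (1501 channels), three replicate scans per sample, forty
samples.  The modeling assumption is that panel scores are smooth —
generally nonlinear — functions of the sample's bulk composition (protein,
lipid, water) and curing state, and that these drivers are encoded in the
NIR overtone/combination bands.  A linear PLS baseline is carried along to
test that assumption: when the score–spectrum map is nonlinear, PLS
prediction degrades while kernel SVR does not.

## Synthetic data generator

No public spectra exist for this design, so the generator is a first-class
module, not a fixture.  Each sample draws a latent composition from a
Dirichlet distribution on the protein/lipid/water simplex (concentration
(22.8, 7.8, 29.4) — 60 × a typical dry-cured-loin proximate composition of
38/13/49 %) and a drying index from Beta(2, 2).  The noise-free spectrum is
a constant diffuse-reflectance baseline (0.3 AU) plus constituent-weighted
Gaussian bands (in wavenumber space; widths specified in nm and converted
at the band center) at the classical assignments: C–H near 1200, 1725/1760
and 2300–2350 nm; N–H/O–H near 1450 nm; O–H at 1900 nm.  The 1900 nm
free-water band shrinks with the drying index (factor 1 − 0.5·d), giving
the drying state its own spectral signature while the 1450 nm band stays
informative about total water.  Each replicate row is corrupted by a
multiplicative gain ~ N(1, 0.05), an additive offset ~ N(0, 0.01 AU) and
i.i.d. channel noise (SD 10⁻³ AU).  Scatter varies per replicate, not per
sample, so MSC/SNV have real work to do and replicate averaging alone
cannot remove it.

Sensory scores: for each attribute, a fixed unit-norm loading vector over
the standardized latents gives z; the signal is the monotone map
z + κ·z³/3 (nonlinearity knob κ, default 1.0 ⇒ roughly 15 % of the signal
variance is invisible to a linear model); Gaussian noise (SD 0.1 in
standardized units by default) is added; the result is affinely rescaled
to the published per-attribute (mean, SD) and clipped to [1, 9].  The
ground-truth signal is exposed (`sensory_signal`) for parameter-recovery
tests.  What the generator does **not** emulate: instrument drift,
wavelength miscalibration, sample-presentation effects, panelist
disagreement structure, or correlated channel noise — so passing tests
demonstrate correctness of the algorithms under the stated statistical
model, not instrument-grade performance on real loins.

## Pipeline conventions and numerical choices

* **Smoothing spline** — natural cubic smoothing spline per spectrum over
  the wavenumber axis, classical trade-off p·Σ(y−f)² + (1−p)·∫f″², i.e.
  roughness weight λ = (1−p)/p (p→1 interpolates, p→0 tends to the OLS
  line); default p = 0.01.  Verified against an independent discrete
  penalized-least-squares solve.
* **MSC** — per-row OLS on a reference spectrum, corrected = (row−a)/b;
  the reference is the calibration-set mean (the all-sample mean is used
  only inside SPXY, where no split exists yet).  Exact on affine
  corruptions and idempotent for a fixed reference.
* **SNV** — row-wise (x−mean)/SD with the n−1 divisor; constant rows are
  an error.
* **Derivatives** — central differences on the uniform grid; endpoint
  channels use one-sided differences of the same order so every
  pre-treatment preserves the channel count (keeps the grid search
  comparable across cells).
* **Normalizations** — column-wise mean-center, autoscale, Pareto
  ((x−μ)/√SD), Poisson (x/√μ, μ>0), MinMax onto [−1, +1] without clipping
  at prediction time.  All statistics are frozen on calibration rows;
  Y is never scaled (an explicit design choice — the SVR tube width ε is
  then in score units).
* **Replicates** — averaged per sample before modeling (default), keeping
  n = 40; a `keep` policy expands scores to all 120 replicate rows for
  sensitivity analyses.
* **SPXY** — joint distance dₓ/max dₓ + d_y/max d_y, Kennard–Stone
  selection with ties broken to the lowest index; calibration size is
  round-half-up(0.67·n) → 27/13 at n = 40.  Distances are computed on
  smoothed + pre-treated (but unnormalized) spectra.  Splits are per
  attribute, since the distance depends on y.
* **RMSECV** — pooled convention √(Σ all held-out e²/n) (a fold-averaged
  alternative is a flag); folds are contiguous blocks of a seeded shuffle
  and are built once per tuning run so every candidate parameter vector is
  scored on identical folds.
* **PSO + pattern search** — global-best PSO on the unit cube (log₁₀
  mapping for C, ε, γ), inertia 0.729, cognitive = social = 1.49445,
  velocity clamp 0.5, boundary reflection; then compass search from the
  best point with step halving down to tolerance.  Defaults: swarm 20 ×
  50 iterations, patience 10 ("full" preset); the "ci" preset (swarm 10 ×
  20, patience 6) is used throughout the test suite and acceptance script
  so full runs finish in minutes — results at that budget are already
  stable because the RBF RMSECV surface is smooth in log-parameters.
  Search box: C ∈ [10⁻², 10²], ε ∈ [10⁻³, 1], γ ∈ [10⁻³, 1] (log), coef0 ∈
  [−1, 1], ν ∈ [0.01, 0.99], degree ∈ {2..5} (rounded continuous
  dimension).
* **Model selection** — lowest RMSECV per attribute, RMSEP only as a
  tie-break: selecting on the prediction set would leak it into training.
* **Merit statistics** — R² is 1 − SSE/SST; RSD% divides RMSEP by the mean
  observed prediction-set value (the convention string is embedded in
  every report); the EJCR regresses predicted on observed and tests
  (0, 1) with the F(2, n−2) ellipse — a zero-residual regression returns
  "contains" with a `degenerate` flag; DW uses the N(2, 4/n) null
  approximation, with prediction residuals ordered by observed value so
  the statistic responds to curvature.
* **Determinism** — every stochastic step (generator, folds, PSO) is
  seeded; per-cell seeds are SHA-256 digests of (master seed, attribute,
  cell coordinates), so a cell's result is independent of which other
  cells are in the grid and a saved manifest reruns byte-identically.
  Fitted models predict from stored arrays in plain numpy (not through the
  solver), so serialized models reproduce predictions bit-exactly.

## Problem sizes used in tests

The test suite runs the full-geometry dataset (40 × 3 × 1501) for
end-to-end checks and a coarse 12-sample × 151-channel variant for unit
tests.  The parameter-recovery check uses the generator's high
signal-to-noise condition (sensory noise SD 0.02, instrument noise
10⁻⁴ AU, nonlinearity and scatter retained) over seeds 1–3 with the "ci"
tuning budget, asserting seed-averaged prediction R² ≥ 0.95 and RSD < 5 %
per attribute and a materially worse PLS baseline.  The acceptance script
runs the realistic-noise defaults once at the given seed.

## Known limitations

* The Durbin–Watson probability ignores the dependence of the exact null
  distribution on the regression design (Imhof/Pan methods are out of
  scope); at n ≈ 13–40 the normal approximation is adequate for a
  screening flag, as checked by simulation.
* The EJCR's degenerate branch declares a perfectly fitted regression
  accurate even if its slope is not 1; callers must inspect the flag.
* With replicate averaging the effective noise floor depends on the
  replicate count; the generator's defaults assume three replicates as in
  the emulated design.
* SNV/MSC only approximately preserve the ranking of band-area features
  even without scatter (row-wise rescaling interacts with composition);
  the pipeline never relies on exact preservation.
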