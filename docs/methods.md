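# Methods

## Forward signal model

The tissue model is the standard two-compartment restricted-diffusion
picture used for cell-size imaging: impermeable spheres of diameter *d*
(intracellular water, volume fraction *f*<sub>in</sub>, diffusivity
*D*<sub>in</sub>) embedded in hindered extracellular water with a single
apparent diffusivity *D*<sub>ex</sub>. Exchange, membrane permeability,
non-spherical geometry and intra-voxel size distributions are all
ignored; *D*<sub>ex</sub> is frequency independent (the data being
emulated report one extracellular diffusivity, not a dispersion
coefficient).

Intracellular attenuation uses the Gaussian phase approximation. With
the roots μ<sub>k</sub> of j₁′(μ) = 0, mode rates
λ<sub>k</sub> = μ<sub>k</sub>²·D<sub>in</sub>/R² and weights
B<sub>k</sub> = 2R²/(μ<sub>k</sub>²(μ<sub>k</sub>²−2)) (which sum to the
equilibrium variance R²/5), the position autocorrelation of a spin in
the sphere is Σ B<sub>k</sub>·exp(−λ<sub>k</sub>|t₁−t₂|) and

ln S = −γ² g² Σ<sub>k</sub> B<sub>k</sub> F<sub>k</sub>(timing),

where F<sub>k</sub> is the double time-integral of the effective
gradient against the exponential kernel. For two rectangular lobes this
reduces to the Murday–Cotts expression; for two lobes of an integer
number of cosine periods the closed form was derived by direct
integration and verified against brute-force numerical quadrature of
the kernel (< 10⁻³ relative). The mode sum is truncated adaptively:
K doubles from 32 until ln S changes by < 10⁻⁸ (cap 4096), which keeps
the free-diffusion limit accurate even for very large spheres where the
spectrum is nearly continuous.

Units are µm, ms, µm²/ms and mT/m internally; b-values are exposed in
s/mm² (1 s/mm² = 10⁻³ ms/µm²) and γ = 2.675·10⁻⁴ rad/(ms·mT/m·µm).
Exactly one of gradient amplitude and b-value is free per measurement;
the other follows from the closed-form b of the waveform
(γ²g²δ²(Δ−δ/3) for PGSE, γ²g²δ/ω² for cosine OGSE).

Two physical regimes are worth noting because tests assert them at
parameter values where they genuinely hold. The approach of the
apparent intracellular ADC to *D*<sub>in</sub> at high oscillation
frequency follows the slow √(1/ω) dispersion law, so "short-time"
behaviour within 5% needs ~1 kHz on a 20 µm cell, not a few hundred Hz.
Likewise a "free-diffusion" sphere must be large against the boundary
layer: the Mitra correction (4/(9√π))·(3/R)·√(D·t) is still ~3% at
d = 200 µm for clinical timings and falls below 1% only for millimetre-
scale spheres.

## Acquisition scheme

The protocol timing is a representative clinical 3-T stand-in: PGSE
δ = 12 ms, Δ = 30 ms; cosine OGSE at 20 Hz (1 period per 50 ms lobe)
and 40 Hz (2 periods per 50 ms lobe); b = {0, 300, 600, 1000, 1500}
s/mm² for PGSE and 20 Hz and {0, 300, 600, 1000} for 40 Hz, where
gradient amplitude limits bite first. All timing is overridable through
the scheme JSON. The OGSE lobe separation is not part of the public
timing surface; lobes are placed contiguously by default (the
cross-lobe term of the GPA sum is negligible for cosine lobes), with an
optional separation field for other layouts.

## Voxelwise fitting

Three parameters (*d*, *f*<sub>in</sub>, *D*<sub>ex</sub>) are fitted
per voxel by bounded trust-region least squares with
*D*<sub>in</sub> frozen at 1.56 µm²/ms. Bounds are physiologically
plausible tumor ranges: d ∈ [5, 25] µm, f_in ∈ [0, 1],
D_ex ∈ [0.1, 3.1] µm²/ms. A deterministic 4×4×4 start grid spans the
bounds; starts are ranked by initial residual and the best six are
refined, the lowest final RSS winning (ties break toward smaller *d*,
then smaller *f*<sub>in</sub>). Because the intracellular signal is a
smooth function of *d* alone for fixed timing, each scheme gets a dense
cubic-spline cache of ln S<sub>sphere</sub>(d) (257 knots over the
bounds), which reproduces the spectral sum far below optimizer
tolerance (10⁻⁸) and makes per-voxel fits ~30 ms. Non-converged or
invalid voxels (non-positive b=0 signal) are excluded from VOI means,
never imputed; a warning fires if more than half a mask fails.
Cellularity is reported as 100·*f*<sub>in</sub>/*d* in 10⁻² µm⁻¹, the
scale on which typical tumor values sit near 2–3 and which matches the
magnitude of the published group means this package emulates.

ADCs are monoexponential: the least-squares slope of −ln S against b
with a free intercept, per sequence. rADC compares the 40 Hz OGSE and
PGSE ADCs in percent.

## Monte-Carlo oracle

The physics cross-check is a random walk of (by default) 10⁵ spins
uniformly seeded in an impermeable sphere, Gaussian steps with
per-axis σ = √(2·D·dt) and specular reflection of the radial overshoot
at the wall, phase accumulated against the discretized effective
waveform, signal = ⟨cos φ⟩ with a reported standard error. The default
step keeps the 3D rms displacement at d/20.5; steps coarser than d/20
are rejected. The estimate is flat under 8-fold step refinement at the
tested conditions. GPA and oracle agree to ≲0.005 in ln-signal for
d ≤ 14 µm at b = 1000 s/mm²; at d = 20 µm the two differ by up to
~0.016 because the Gaussian phase approximation itself degrades as the
intracellular attenuation grows — a known property of the expansion,
not a simulator artifact (the difference survives step refinement and
walker-count increases). Anyone using the forward model at large cell
sizes and strong weighting should expect ~1–2% model error there.

## Synthetic data

Generators are pure functions of (configuration, seed).

* **Phantoms.** 32³ default grid at 2 mm voxels with an ellipsoidal
  tumor of ~9–10 cm³ (the median tumor-volume scale of the emulated
  cohort); per-region two-compartment parameters; Rician magnitude
  noise with σ = 1/SNR defined at b = 0. The high-SNR Rician mean
  excess is below 1/(2·SNR²) relative, and a test pins that bound.
* **Test-retest.** Lognormal subject means (default mean 2.4,
  between-subject CV 20%, chosen from the 10–33% spread implied by the
  published per-metric group SDs) with unit-mean multiplicative
  lognormal within-subject noise (default CV 9%). Because the noise is
  multiplicative, the raw-scale estimand of the within-subject-SD
  method is within_cv·√(1+between_cv²); the generator records it, and
  recovery tests compare against it. The heteroscedasticity this
  design implies makes the n-df chi-square interval for wSD slightly
  narrow (measured coverage ~91–93% instead of the nominal 95% at
  n = 54) — a structural property of pairing a multiplicative noise
  model with a homoscedastic interval, documented here rather than
  hidden by retuning the generator.
* **Reader masks.** Boundary voxels of the reference mask are flipped
  with a probability found by bisection under common random numbers
  (monotone in the flip probability), widening the boundary shell as
  needed, until the Dice target is hit within 0.01.
* **Cohort.** Response labels are assigned first with exact counts
  (220 participants, 151 responders by default); covariates and
  imaging VOI means are then sampled conditionally on the group from
  the published training-set marginals and group summaries.
  Cellularity and rADC are derived row-wise from the sampled
  (f_in, d) and ADCs, so the deterministic relations between reported
  metrics hold exactly in every row. An `effect_scale` knob
  interpolates all group contrasts toward the pooled distribution
  (0 = null generator). A separate helper assigns labels through a
  generative logistic model for parameter-recovery and calibration
  simulations.
* **Histology pairs.** Gaussian-copula blends reproducing configured
  Pearson correlations (defaults 0.67/0.34/0.27 for diameter,
  cellularity, f_in on a 97-sample subset) on a standardized
  histology scale.

What passing tests on these data do **not** show: robustness to
susceptibility distortion, partial-volume and necrosis effects, reader
delineation behaviour on real anatomy, exchange between compartments,
or covariate correlation structure beyond what the group-conditional
sampling induces. The generators reproduce printed *marginal* summaries,
not the unobserved joint distribution of the source population.

## Statistics

* Bland–Altman limits use 1.96·SD with the n−1 SD; RC = 1.96·√2·wSD
  with wSD² = Σdᵢ²/(2n) and a chi-square CI (n df) on Σdᵢ²; wCV divides
  wSD by the grand mean of all measurements. RC equals the
  Bland–Altman half-width whenever the bias is negligible, and every
  AgreementReport asserts the bracketing invariants.
* ICC is the two-way mixed-effects, absolute-agreement, single-rater
  form with the McGraw–Wong F-based interval; it matches pingouin's
  ICC(A,1) to 10⁻⁶ in tests. A zero-variance matrix returns ICC 1 with
  a degenerate flag. Kappa is unweighted (quality scores treated as
  nominal).
* The stratified split apportions per-stratum training counts by
  largest remainder so stratum and grand totals are simultaneously
  consistent (220 → 154/66 with 106/48 responders/nonresponders in
  training). Categorical predictors are reference-coded by the
  smallest category (ties alphabetical). Chi-square tests carry no
  continuity correction; 2×2 tables with any expected count < 5 route
  to Fisher's exact test.
* AUC is the tie-corrected Mann-Whitney estimator (equal to exhaustive
  pairwise concordance with half-credit ties); bootstrap CIs are
  percentile, class-stratified, 1000 resamples by default. The DeLong
  test uses midrank structural components. Youden cutoffs scan
  midpoints between distinct scores with ties broken toward higher
  specificity, and predictive values carry explicit
  numerator/denominator pairs. Hosmer–Lemeshow uses equal-count risk
  deciles (ties merged with a warning) and G−2 degrees of freedom.
  Decision curves report NB(p) = TP/n − FP/n·p/(1−p) against treat-all
  and treat-none.
* The AUC sample-size routine solves the two-sided normal power
  equation with Hanley–McNeil variances and fractional group sizes;
  the published design inputs (0.50 vs 0.75, 70% positives, 90% power)
  give n = 57 here against a printed 59 from closed-source software —
  within the tolerance the calculation itself warrants.

## Problem sizes

The shipped analyses and tests use a 16³ phantom (~600 tumor voxels)
at SNR 50, 10⁵–3·10⁵ Monte-Carlo walkers, 500 test-retest replications,
1000 null simulations for DeLong and Hosmer–Lemeshow calibration, and
100 simulated studies for the end-to-end direction check — sizes at
which every estimate's Monte-Carlo error is small against the bands
being asserted.

## Known limitations

GPA error at large d and strong weighting (above); single-scanner,
single-protocol emulation; no spatial regularization across voxels; the
cohort generator's per-group sampling reproduces univariable contrasts
exactly but multivariable effect sizes only approximately; Fisher
routing applies to 2×2 tables only (larger sparse tables fall back to
chi-square with a warning).
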