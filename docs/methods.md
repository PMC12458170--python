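# Methods

## The diffusion model

Each voxel's diffusion-weighted signal is modelled as a linear mixture of
three water pools with fixed diffusivities:

| compartment | axial D (mm²/s) | radial D (mm²/s) | angular order |
|---|---|---|---|
| restricted | 1×10⁻³ | 0 | even SH, l ≤ 4 |
| hindered | 1×10⁻³ | 0.9×10⁻³ | even SH, l ≤ 4 |
| free | 3×10⁻³ (isotropic) | — | l = 0 |

Because the restricted and hindered kernels are axially symmetric, the
forward map from each pool's orientation distribution to the measured signal
is a spherical convolution.  In the real, even-order spherical-harmonic (SH)
basis this convolution is diagonal per degree l: the degree-l rotational
response of a kernel S(u) = exp(−b(D_rad + (D_ax − D_rad)u²)) is the
Legendre projection r_l(b) = ½∫₋₁¹ S(u) P_l(u) du, evaluated by 64-node
Gauss–Legendre quadrature (exact to machine precision for the smooth
kernels with b·D ≤ 9 used here; at b = 0 the responses are set to their
exact values 1 and 0).  r₀ is the spherical mean of the kernel.

The voxel model is therefore a single design matrix with 31 columns
(restricted 15, hindered 15, free 1) whose (i, j) entry is
r_l(b_i)·Y_lm(g_i), and fitting is one regularised least-squares solve per
voxel (spherical deconvolution).  The SH convention is the modified real
basis standard in diffusion MRI, ordered by l ascending then m ascending;
it is orthonormal on the sphere, which the tests verify by Fibonacci-grid
quadrature.

### Normalised metrics

With N the Euclidean norm of the full 31-coefficient vector:

* RNI = |restricted l=0| / N — isotropic (spherical-mean) restricted
  fraction, the cellularity-sensitive metric;
* RND = ‖restricted l=2,4‖ / N — directional restricted fraction
  (oriented neurites);
* HNI, HND — hindered analogues; FNI = |free| / N.

Totals combine the two parts either additively (`sum`, the default:
RNT = RNI + RND) or in quadrature (`euclidean`: RNT = √(RNI² + RND²)).
Both conventions circulate; the additive reading is the default here and
the quadrature form is one flag away.  All outputs are clipped to [0, 1];
with the additive convention the clip can in principle break exact
additivity when RNI + RND > 1, which cannot occur for the non-negative
mixtures the model is meant for.  The normalisation denominator (full-vector
Euclidean norm) is a documented choice; the literature states only that the
indices are "normalised to yield signal fractions".

### Numerical choices in the solver

The least-squares problem is solved by SVD with a Tikhonov ridge,
λ = 10⁻⁶ relative to the largest singular value, **in a column-equilibrated
basis** (each design column scaled to unit norm).  Equilibration matters:
the raw design's condition number is ≈7×10⁴ because the nearly isotropic
hindered kernel barely excites l = 4 (column norms ≈10⁻⁴), and a relative
ridge applied to the raw matrix would bias recovered coefficients at the
10⁻² level.  After equilibration the condition number is ≈14 and noiseless
in-model signals round-trip to ≈10⁻⁸ relative error.

The flip side of exact recovery is amplification: any signal component
outside the model class (SH content above l = 4, or noise) is mapped into
the near-unobservable hindered l=4 coefficients with gain ≈10⁴.  For noisy
data a stronger ridge (10⁻³–10⁻²) is appropriate and is exposed both in the
API and the CLI (`--ridge`).  Voxels with non-finite signal or non-positive
mean b0 signal are flagged invalid (NaN in metric maps), never raised over.

## The phantom

The acquisition generator reproduces the study protocol: 6 b = 0 volumes
plus 6/15/15/60 directions at b = 500/1000/2000/3000 s/mm² (102 volumes).
The study's own direction tables are not published, so per-shell directions
come from a seeded Fibonacci-sphere layout — near-uniform, deterministic per
seed, and adequate for a single-fiber phantom (it is not an electrostatic-
repulsion optimised set).

Voxel signals are fraction-weighted sums of the compartment signals:
restricted and hindered as axially symmetric tensors about a fiber axis
(optionally averaged over a Watson-style orientation distribution with
concentration 1/dispersion; the default is an ideal stick), free as a
mono-exponential isotropic decay.  Rician noise follows the magnitude-MRI
convention √((S+ε₁)² + ε₂²) with σ = S(b=0)/SNR.  A `bandlimit` flag
restricts the anisotropic compartments to their even-SH content up to the
model's lmax, producing signals exactly inside the model class — used by
tests that check in-model recovery; the full tensor (default) carries the
l > 4 remainder of an ideal stick and exercises the truncation behaviour
discussed above.  Scanner artifacts (motion, eddy currents, susceptibility)
are not simulated; motion enters the pipeline only as precomputed RMS
summaries.

## The cohort generator

The cohort table emulates the statistical structure the ROI analysis
assumes, with defaults fixed at the study conditions:

* groups: 81 ADHD / 78 TD children;
* anthropometrics drawn per group from the published means and SDs
  (BMI 16.68 (2.39) vs 16.48 (2.27); % body fat 23.04 (8.11) vs 22.31
  (6.77); waist 57.93 (7.94) vs 57.34 (5.69) cm), with a latent correlation
  of 0.6 among the three measures (a realistic mid-range value; the paper
  reports no correlation matrix);
* covariates: age ~ U(4, 7) years, sex ~ Bernoulli(0.65), a 4-level parent
  education variable, positively skewed (lognormal) movement;
* outcomes: each `metric_roi` column is β·z(BMI) (+ optional interaction)
  plus small covariate effects plus Gaussian noise scaled so the total
  variance is 1, with β = 0.22 by default — the magnitude of the strongest
  published brain–BMI associations;
* missingness: waist and % body fat deleted missing-at-random with
  probability logistic in group and standardized age (coefficients 0.5),
  intercept calibrated so the expected rates equal the study's 13.8% and
  12.6%;
* obesity status: BMI at or above the 85th percentile of the synthetic BMI
  distribution (the overweight/obese CDC cutoff; the threshold is a config
  parameter, and LMS-based classification against a user-supplied growth
  reference is available separately).

What the generator does **not** reproduce: real anthropometric skewness and
measurement error, age-dependent BMI norms, site/scanner effects, spatial
correlation among ROI outcomes, and any non-MAR missingness mechanism.
Passing tests therefore demonstrate the correctness of the estimation
machinery under the assumed structure, not robustness to violations of it.

## Imputation and pooling

Fully conditional specification: each incomplete continuous variable is
regressed on all other numeric variables; regression coefficients and the
residual variance are drawn from their posterior under the standard
noninformative prior, and missing entries are replaced by posterior
predictive draws.  Two (or more) parallel chains run 50 Gibbs sweeps between
saved imputations (and before the first), and 20 completed datasets are
collected round-robin across chains.  Convergence is summarised by the
Gelman–Rubin potential scale reduction factor of the per-sweep means of the
imputed values, second half of each chain; values below 1.05 indicate
stable imputations.  Only continuous variables carry missingness in this
design, so no categorical imputation models are provided.

Rubin's rules combine the m per-imputation estimates: Q̄ (mean), W̄ (mean
within variance), B (between variance), T = W̄ + (1 + 1/m)B, with
Barnard–Rubin small-sample degrees of freedom when the complete-data df is
known.  When B = 0 (estimates identical across imputations, e.g. a
predictor untouched by imputation), the df reduce to the observed-data
form.

## ROI analysis

Per (metric × ROI × predictor), Model 1 regresses the z-scored outcome on
the z-scored predictor, the group indicator, their interaction, and the four
covariates (age, sex, parent education, movement; continuous ones z-scored,
binaries left 0/1).  The interaction term is pooled across imputations and
Benjamini–Hochberg-corrected across the 10 ROIs within the metric
(predictors are treated as separate families).  If no interaction survives
at α = 0.05, the model is refit without it (Model 2) and the pooled main
effect is reported with its own within-metric FDR.  The semipartial
correlation is computed from the pooled t statistic and the mean R² across
imputations as r_sp = t·√(1 − R²)/√(df_resid).

Group contrasts use the pooled-SD two-sample t test with Cohen's
d = (mean_TD − mean_ADHD)/s_pooled (the sign convention required by the
published negative d values alongside higher ADHD means) and a normal-
approximation CI with Var(d) = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)).  Binary
measures use the Yates continuity-corrected χ² and φ = √(χ²/N) — the only
convention that reproduces the published φ = 0.06 (the uncorrected χ² gives
0.08).

Motion QC excludes subjects whose mean RMS displacement exceeds 1.7 mm
(one voxel) — strictly greater-than, so a subject exactly at the cutoff is
retained; retained subjects carry their RMS value as the movement
covariate.

## Problem sizes in the shipped checks

The replicate study behind the slope-recovery numbers uses 200 synthetic
cohorts (n = 159, β = 0.22, study missingness, m = 20 imputations each) and
a single outcome column, which is sufficient to pin the mean pooled β̂ and
CI coverage to ±0.01–0.03 Monte-Carlo error.  The null FDR check uses 200
complete-data cohorts over the full 10-ROI family with m = 2 (pooling is
degenerate without missingness, so larger m adds cost but no information).
Deconvolution checks use 25–50 random voxels on the full 102-volume scheme.

## Known limitations

* The deconvolution is unconstrained; negative lobes in fitted FODs are
  possible and only the normalised, clipped metrics are guaranteed to lie
  in [0, 1].  A bound-constrained option for the isotropic coefficients
  (`nonneg_isotropic`) is not the default because the linear solver's
  exactness underpins the round-trip guarantees.
* Watson dispersion in the phantom is discretised on a 256-point Fibonacci
  grid; for concentrations above ~50 the quadrature under-resolves the peak.
* The imputation engine covers continuous variables only.
* The LMS growth-reference table is user input; no CDC data ship with the
  package.
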