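# Methods

## Model

A quantitative trait measured on n related individuals is modelled per
family block b as y_b ~ MVN(X_b beta, Omega_b).  The mean model X carries
an intercept, by default the individual's standardized socioeconomic score
(zSES) — so that variance-function estimates are not confounded by an
unmodelled mean trend — and any user-supplied covariates.  The covariance
combines three components:

* **Additive genetic.**  Share proportional to the additive relationship
  K_ij = 2 phi_ij, computed by the recursive tabular method
  (phi_ii = (1 + phi_fm)/2, phi_ij = (phi_jf + phi_jm)/2 over a
  parent-before-offspring ordering).  The recursion handles inbreeding
  loops naturally (diagonal 1 + F); no special casing is needed or done.
* **Household.**  Share governed by the binary same-household indicator
  H_ij.  Individuals with no recorded household contribute no household
  variance (zero row and column, including the diagonal).
* **Residual environmental.**  Diagonal only, by the standard assumption
  that genetic and residual effects are uncorrelated.

GxE enters through log-linear variance functions
sigma^2(z) = exp(alpha + gamma z) — exponential to keep variances positive
with z on its natural standardized scale — and exponential-decay
correlation functions rho(z_i, z_j) = exp(-lambda |z_i - z_j|) for the
genetic and household components.  Cross terms use the geometric mean
sqrt(sigma^2(z_i) sigma^2(z_j)), the only construction consistent with a
variance function indexed by the individual.  Setting all gammas and
lambdas to zero reduces Omega bit-identically to the classical polygenic
(model 1) or polygenic + household (model 2) decomposition; this reduction
is asserted in the test suite.  The decay kernel exp(-lambda |d|) is a
positive-definite function, and the elementwise (Schur) product with the
PSD kinship matrix preserves positive semidefiniteness, so Omega is
positive definite whenever sigma_e^2 > 0.

## Estimation

The likelihood factorizes over the connected components of the union of
the parent-offspring graph and the same-household graph; household links
can merge otherwise unrelated nuclear families, so blocking on the
pedigree alone would be wrong whenever the household component is active.
Individuals missing the trait, zSES, or a covariate are dropped from y and
Omega but retained in the kinship computation, where they still transmit
relatedness between observed relatives.  Missing data are never imputed.

Fitting maximizes the profile likelihood over the variance parameters
theta = (alphas, gammas, lambdas); the mean coefficients are concentrated
out by GLS at every theta, which leaves the maximum and (by the envelope
theorem) the gradient unchanged relative to joint optimization.  The
gradient is analytic: d l/d theta_k = -1/2 sum_b tr[(Omega_b^{-1} -
s_b s_b') dOmega_b/dtheta_k] with s_b = Omega_b^{-1}(y_b - X_b beta-hat),
and each dOmega/dtheta is an elementwise product of the component matrix
with a fixed geometry factor ((z_i+z_j)/2 for gammas, -|z_i - z_j| for
lambdas).  The finite-difference gradient is cross-checked in the tests.

Numerical choices:

* Optimizer: L-BFGS-B, `ftol` 1e-11 (loglik changes below ~1e-8 count as
  converged), `gtol` 1e-7, at most 500 iterations.
* Bounds: lambdas live on [0, 20] on their natural scale — not log scale —
  because lambda = 0 is a null hypothesis of scientific interest and must
  be attainable exactly.  Alphas are boxed to log(var(y)) + [-20, +5] so a
  vanishing component is numerically reachable without leaving the
  feasible region; gammas to [-5, 5] per zSES unit.
* Multi-start: a moment-style start (component shares of the trait
  variance, gammas 0, lambdas 0.05) plus seeded N(0, 0.5) jitters;
  5 starts by default.  In the replicate simulation studies two starts are
  used: on generator output the moment start is already in the basin of
  the optimum, and a pilot comparison of 2 versus 4 starts over 24
  replicates changed no fitted likelihood by more than 1e-9.  Null fits in
  the testing hierarchy are warm-started from the full-model optimum.
* A lambda estimate below 1e-6 counts as sitting on its boundary.
* Null models for sigma_g^2 = 0 / sigma_c^2 = 0 are expressed by removing
  the component from the model specification rather than driving an alpha
  to -infinity.
* Degenerate inputs (fewer observations than parameters, a single tiny
  block) are refused with a non-identifiability error.

Standard errors come from the inverse central-difference Hessian of the
profile likelihood at the optimum (pseudo-inverse when a component is
nearly vanishing), restricted to interior parameters; boundary estimates
are flagged and reported without SEs.  The SE of h^2 (a ratio of variance
functions) uses the delta method in the fitted log-variance
parameterization; a Hessian taken in a direct (sigma_g^2, sigma_e^2)
parameterization would differ slightly in finite samples.

## Testing procedure

Three gatekept stages, each at alpha = 0.05 by default:

1. **Heritability and household screening.**  sigma_g^2 = 0 and
   sigma_c^2 = 0 are boundary hypotheses; their LRT statistics follow the
   equal mixture (1/2) chi2_0 + (1/2) chi2_1, so p = 0.5 P(chi2_1 >= stat),
   exactly 0.5 for an estimate on the boundary.  The household decision
   selects model 1 or model 2 for everything downstream.
2. **Joint GxE test.**  The full GxE model (free gamma_g, lambda_g,
   gamma_e, plus gamma_c, lambda_c under model 2) against the chosen base,
   referred to chi2 with 3 or 5 df.  The exact null is a mixture because
   the lambdas sit on a boundary, so plain chi2 is conservative; the
   simulation suite measures the realized type-I error (about 0-2% at
   nominal 5% in the null-calibration battery) rather than pretending the
   reference is exact.  Raw p-values are adjusted across the trait panel
   (Bonferroni min(1, m p) by default, m the panel size; Holm and
   Benjamini-Hochberg available).
3. **Component tests.**  Single-parameter LRTs against the full fit:
   chi2(1) for the gammas, the half-mixture for the lambdas.  When the
   full-model lambda estimate is already on its boundary the constrained
   optimum coincides with the unconstrained one, so the statistic is
   exactly 0 and the p-value exactly 0.5 — boundary estimates therefore
   print as 0.50000 in the component-test table.

Negative LRT statistics from optimizer round-off are clipped to zero;
clips larger than 1e-6 are logged as warnings.

## Preprocessing

zSES is the standardized sum of the standardized socioeconomic index and
education years (n-1 denominator throughout); it is invariant to affine
rescaling of either input and is computed on the post-exclusion sample by
default (configurable).  Exclusion flags (diabetes, diabetes medication,
hypertension medication, dyslipidemia medication) drop rows before any
other step.  Traits are residualized on their covariate list by OLS — the
explained variance share is reported alongside heritability — and the
residuals are mapped to normal scores by the rank-based transform
Phi^{-1}((r - 3/8)/(n + 1/4)) (Blom offset, configurable), with ties
sharing their average rank.  A mediation screen regresses zSES on one
candidate covariate at a time and Bonferroni-adjusts the slope p-values.
A metabolic-syndrome classifier from four printed thresholds (TG > 150
mg/dL; HDL < 40/50 mg/dL by sex; BP >= 135/85 mmHg; fasting glucose > 100
mg/dL; positive at >= 3 flags) is included as a utility; the blood-pressure
criterion circulates in print as "<135/85", which we read as a typo for
the at-or-above direction — the direction is configurable.

## Synthetic data generator

The generator emulates the recruitment structure of an extended-family
study: each of 42 families contains two unrelated founder couples
(proband's and spouse's kin) whose offspring intermarry once; the other
offspring marry in external founders with probability 0.8; sibships are
1 + Poisson(2.5) (mean 3.5); three generations; one household per married
couple, with unmarried children in the parental household.  These defaults
put simulated totals at roughly 1,250-1,450 individuals, bracketing the
emulated study's ~1,100-1,400 analyzable sample.  zSES adds a
household-level N(0, tau^2) component (tau = 1 by default; there is no
published within-household SES correlation to calibrate against, so this
is a documented convention) to unit individual noise, then standardizes.
Traits are drawn per family block as y = X beta + L eps with L the
Cholesky factor of the block covariance built from the true parameters, so
simulated moments match the fitted model's covariance by construction.
Optional covariates: age uniform on 18-94 and sex with 57% female,
matching the emulated study's descriptive margins.

What the generator does **not** emulate: proband-based ascertainment (the
families are drawn unconditionally), missing-data patterns, measurement
error in SES, non-Gaussian trait distributions (real traits reach
normality only after the rank transform), and secular or age trends in
SES.  Passing recovery tests therefore demonstrates correctness of the
estimator and tests under the stated model, not robustness to these
real-data complications.

Named presets fix the study conditions used throughout the test battery:
`null` (no genetic variance), `polygenic` (h^2 = 0.45, the fasting-glucose
scale), `variance-het` (gamma_g = -0.5, lambda_g = 0.3 — genetic effects
upregulated at low SES), `corr-decay` (lambda_g = 0.5), and
`household-het` (gamma_c = -0.5 with h^2 = 0.31, c^2 = 0.11, the systolic
blood-pressure pattern).

## Problem sizes and determinism

The replicate studies run at the default 42-family scale: 50 replicates
for heritability recovery (mean h^2 within 0.05 of truth; mean delta-method
SE about 0.05), 50 for GxE recovery (replicate means of all free
parameters within 3 replicate-SEs of truth; gamma_g-test power >= 0.8), and
200 for null calibration (gamma_g type-I error inside the binomial 95% CI
of 0.05; lambda_g boundary mass 0.5 +- 0.07).  The acceptance script uses
25/25/100 replicates for the same quantities.  Every random draw flows
from a single integer seed — generator output, optimizer jitter, and
pipeline output files are byte-identical across repeated runs.

## Scope and limitations

Single-trait analyses only (no multivariate decomposition); no dominance,
epistasis, or marker-based IBD; no REML (ML estimates of variance
components carry the usual small downward bias, immaterial at several
hundred effective degrees of freedom); no ascertainment correction; the
covariate lists per trait are user-supplied rather than selected by any
automated model search.  Fits re-estimate the total variance freely; with
inverse-normalized inputs (variance 1 by construction) the distinction
from a constrained-total parameterization is negligible.
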