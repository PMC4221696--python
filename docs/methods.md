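# Methods

This package implements multi-line genomic prediction for a three-line
layer-hen setting: two closely related brown lines (B1, B2) and one
distantly related white line (W1), with the same trait measured in each
line. It provides the linear and non-linear predictors, the variance
component machinery, the evaluation statistics, and a synthetic data
generator that stands in for the proprietary breeding data such studies
are run on.

## Prediction models

All predictors are ridge-type regressions of pre-corrected phenotypes on
marker dosages (0/1/2), fitted per training scenario.

**Ridge regression.** With centered dosages X (n animals x m markers) and
penalty gamma > 0, the primal solution is w* = (X'X + gamma I)^-1 X'y and,
by the Woodbury identity, identically w* = X'(XX' + gamma I)^-1 y. The
dual form costs O(n^3) instead of O(m^3), which matters because n << m.
Both are implemented and tested to agree to 1e-8.

**Kernel ridge.** Replacing inner products with a kernel K(x, t) gives
y* = y'(K + gamma I)^-1 k, where K is the training Gram matrix and k the
vector of kernel values between training animals and the test animal.
Kernel families:

- linear: K(x, t) = x't (equivalent to ridge regression);
- polynomial: K(x, t) = (x't + c)^l, inhomogeneous when c > 0. The degree
  and shift actually used in the original study are not reported; the
  defaults here are l = 2, c = 1.
- distance: K(x, t) = exp(-(d_p(x, t)/h)^q) with d_p the L_p norm of
  x - t. p = 2, q = 1 (the exponentiated Euclidean distance) is the RBF
  form used by default; p = 1 gives the Laplacian kernel; q = 2 the
  classical squared-exponential Gaussian. Which exact form the original
  study computed is not reported; all are exposed.

A bandwidth h is required in practice: with thousands of markers, raw
distances are of order sqrt(m) and exp(-d) underflows to zero for every
pair, making the unscaled kernel degenerate. The default is the median
heuristic (median pairwise training distance); h = 1 recovers the
unscaled form. Genotypes are centered by training-set marker means before
any kernel, consistent with the intercept-free model; phenotypes are
centered by the training mean, which is added back at prediction.

**GBLUP.** The genomic relationship matrix is G = ZZ' / (2 sum f_j(1-f_j))
with Z the dosages centered at twice the allele frequencies. GEBV come
from the single-trait mixed model; with shrinkage lambda = sigma_e^2 /
sigma_g^2 this is algebraically identical to dual ridge on Z with gamma =
lambda * 2 sum f(1-f), an identity the tests enforce. lambda can be
supplied, derived from a heritability, or selected by cross-validation.

**Multi-trait GBLUP.** The same trait in different lines is modelled as
separate, genetically correlated traits: u ~ N(0, Sigma_g x G)
(Kronecker), with Sigma_g the per-line genetic variances scaled by the
between-line correlation matrix, and a diagonal residual (traits are
observed on disjoint animals). The implementation solves the
observed-data form u_hat = (Sigma_g x G) Z' V^-1 (y - Xb): for the
training sizes involved (a few thousand records) this dense solve is
cheaper and numerically equivalent to the full mixed-model equations.
Per-trait means are absorbed by simple centering rather than joint GLS
estimation — phenotypes reach the model already pre-corrected for the
hatch-week effect, so only a trait-level mean remains, and this choice
makes the degenerate cases exact: identity correlation reduces MTGBLUP to
per-line GBLUP, and unit correlation with equal variances reduces it to
pooled GBLUP, both verified to 1e-8/1e-6.

**PCA variants.** RRPCA/PolyPCA/RBFPCA project dosages onto the leading
principal components retaining 97% of genotype variance by default. In
the scenario pipeline the loadings are re-fitted on each scenario's
training animals only and validation animals are projected with the
training means and loadings — the only leakage-safe reading, since the
original description does not say whether PCA was refit per training set.
At 100% retained variance the projection is an isometry of the fitted
row space: centered inner products with training animals (hence linear
and polynomial predictions) are always preserved, while test-to-train
distances (hence RBF predictions) are preserved exactly when the
projection is fitted on a matrix whose row space contains the test
animals. The invariance checks therefore fit the projection on the
stacked train+test genotypes, which is also how an unsupervised
genotype PCA over "the data" is commonly run.

## Penalty selection

The original study does not state how gamma was chosen. Here gamma (and
GBLUP's lambda when no heritability is given) is selected by seeded
k-fold cross-validation, stratified by line, maximizing held-out
predictive correlation over a 10-point log grid spanning six decades
around n (scaled by the mean Gram diagonal so the grid is comparable
across kernel families). Selection uses the one-standard-error rule:
among penalties whose mean fold score is within one fold-SE of the best,
the largest wins. Under pure noise the held-out correlation is flat in
gamma, so plain argmax would pick an arbitrary grid point; the 1-SE rule
drifts to heavy shrinkage, which is the sensible null behaviour. Each
fold's system is eigendecomposed once, so the grid costs one
decomposition per fold.

## Variance components

Between-line genetic correlations are estimated by bivariate genomic
REML on the phenotyped, genotyped animals of each line pair (the original
analysis used tens of thousands of additional non-genotyped relatives
through a combined pedigree-genomic matrix, so its standard errors are
much smaller than what genotyped-only data can give; this is a documented
narrowing, not an equivalence). The bivariate model has genetic
covariance Sigma_g x G and a diagonal per-trait residual.

Updates are expectation-maximization: EM is monotone in the REML
log-likelihood, which is asserted on every accepted iterate. Convergence
is accelerated by a SQUAREM-style extrapolation — after two plain EM
steps an extrapolated parameter vector is evaluated and kept only if it
does not lose likelihood — so the recorded trace stays monotone by
construction while typical runs converge in 15-25 likelihood
evaluations. Standard errors come from the inverse average-information
matrix at the optimum; the correlation SE uses the delta method.
Iteration stops when the likelihood gain drops below `tol` (default 1e-4)
or the relative parameter change falls below 1e-6. Variances are floored
at 1e-8 of the phenotypic variance; estimates at that floor, or a
correlation clamped to +-0.999, set a boundary flag rather than failing.
The univariate estimator works in the eigenbasis of G, making each
iteration O(n) after one decomposition.

Three-line correlation matrices are assembled from the three pairwise
runs (as the original two-step analysis does); per-line variances are
averaged over the pairs containing the line. A non-PSD assembly is bent
by flooring eigenvalues at 1e-6, rescaling to unit diagonal, and flagged.

## Evaluation

Phenotypes are pre-corrected for hatch week by subtracting per-level
means estimated on the training animals of the scenario; a validation
level unseen in training is an error. The accuracy surrogate is the
predictive correlation: the Pearson correlation between validation
phenotypes and GEBV, deliberately not divided by sqrt(h^2) because the
kernel models may capture non-additive variance. Its approximate
standard error is (1 - rho^2)/sqrt(N - 2) with N the number of
validation animals. (The source text describes N as the number of
training animals, but the SE range it prints — 0.058 to 0.065 — is only
consistent with N near 240, the validation cohort size, and that reading
is used here; the package reproduces the printed range exactly from the
printed correlations.)

Scale bias is the slope b1 of the OLS regression of phenotype on GEBV;
its SE is the standard deviation of the slope over B = 10 000 seeded
bootstrap resamples of the validation animals (a resample with constant
GEBV is redrawn and counted), and b1 is declared compatible with 1 when
|b1 - 1| < 2 SE. Reported values are rounded half-up to three decimals.

## Blending and complementarity

Two models' predictions are combined as beta*a1 + (1-beta)*a2 over a
beta grid (default step 0.05); endpoints reproduce the single-model
correlations exactly. The sweep is evaluated on the validation data
itself, mirroring how such curves are usually presented; this is an
optimistic (non-nested) evaluation and is labelled as such.
Complementarity of a model set is the correlation matrix of their
predictions on common validation animals.

## Synthetic data generator

No real data ships with the package; the generator emulates the study
conditions and is itself first-class, tested code.

- **Line divergence.** Ancestral allele frequencies are uniform on
  (0.1, 0.9); each branch of the ((B1,B2),W1) tree applies a
  Balding-Nichols draw Beta(p(1-F)/F, (1-p)(1-F)/F). Defaults F = 0.05
  on the brown branches and F = 0.20 on the white branch, free
  parameters chosen so that B1-B2 divergence is clearly smaller than
  either line's divergence from W1 (verified via realized FST).
  Frequencies are clipped to (0.001, 0.999).
- **LD.** Haplotypes follow a first-order copying process: each marker
  reuses the previous marker's latent uniform with probability `ld_rho`
  (default 0.8), else draws fresh; the allele is the indicator
  u < f_j, so per-marker marginal frequencies are exact while adjacent
  markers are positively associated. This produces the local genotype
  similarity that distance kernels exploit, at desk scale and with a
  single transparent parameter; it is not a coalescent and carries no
  recombination map, mutation model, or pedigree.
- **Trait.** 300 of 5000 markers are QTL (default). Per QTL, the vector
  of line-specific allele effects is multivariate normal with the
  configured between-line correlation matrix — default
  (1, .63, -.26 / .63, 1, -.55 / -.26, -.55, 1), which is PSD. Effects
  are first scaled per line by expected variance and then rescaled by
  the realized TBV variance of the line's sampled animals (LD between
  QTL contributes covariance the frequency-based expectation misses),
  so the per-line genetic variance equals h^2 exactly on the sample.
  Phenotypic variance within a line is 1 by construction: residual
  variance is 1 - h^2, default h^2 = 0.3 per line (a typical value for
  early egg production; the original trait's heritability is not
  reported). A hatch-week factor (10 levels, i.i.d. normal effects with
  sd 0.25 — likewise a free parameter) is added on top.
- **Cohorts.** ~1000 training and 240 validation animals per line
  (matching the study's cohort sizes); the validation cohort is an
  independent draw from the same line frequencies, i.e. an i.i.d.
  stand-in for a youngest generation, with no explicit pedigree or
  selection.

What passing tests on this generator do **not** show: behaviour under
real across-line LD sharing (here lines share QTL but haplotype chains
are simulated independently), under selection-induced family structure,
or at the full 45k-marker scale.

## Problem sizes used in the checks

The acceptance-style checks run at deliberately chosen desk scales: the
bivariate REML recovery uses two lines of 800 animals and 3000 markers
over 10 seeds; the multi-line regime check uses the full default
configuration (3 x 1240 animals, 5000 markers) over 10 seeds with GBLUP
and the h^2-implied lambda; equivalence checks use 20-50 animal
instances where exact linear algebra identities are the point.

## Numerical choices

- Symmetric solves use Cholesky; the kernel-ridge solver reports a
  condition estimate when factorization fails. The MTGBLUP covariance
  gets a jitter of 1e-8 * trace/n only if factorization fails.
- Gram matrices are symmetrized and distance-kernel diagonals pinned to
  exactly 1; PSD is enforced in tests to min eig >= -1e-8 * max eig.
- Non-PSD correlation matrices (user input or pairwise REML assembly)
  are bent by eigenvalue flooring at 1e-6 with rescaling to unit
  diagonal; PSD-but-singular matrices (e.g. all-ones) pass through
  untouched and are sampled through an eigenvalue factorization, so
  perfect correlation yields exactly proportional effects.
- Missing genotypes are a hard error everywhere (the emulated data were
  fully edited upstream); the only marker QC is the per-training-set
  removal of non-segregating markers.

## Known limitations

- Genomic-only REML has materially larger correlation SEs than the
  pedigree-augmented original; at 800 animals per line the SE of a
  single correlation estimate is roughly 0.1-0.25.
- The beta sweep tunes the blend weight on validation data (see above).
- No VCF/BGEN input, no imputation, no Bayesian whole-genome
  regressions, no single-step relationship matrices, no >2-trait joint
  REML.
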