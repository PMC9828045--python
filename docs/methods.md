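# Methods

This note documents the statistical machinery behind `morphomod`: the
models and estimators, the default parameters and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical decisions made where the design was genuinely open.

## Shape alignment and symmetry

**Generalized Procrustes Analysis.** Each configuration is centered,
scaled to unit centroid size, and rotated (proper rotations only,
det R = +1) onto an iteratively re-estimated mean shape; the mean is
re-centered, rescaled to unit size, and re-anchored to its previous
orientation each iteration. Iteration stops when the mean moves by less
than `tol` (default 1e-10; `max_iter` 1000 — widely dispersed shape
samples converge linearly at a rate near 0.9 per iteration, so a tight
tolerance needs a few hundred iterations; iterations are cheap). The
converged configuration set is put in a canonical frame by rotating the
consensus onto its principal axes with a deterministic sign rule, which
makes the output invariant to arbitrary rotation/translation/scaling of
the input.

**Object-symmetry decomposition.** For every specimen a mirrored copy is
built by negating one coordinate axis (default y) and swapping each left
landmark with its right partner; a joint GPA over the 2S configurations
aligns originals and reflections together. The symmetric component of a
specimen is the average of its two aligned copies; the asymmetric
component is the remainder. The symmetric and asymmetric parts live in
orthogonal subspaces, so Procrustes sums of squares decompose exactly.
All downstream analyses consume the symmetric component.

Two consequences of this construction are worth keeping in mind when
interpreting results. First, the mirror plane of the aligned data is the
consensus's own symmetry plane, not necessarily a coordinate plane.
Second, mirror-averaging halves the variance of paired landmarks in all
three coordinates but only removes the out-of-plane coordinate of midline
landmarks; modules that differ in their midline fraction therefore differ
systematically in per-landmark symmetric-component variance even when the
underlying coordinate-level variances are equal.

**Allometry gate.** Shape (the 3P-column symmetric component) is regressed
on log centroid size by generalized least squares under a Brownian-motion
species covariance; significance uses randomized residual permutation of
the intercept-only reduced model, observed statistic included in the null
set (minimum attainable p = 1/(n_perm+1)). Size correction is an explicit
opt-in flag, default off, applied only when the test is significant.

## Modularity statistics

**Covariance ratio.** For a partition into two modules,
CR = √(‖S₁₂‖²_F / √(‖S₁₁°‖²_F · ‖S₂₂°‖²_F)), where S₁₂ is the
between-module covariance block and S₁₁°, S₂₂° the within-module blocks
with zeroed diagonals; for more than two modules, the arithmetic mean of
all pairwise CRs. The permutation null reassigns whole landmarks (their
three coordinates as one unit) to modules preserving module sizes;
p = #(null CR ≤ observed, observed included)/(n_perm+1), and the effect
size Z_CR = (CR_obs − mean(null))/sd(null) on the untransformed
permutation distribution (more negative = stronger modular signal). Note
that for equal-size two-module partitions a random reassignment
occasionally reproduces the partition (or its label swap) exactly, so the
theoretical p-value floor is not always attained. The phylogenetically
corrected variant replaces the specimen covariance with the evolutionary
covariance (X − 1âᵀ)ᵀC⁻¹(X − 1âᵀ)/(N−1) under Brownian motion, with â the
GLS root estimate.

Pairwise comparisons of Z_CR across hypotheses use a two-sample normal
approximation (each standardized null has unit spread, so
p = 2Φ(−|z_i − z_j|/√2)); this is a documented approximation, adequate for
ranking but not a substitute for a joint permutation test.

**Landmark correlations.** The correlation between landmarks l and m is an
absolute vector-congruence coefficient:
r_lm = |Σ_s d_l,s · d_m,s| / (‖d_l‖ ‖d_m‖), with d the per-specimen
3-vector deviations from the consensus. Centering conventions differ among
published congruence implementations; this package centers across
specimens only. With a tree, the rows are independent contrasts of the 3P
coordinate columns and the effective row count is N − 1.

**Correlation-model selection.** Every hypothesis expands into
parameterization schemes assigning one free ρ per group of landmark pairs
(a: shared within + shared between; b: separate within; c: separate
between; d: both separate; two-module partitions only admit a and b, since
they have a single between-module pair). Correlations are Fisher-z
transformed; within each ρ-set the normal likelihood with
sd = 1/√(n_eff − 3) is maximized exactly by the z-space mean, so
ρ̂ = tanh(mean z) — no grid search is needed. Model size is
K = (#ρ-sets) + 1 and AICc = −2·MaxL + 2K + 2K(K+1)/(n−K−1) with
n = P(P−1)/2 unordered landmark pairs (the quantity the likelihood is a
product over); Akaike weights are normalized over the compared set.
n_eff is the number of rows used to build the matrix (S raw, N−1
corrected), since those are the exchangeable observations.

## Macroevolutionary models

**Species covariances** (unit rate; the rate enters through the trait
covariance R): BM C_ij = t_ij (shared root-to-MRCA path length); OU with
fixed root at the optimum C_ij = exp(−α d_ij)(1 − exp(−2α t_ij))/(2α)
(requires ultrametric trees; a stationary variant is out of scope); EB
C_ij = (exp(r t_ij) − 1)/r with the analytic BM limit below |r| < 1e-8.
α and r are parameterized per unit tree height internally and converted
through the height in Myr for reporting, which makes the half-life
arithmetic t½ = (ln 2 / α) · height exact as displayed. EB's r is
unconstrained in sign (|r|·height ≤ 50).

**Penalized restricted likelihood.** Coordinate blocks are
high-dimensional (q up to 3P > N), so the q×q trait covariance R cannot be
estimated unpenalized. For each candidate evolutionary parameter θ the
data are projected onto an orthonormal basis of mean-orthogonal (Helmert)
contrasts and whitened by the Cholesky factor of the projected species
covariance; the whitened rows are i.i.d. N(0, R) under the model. R is
estimated by linear shrinkage toward its diagonal,
R̂(γ) = (1−γ)S + γ·diag(S), and (θ, γ) are chosen to maximize the
leave-one-row-out cross-validated Gaussian log-density (including the
log-determinant of the projected species covariance, so scores are
comparable across θ). The restricted likelihood is used rather than
profiling the root state because the profile likelihood carries a
systematic upward small-sample bias in θ — on Brownian data it favors
OU/EB by 2–3 log-likelihood units at N = 38, enough to overturn
information-criterion comparisons — while the restricted version is
unbiased in the same Monte Carlo experiment. Grids: γ over
{0.01, …, 1.0} (9 points), α over a 15-point log grid on [1e-3, 50] per
unit height, r over a symmetric 15-point log grid on ±[0.05, 10] with 0.
A parameter landing on a grid boundary is flagged in the result.

**GIC.** GIC = −2·log_lik + 2·df with
df = (0 for BM, 1 for OU/EB) + q root states +
(1−γ)·q(q+1)/2 + γ·q covariance parameters — a linear interpolation of the
covariance parameter count in the shrinkage intensity. This is a
deliberately simple surrogate for the trace-form effective degrees of
freedom of penalized estimators; absolute GIC values are therefore not
comparable across packages, and only GIC differences between models fitted
by this package are meaningful. Model support over a set of candidate
trees reports mean ± 2SD of GIC per model and the percentage of trees on
which each model attains the lowest GIC (ties resolve to the earlier model
in the fixed order BM, EB, OU).

**Rates.** σ²_mult for module m is the mean squared BM-whitened,
root-centered deviation per landmark, Σ_i ‖ỹ_i,m‖²/(N·p_m). The observed
max/min ratio (and each pairwise ratio) is tested against simulations from
a common-rate covariance: the observed evolutionary covariance rescaled so
every module carries the pooled per-landmark rate. Each simulated dataset
is passed through the same Procrustes superimposition as the observed data
before rates are recomputed — without this the null is anticonservative,
because the observed statistic carries alignment-induced structure the raw
matrix-normal simulations lack. Standardizing by landmark count is a
configurable choice, made because modules differ in landmark number.

**Disparity.** Per module, Procrustes variance divided by landmark count;
per-specimen per-landmark-standardized squared deviations serve as
replicate observations in a one-way Tukey-HSD comparison across modules
(via statsmodels).

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
the study's own scale: 38 species on a pure-birth tree rescaled to exactly
11.5 Myr; 52 landmarks in a bilaterally symmetric flower-like template
(sepals 14, lateral petals 10, labellum 12, column 14, column-foot 2 — the
two column-foot points are the landmarks the starred hypotheses reassign;
per-organ counts are a package choice, user-overridable); block-structured
trait correlations over the 3P coordinates (same-axis coordinates of two
landmarks correlate at ρ_within = 0.5 inside a module and ρ_between = 0.15
across modules by default — values inside the ranges the analysis itself
estimates on such data); per-coordinate rate 1e-4 per Myr, which yields
shape deviations a few percent of configuration size, i.e. realistic
Procrustes-scale variation; BM per module by default, with per-module OU
or EB available. Under mixed models, cross-module correlation is carried
by shared standard-normal innovations with per-module tree transforms — an
approximation, exact when all modules share one model.

What the generator does **not** emulate — and hence what passing tests do
not show about real data:

* Generated correlations are *innovation-level*; Procrustes alignment
  necessarily attenuates them (removing translation subtracts each
  specimen's common mode, so an all-positive equicorrelated block
  structure cannot survive into shape space at its nominal values — the
  average analyzed-space correlation is forced toward −1/(P−1)).
  Block contrast is preserved but compressed: generated 0.5/0.15
  realizes as roughly 0.31/0.20 in the symmetric component.
* Real floral landmark data have heterogeneous per-landmark variances,
  localized covariation and measurement error; the generator's blocks are
  homogeneous.
* Hypotheses differing by very few landmarks (the starred variants move
  two of 52) are near-twins at N = 38; on synthetic data the analysis
  reliably identifies the generating four-module *structure* but cannot
  reliably separate such twins — consistent with the behavior of the
  statistics themselves, whose values for twin hypotheses are nearly
  identical.

## Defaults and reproducibility

Permutation/simulation counts default to 999 (observed statistic always
included; p-value floor 1/(n_perm+1)). Every stochastic operation takes a
mandatory seed; the pipeline derives per-stage seeds from one master seed
and records them, along with a configuration hash, in the report's
provenance block — rerunning the same configuration reproduces the report
byte for byte. Test suites and the acceptance script run reduced problem
sizes (e.g. 20 replicates, q = 30 trait blocks, 199–999 permutations),
chosen as the smallest sizes at which the monitored proportions are
stable.

## Known limitations

* Single-optimum OU only; multi-peak OU for high-dimensional shape data is
  out of scope.
* The CR effect-size comparison across hypotheses is a normal
  approximation, not a joint resampling test.
* The congruence-correlation centering convention and the GIC
  effective-df surrogate are package choices among several published
  variants; comparisons should stay within one convention.
* OU and positive-r EB are nearly unidentifiable on ultrametric trees of
  this size; model preference between them should be read with the
  half-life and the tree-support percentage together.
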