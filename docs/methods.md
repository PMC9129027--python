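# Methods

## Model

For N individuals with outcome y, candidate mediator m and exogenous design
X (N×D; D = 1 for a SNP dosage, D = 8 for founder-haplotype dosages), the
causal configurations are indicator triples θ = (θ_a, θ_b, θ_c): a is the
edge X→M, c is X→Y, and b takes three states — absent, M→Y, or the reactive
direction Y→M (written "\*").  The twelve configurations are labelled
ML1–ML12; the anchored ones are ML4 = (1,1,0) complete mediation,
ML5 = (0,0,1) a QTL on Y only, ML7 = (1,0,1) co-local, ML8 = (1,1,1) partial
mediation, and ML9–12 the reactive block.  The remaining labels follow
binary counting order on (θ_c, θ_a, θ_b); the θ↔label table is a frozen
constant (`medbayes.core.MODELS`), so results are label-stable.

Given a non-reactive configuration, the joint density of (m, y) factorizes
as p(m | θ_a) · p(y | m, θ_b, θ_c), each factor a weighted Gaussian linear
model.  With conjugate priors — coefficients N(0, σ²·v) with v from the
hyperparameters below, residual precision Gamma(κ/2, λ/2) — every
regression parameter integrates out analytically and each factor is a
zero-location multivariate Student-t with κ degrees of freedom and scale
matrix (λ/κ)(W⁻¹ + X V Xᵀ), where X here is the concatenated design
[1 | Z | edge blocks] and V the matching diagonal prior covariance.  The
literature often writes this distribution as t_κ(0, λ[W⁻¹ + XVXᵀ]) without
fixing the density normalization; this package implements the exact
normal–inverse-gamma marginal (the (λ/κ) scale convention), and the test
suite pins the convention against a brute-force numerical integration of
the priors rather than against notation.

Posterior model probabilities are exp(log marginal likelihood + log prior),
normalized by log-sum-exp over the models with positive prior weight, so
likelihood spreads of thousands of nats cannot underflow.  Model-prior
presets: **default** (uniform over ML1–8, reactive excluded), **reduced**
(uniform over the non-reactive models with edge c present: ML5–8),
**expanded** (uniform over all twelve); arbitrary 12-weight vectors are
accepted.

## Hyperparameters

| parameter | meaning | default |
|---|---|---|
| κ = (κ_m, κ_y) | residual-precision prior shape ×2 | (0.001, 0.001) |
| λ = (λ_m, λ_y) | residual-precision prior rate ×2 | (0.001, 0.001) |
| τ²_μ | intercept prior variance (relative to σ²) | 1000 per equation |
| τ²_Z | covariate-effect prior variance | 1000 per equation |
| φ² = (φ²_a, φ²_b, φ²_c) | per-edge effect-to-error variance ratio | (1, 1, 1) |

τ is sometimes quoted as "1000" without units; this package interprets it
on the variance scale (τ² = 1000) and exposes it as a configuration knob.
The choice is immaterial in practice — any variance large relative to
standardized data is vague — and the suite checks that model rankings agree
between τ² = 10³ and 10⁶.

As an alternative to fixed φ², the empirical option sets, per edge,
PVE = 1 − SSR_alt/SSR_null from ordinary least squares (a: m on X; b: y on
m; c: y on X; null = intercept only), clamps PVE to [1e-4, 1 − 1e-4]
(φ² = 0 would silently delete an edge, PVE = 1 is non-finite), and uses
φ̂² = PVE/(1 − PVE).

## Reactive configurations and identifiability

For θ_b = "\*" the roles of the two traits swap: the marginal equation is
for y with the c-edge design and y-side hyperparameters, and the
conditional is m given y with the a-edge design, y entering as a predictor
with prior ratio φ²_b.  (An alternative reading would attach edge a to the
marginal equation; the reading used here is the one that matches the
generative chain X→Y→M, where the QTL enters the y-equation.  At the
default φ² = (1,1,1) the two readings coincide.)

Two reactive configurations are Markov-equivalent to non-reactive ones and
hence not identifiable from data: (0,\*,0) ≡ (0,1,0), and (1,\*,1) ≡ partial
mediation (1,1,1).  For (0,\*,0) the role-swap formulas are *algebraically*
identical to the (0,1,0) factorization once y and m are standardized (their
squared norms coincide), and the package computes it via the swap — the
equality is a genuine numerical check.  For (1,\*,1) the edge-wise conjugate
priors are not exactly likelihood-equivalent between the two factorization
orders (the X blocks enter the marginal scale matrix asymmetrically, a
~10⁻² nat discrepancy), so the package evaluates this configuration in the
canonical partial-mediation order: a score that differed between
observationally equivalent DAGs would be reporting a prior-parameterization
artifact as evidence about causal direction.  Posterior mass on ML12 vs ML8
under the expanded prior therefore reflects the prior alone, which is the
honest statement of what the data can say.

## Standardization, weights, missing data

y and m are standardized to mean 0 and unit sample variance after row
alignment and joint missing-row removal (dropped counts are logged), and
before any likelihood evaluation; X and covariates are left on their
original scale (covariates are deliberately not standardized).  Variation
below the float resolution of the values (sd ≤ 1e-13·max|v|) is treated as
a constant trait and rejected.  Observation weights enter as W⁻¹ in the
residual covariance and must be strictly positive.

## Numerics

Scale-matrix log-determinants and quadratic forms use the low-rank identity
through the p×p capacitance matrix I + UᵀWU with U = X V^{1/2} (zero prior
variance deletes a column exactly); since W⁻¹ is positive definite the
factorization cannot fail for collinear designs — founder-haplotype dosages
whose rows sum to a constant are handled without column dropping.  A
jittered retry (1e-10 · trace/p) backs up the Cholesky factorization.
Posterior group odds log[p/(1−p)] clamp p to [1e-10, 1 − 1e-10] because
point-mass posteriors occur routinely in simulations; the log base is e by
default with a base-10 switch.

## Comparators

* **Sobel**: β̂_a from OLS of m on (1, Z, x), β̂_b from OLS of y on
  (1, Z, x, m); z = β̂_aβ̂_b / √(β̂_a²se_b² + β̂_b²se_a²) against the standard
  normal.  First-order variance only (no Goodman second-order term, no
  bootstrap).  Restricted to scalar x: with D > 1 the indirect effect is a
  vector and the test does not apply.  Note the statistic is conservative
  when both paths are null (rejection ≈ 0 at nominal 0.05) and calibrated
  when exactly one path is null; the suite checks both regimes.
* **LOD drop**: fixed-effects LOD = (N/2)·log10(RSS_null/RSS_full); drop =
  LOD(y~X) − LOD(y~X | m), also reported scaled by the marginal LOD.
  Kinship random effects are out of scope (see Limitations).
* **IV (2SLS)**: stage 1 m ~ (1, Z, X) giving m̂; stage 2 y ~ (1, Z, m̂);
  the standard error uses conventional 2SLS residuals (observed m at the
  stage-2 coefficients) and p-values use a t reference with N − 2 degrees
  of freedom.  Covariates, when supplied, enter both stages.

## Simulator

A trait with one QTL is y_sim = s_β·Xβ_raw + s_ε·ε_raw with β_raw, ε_raw
standard normal and s_β = √(nφ²/((n−1)V(Xβ_raw))),
s_ε = √(n(1−φ²)/((n−1)V(ε_raw))), V the population variance.  The scaled
components' sample-variance ratio equals the target effect size φ² exactly
(the n/(n−1) factors cancel); the suite asserts this to 1e-12.  Scenarios:
**co-local** — m and y share β_raw with independent noise; **complete** —
y built from m·β_m; **partial** — y = direct X component + m component +
noise, the two signal components splitting the target effect size according
to the direct:indirect ratio (1:1 by default, i.e. equal sample variances);
**reactive** variants swap (m, y); **y_only** / **none** — null scenarios.
β_raw is redrawn per replicate (pinnable).  The signal–noise and
direct–indirect cross terms are left random, so a partial-mediation
replicate can have direct and indirect contributions that partially cancel
in the marginal X→Y association — visible as occasional negative LOD drops.

Genotype designs: balanced splits are deterministic nearest-equal
assignments shuffled by the seeded generator (exactly 100/100 at n = 200);
multi-allelic designs expose k functional alleles as k−1 indicators;
haplotype designs draw two founders per individual (dosage rows sum to 2).
A tag variant in LD with a balanced binary truth is built by symmetric
random flips with probability p = (1−r)/2, giving expected Pearson
correlation 1 − 2p (the construction is not unique; any monotone scheme
reaching the target correlation would do), with the realized r reported.

The generator emulates the benchmarking conditions — balanced variants,
exact effect sizes, Gaussian noise, unrelated individuals — and none of the
structure of real populations: no kinship or population structure, no
linkage maps or 36-state diplotypes, no mediator measurement error, no
confounding.  Passing benchmarks therefore demonstrate correctness of the
method under its own assumptions, not robustness to those features.

## Problem sizes used in the checks

The end-to-end suite runs the study at desk scale: 10 random datasets
(N = 5, D ∈ {1,2}) for the brute-force oracle comparison (tolerance 0.05
nats); 100 random datasets for the identifiability identities (1e-10); a
{0.2, 0.5, 0.8}² effect grid with 20 replicates per cell at n = 200 for
scenario recovery and the LD-misspecification shift; 500 replicates per
class at n = 24 for the ROC comparison; 2000 replicates for Sobel
calibration.  These sizes keep the full run to a couple of minutes while
leaving the pass/fail margins wide.

## Limitations

Single candidate mediator per model (no joint multi-mediator models); no
kinship/LMM correction — LOD scores and likelihoods assume exchangeable
residuals, so population structure must be handled upstream (e.g. by
rank-normalizing residuals from a kinship model); no moderated mediation;
no bootstrap CIs for the indirect effect; genotype parsing (VCF/PLINK) is
upstream of the tabular CSV/TSV interface.
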