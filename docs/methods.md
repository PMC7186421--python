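# Methods

## Scope

`gxp` implements a genotype-by-population (G×P) interaction analysis for
polygenic traits: SNP-heritability by GREML, random-regression reaction-norm
models (RNM) with a continuous ancestry covariate, nested likelihood-ratio
tests, bivariate GREML genetic correlations between populations, and
simulation studies of participation-selection and collider bias.  Everything
runs on synthetic two-population cohorts produced by the package's own
generator; no external genotype or phenotype data are required.

## Models

Phenotypes are modelled as y = μ + g + e with g ~ N(0, A σ²g), e ~ N(0, I σ²e),
where A is the genomic relationship matrix

A_ij = (1/L) Σ_l (x_il − 2p_l)(x_jl − 2p_l) / (2 p_l (1 − p_l)),

with p_l the sample reference-allele frequency (the Hardy–Weinberg
expectation 2p(1−p) is used for var(x_l), the convention of the dominant
GREML tooling).  Missing dosages are mean-imputed per SNP before centering.
SNP-heritability is h² = σ²g / (σ²g + σ²e), with a delta-method SE.

The reaction-norm models regress the random effects on a continuous
covariate c (an ancestry PC standardized to mean 0, SD 1):

* G×P: y = μ + g₀ + g₁·c + e, giving
  V = A·var(g₀) + (A∘cc′)·var(g₁) + (A∘(c1′+1c′))·cov(g₀,g₁) + I·var(e₀).
  The covariance expansion follows algebraically from var(g₀ + c·g₁); the
  G×P model carries a homogeneous residual, matching the component set
  reported for such fits.
* R×P: y = μ + g + e₀ + e₁·c, V = A·var(g) + I·var(e₀) + diag(c²)·var(e₁)
  + 2·diag(c)·cov(e₀,e₁).
* Full: both expansions (6 parameters).

Parameter counts: baseline 2, G×P 4, R×P 4, full 6, so each nested
comparison is a 2-df LRT.  The σ²g = 0 heritability screen is a boundary
test and uses the 50:50 mixture ½χ²₀ + ½χ²₁ (p = 0.5 at statistic 0).

Estimates from a G×P/full fit are admissible only inside the valid
parameter space: var(ĝ₀) ≥ 0, var(ĝ₁) ≥ 0 and |cov(ĝ₀,ĝ₁)| ≤
√(var(ĝ₀)·var(ĝ₁)); fits violating any criterion are excluded from
downstream tests.  This is only observable because estimation is
*unconstrained* (components may go negative while V stays positive
definite) — a constrained optimizer would never produce excludable fits.

Bivariate GREML treats one trait measured in two disjoint populations as
two traits sharing a GRM; the residual covariance is structurally zero and
r_g = σ_g12 / √(σ²g1 σ²g2) with a delta-method SE.  The heterogeneity test
is a 1-df LRT of the free model against σ_g12 = √(σ²g1 σ²g2) (r_g = 1),
fitted directly in the (a₁, a₂) = (σ_g1, σ_g2) parametrization.  The
same-sample layout (two traits, one cohort) frees the residual covariance
(6 parameters) and is used both for the phenotype-vs-PC screen and for the
collider-biased trait–trait correlation.

## REML estimation

Average-information (AI) REML with 3 generalized-EM warm-up iterations,
step-halving (the restricted log-likelihood trajectory is monotone
non-decreasing), a gradient-direction fallback when the AI step fails
(near-singular AI at degenerate optima), and a step-norm cap.  Convergence:
|Δ log L_R| < 1e−6, at most 100 iterations; non-convergence is flagged on
the result, not raised.  Starting values: half the phenotypic variance for
the main genetic and residual components, 0 for interaction terms.
Standard errors come from the inverse AI matrix at the optimum.

Three equivalent evaluation paths exist, cross-checked against a
brute-force dense evaluation (explicit inverse, determinants, fixed-effect
projection) in the tests:

1. **Dense** — generic V = Σ θ_k M_k, any model, O(n³) per iteration.
2. **Spectral** — baseline GREML in the eigenbasis of A, O(n) per
   iteration after one eigendecomposition.
3. **Reduced-basis (low-rank)** — when L ≪ n, every model matrix maps the
   column space of [G, DG, X, y] (dimension M ≤ 2L + 3) to itself and acts
   as a scalar (or, for stacked traits, 2×2) multiple of the identity on
   its orthogonal complement.  Projecting onto an orthonormal basis of that
   column space gives an M-dimensional REML problem plus an analytic
   complement term (−½ ν log σ²e in the log-likelihood, ν/σ²e in the trace);
   the reduction is exact, not an approximation.  This path makes
   biobank-scale simulated cohorts (n ≈ 14,000–28,000) tractable on one CPU
   and is what the bias studies use.

## Synthetic cohorts

Genotypes: ancestral allele frequencies uniform on [0.05, 0.5]; population
frequencies Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.01 by
default (European-scale differentiation, clearly visible on PC1); dosages
Binomial(2, p_pop); no linkage disequilibrium; all SNPs autosomal and
unambiguous by default.  Phenotypes: per-SNP main and interaction effects
are bivariate normal over the causal set (all SNPs by default) with
correlation cov_g01_corr; individual values use sample-standardized
dosages; the total variance at covariate value 0 is 1, with var(g₀) = h²,
var(g₁) = var_g1_frac·h², var(e₁) = var_e1_frac·(1−h²).  Cross-population
genetic correlation is 1 (shared effects) unless rg_cross < 1 draws
partially independent per-population effect vectors.  Optional
observation-scale distortions for robustness studies: a fixed covariate
mean effect (beta_c), a standardized χ² residual (skewed), and a monotone
exponential output transform.

Participation selection is logistic: P(S=1 | y, pop) =
logistic(α_pop + ln(OR_pop,Y)·y [+ ln(OR_pop,Z)·z]) with traits
standardized to unit SD, so an odds ratio acts per SD of phenotype; α_pop
is calibrated by bisection so each population's expected participation
equals the target rate (default 0.5, which maximizes the selected sample
for a fixed pool).  A master seed spawns independent per-replicate
substreams; scenarios share replicate cohorts (only selection differs).

What the generator does *not* emulate: linkage disequilibrium, imputation
error, sex chromosomes, assortment, shared environment, or the real
confounder structure of biobank traits.  Passing tests therefore show the
statistical machinery behaves as designed under its own assumptions, not
that real-data findings are artifact-free.

## Bias studies and problem sizes

The selection study simulates a G×P-null trait (var_g1_frac = 0, r_g = 1
across populations), selects participants per scenario, recomputes the GRM
and PC1 on each selected sample, adjusts the trait for PC1 as a fixed
effect, and records the 2-df G×P LRT rejection rate at α = 0.05, the 1-df
bivariate heterogeneity LRT rejection rate, and the mean/SE of r̂_g.  The
collider study adds an independent trait Z to the participation logit and
additionally estimates the Y–Z genetic correlation on the selected sample.

A point established empirically during development and documented here
because it drives the study sizes: logistic selection with OR ≈ 2–3 per SD
tilts a Gaussian phenotype almost entirely in *mean* (in the
strong-selection limit the selected distribution is an exponential tilt,
which shifts a Gaussian without changing its variance).  The spurious
interaction signal under differential selection comes from the remaining
few-percent variance differential between populations, so the LRT
noncentrality is small per individual (~3×10⁻⁴) and gross inflation of the
type-I error is a large-sample phenomenon.  The differential-selection
scenarios therefore run at the analysis scale of the emulated study design
(14,000 per population before 50% participation, ~14,000 analyzed), which
the reduced-basis REML path makes affordable.  The no-selection and
equal-selection calibration scenarios run at 7,000 per population: the
unconstrained 2-df LRT proved slightly anti-conservative at much smaller n
(a few points above nominal at n ≈ 3,000) and cleanly calibrated from
n ≈ 7,000; the collider study runs at 4,000 per population.  The SNP panel
is L = 300 unlinked markers: with n ≫ L this *improves* the precision of
variance-component estimates (GREML information grows with the variance of
relatedness, ∝ 1/L) while PC1 still separates the populations essentially
perfectly (FST·√(nL) ≈ 20).  Replicates: 60 for calibration scenarios, 40
for the differential scenarios, 60 for the collider study — chosen to keep
the acceptance script within a desk-scale runtime; binomial SEs at these
counts are quoted alongside every rejection rate in the tests.

## Pipeline

The screening pipeline stages, in order: SNP QC (call rate ≥ 0.95, HWE
χ² p ≥ 1e−4, MAF ≥ 0.01, A/T–G/C removal, applied sequentially in that
order), GRM, greedy relatedness pruning (> 0.05, random member of each
pair, seeded), ancestry PCs (+ rectangle partition where labels are
needed), confounder adjustment by OLS pre-residualization (confounders plus
the leading PCs as fixed effects), heritability screen (mixture LRT,
α = 0.05), same-sample bivariate screen of the trait against each PC
(passes when both genetic and residual covariances are within 2 SE of 0),
per-covariate G×P fit, validity filter, 2-df LRT against the baseline at
the Bonferroni level fwer/(n_traits·n_covariates), rank-INT re-fit of the
survivors (INT applied to the raw trait, then re-adjusted), and the
orthogonality test (full vs R×P and full vs G×P, 2 df each) for the final
survivors.  Every trait×covariate pair exits at exactly one stage, and the
report records the exit stage and the statistics computed up to it.

PCs are tested one at a time by default; fitting two PC covariates jointly
is possible through the library but is collinearity-prone and not part of
the default pipeline.

## Numerical and design choices

* Rank-INT uses Blom scores, Φ⁻¹((r − 3/8)/(n + ¼)), ties averaged — the
  dominant convention in genetics.
* The rectangle partition is boundary-inclusive (ties go to POP3).
* PC sign convention: largest-magnitude loading positive.
* The HWE test is the 1-df χ² goodness-of-fit (adequate at synthetic
  scale; an exact test would matter only for very rare genotype classes).
* Confounders are pre-residualized rather than fit inside the mixed model;
  OLS residualization commutes with the intercept-only REML fixed effects
  and keeps every solver path applicable unchanged.
* The heterogeneity-test null is r_g = 1: with estimates near 1 and
  "heterogeneity" p-values attached to them, a null of no heterogeneity
  (r_g = 1) is the only consistent reading.
* Degenerate inputs: constant reaction-norm covariates are rejected (a
  test-only bypass exists and reproduces the baseline log-likelihood);
  monomorphic SNPs are a hard error naming the SNP; an identity GRM
  triggers a non-identifiability warning.

## Known limitations

* The finite-sample null distribution of the 2-df G×P LRT drifts a few
  points around its nominal size below n ≈ 5,000; it is well calibrated at
  the scales where the calibration claims are made.
* r̂_g is a ratio estimator; with noisy per-population genetic variances
  (small n·panel information) its replicate mean is biased upward.  Study
  sizes here keep the component SEs small enough that the bias is
  negligible (< 0.01).
* Binary traits are out of scope (the reaction-norm machinery here is not
  verified for liability-scale responses), as are LD-aware GRMs,
  leave-one-chromosome-out designs and multi-response reaction norms.
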