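# Methods

## Scope

`gsenspy` quantifies how much of an observed exposure–outcome correlation
is attributable to shared genetic factors. It is built around three
estimators — REML variance components on a genetic relationship matrix
(SNV-based heritability), the Falconer decomposition of twin pair
correlations (twin-based heritability), and a latent-variable SEM that
combines polygenic scores with either heritability — plus a synthetic
cohort generator that provides ground truth for all of them.

## Generative model of the synthetic cohorts

Genotypes are unlinked biallelic variants, dosage ~ Binomial(2, p) with
p ~ Uniform over the configured MAF range. Linkage disequilibrium is
deliberately absent: the downstream methods consume PRSs, relationship
matrices and correlation matrices, none of which require LD structure to
be exercised, and LD would complicate the closed-form ground truths.

Per-variant effects follow a Gaussian infinitesimal model: every variant
is causal, with (βx, βy) drawn bivariate-normal at correlation r_g (the
pleiotropy knob) and rescaled so the population variance of the centred
genetic value Σβ(x−2p) equals the target heritability *exactly for the
realized draw*. Phenotypes are

    X  = Gx + e,              Var X = 1
    Y* = b·X + Gy + e',       Y = Y*/sd(Y*)

so the exposure–outcome correlation decomposes in closed form into a
causal part b and a confounded part r_g·√(h²x·h²y), each divided by
sd(Y*) = √(1 + b² + 2b·r_g·√(h²x·h²y)). The true confounding proportion

    r_g·√(h²x·h²y) / (b + r_g·√(h²x·h²y))

is exposed as `true_confounding_proportion` and is the recovery target of
the validation suite. Note two scale conventions: the generator's `h2y`
is the variance of Gy on the *exposure* scale, while the standardized
outcome's total genetic variance — what a variance-component estimator
targets, and what the SEM constraint refers to — is
`standardized_outcome_h2`, which also counts the genetic variance arriving
through the causal path from the heritable exposure.

Discovery-GWAS weights are β + N(0, 1/(n_gwas·2p(1−p))), the
large-sample variance of a marginal per-variant regression estimate. With
m unlinked variants the resulting PRS r² is approximately
h²/(1 + m/(n_gwas·h²)), so the discovery size is the single knob for PRS
quality. The pipeline default (n_gwas = 5000 against a 1000-variant
panel) puts PRS r²/h² near 0.3–0.5, in the realistic regime where the PRS
explains well under the full SNV heritability; no claim is made of
matching any particular cohort's r². Twins are simulated at the phenotype
level (bivariate normal with correlation h²+c² for MZ, h²/2+c² for DZ),
since the twin estimator consumes only pair correlations.

Covariates (age ~ N(9.9, 0.6), sex ~ Bernoulli(0.5), five recruitment
sites) receive small linear effects (0.05–0.10 SD) — enough to make the
residualization stage consequential without dominating the phenotypes.

What the generator does **not** emulate: LD and rare-variant
architecture, ancestry structure and admixture, assortative mating,
gene–environment interaction, reporter effects, and measurement floors or
skew of real questionnaire instruments (a rank-based inverse-normal
transform and a log(x+1) transform are provided for such data, and the
rank transform is applied to the simulated exposure by default, where it
is close to a no-op). Passing tests therefore demonstrate correctness of
the estimators under the stated statistical model, not robustness to
those real-data complications.

## Pipeline defaults

The default configuration emulates the study conditions the package is
aimed at: a cohort of 2000 children (desk-scale stand-in for a cohort of
several thousand), SNV-scale heritabilities 0.08 (exposure), 0.18 and
0.07 (the two outcomes), genetic correlation 0.5 between exposure and
each outcome, causal paths sized so the total correlations land near 0.10
and 0.05, twin-based heritabilities 0.58/0.88/0.48 estimated from 216 MZ
and 333 DZ pairs, and covariates age, sex, site.

## SNV-based heritability (GRM + REML)

The GRM is A_jk = (1/m)·Σ_i (x_ij−2p_i)(x_ik−2p_i)/(2p_i(1−p_i)), with
allele frequencies taken from the analyzed sample (an override exists for
supplying generating frequencies). Variants with zero sample variance
carry no information and are dropped with a logged count.

REML for y = Cb + g + e, Var = σ²_g·A + σ²_e·I proceeds by projecting out
the fixed effects with an orthonormal null-space basis, eigendecomposing
the projected GRM once, and profiling the restricted likelihood down to a
one-dimensional function of h² = σ²_g/(σ²_g+σ²_e), which is maximized by
bounded scalar search on [0, 1]. This parametrization is a monotone
transform of the variance ratio, so it finds the same optimum as a
ratio-space search while remaining well conditioned near h² = 1, and it
is globally robust in a way Newton-type average-information updates are
not. Endpoints are compared explicitly (the bounded search never
evaluates them), and boundary estimates are reported as such rather than
truncated mid-optimization. The SE of h² is read off the numerical
curvature of the profile log-likelihood at the optimum (at the nearest
interior point when the estimate is on the boundary, where the quadratic
approximation is indicative only). A direct matrix-inversion evaluation
of the same restricted likelihood (identical constant convention,
including the −log|XᵀX| term) is kept as an independent cross-check; the
two agree to 1e−8 and the optimum beats a 101-point profile grid in the
test suite. A GRM that is numerically the identity leaves the two
components unidentifiable and raises. Only the single-GRM model is
implemented; multi-component and bivariate REML are out of scope.

## Twin-based heritability

Intraclass correlations use double-entry Pearson (each pair in both
orders), which is exchangeable in twin order by construction. The
Falconer point decomposition a² = 2(r_MZ−r_DZ), c² = 2r_DZ−r_MZ,
e² = 1−r_MZ is used rather than a maximum-likelihood ACE fit because only
the a² point estimate and its SE feed the downstream sensitivity models;
a full ACE SEM is a possible extension. Sampling noise can push the raw
shares outside [0, 1]; they are clamped and renormalized to sum exactly
to 1, with a flag. The SE of a² comes from the delta method on Fisher-z
SEs of the two correlations, using the number of pairs (not the doubled
entries) as the effective sample size — the conservative choice. Note a
point-estimate caveat: when the downstream analysis needs strict
comparability with an ML ACE fit, the two can differ in finite samples.

## Polygenic scores

score_i = Σ_j w_j·dosage_ij over the variants shared between the weight
table and the genotype matrix, then z-standardized with the population-SD
convention (divide by n — tiny worked examples are sensitive to this).
Weights are consumed as given; LD-aware reweighting is out of scope, as
the sensitivity framework needs only a noisy PRS with measurable r².

## The confounding-decomposition SEM

Variables are residualized on covariates (least squares, categorical site
expanded to indicators) and z-scored; their Pearson correlation matrix S
with its n is the sufficient statistic. Sample correlation matrices of
real columns are PSD by construction; user-supplied matrices that are
mildly indefinite (smallest eigenvalue > −0.05) are repaired by
eigenvalue clipping with a warning, anything worse raises.

Model structure and the outcome-heritability constraint are given in the
README. Design choices where the convention was genuinely open:

* **Outcome constraint.** h²y pins the *total* modelled genetic variance
  of Y — the direct latent path plus the path through the heritable
  exposure plus their covariance, c² + 2abρg·c + a²b². This convention is
  testable (it reduces to c = √h²y at b = 0, to c = √(h²y − a²b²) at
  ρg = 0, and it matches what a variance-component estimator measures on
  the outcome). The alternative c² = h²y is available behind
  `outcome_constraint="direct"` for comparison; published implementations
  of PRS-measurement-error SEMs are not explicit on this point, so
  third-decimal differences from them are possible.
* **Discrepancy.** The ML form on the correlation matrix treated as a
  covariance of standardized variables — the SEM default, and it supplies
  a likelihood-ratio-style misfit value. Note that under a deliberately
  "wrong" heritability (the point of a sensitivity analysis, e.g. twin h²
  far above the molecular value) the model is misspecified and the
  reported `fit_discrepancy` is large; the implied total effect can then
  deviate from the observed correlation. Estimates are still the
  constrained-ML projection, which is exactly what the bounds narrative
  needs, and the misfit value makes the tension visible.
* **Non-negativity of b** is a box constraint (default on): the residual
  association is floored at null rather than allowed to flip sign. This
  makes `confounding_pct` land in [0, 100] whenever the total is
  positive.
* **Optimization.** L-BFGS-B from six deterministic starts — combinations
  of λ ∈ {0.5, 0.9} × ρg ∈ {0, 0.5}, a start assembled from the observed
  correlations, and one from the PRS-only estimates — followed by a
  Nelder-Mead polish. The objective can be multimodal near constraint
  boundaries; on noiseless forward-generated matrices the fit recovers
  the generating parameters to 1e−4 and drives the discrepancy below
  1e−8 (test suite).
* **Feasibility.** The supplied h² must be at least the variance its PRS
  already explains (λ ≤ 1 otherwise has no solution); the constraint
  solver raises when the causal path alone implies more outcome genetic
  variance than h²y permits. Infeasible grid points in the heritability
  sweep are marked, not fatal. For the outcome-PRS-only model no r²-based
  precheck is applied: r(Sy,Y) can legitimately exceed √h²y through the
  causal path, so admissibility is decided by the λy root itself.
* **Outcome-PRS-only model.** Just identified; solved in closed form
  (quadratic in λy, positive root), with a constrained numerical fallback
  when the closed form violates a bound. Agrees with the numerical
  minimizer to 1e−6 in the test suite.
* **Confidence intervals.** Nonparametric percentile bootstrap over
  individuals when raw columns exist; a Wishart Monte-Carlo (covariance
  matrices sampled at the observed n, converted to correlations, refit)
  when only a summary matrix is available. Both are labelled in the
  output; infeasible replicates are dropped, counted, and escalate to an
  `unstable` flag beyond 20%.
* **Heritability inputs are plug-in point estimates**; their sampling
  error is not propagated into the SEM intervals. This matches the
  intended use (bounds under assumed h² scenarios) but understates total
  uncertainty when h² is itself noisy.

The heritability sweep refits along a grid of assumed outcome h² values
and reports the smallest h² at which the residual path drops to ≤ 1e−4
(effectively the boundary b = 0 under the non-negativity constraint),
refined by bisection between the bracketing grid points to 1e−6.

## Numerical conventions and degenerate inputs

Seeding: one master seed; each stage derives an independent generator
from (seed, CRC-32 of a stage label), so draws are stable under stage
reordering. Identical seeds reproduce byte-identical pipeline reports
(floats are rounded to 10 decimals at the report boundary only).
Degenerate cases raise early with specific messages: constant phenotypes
(rank transform, residualization), zero-variance scores, empty variant
intersections, rank-deficient covariates, all-monomorphic panels,
identity GRMs, twin groups with fewer than two pairs or zero variance.

## Problem sizes in the validation suite

The test suite and acceptance script run recovery experiments at desk
scale, chosen so each check is statistically decisive for its stated
tolerance: SEM confounding recovery on 25 replicate cohorts of n = 4000 ×
m = 2000 per truth (±10 percentage points), bound ordering on 25 cohorts
of n = 2500 × m = 1200, REML recovery on 25 cohorts of n = 1500 ×
m = 3000 (±0.05 on mean ĥ²), twin recovery on 50 replicates of 500+500
pairs per grid cell, and Monte-Carlo closed-form checks at n = 20000.
The acceptance script uses 8–10 replicates per quantity.

## Known limitations

* Single-GRM REML only; no GREML-LDMS, bivariate REML or relatedness
  pruning (the simulator produces unrelated individuals).
* Falconer rather than ML ACE; no sex-limitation or ADE models, no
  zygosity inference from genotypes.
* No mediation decomposition ("mediated pleiotropy" is distinct from the
  confounding estimated here) and no gene–environment interaction.
* The SEM treats n as the correlation-matrix sample size; covariate
  residualization's lost degrees of freedom are ignored (negligible at
  cohort scale).
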