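# Methods

## The model

A phenotype y is measured at two visits on both members of twin pairs. On
the analysis scale (natural log; the phenotype is strictly positive and
right-skewed on the raw scale) the two-visit vector of one person is modelled
as

    y = μ + L_A a + L_C c + L_E e

where a, c, e are latent standard-normal factor vectors (one factor per
visit) and L_A, L_C, L_E are lower-triangular 2×2 path matrices with entries
(x11; x21, x22). Each component's across-visit covariance is L_X L_Xᵀ, which
is positive semidefinite for any real paths — the reason the optimization is
run over raw paths rather than variances. Cross-twin sharing identifies the
components: MZ pairs share a fully, DZ pairs with correlation 0.5, c is
shared fully in every pair, e never. Dominance is not modelled. The expected
4×4 pair covariance in slot order (twin1·v1, twin1·v2, twin2·v1, twin2·v2)
is assembled from within-twin blocks A + C + E and cross-twin blocks
k·A + C, and is positive definite whenever the unique-environment factor has
positive variance at both visits.

Sign indeterminacy: flipping the sign of a whole column of any factor leaves
L L ᵀ unchanged, so all reported solutions are reflected to non-negative
diagonals (a11, a22, … ≥ 0); every derived statistic is invariant to these
flips (property-tested).

## Likelihood and fitting

The log likelihood is full-information: each pair contributes the
multivariate-normal log density of its *observed* phenotype slots, using the
matching sub-matrix of the expected pair covariance and sub-vector of
expected means. Singletons reduce to the within-person marginal; a pair with
nothing observed contributes zero. Means are per-visit intercepts, always
group-specific in multigroup fits, optionally extended by covariate slopes
(mean arterial pressure enters the means model as μ_v + β_v·MAP, shared
across twins and groups). Modelling the covariate in the means — rather than
residualizing beforehand — keeps the treatment of missing data consistent
with the likelihood; a pre-residualization mode can be emulated by
transforming the table before fitting but is not the default path.

For speed the dataset is packed into blocks sharing (group, zygosity,
observation pattern), so one deviance evaluation is a handful of vectorized
Cholesky solves. The deviance (−2 log L) is minimized with L-BFGS-B
(numerical gradients, `ftol` 1e-11, `gtol` 1e-7) from a moment-based start
plus up to four seeded perturbed restarts (default 3 starts total).
Parameter points whose expected pair covariance has an eigenvalue below
1e-10 receive a large graded penalty that slopes back toward the feasible
region. Start values split the visit-wise sample variances A:E = 0.5:0.5, or
A:C:E = 0.4:0.2:0.4 when C is free — an *exactly* zero shared-environment
start is a stationary point of the deviance in the path parameterization
(the likelihood depends on c-paths only through their products), so the C
start must be interior. Cross paths start at 0.1 × the within-visit scale.
Gradient norms at the solution are reported from scipy finite differences.

Replicated simulation studies in the tests and the reproduction script use
two starts per fit: with a single start the occasional stalled full-model
fit deflates likelihood-ratio statistics, which is visible as
under-rejection in null calibrations.

## Model comparison

Nested models are compared by likelihood-ratio χ² with df equal to the
difference in free parameters. The ladder runs ACE vs AE, ACE vs CE and
AE vs E (df 3 each in the bivariate model: dropping a component removes
three paths), then tests e21 = 0, a21 = 0 and a22 = 0 (df 1) within the
selected model; non-significant paths are dropped and the final
specification refitted. When both AE and CE are acceptable against ACE, AE
is preferred (MZ > DZ correlations indicate genetic rather than
shared-environment resemblance). Information criteria are deliberately not
used.

All tests use the standard χ² reference, including components on the
boundary of their parameter space. This is conservative for boundary nulls:
a22 enters the likelihood only through a22², so under a true a22 = 0 the LRT
statistic follows the 0.5·δ₀ + 0.5·χ²(1) mixture and the standard χ²(1)
reference rejects at about 2.5% when 5% is nominal (about half the fitted
statistics are exactly zero). The regular e21 = 0 test calibrates at the
nominal rate. Both behaviours are verified by simulation in the test suite;
users should read boundary-path p-values as conservative.

The multigroup homogeneity test compares a full model with free paths per
ethnicity × sex group against a reduced model with paths equated across
groups; means stay group-specific in both, so the test targets variance
components, not the well-established mean differences. df =
(groups − 1) × path-parameter count (e.g. 3 × 6 = 18 for the bivariate AE
model over four groups). Opposite-sex DZ pairs have no single pair-level sex
and are excluded from ethnicity × sex analyses (they are retained in pooled
and ethnicity-only analyses); exclusions are recorded on the fit result.

## Confidence intervals

Intervals for derived quantities (per-visit heritability, specific
heritability, difference-score heritability, r_g, r_ph) are profile
likelihood: the bound is the quantity value at which the deviance, minimized
subject to an equality constraint on the quantity (SLSQP), rises above the
minimum by the χ²(1) quantile of the level (3.84 at 95%). The search steps
outward geometrically from the point estimate and Brent-solves the crossing;
a profile that reaches the quantity's natural domain boundary ([0, 1] for
fractions, [−1, 1] for correlations) first is reported at the boundary and
flagged one-sided. Simulated coverage for visit-1 heritability at 200 + 200
pairs is close to nominal (checked over 200 replicates). A parametric
bootstrap was considered and not implemented: the profile construction
respects the bounded parameter space directly and matches the interval style
the derived quantities need.

## The synthetic-cohort generator

The generator is the exact generative mirror of the model: per pair it draws
the latent factors with the twin sharing structure (DZ genetic factors as
√0.5·pair + √0.5·individual), applies the path weights and per-visit
group means, optionally adds a Gaussian mean-arterial-pressure covariate
(with configurable effect β on the log phenotype), applies MCAR missingness
independently per phenotype entry with per-visit probability, and generates
singletons as pairs with the co-twin removed. Phenotypes are exponentiated
to the raw scale for the canonical wide CSV so a full pipeline run exercises
the log-transform step. One master seed drives per-group child streams, so
identical (config, seed) gives byte-identical datasets.

The packaged configuration (`published_fit_config`) encodes the study
conditions this package emulates: unit log-scale phenotypic variance at both
visits with the best-fitting AE structure (a11² = 0.62, a21² = 0.16,
a22² = 0.19, e11² = 0.38, e21 = 0, e22² = 0.65, no C), the published group
composition (EA: 46 MZ + 75 DZ pairs + 47 singletons, 52.2% female; AA:
25 MZ + 59 DZ pairs + 40 singletons, 58.7% female — split by sex so
per-cell individual counts are 138/151/86/122), log-scale means μ =
ln(m) − ½ chosen so log-normal back-transformed means match the published
raw-scale group means, zero MAP effect (adjustment left the published
results unchanged), and zero extra missingness (the published per-group
counts are identical at both visits; singletons are the only
incompleteness). Missingness rates are configurable for testing the FIML
machinery.

What the generator does *not* emulate — and hence what passing tests do not
establish about real cohorts: all pairs are same-sex (the published cohort
almost certainly contained opposite-sex DZ pairs); the unit log-scale
variance makes the raw-scale distribution far more dispersed than real PWV
(raw-scale SDs are not matched, only means — every published standardized
quantity is scale-invariant, so this costs nothing for the analysis targets);
missingness is MCAR, not attrition correlated with the phenotype; there are
no within-visit age trends, no assortative mating, no gene–environment
interaction, and singleton zygosity labels are arbitrary (a marginal
likelihood never uses them).

## Numerical and reporting conventions

* Twin correlations are double-entry Pearson (each pair enters in both
  orderings), making them exactly invariant to twin labelling; published
  twin-correlation tables rarely state their estimator, and single-entry
  Pearson values can differ slightly.
* Descriptives use individual-level means with sample SD (n − 1 divisor);
  strata below the minimum pair count (3) or with no data are marked
  unavailable, never fabricated.
* Cross-visit component correlations with zero component variance at either
  visit are reported as undefined (`None` / `"undefined"`), since 0 and 1
  are both misleading at that boundary; likewise the difference-score
  fractions when Var(Δ) = 0.
* Fractions and correlations are conventionally displayed at 2 decimals;
  machine outputs keep full precision.
* Natural log is used for the transform; all standardized results are
  base-invariant.
* Negative LRT statistics beyond 1e-6 trigger a refit warning and are
  clipped to zero for reporting.

## Problem sizes used in the checks

Replicated studies use 200-replicate batteries of 200 MZ + 200 DZ complete
pairs (the scale of the emulated cohort), generator-vs-model moment checks
use 50,000 pairs per zygosity with an element-wise 0.01 band on the 4×4
sample covariance, and large-n single-fit consistency checks use 10,000
pairs per zygosity with a 0.01 band on standardized components. The ladder
selection-consistency check runs 12 replicates at 500 + 500 pairs. These
sizes make Monte-Carlo error small relative to each asserted band.

## Known limitations

* Two visits only; no sex-limitation models; no dominance; no annualized
  progression rates (only the two-visit difference score).
* Boundary p-values are conservative (see above); no mixture-reference
  option is provided.
* Profile intervals for quantities whose component variance can vanish
  (r_g with V_A → 0) can fail inside the constrained search near the
  degenerate region; intervals for variance fractions are robust.
* The FIML means model assumes covariates are observed wherever the
  phenotype is; pairs violating this raise an error rather than being
  silently dropped.
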