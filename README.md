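# twinchol

Bivariate Cholesky twin modelling of a longitudinally measured phenotype —
built around the classical twin design applied to carotid-distal pulse wave
velocity (PWV, m/s), an arterial-stiffness phenotype measured twice (about
three years apart) in European-American and African-American twin pairs.

The package answers the questions such a cohort poses: how heritable is the
phenotype at each visit, do the same genes act at both visits or do novel
genetic effects emerge, how much of the phenotype's stability over time
("tracking") is genetic, and is the change itself (the visit-2 − visit-1
difference score) heritable?

## Model

For a phenotype measured at two visits, the phenotypic 2×2 covariance across
visits is decomposed into additive-genetic (A), shared-environment (C) and
unique-environment (E) components, each loaded through a lower-triangular
Cholesky factor

    L_X = | x11   0  |        X ∈ {A, C, E},   Cov_X = L_X L_Xᵀ
          | x21  x22 |

so every component covariance is positive semidefinite by construction.
Twin-pair resemblance identifies the components: monozygotic (MZ) twins share
their A factors fully, dizygotic (DZ) twins with coefficient 0.5, C is shared
fully within any pair and E not at all. The expected 4×4 pair covariance
(twin1·v1, twin1·v2, twin2·v1, twin2·v2) has within-twin blocks A + C + E and
cross-twin blocks k·A + C, k ∈ {1, 0.5}.

Estimation is full-information maximum likelihood (FIML): each pair
contributes the multivariate-normal log density of whatever subset of its
four phenotype slots is observed, so incomplete pairs and singletons enter
without imputation. Model selection uses likelihood-ratio tests down a nested
ladder (ACE vs AE, ACE vs CE, AE vs E, each df 3, then single-path tests of
e21, a21, a22, df 1), and multigroup homogeneity across ethnicity × sex
equates path coefficients while leaving means group-specific. Derived
statistics are closed-form in the paths: per-visit heritability
h²_v1 = a11²/(a11² + c11² + e11²), h²_v2 = (a21² + a22²)/V_tot2, the visit-2
*specific* (novel-genes) heritability a22²/V_tot2, cross-visit component
correlations such as r_g = COV_A/√(V_A1·V_A2), the model-implied tracking
correlation r_ph, and the δ-weights difference-score decomposition
V_X(Δ) = (x21 − x11)² + x22². Confidence intervals are profile-likelihood
based. A synthetic-cohort generator mirrors the model generatively and ships
a packaged configuration emulating the study cohort (best-fitting AE model
with h² 0.62 → 0.35, 0.19 visit-2-specific; 46/75/47 and 25/59/40
MZ-pairs/DZ-pairs/singletons in the two ethnic groups).

## Worked example

```python
import twinchol as tc

cfg = tc.published_fit_config()              # packaged cohort emulation
ds = tc.simulate_cohort(cfg, seed=20210426)  # 292 pairs, 87 singletons
logged = tc.log_transform(ds)                # analysis happens on log(PWV)

print(tc.twin_correlations(logged, visit=1).to_string(index=False))
rep = tc.model_ladder(logged, tc.FitOptions(restarts=2, seed=0))
print(rep.to_text())
d = tc.compute_derived(rep.final_fit.params)
print(f"h2_v1={d.h2_v1:.2f}  h2_v2={d.h2_v2:.2f}  specific_h2={d.specific_h2:.2f}")
print(f"r_ph={d.r_ph:.2f}  r_g={d.r_g:.2f}  h2_delta={d.h2_delta:.2f}")
```

prints

```
ethnicity zygosity  visit  n_pairs        r
       AA       MZ      1       25 0.455967
       AA       DZ      1       59 0.284543
       EA       MZ      1       46 0.719100
       EA       DZ      1       75 0.217771
Model comparison ladder
-----------------------------------------------
ACE vs AE                    chi2=   1.460  df=3  p=0.6916
ACE vs CE                    chi2=  16.020  df=3  p=0.0011
AE vs E                      chi2=  69.115  df=3  p=0.0000
AE: e21 = 0                  chi2=   0.334  df=1  p=0.5636
AE: a21 = 0                  chi2=  30.391  df=1  p=0.0000
AE: a22 = 0                  chi2=   5.139  df=1  p=0.0234
selected model: AE
final spec: components=AE, dropped e21
final deviance: 2621.8474
h2_v1=0.62  h2_v2=0.38  specific_h2=0.22
r_ph=0.31  r_g=0.65  h2_delta=0.26
```

Reading the output: MZ twin correlations exceed DZ correlations in both
ethnic groups (genetic resemblance); the ladder keeps A and E, drops the
shared environment and the environmental cross path e21, and retains both
genetic paths — so the phenotype is heritable at both visits, tracking
(r_ph ≈ 0.31) is carried entirely by genes shared across visits
(r_g ≈ 0.65), novel genetic effects contribute at visit 2 (a22 ≠ 0), and the
three-year change itself is modestly heritable (h²_Δ ≈ 0.26). At this
single-cohort sample size the point estimates scatter around the generating
truth (0.62 / 0.35 / 0.19) with the sampling spread the profile intervals
describe.

There is also a CLI: `twinchol simulate`, `twinchol fit`, `twinchol ladder`,
`twinchol report` (full bundle: descriptives, twin correlations, ladder,
derived statistics with CIs, and a mean-arterial-pressure-adjusted rerun),
and `twinchol recover` (replicated simulate-and-refit).

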