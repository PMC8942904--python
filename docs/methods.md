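# Methods

This note documents the statistical models implemented in `epinoia`, the
assumptions behind the synthetic breeding-program generator, and the
numerical choices that matter when reproducing or extending the analyses.

## Models

All three models describe plot-level yield `y` (kg per plot) of inbred lines
evaluated in multi-environment trials:

```
I        : y = Xb + Z1 l + Z2 f + sum_{i=1..9} Z_{i+2} s + e
I+GA     : adds Z3 g,  g ~ N(0, G sigma_g^2)
I+GA+GAA : adds Z4 h,  h ~ N(0, H sigma_h^2)
```

* `b` — fixed trial effects, one level per trial nested within
  year x location x breeding cycle (full-rank one-hot coding; with the trial
  factor as the only fixed term no level needs dropping).
* `l ~ N(0, I sigma_l^2)` — uncorrelated line effect. It absorbs genetic
  variance not captured by the markers, which is why broad-sense heritability
  always includes it.
* `f ~ N(0, I sigma_f^2)` — line-by-environment (year x location)
  interaction.
* `s ~ N(0, I sigma_s^2)` — spatial position effects. Every plot is covered
  by the nine positions of the 3x3 square centred on it; each trial's grid is
  padded with a one-deep ring of *virtual* positions so border plots also
  have nine covering positions. Virtual positions carry effects but no
  phenotypes. A plot's spatial variance contribution is therefore
  `9 sigma_s^2`.
* `e ~ N(0, I sigma_e^2)` — residual. Homogeneous across trials; dominance
  terms are omitted because residual heterozygosity of F6 lines is ~3% and
  dominance contributes negligibly.

### Relationship matrices

The additive matrix follows the NOIA (natural and orthogonal interactions)
parametrization: the coefficient for allele count `x` in a marker with
genotypic frequencies `p_Aa`, `p_aa` is `(p_Aa + 2 p_aa) - x`, i.e. the
negated deviation from the observed mean count, so each coefficient column
sums to zero. With `H_a` the lines x markers coefficient matrix,

```
G = H_a H_a' / (tr(H_a H_a') / n)        (mean diagonal exactly 1)
H = (G ∘ G)  / (tr(G ∘ G) / n)           (Hadamard square, renormalized)
```

Because the NOIA additive coefficient is exactly the negated VanRaden-centred
allele count, the trace-normalized VanRaden matrix is identical to `G`; the
package keeps both constructions and the test suite asserts their agreement
to 1e-10, plus the equality of the resulting model fits (EG-BLUP/NOIA
equivalence). Genotypic frequencies are counted on hard calls before mean
imputation; the coding is affine in the allele count, so applying it to
fractional imputed values is exact, and because mean imputation preserves
column means the VanRaden identity survives imputation.

Some presentations print the homozygote NOIA coefficient as
`-(p_Aa - 2 p_aa)`; that form does not centre the column and breaks both the
trace normalization and the VanRaden identity, so the centred form above is
used throughout.

### Marker quality control

Markers with minor allele frequency `< 0.05` (computed on observed calls) or
call rate `< 0.90` are removed; both thresholds are strict, so boundary
markers survive. Missing calls are then replaced by the marker's mean
observed allele count.

## AI-REML

Variance components are estimated by restricted maximum likelihood on the
observation-level covariance `V = sum_k sigma_k^2 Z_k K_k Z_k' + sigma_e^2 I`
with average-information (AI) updates:

* Start values split the phenotypic variance equally across all components.
* Each iteration proposes a Newton step in the AI metric over the components
  not pinned at the variance floor, clips it at the floor, and damps it
  (factors 1, 1/2, 1/4, 1/10) until the restricted log-likelihood does not
  decrease. If no damped AI step ascends, a guaranteed-ascent EM step is
  taken instead. Accepted iterations are therefore monotone in the
  restricted likelihood, which the test suite asserts on every fit.
* Convergence: relative change of every parameter `< 1e-8` and relative
  log-likelihood change `< 1e-10`, within 100 iterations; non-convergence
  raises an error carrying the iteration trace.
* Estimates are clamped at a floor of `1e-8 x var(y)` rather than allowed to
  go negative, keeping all covariance matrices valid; floored components are
  flagged in the output.
* Standard errors and the sampling correlation matrix of the estimates come
  from the inverse AI matrix at the optimum. These sampling correlations are
  what the non-orthogonality report summarizes: when the epistatic term
  enters, a strongly negative additive-epistatic sampling correlation and a
  drop in the additive estimate signal that the genetic partition is not
  orthogonal.

BLUE/BLUP solutions come from Henderson's mixed-model equations at the
estimated components. Relationship-matrix inverses use eigenvalue clipping
(eigenvalues below `1e-8 x` the largest are raised to that bound) because
marker panels on closed breeding populations are routinely numerically rank
deficient; a fixed diagonal ridge proved insufficient to keep the Henderson
coefficient matrix positive definite. Terms with exactly zero variance are
dropped from the equations and their predictions set to zero.

## Cross-validation

* **LOO** (leave-one-line-out): all plots of one line are masked and its
  GEBV/GEEV predicted from the rest; every line is a fold.
* **LSO** (leave-one-cycle-out): all phenotypes of one breeding cycle are
  masked; this is the scenario a breeder faces with unphenotyped material.

Predictive ability is the Pearson correlation between the pooled partial
predictions and fixed-effect-corrected line means (plot phenotype minus the
fitted fixed effect from a full-data fit, averaged per line). Checks are not
selection candidates and are excluded from the correlation (configurable).

Variance components are by default estimated once on the full data and held
fixed across folds: re-running REML for every LOO fold is computationally
implausible at realistic scale and fold-wise components differ negligibly
when one line of thousands is removed. Under this policy each LOO fold is
solved exactly by a low-rank Woodbury downdate of the full-data
mixed-model-equation Cholesky factor — algebraically identical to re-solving
the equations with the line's rows deleted, which the test suite verifies
against direct refits. Per-fold REML re-estimation is available
(`vc_policy="per_fold"`) and practical for the handful of LSO folds.

Model comparison uses an ordinary nonparametric bootstrap at full sample
size, paired across models (both predictive abilities computed on the same
resampled lines), with 10,000 replicates by default, summarized by bootstrap
standard errors and a two-tailed paired t-test at threshold 0.01. The
relative difference `RD = (PA_AA - PA_A) / PA_A` is computed on unrounded
correlations. The ceiling `sqrt(n h^2 / (1 + (n-1) h^2))` gives the maximum
attainable correlation against means of `n` repeated plots; for total-merit
predictions the additive-plus-epistatic variance share replaces `h^2`.

The LR method contrasts "whole" predictions (full-data fit) with "partial"
predictions (from cross-validation): bias `mu_wp = mean(u_p) - mean(u_w)`
(expectation 0) and dispersion `b_wp = cov(u_w, u_p) / var(u_p)`
(expectation 1; values below 1 indicate inflated partial predictions).

## Heritability

Plot phenotypic variance sums the model's components with spatial counted
nine-fold: `sigma_P^2 = sigma_l^2 [+ sigma_g^2 [+ sigma_h^2]] + sigma_f^2 +
9 sigma_s^2 + sigma_e^2`. Narrow-sense `h^2 = sigma_g^2 / sigma_P^2` is
reported only for the purely additive genomic model — under the epistatic
model the additive estimate is not interpretable in isolation and requesting
`h^2` emits a warning. Broad-sense `H^2` divides the model's total genetic
variance (`sigma_l^2` alone, plus `sigma_g^2`, plus `sigma_h^2` as the model
grows) by `sigma_P^2`. When reproducing tabulated components, the spatial
row is interpreted as the 9-plot total — the only reading under which the
tabulated narrow-sense heritability (0.15) follows from the printed values —
and `VarianceComponents.from_plot_totals` converts it back to the
per-position scale. Report rounding mirrors the tabulated convention
(2 decimals for heritabilities, 3 for variances); full precision is always
retained in the JSON output.

## Synthetic breeding program

The generator emulates the data structure the models assume:

* **Founders**: fully homozygous, allele frequencies drawn per marker from a
  configurable interval (default U(0.1, 0.5)).
* **Crosses and SSD**: bi-parental crosses followed by (default) five
  generations of single-seed-descent selfing with independent Mendelian
  segregation per marker — expected F6 heterozygosity `(1/2)^5 ≈ 3.1%`.
  There is no linkage map: linkage disequilibrium in the generated panels
  arises from relatedness (full-sib families), which crossing plus selfing
  already induces, and that is the LD that matters for the relationship
  matrices. A map hook is left as configuration.
* **Genetic effects**: additive values are `sum_j alpha_j x_ij` over a
  random QTL subset, epistatic values `sum_(j,k) beta_jk w_ij w_ik` over
  random marker pairs with `w` the centred count; effects are rescaled so
  realized line variances match the targets exactly (factors logged).
* **Trials**: per cycle, `blocks x lines-per-block` lines are laid out per
  trial with two replicates each plus replicated check lines (46 plots per
  block under the defaults); blocks form grid columns, re-randomized per
  trial. Phenotypes add a trial effect (i.i.d. normal, default SD 0.5 kg
  around a grand mean of 8.71 kg, matching typical plot yields), the line /
  additive / epistatic values, a line-by-environment draw, the nine covering
  spatial effects (drawn on the padded grid, so virtual border positions
  receive real draws but no phenotypes), and residual noise.
* **Missing genotypes**: injected completely at random (default 1.3%) into
  the exported genotype file only; the truth tables keep clean genotypes.
* **Checks**: simulated as ordinary genotyped lines flagged `is_check`, so
  the fitter can include or exclude them from genomic terms.
* **Founder sharing**: by default all cycles draw crosses from one founder
  pool; `shared_founders=False` gives every cycle a disjoint pool, producing
  genetically unrelated cycles for across-cycle validation scenarios.

Everything is driven by generator streams spawned from one seed; identical
configurations yield byte-identical outputs.

What the generator does *not* emulate: genetic linkage maps (see above),
selection during the breeding cycles, seed-source/field-management
heterogeneity, genotyping error beyond random missingness, and
autoregressive or trend-like spatial structure (position effects are i.i.d.).
Passing tests therefore demonstrate correctness of the estimation machinery
under the generating model's assumptions, not robustness of the models to
real-data violations of those assumptions.

## Problem sizes used in the test suite

The heavier checks run at sizes chosen to keep the whole suite comfortably
reproducible on a laptop while leaving the mechanisms identifiable:

* Parameter recovery: 2 cycles x 150 lines (6 blocks of 25), 2 locations,
  800 markers, 250 QTL / 200 pairs — 1,296 plots, 10 seeds.
* Directional cross-validation contrast: 2 cycles x 60 lines (8 full-sib
  families of 16), 2 years x 2 locations per cycle, 600 markers, epistatic
  share 74% of genetic variance — 1,056 plots per program, 10 seeds per
  scheme, with disjoint founder pools in the across-cycle scenario. Two
  years of phenotyping per cycle are used because with a single year the
  epistatic variance is on the edge of identifiability at this scale (REML
  floors it in a minority of seeds, collapsing the epistatic model onto the
  additive one).
* Model equivalence: one cycle of 150 lines, 400 markers.

## Known limitations

* Dense linear algebra throughout: practical to a few thousand plots /
  MME dimension; full breeding-program scale (tens of thousands of plots,
  thousands of lines) would want sparse factorization of the mixed-model
  equations.
* Homogeneous residual variance across trials; no autoregressive spatial
  alternatives; single trait.
* The bootstrap paired t-test treats the 10,000 replicate pairs as the
  inferential sample, following the published procedure; with that many
  replicates even small PA differences reach significance, so the p-value
  should be read jointly with the bootstrap SEs.
* `h^2` under the epistatic model is deliberately not reported (warning
  instead) because the genetic partition is demonstrably non-orthogonal.
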