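# Methods

This note documents the statistical model, the synthetic-data generator, and
the numerical and design choices behind `multiprs`, at the level of detail a
maintainer or reviewer needs to judge what the package's tests do and do not
demonstrate.

## The ensemble model

The observed phenotype (SBP or DBP, mmHg) is decomposed through two
consecutively trained components. The baseline model `M_b` predicts the
phenotype from non-genetic covariates `x_b` = (age, sex, group, BMI, study);
the genetic model `M_g` predicts the baseline residuals `r_b = y − ŷ_b` from
the transferable covariates `x_g = x_b ∖ {study}` plus PRS features. The
ensemble prediction is `ŷ_b + r̂_b`, and `y = ŷ_b + r̂_b + r_g` holds exactly
by construction (`r_g` is defined as the remainder); the test suite audits
this identity to 1e-9 on scored data.

The split into two components is not merely organisational: `study` is the
only covariate that cannot be harmonized across datasets, so confining it to
`M_b` makes `M_g` fully transferable. Cross-dataset calibration refits `M_b`
on the new cohort — deliberately without a train/test split, since no
hyperparameter of the new baseline is evaluated on held-out data from that
cohort — and reuses the trained `M_g` byte-for-byte (verified by hashing its
serialized state).

Assumptions: residual stacking treats `r_b` as a fixed target when fitting
`M_g`; uncertainty in `M_b` is ignored at that stage. Both phenotypes are
modelled marginally; no shared-residual structure between SBP and DBP is
exploited.

### Engines and tuning

* `linear`: OLS via statsmodels with one-hot categories (first level
  dropped). Coefficient standard errors are retained for the parameter
  recovery checks. Unseen category levels at prediction time raise an error
  naming the level; silent coercion would corrupt calibration.
* `gbt`: xgboost gradient-boosted trees, `tree_method="hist"`, single
  thread for bit-reproducibility. Hyperparameters are chosen by seeded
  random search over depth 2–8, learning rate 0.01–0.3 (log-uniform),
  row/column subsampling 0.5–1.0, with the tree count governed by early
  stopping (cap 2000, patience 25) inside K-fold cross-validation; the best
  configuration is refit at the mean stopped tree count. Trials are scored
  by mean validation R² (the residual form of PVE) rather than the
  variance-ratio form, which would reward high-variance overfit predictors
  during selection. `n_trials=0` skips the search and uses depth 3 /
  learning rate 0.1 with CV-chosen tree count — the cheap setting used in
  replicated directional tests where both arms share the same engine.
* `lasso`: standardise-then-LASSO with the penalty chosen by K-fold CV over
  100 log-spaced values from the analytic λ_max = max|X'r|/n down by 1e-4.
  Used for local-PRS selection; the fitted sparse model can itself serve as
  the genetic model, or the selected columns can be refit with either other
  engine (three-way comparison).

### PRS construction

Clump-and-threshold with defaults r² ≤ 0.1 within 1000 kb windows, and the
seven-threshold grid {5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2}. Clumping
is greedy: repeatedly take the remaining variant with the smallest p-value
as an index and remove all same-chromosome variants within the window whose
squared dosage correlation with it reaches the cutoff. Ties on p break by
(chromosome, position), making the output invariant to row order; a
brute-force oracle check over 200 random ≤50-variant panels is part of the
acceptance suite. Clumping runs once per source at the full variant set and
the p-value threshold is applied per column afterwards, mirroring standard
clump-then-threshold tooling. LD r² is computed on the scoring panel's own
dosages by default (it acts as its own LD reference); an external reference
panel may be passed instead.

Scores are raw weighted allele-dosage sums in mmHg (no per-column
z-scoring): tree models are scale-invariant and raw sums keep the additive
interpretation. A `standardized()` view exists for linear engines. Local
PRSs use a single threshold (1e-2) within each LD region; regions
contributing no variant are dropped rather than zero-filled so the LASSO
never sees constant columns. Missing dosages are mean-imputed per variant
before scoring. Allele harmonization flips effect signs for swapped
alleles, drops strand-ambiguous (A/T, C/G) pairs by default, and matches by
(chromosome, position, allele set) — never rsID.

### GWAS algebra

`subtract_gwas` removes a sub-cohort's contribution from a fixed-effects
meta-analysis by exact inverse-variance inversion: with w = 1/SE²,
`w_rem = w_meta − w_sub`, `β_rem = (w_meta β_meta − w_sub β_sub)/w_rem`,
`SE_rem = w_rem^{-1/2}`, p recomputed from the Wald statistic. This is the
exact inverse when the sub-cohort entered the meta-analysis as an
independent study; overlap that is partial or dependent leaves residual
contamination that no summary-level procedure can fully remove. Variants
where the sub-cohort carries at least the meta's weight are dropped with a
warning. The marginal GWAS uses the Frisch–Waugh projection so all variants
are fit in one vectorised pass; p-values come from the t distribution with
n − k − 1 degrees of freedom.

### Evaluation

PVE is implemented exactly as `(1 − (var(out) − var(ôut))/var(out)) × 100`,
which algebraically equals `100·var(ôut)/var(out)`. This differs from the
conventional R²-style `1 − var(out − ôut)/var(out)` unless predictions and
errors are uncorrelated (they are, asymptotically, for the linear engine on
its training distribution); a `residual_based` flag provides the
conventional form, and internal model selection always uses it. Variances
use the unbiased (n−1) estimator throughout. Bootstrap CIs resample test
individuals with replacement at the analysis sample size — per stratum when
stratified — re-apply the already-trained models, and take the 2.5/97.5
percentiles of (by default) 100 replicates. Replicates with zero phenotype
variance are dropped and counted. Strata under 30 individuals are flagged
wide-CI; strata with n ≤ 1 are skipped.

## Cohort harmonization

Medication adjustment adds +15 mmHg (SBP) / +10 mmHg (DBP) to treated
individuals, approximating their untreated pressure; it is applied before
outlier handling, and a `med_adjusted` flag makes the operation
non-repeating. Outliers are masked per phenotype — values strictly below the
1st or strictly above the 99th percentile, with percentiles computed over
the complete input (linear-interpolation quantile estimator, recorded in
the removal report). Masking (NaN) rather than row deletion keeps SBP and
DBP analysis sets independent. Relatedness filtering removes individuals
greedily by descending number of remaining related partners (kinship ≥
2^(−9/2) ≈ 0.0442, the degree-3 bound), with id-order tie-breaks; a
post-audit asserts no related pair survives. Greedy max-degree removal does
not minimise the number removed on every graph, but is deterministic and
near-optimal on the sparse kinship graphs of biobank-scale cohorts.

Note one interaction the tests exercise explicitly: quantile truncation of
the phenotype attenuates downstream OLS coefficients toward zero (tail
truncation reduces covariance more than variance). The parameter-recovery
test therefore disables trimming; the attenuation under trimming is an
inherent property of the procedure, not an estimation defect.

## The synthetic-data generator

The generator produces the statistical structure the framework assumes,
not a demographic simulation.

**Genotypes.** Block-LD dosages from a latent-Gaussian threshold model: for
each block and population, two haplotype indicators per variant are
thresholded from equicorrelated normals, and the latent correlation is
calibrated through the tetrachoric relation (bivariate-normal orthant mass
via Owen's T) so that mean pairwise dosage r² within the block matches the
configured `block_r2`; blocks are independent. Variants within a block share
the block's per-population allele frequency: a threshold model cannot reach
high dosage r² between variants of materially different frequency (the
tetrachoric ceiling), and tightly linked variants sharing frequency is
itself realistic. Block anchor frequencies are uniform on `maf_range`
(default 0.05–0.5) and diverge across populations by a Balding–Nichols draw
with per-population `fst` (defaults 0.02–0.10 across five groups mixed
49/23/19/7/2 percent, approximating a large multi-ethnic U.S. cohort).
Related pairs are injected by copying each variant from the partner with
probability 2φ, giving genotype correlation ≈ 2φ for the declared kinship φ.

**Phenotypes.** SBP = intercept (125) + covariate function + genetic score
+ N(0, residual_sd²), with age ~ U(30, 80), BMI ~ N(28, 5), sex ≈ 55%
female, group offsets, and optional non-linear terms (age×BMI product,
extra slope past age 60). Default linear effects (0.45 mmHg/yr age, 4 mmHg
sex, 0.9 mmHg per kg/m² BMI) put the covariate share of SBP variance near
28%, matching what demographic covariates achieve in large blood-pressure
cohorts; residual_sd defaults to 13 mmHg. The raw genetic score G·β is
rescaled so its realized variance share equals `h2_prs` (default 0.10)
exactly in expectation; the truth object records realized shares, the
scaled per-allele effects, and the per-individual true scores. DBP uses the
same genetic score with covariate effects and noise scaled by
`dbp_factor = 0.5`. Medication use is assigned with probability increasing
in latent SBP (≈25% overall) and measured values of treated individuals are
lowered by exactly 15/10 mmHg — the inverse of the harmonization rule, so
adjustment recovers the latent phenotype exactly.

Causal effects are Gaussian on a `causal_fraction` of variants. Populations
may carry distinct effect vectors with cross-population correlation
`effect_corr` (default 1.0) plus a per-population multiplier
(`group_effect_scale`); the correlation parameter exists because a scalar
multiplier alone cannot produce the population-specific causal structure
needed to study multi-GWAS gains in mismatched populations.

**Discovery GWAS.** Structural parameters (frequencies, LD, effects,
population assignment) derive deterministically from `config.seed`, so a
discovery cohort shares the panel's structure while containing new
individuals. The default mode simulates the discovery cohort explicitly and
runs the marginal GWAS on it; an `analytic` mode samples
β̂ ~ N(marginal β, SE) with the LD-tagged marginal effect and SE computed
from a moderate reference draw — the exact sampling distribution at a
fraction of the cost, used where tests need very large discovery sizes.
Monomorphic variants are emitted with NaN estimates and excluded downstream.

**What the generator does not emulate:** recombination-map LD decay,
imputation error, assortative mating, gene–environment correlation,
longitudinal measurement error, EHR-style missingness, or realistic
demographic history. Passing tests therefore demonstrate correctness of the
machinery and the qualitative behaviour of the design (non-linear baseline
gains, multi-GWAS transfer gains, calibration gains) under the stated
generative assumptions — not performance levels on real cohort data, whose
headline PVEs depend on data we do not model.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes — panels of 2,000 to
10,000 individuals and 40–300 variants in 4–50 blocks, discovery GWAS of
1e5–2e5 (analytic mode), 20 replicate seeds for every replicated claim —
chosen so the full suite completes in about a minute on a single core while
keeping each check's Monte-Carlo error far from its decision boundary. All
randomness flows from a single integer seed through named child generators
(CRC32-tagged `SeedSequence` spawns), so every pipeline artifact, including
bootstrap CIs and xgboost fits (single-threaded `hist`), is bit-reproducible
given the config; the manifest records the config echo and derived seeds
needed to re-run an experiment exactly.

## Known limitations

* The inverse-variance subtraction assumes the removed GWAS entered the
  meta-analysis exactly and independently; partial overlap is not modelled.
* Greedy clumping with the panel as its own LD reference inherits the
  panel's sampling noise in r²; small panels can retain marginally
  correlated pairs.
* The printed-formula PVE can exceed the conventional R² when predictions
  are noisy; both are available, and comparisons in this package always use
  a single form on both sides.
* LASSO selection inherits the usual irrepresentable-condition caveats;
  support recovery is demonstrated for approximately independent local PRS
  columns (disjoint LD regions), the intended use.
* The kinship-injection scheme produces the declared pairwise coefficient
  but no higher-order pedigree structure.
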