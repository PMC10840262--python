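# Methods

## The problem

A polygenic risk score for individual *i* is a weighted sum of effect-allele
dosages, `PRS_i = Σ_j d_ij w_j`. The weights `w` are estimated, so `PRS_i`
inherits their uncertainty. This package represents each individual's score
as a distribution of draws — frequentist bootstrap replicates or Bayesian
posterior samples — and propagates that distribution through percentile-based
risk stratification, relative-risk estimation, and risk-prediction models in
a case-control design. Both estimation arms summarize the per-individual
distribution the same way: mean, standard deviation, and the empirical
`((1−p)/2, (1+p)/2)` quantile interval with linear interpolation between
order statistics. The interpolation convention is fixed package-wide because
interval endpoints feed hard classification decisions; `p = 0` degenerates
to the median and `p = 1` to the full range of the draws.

## Bootstrap arm (cross-validated fixed SNP panel)

Individuals are split into k = 5 folds stratified by case status. For each
fold, one joint multivariable logistic regression of case status on all
scored SNP dosages plus covariates (age, gender, smoking status, top-10
principal components) is fit on the other k−1 folds; B bootstrap refits of
the training folds (cases and controls resampled separately, preserving the
class balance of a case-control design) provide B weight vectors, and each
held-out individual is scored with every one of them. Held-out-only scoring
keeps each individual's draws independent of their own phenotype. Covariate
coefficients are discarded: the score is genetics-only. Design choices that
were genuinely open:

- *Joint vs marginal fits.* The default is one joint model per refit — it
  avoids double-counting LD between scored SNPs; `marginal=True` provides
  per-SNP fits for comparison.
- *Separation.* A refit that fails to converge or produces runaway
  coefficients (|standardized coef| > 30) is repeated with a light L2
  penalty (C = 100) and counted in the diagnostics; features are internally
  z-scaled for conditioning and coefficients mapped back to the per-allele
  scale.
- *PCs are computed once globally*, not per training fold.

Calibration: across replicate cohorts in which the scored SNPs carry all the
genetic signal (so the regression is correctly specified), the nominal 95%
interval covers the score implied by the true generative coefficients for
~95% of individuals. Coverage aggregated within a single cohort is lumpy —
it hinges on k = 5 fold-level estimation errors — so the test aggregates
over eight replicate cohorts.

## Posterior arm (spike-slab Gibbs sampler)

The model is the standard summary-statistics formulation: marginal effects
`β̂` on standardized genotypes observe the true effects through the LD
matrix, `β̂ ~ N(R β, R σ_e²/n)`, with the spike-slab prior
`β_j = 0` w.p. `1 − p_causal`, else `N(0, h²/(M·p_causal))`. A
systematic-scan Gibbs sampler residualizes each coordinate against the rest
(`β̃_j = β̂_j − Σ_{k≠j} R_jk β_k`), forms the conjugate slab conditional
(variance `v = (n/σ_e² + 1/σ_β²)^{-1}`, mean `v·n·β̃_j/σ_e²`), draws
inclusion from the analytic posterior odds, and samples the slab normal or
an exact zero. With identity LD and `p_causal = 1` every coordinate is
conjugate normal-normal, giving the closed-form oracle used by the tests:
posterior mean `β̂_j · nσ_β²/(nσ_β² + σ_e²)`.

Numerical and design choices:

- *Summary statistics* are linear regressions of the covariate-residualized
  0/1 phenotype (rescaled to unit variance) on standardized dosages — the
  standard continuous-trait approximation for case-control data in
  LDpred-style pipelines; it keeps the Gaussian likelihood of the sampler
  exact. `σ_e² = 1` by default.
- *LD is block-diagonal* (matching the simulator's architecture), each block
  a sample correlation matrix with ε = 0.01 added to the diagonal;
  a block that is singular after regularization raises with advice to
  increase ε.
- *Schedule*: 700 iterations, 200 burn-in, thin 1 by default (500 retained
  draws). These are desk-scale defaults; the conjugate oracle and recovery
  tests pass at 300–700 iterations.
- *Scoring scale.* Sampled effects live on the standardized-genotype scale,
  so posterior PRS draws use standardized dosages (training-fold means and
  s.d.s when scoring held-out individuals). Mixing raw dosages with
  standardized-scale effects would be scale-inconsistent.
- *Train/score separation* mirrors the bootstrap arm: stratified k-fold,
  effects sampled on training folds only.

## Stratification

Thresholds and ranks are defined on the population distribution of
per-individual PRS **means**; each draw is ranked against that reference
(midrank convention for ties). The alternative (ranking against all pooled
draws) is available via `reference="pooled"`. Classification is strict:
"above threshold" means strictly greater, so a tie at the threshold value is
uncertain. Deciles are left-closed/right-open on means with the top decile
right-closed. Decile certainty requires the whole p-level interval inside
the mean's decile (one-sided at the extreme deciles). Concordance counts
individuals above the t-th percentile under both estimators and reports the
percentage against the *nominal* group size `N·(100−t)/100`, matching the
printed-table convention. Because empirical quantile intervals are nested in
p, the certain sets shrink monotonically as p grows — the sensitivity curve
is monotone non-increasing by construction.

## Evaluation

Odds ratios come from multivariable logistic regression (statsmodels MLE)
of case status on a risk-group indicator plus age, gender and smoking
status; Wald 95% intervals and p-values are reported, and a 2×2 with no
covariates reproduces the cross-product OR and Woolf interval exactly.
Mean-based decile contrasts are pairwise fits of each decile against the
lowest. Quasi-separation is flagged (and stabilized with a tiny L1 penalty),
never silently dropped. AUC uses stratified 5-fold cross-validation of
logistic models over an incremental predictor ladder (risk group; +age;
+gender; +smoking status or +pack-years; covariates only); the interval is a
normal approximation over fold AUCs, and reported `n` always equals the rows
actually fitted.

## Synthetic cohorts

The generator supplies the ground truth the real study cannot:

- *Genotypes*: two independent haplotypes per individual, each a latent
  Gaussian AR(1) field (block size and ρ configurable) thresholded at the
  normal quantile of a per-variant allele frequency drawn uniformly from
  `maf_range`. Marginally each variant is in exact Hardy-Weinberg
  proportions; within-block LD grows with ρ. The implied genotype
  correlation is below the latent ρ (copula attenuation), which is why LD
  tests measure realized correlations rather than asserting ρ itself.
- *Effects*: spike-slab with slab variance `h²/(M·p_causal)` on the
  standardized scale, so the genetic score variance is ≈ h².
- *Covariates*: age ~ N(62.9, 10.6²), 62% male, smoking
  never/former/current at 19.3/38.2/42.4%, pack-years log-normal
  (meanlog 3.2, sdlog 0.8) among ever smokers and exactly zero for never
  smokers — marginals chosen to mimic a large lung-cancer consortium's
  baseline table. The covariate log-ORs on disease (0.15/decade of age,
  0.10 male, 0.60 former, 1.00 current, 0.008 per pack-year) are generative
  defaults chosen once for plausible covariate-outcome contrasts; the
  source study reports no generative values, so these are testing
  conditions, not epidemiological estimates.
- *Disease*: logistic link on genetic score + covariate effects by default
  (matching the downstream logistic evaluation), with a liability-threshold
  option; the intercept is calibrated so the source-pool prevalence hits
  `base_prevalence` (0.55), and the cohort is subsampled to the exact
  requested case:control counts (default 1717:1289, a 1:10 scale-down of
  the motivating study's 17,166:12,894).

What the generator does **not** emulate: population structure/admixture
(PCs on simulated data capture noise), genotyping/imputation error,
missingness mechanisms other than MCAR, interactions or non-linear covariate
effects, and realistic genome-scale LD. Passing tests therefore demonstrate
that the machinery is correct and that the qualitative phenomena
(uncertainty-aware classification shrinking the certain set, many-small-
effect scores carrying more individual-level spread, imperfect
cross-estimator concordance, larger certain-subset odds ratios) emerge under
a known architecture — not that any specific real-data number is recovered.

## Problem sizes used by the test suite and acceptance script

Simulation-backed checks run at desk scale chosen as the package's own
defaults: cohorts of 1000–4000 individuals, 16–500 variants, B = 60–200
bootstrap refits, 300–700 Gibbs iterations; directional comparisons
aggregate 20 seeded replicate studies. The acceptance script uses 1717
cases / 1289 controls, 500 variants, B = 200 and 500 Gibbs iterations, and
derives every stream of randomness from the single `--seed` argument.

## Known limitations

- The Gibbs sampler is a pure-Python coordinate loop; fine up to a few
  thousand variants, not genome-scale. Only block-diagonal LD is supported
  (no banded windows), and hyperparameters (`p_causal`, `h²`) are fixed from
  config rather than estimated.
- Bootstrap quantile intervals are percentile intervals; no bias-corrected
  (BCa) variant.
- The fixed-weight arm treats weights as exact (that is its point — the
  contrast arm for the two interval methods).
- Sample-level QC (relatedness, heterozygosity) and LD pruning before PCA
  are out of scope.
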