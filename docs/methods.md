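# Methods

## Model

`gxesum` estimates the share of phenotypic variance explained by genome-wide
genotype-by-environment interaction (GxE) from GWAS summary statistics of
SNP-by-environment interaction effects, without individual-level genotypes at
fit time. The generative view is a first-order reaction-norm model

    y = b + g0 + g1 ∘ E + τ0 + τ1 ∘ E

with `g0 = X β0` the main polygenic value, `g1 = X β1` a polygenic value whose
expression scales with a standardized environmental covariate `E`, `τ0` an
environment-stable residual and `τ1` an environment-modulated residual (RxE,
i.e. residual heteroskedasticity across the environmental gradient). `X` is
the column-standardized n×m genotype matrix. Writing `h²g1` and `h²τ1` for
the phenotypic variance fractions of `g1 ∘ E` and `τ1 ∘ E`, the expected Wald
chi-square of the per-SNP interaction coefficient is linear in the SNP's LD
score ℓ_j:

    E[χ²_j] = (N h²g1 / M) ℓ_j + 1 + (κ − 1)(h²g1 + h²τ1)

where N is the GWAS sample size, M the SNP count and κ the kurtosis of E
(κ = 3 for normal E, giving the intercept 1 + 2(h²g1 + h²τ1)). The slope of
a weighted regression of χ² on ℓ therefore measures GxE, while RxE, scale
effects and similar environment-linked inflation move only the intercept —
that separation is what keeps residual heterogeneity from masquerading as
interaction. `h²τ1` is recovered from the intercept as
`(intercept − 1 − (κ−1) h²g1)/(κ−1)`; negative values are reported as-is
(they are estimation noise, and RxE recovery is a diagnostic, not the
primary estimand — for binary traits the dichotomization itself generates
statistical scale effects that land in the intercept, so intercept-derived
RxE should not be over-read there).

Key assumptions: effects are polygenic and i.i.d. across SNPs (E[β1] = 0);
any single SNP explains a negligible share of Var(E), so fourth-moment
cross-terms reduce to κ; the phenotype is pre-adjusted for confounders and
the main effect of E; and the 1 − 3/N factor on the slope is taken as 1
(the exact N − 3 form is available via `approx_large_n=False` for small-N
checks).

## Estimation pipeline

1. **Pre-adjustment** (`preadjust_phenotype`): OLS residuals of the outcome
   on an intercept, the environment and any confounders, re-standardized to
   unit variance. Missing entries are either mean-imputed (maximizing N) or
   row-dropped; the drop path returns the kept-row mask so genotypes can be
   subset consistently. Binary 0/1 outcomes go through the same linear
   adjustment.
2. **Interaction scan** (`interaction_scan`): per SNP, the linear model
   `y = a + b_m x_j + b_1 (x_j ∘ E) + e` fit by least squares on
   standardized genotypes and standardized E; χ²_j is the squared t-ratio
   of `b_1` with the homoskedastic SE (an HC0 option exists but the
   intercept theory is stated for the classical Wald statistic). The scan
   is vectorized through per-SNP 3×3 normal equations and is verified
   against a one-SNP-at-a-time OLS oracle to 1e−8. Binary outcomes use the
   same linear model: the simulations generate disease by thresholding a
   probit-style liability, which a linear model approximates well, and
   logistic fits can be biased in this setting.
3. **LD scores** (`estimate_ld_scores`): ℓ_j = 1 + Σ r̂² over neighbours
   within a SNP-count window, bias-adjusted by default
   (r̂² − (1−r̂²)/(n−2)); the raw estimator is retained because it makes
   toy algebra exact (k duplicated SNPs score exactly k). The window unit
   is SNP count, since synthetic maps carry no genetic distance.
4. **Regression** (`GxESum`, a scikit-learn estimator): weighted least
   squares of χ² on N ℓ/M with a free intercept. Default weights multiply
   the LDSC-style overcounting term 1/max(ℓ,1) by the heteroskedasticity
   term 1/(2 (intercept + slope·Nℓ/M)²), iterated twice (moment-matched
   start → refit with updated weights). `weighting="none"` gives plain OLS
   for exact algebraic checks. The predicted mean is floored at 1e−3 when
   forming weights. N is the median per-SNP sample size; M defaults to the
   SNP count after the inner join of sumstats and LD scores on SNP id.
5. **Uncertainty**: delete-one-block jackknife over contiguous SNP blocks,
   default 200 blocks (m/10 when m < 2000), weights held fixed across
   deletions (block cross-product subtraction makes each leave-one-out
   refit exact under fixed weights). SE = sqrt((B−1)/B Σ(θ_b − θ̄)²).
   Significance is a two-sided normal Wald test of h²g1/SE; fits with
   fewer than 200 SNPs are refused by default because the jackknife
   becomes meaningless.
6. **Liability scale** (`observed_to_liability`): for 0/1 traits, h²g1 and
   its SE are multiplied by k(1−k)/z² (Robertson factor), z the normal
   density at the threshold Φ⁻¹(1−k). The factor is π/2 at k = 0.5 and
   grows as k → 0, which is why rare-disease estimates are much noisier on
   the liability scale. The SE uses the same constant factor (delta
   method). The transform assumes near-normal phenotypes and small
   interaction effects; it degrades for large GxE at extreme prevalence.

The kurtosis fed to the fit is the sample fourth standardized moment of E
without small-sample correction (the theory is stated in population
moments). It affects only the intercept decomposition, not the slope, its
SE, or the Wald p-value.

## Synthetic data generator

The generator exists so every stage is testable end-to-end with no external
downloads; it emulates the study conditions the calibration experiments
assume.

- **Genotypes**: per SNP an allele frequency p_j ~ Uniform(0.01, 0.5) and
  dosages Binomial(2, p_j). Within blocks of `ld_block_size` SNPs (default
  50) the two allele draws per individual share a latent Gaussian factor
  with pairwise correlation `within_block_r` (default 0.3, Gaussian copula
  thresholded at p_j), so LD is block-exchangeable and decays to zero
  exactly at block boundaries. This replaces the real reference-panel LD of
  the original experiments with a structure whose LD scores are tunable and
  brute-force checkable; realized dosage correlations are attenuated below
  the latent correlation, increasingly so for mismatched allele
  frequencies. MAF spread within blocks is also what gives ℓ_j its
  variance, which the regression needs.
- **Environment**: standardized draw from normal, t (df = 8, kurtosis 4.5),
  uniform (kurtosis 1.8) or symmetric binary (kurtosis 1), optionally mixed
  with the standardized aggregate genetic value and/or stable residual to
  hit target G-E and R-E correlations (defaults 0; the null grids use 0.1),
  then re-standardized. Confounding is induced at the trait level, not
  per-SNP, matching how genotype-environment correlation is conceived in
  reaction-norm analyses.
- **Phenotype**: β0, β1 i.i.d. normal with total variances h²g0 (default
  0.3, typical of heritable complex traits) and h²g1; all SNPs causal by
  default (the causal fraction for the original simulations is not public;
  all-causal is the neutral choice for a polygenic-theory check);
  per-individual τ1 ~ N(0, h²τ1); τ0 fills the remaining budget; the sum is
  standardized to mean 0, variance 1 with all four components retained for
  diagnostics. Binary traits threshold the standardized liability at
  Φ⁻¹(1−k) — confounding and RxE act on the liability scale, before
  thresholding.

What the generator does **not** emulate: real LD (long-range decay, MAF-LD
coupling), ascertained case-control sampling, collider-driven participation
bias (that generative model is not public, and guessing one would test the
guess, not the method), relatedness, or population stratification. Passing
calibration here shows the estimator's algebra and its jackknife are sound
under block LD and trait-level confounding — not that real-cohort QC issues
are handled.

## Study conditions and problem sizes

The calibration suites run the eight continuous null scenarios (no GxE; RxE
variance 0 or 0.1 crossed with G-E and R-E correlations 0 or 0.1) and the
eight binary null cells (liability RxE 0 or 0.1 × prevalence 0.025, 0.05,
0.1, 0.5), with the pooled rejection rate at p < 0.05 compared to the
two-sided binomial 95% band for the replicate count used (the familiar
0.03/0.07 rule at 500 replicates). The packaged suites use n = 2500
individuals, m = 10000 SNPs and 100 replicates per scenario, with an
independent genotype panel per scenario: replicates sharing a panel are
positively correlated, so pooling across eight independent panels is what
keeps the binomial band an honest yardstick for the pooled rate. This is a
deliberate desk-scale rendition of the original design (one real cohort of
~7300 individuals, ~583k SNPs, 500 replicates);
parameter-recovery checks use n = 5000, m = 20000 and 50 replicates per
configuration with GxE variance 0.025 or 0.05 and RxE 0 or 0.1. At these
sizes the per-replicate slope SE is large relative to biobank practice, but
calibration and unbiasedness are scale-free properties of the pipeline.

## Numerical choices

- Standardization uses the sample SD with ddof = 1 throughout; correlations
  are therefore X'X/(n−1) on standardized columns.
- Monomorphic SNPs: resampled (bounded retries, preserving the block's
  shared factors) during simulation; a hard error in LD score estimation;
  dropped with a log entry in the scan when the interaction column is
  numerically constant (variance ≤ 1e−12).
- The two-step weight recomputation clips the slope at 0 and floors the
  predicted mean chi-square at 1e−3 inside weights only; point estimates
  are never clipped.
- Ties/degeneracy: LD scores with zero variance make the regression
  impossible and raise; jackknife SEs of an exactly homogeneous input are
  exactly 0, in which case the Wald p is defined as 1 for a zero estimate.
- Seeding: every stochastic stage takes a `numpy.random.Generator` or an
  integer seed; suite runs derive all replicates from one generator, so a
  single integer reproduces the whole experiment.

## Known limitations

- RxE recovered from the intercept is unreliable for binary traits
  (thresholding-induced scale effects) and under strong unmodeled
  heteroskedasticity; it is reported for diagnostics, unclamped.
- Main-effect heritability h²g0 is out of scope: in this model the
  pre-adjustment for E can over-adjust g0 under large G-E/R-E correlation,
  so main-effect estimates from interaction-model summary statistics need
  independent tooling.
- The jackknife treats SNP blocks as the unit of resampling; replicate-level
  noise shared across all SNPs (one realization of E and τ1 per dataset)
  loads mostly on the intercept, and empirically the slope SE tracks the
  between-replicate SD within ~5–10% at the packaged sizes, but this is an
  approximation inherited from the summary-statistic design.
- Per-SNP weighting beyond the adapted LDSC scheme (e.g. exact FWLS under
  the interaction model) was not pursued; the scheme is a documented
  convention, not a claimed optimum.
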