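# Methods

This note documents the statistical models implemented in `mivoom`, the
design choices made where the design was genuinely open, the synthetic-data
generator's calibration, and the numerical conventions. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## The estimation problem

The target of inference is, per gene g, the log₂ fold-change β_g in
expression per one-unit increase in an ordinal stress exposure (prenatal
stressful-life-event sum, 0–14, or maternal childhood-traumatic-event sum,
0–3), adjusted for an a-priori covariate set: confounders (race, ethnicity,
household income, household size, education, neighborhood deprivation),
precision variables (fetal sex, gravidity, delivery method, labor type,
site, maternal age, sequencing batch), and potential mediators
(pre-pregnancy BMI, tobacco, alcohol) which are included in the primary
model, dropped in the "no-mediators" variant; gestational age enters only
its own sensitivity variant. Effects are also reported as percent change,
(2^β − 1)·100%.

Exposure and expression are never imputed; samples missing the exposure are
excluded at the start of every analysis. Covariates, however, have
missingness (up to ~18% for the exposure itself and ~5% for several
covariates), and the three supported strategies differ exactly in how they
handle incomplete covariates.

## Precision-weighted moderated gene-wise models

Counts are filtered (biotype ∈ {protein_coding, processed_pseudogene,
lncRNA}; then mean log₂-CPM ≥ 0 across the analytic samples — the boundary
is retained since the removal rule is strictly-below), normalized by TMM,
and modelled on the log₂-CPM scale:

* log-CPM: log₂((y + 0.5) / (L·f + 1) · 10⁶) with library size L and TMM
  factor f. The pseudo-count 0.5 (and 2×0.5 on the library) is the standard
  smoothed-CPM convention; it is configurable.
* TMM: reference sample = the one whose 75th-percentile CPM is closest to
  the mean of those percentiles; per pair, M- and A-values of doubly
  positive genes are rank-trimmed (30% on M, 5% on A) and combined by an
  inverse-asymptotic-variance weighted mean; factors are rescaled to
  geometric mean 1. Fewer than two samples yields unit factors with a
  warning.
* Precision weights: per-gene OLS on the filtered log-CPM matrix gives
  residual SDs; sqrt(SD) is smoothed against average log₂ count by lowess
  (span 0.5, 4 robustness iterations — conventional defaults for this
  smoother); each observation's weight is the predicted sqrt-SD at its
  fitted log₂ count raised to the −4th power, with predictions clamped to
  the trend endpoints outside the fitted range.
* Per-gene weighted least squares with gene-specific weights is computed in
  a single batched pass (a genes × p × p normal-equation tensor via one
  GEMM), which keeps the many-imputations workload tractable.
* Moderation: gene variances are modelled as scaled-F around a prior
  (s₀², d₀) estimated by digamma/trigamma moment matching on log s²_g; the
  posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) enters the
  moderated t on d₀ + d_g degrees of freedom. Homoscedastic ensembles hit
  the d₀ = ∞ branch (full pooling) without error; d₀ = 0 recovers ordinary
  t-statistics. This implementation reproduces the reference R
  implementation's coefficients and moderated statistics to correlation
  ≥ 0.998 on shared data (the residual difference traces to lowess and
  pseudo-count details).
* Multiplicity: Benjamini–Hochberg step-up within each analysis; counts of
  genes at FDR < 0.05 and < 0.10 are logged per run.

Categorical covariates are dummy coded against their most frequent level;
exposure inference is invariant to that reference choice (asserted by a
test). Rank-deficient designs are rejected with the aliased columns named,
never silently repaired; the one sanctioned column drop is fetal sex inside
sex-stratified runs, where it is constant by construction.

## Gene-binned multiple imputation with Rubin pooling

Chained-equation imputation should condition on the outcome, but ~10⁴
outcome genes cannot all be predictors. The binned scheme:

1. Shuffle genes (seeded) into bins of `bin_size` (default 50; per-bin seeds
   are derived as a seed sequence of (base, bin index, imputation index) so
   results are independent of execution order).
2. Per bin, impute the covariates M times (default M = 10) by chained
   equations whose predictors are all other covariates, the exposure, and
   the bin's log-CPM rows. Continuous variables use predictive mean
   matching (bootstrap-refit linear model, 5 donors); binary variables a
   bootstrap-refit logistic draw; categoricals a multinomial logistic draw.
   The bootstrap refit supplies parameter uncertainty, making the
   imputations approximately proper. Default 10 iterations; variables are
   visited in increasing-missingness order; a variable with >50% missing
   and no informative predictors falls back to marginal draws with a
   warning.
3. Per completed dataset, the design, precision weights, and weighted fits
   are recomputed from scratch (weights are re-estimated per imputed
   dataset), and variance moderation is applied across all genes of that
   dataset. The squeezed variances enter the pooling ("moderate within,
   then pool"); the alternative order (pool raw, then squeeze the
   within-imputation component) is available via `moderation="pooled"` and
   compared in a test — the two give identical pooled estimates and highly
   concordant rankings.
4. The bin's genes are pooled by Rubin's rules: Q̄ = mean(β̂_m),
   Ū = mean(v_m), B = var(β̂_m), T = Ū + (1 + 1/M)B, with Barnard–Rubin
   degrees of freedom ν = (1/ν_old + 1/ν_obs)⁻¹, λ = (1+1/M)B/T,
   ν_old = (M−1)/λ², ν_obs = ((ν_com+1)/(ν_com+3))·ν_com·(1−λ), where ν_com
   is the moderated complete-data df (capped at 10⁹ for the d₀ = ∞ branch).
   B = 0 cleanly reduces to ν = ν_obs.
5. BH adjustment across all genes at the end.

When no covariate cell is missing the pipeline short-circuits: every
completed dataset equals the observed one, B = 0, and the pooled t equals
the direct pipeline's moderated t exactly — the reduction identity the
acceptance suite checks at |Δt| < 1e-8.

Identical completed covariate tables within a run are detected by hashing
and fitted once (a bounded cache), which makes low-missingness datasets
cheap without changing results.

## Sensitivity strategies

* Complete case: drop samples missing any design column, then the direct
  pipeline.
* Random-forest single imputation: missForest-style — initialize with
  marginal mean/mode, loop variables in increasing-missingness order
  fitting a random forest (default 100 trees) on the currently completed
  other covariates plus any fully observed exposure, and stop when the mean
  out-of-bag error increases or after 10 iterations. Single imputation
  treats imputed values as known, so its inference is slightly optimistic;
  it is a sensitivity analysis, and the enrichment stage consumes it only
  for its (rank-stable) gene statistics.
* Cross-method agreement is quantified as the Spearman correlation of
  per-gene p-value ranks (ties mid-ranked) over the shared gene universe.

## Ensemble gene-set enrichment

Five methods spanning the competitive/self-contained spectrum are computed
per set (moderated t converted to the z scale for the competitive tests):
hypergeometric over-representation of the set among the top-k genes by raw
p (k = 500 — deliberately not an FDR-gated list, which would be empty for
weak-signal exposures); a camera-style member-vs-rest mean comparison with
variance-inflation factor 1 + (m−1)ρ̄ (default ρ̄ = 0.01, configurable) on
G − 2 df; a Welch two-sample t (gage-style); and two sample-score
regressions (z-score column sums / √m, and PLAGE's leading right singular
vector with its sign fixed by positive correlation with mean member
expression), each regressed on the exposure within the full design. Sets
are restricted to the tested universe and bounded to [10, 500] members by
default.

Combination rule: the per-set method p-values are combined by Wilkinson's
minimum-p statistic (Beta(1, k)); Fisher's −2Σlog p (χ²₂ₖ) is available.
Wilkinson is the default because the five methods are positively dependent
(three of them act on the same member statistics) and Fisher's independence
reference is anti-conservative under that dependence, measurably violating
null calibration in simulation, while the minimum-p rule is conservative
under positive dependence. Direction is the unweighted mean member log2FC;
BH is applied within each collection. Sex-stratified runs execute the
ensemble independently per stratum and tabulate direction concordance for
sets reported in both.

## Synthetic cohort generator

The generator defines the validation conditions; its defaults are the
study's printed statistics and are not tuned per experiment.

* Covariate marginals: truncated normals (maternal age 27.884 ± 5.677 on
  [16, 43]; BMI 27.7 ± 7.5 on [14, 62]; deprivation 0.171 ± 0.802 on
  [−1.482, 2.804]), a truncated lognormal for income (mean 56,277,
  SD 43,074, range [2,493, 214,975]), a truncated Poisson(2.6) for
  gravidity, and the printed category frequencies for race, ethnicity,
  education, household size, labor type, delivery method and site. For all
  truncated laws the pre-truncation location is solved numerically so the
  post-truncation mean equals the printed value (tabulated statistics
  describe the observed, range-limited data). Gestational age
  (38.8 ± 2.2 weeks) and four equal sequencing batches are not tabulated in
  the source and carry conventional values.
* Exposures: the SLE sum follows a zero-inflated negative binomial
  truncated to [0, 14], solved once (scipy root finding, frozen in
  `_calibration.py`) to match mean 1.576, SD 1.861 and zero mass 0.379; the
  three CTE items are thresholded latent Gaussians at rates
  26.3% / 8% / 19% with a common latent correlation 0.5405 solved so that
  P(no item) = 0.637. A Gaussian copula correlation of 0.2626 between the
  SLE latent and each item latent was solved by large-sample simulation to
  reproduce Spearman ρ = 0.226 between the sums; the implied dual-exposure
  fraction (~26.6%) then falls out of the model rather than being fitted.
* Missingness: per-variable rates default to the study's table (SLE 17.9%,
  CTE 3.4%, income 5.3%, …). The default mechanism is MAR via a logistic
  model on fully observed columns (site, fetal sex), with the intercept
  calibrated per variable so the marginal masked fraction equals the
  requested rate exactly in expectation; MCAR is available, MNAR is out of
  scope. Missingness is injected after counts are generated, so a complete
  truth always exists.
* Counts: NB with mean cpm_g/10⁶ · L_s · 2^(Σβ·exposure + Σγ·covariate),
  log-normal library sizes (default mean 10⁶, CV 0.3 — a deliberately
  desk-scaled depth; cohort-scale 3×10⁷ is configurable), baseline log₂
  abundances from a truncated normal, and a decreasing mean–dispersion
  trend φ = 0.04 + 2/cpm with log-normal scatter (bulk-RNA-seq-like
  biological coefficients of variation; φ = 0 falls back to Poisson).
  Three designated genes carry SLE effects +0.07, −0.04, −0.03 log₂ per
  event by default; fetal sex affects a random 10% of genes and batch all
  genes weakly, so the design adjustment is exercised. The truth table
  records every generating parameter.

What the generator does not emulate: gene–gene co-expression networks
(genes are conditionally independent given the design), outcome-dependent
exposure (no reverse causation), confounding between exposure and
covariates, MNAR missingness, and count artifacts (GC/length bias,
duplicates). Passing tests therefore demonstrate correctness of the
estimators under the assumed model, not robustness to those violations.

## Validation design and problem sizes

The simulation-based checks run at deliberately reduced sizes, chosen once:

* Reduction identity: 2,000 genes × 600 samples, M = 5 — exact agreement
  (|Δt| < 1e-8) of MI/single-imputation/complete-case with the direct
  pipeline when nothing is missing.
* Null error control: 20 seeds at 500 genes × 600 samples, M = 3, 2
  chained-equation iterations, plus a 40-random-set enrichment ensemble per
  seed. The companion calibration evidence (bulk and extreme-tail p-value
  rates, and an oracle analysis on the same draws) is discussed with the
  test; note that "zero discoveries" per seed is a Simes-level event with
  ~5% probability under perfect calibration, so occasional non-clean seeds
  are expected behavior, not miscalibration.
* Parameter recovery: 25 replicate cohorts at n = 874 with standard
  missingness, 200 genes, M = 5, 3 iterations; the planted effects must be
  recovered with |mean bias| ≤ 0.015. A separate MAR scenario makes a
  covariate's missingness depend on the effect gene's observed expression;
  there complete-case selection is biased and MI (which uses expression as
  an imputation predictor — the method's raison d'être) must not be worse.
* Concordance: MI vs single imputation rank correlation > 0.9 on a
  600-sample fixture with standard missingness.

## Known limitations

* Within-bin imputation uses up to `bin_size` gene predictors; at small
  sample sizes large bins make the imputation models ill-posed — keep
  bin_size ≲ n/5.
* Rubin inference with very small M (2–3) is approximate in the far tail;
  the method default is M = 10.
* The camera inter-gene correlation is a fixed scalar, not estimated from
  residuals.
* The enrichment ensemble's combined p-value is a ranking device; its
  absolute scale depends on the inter-method dependence and is controlled
  for error only through the conservative minimum-p rule.
* No random-effects/duplicate-correlation modelling, surrogate-variable
  adjustment, or gene-length normalization.
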