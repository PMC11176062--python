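# mivoom

Differential expression of bulk RNA-seq counts against ordinal exposures when
model covariates are incompletely observed.

The motivating setting is a pregnancy-cohort study of placental gene
expression and maternal psychosocial stress: each participant carries a
prenatal stressful-life-event sum (SLE, 0–14) and a maternal
childhood-traumatic-event sum (CTE, 0–3), and the regression adjusts for a
sizeable a-priori covariate set (sociodemographics, obstetric factors, site
and batch), many columns of which have missing values. Dropping incomplete
samples wastes data and can bias estimates; imputing covariates properly
requires the outcome — but with ~14,000 outcome genes the usual chained
equations cannot include them all.

`mivoom` implements the gene-binning resolution of that impasse, plus the
surrounding pipeline:

* **Gene-binned multiple imputation** (primary method): genes are shuffled
  into bins; within each bin, chained equations (predictive mean matching /
  logistic / multinomial draws) impute the covariates using the exposure, the
  other covariates, and the bin's log-CPM values as predictors; each
  completed dataset is analysed with precision-weighted gene-wise linear
  models and empirical-Bayes variance moderation; per-gene estimates are
  pooled by Rubin's rules

      Q̄ = mean(β̂ₘ),  T = Ū + (1 + 1/M)·B,  t = Q̄/√T

  on Barnard–Rubin adjusted degrees of freedom.
* **Precision-weighted moderated models**: log₂-CPM values with TMM
  library-size factors, observation weights from a lowess mean–variance
  trend (weight = predicted sqrt-SD⁻⁴), weighted least squares per gene,
  and gene-variance shrinkage toward a scaled-F prior
  (s̃²ᵍ = (d₀s₀² + dᵍs²ᵍ)/(d₀ + dᵍ)), with BH FDR control. Effects are
  reported as log₂ fold-change per one-unit exposure and as percent change
  (2^log2FC − 1)·100%.
* **Sensitivity strategies**: complete-case analysis and iterative
  random-forest single imputation, plus a p-value rank-concordance
  comparison across the three strategies.
* **Ensemble gene-set enrichment**: ORA, camera, gage-style Welch tests,
  z-score and PLAGE sample-score tests over GMT collections, combined
  per set (Wilkinson by default, Fisher available), with directionality and
  sex-stratified runs.
* **A calibrated synthetic cohort generator** reproducing the study's
  printed covariate marginals, exposure distributions (zero-inflated
  negative-binomial SLE sum; correlated Bernoulli CTE items via a Gaussian
  copula, Spearman ρ ≈ 0.226), per-variable missingness rates, and
  negative-binomial counts with planted per-event log2 fold-changes —
  with a truth table for recovery testing.

## Worked example

```python
import mivoom as mv

# a synthetic cohort at the study's conditions, with standard missingness
complete, observed = mv.simulate_cohort(600, seed=11)
counts, truth = mv.simulate_counts(complete, n_genes=2000, seed=12)

spec = mv.DesignSpec(exposure="sle_sum")           # primary covariate set
model = mv.MIDifferentialExpressionModel(
    counts, observed, spec, m_imputations=5, bin_size=50
)
result = model.fit(seed=1)
print(result.summary(top=3))
```

```
Multiple-imputation pooled differential expression: coefficient 'sle_sum'
  genes: 1956   samples: 487   M: 5   bin size: 50
  FDR<0.05: 0   FDR<0.10: 0

          log2FC  percent_change      t    nu         p      q
gene_id
G01210  -0.05153          -3.509 -3.385   543 0.0007621 0.8438
G00000   0.08603           6.144  3.293 539.6  0.001055 0.8438
G01450   0.07366           5.239  3.234 540.5  0.001294 0.8438
```

487 of the 600 samples have the exposure observed and enter the analysis;
1,956 of 2,000 genes survive the biotype and expression filters. `G00000` is
the designated +0.07-log2FC-per-event gene from the simulation truth: its
pooled estimate here is 0.086 log₂ units per stressful life event (≈6.1%
higher expression per event; the per-gene standard error at this sample size
is ≈0.026, so this draw sits within one SE of truth). No gene clears
FDR < 0.05 — expected for per-event effects of this size at n ≈ 500, and the
reason the acceptance checks measure recovery as mean bias across replicate
cohorts rather than per-run significance. Comparing strategies:

```python
si = mv.SingleImputationDEModel(counts, observed, spec).fit(seed=2)
print(round(mv.rank_concordance(result, si), 3))   # prints: 0.996
```

## Command-line pipeline

```bash
mivoom simulate --config config.yaml          # fixture + manifest checksums
mivoom analyze  --config config.yaml          # interaction screen, MI variants,
                                              # CC/SI sensitivity, concordance
mivoom enrich   --config config.yaml          # ensemble + sex-stratified GSEA
mivoom report   --config config.yaml          # consolidated report
```

All stage outputs are plain TSV/JSON stamped with the config hash; identical
config + seed reproduce byte-identical tables.

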