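"""Frozen numerical calibration constants for the synthetic cohort generator.

The exposure marginals are calibrated once, offline, against the printed cohort
statistics and then frozen here so that every run of the generator reproduces
the same study conditions:

* The stressful-life-event (SLE) sum is a zero-inflated negative binomial
  truncated to 0-14, solved (scipy.optimize.fsolve on the truncated pmf) to
  match mean 1.576, SD 1.861 and a zero mass of 0.379.
* The three childhood-traumatic-event (CTE) items are thresholded latent
  Gaussians with a common item-item correlation solved so that the probability
  of reporting no item is 0.637.
* The SLE-CTE dependence is a Gaussian copula correlation between the SLE
  latent and each item latent, solved by large-sample simulation so that the
  Spearman rank correlation of the two sums is 0.226.

Re-deriving these numbers is a few lines of scipy root finding; they are kept
frozen so the generator is a pure function of (params, seed).
"""

# Zero-inflated negative binomial for the SLE sum (before truncation to 0-14).
SLE_ZINB_PI0 = 0.14913134316373983
SLE_ZINB_MU = 1.8544782965200926
SLE_ZINB_SIZE = 1.981771556102932
SLE_MAX = 14

# Marginal item rates: witnessed family violence, physical abuse, sexual abuse.
CTE_ITEM_RATES = (0.263, 0.08, 0.19)
CTE_ITEM_NAMES = ("cte_witness", "cte_physical", "cte_sexual")

# Common latent correlation between CTE items (exchangeable).
CTE_ITEM_LATENT_CORR = 0.5404773709234181

# Default copula correlation between the SLE latent and each CTE item latent.
SLE_CTE_LATENT_CORR = 0.2625862650384521
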