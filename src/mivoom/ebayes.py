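"""Empirical-Bayes variance moderation, BH adjustment, effect-size transform.

Gene-wise residual variances are modelled as scaled F draws around a global
prior (s2_0, d0); the hyperparameters are estimated by moment matching of
log s2_g (digamma/trigamma inversion), each gene's variance is squeezed to

    s2_tilde = (d0 * s2_0 + d_g * s2_g) / (d0 + d_g),

and the moderated t-statistic t = beta / sqrt(s2_tilde * v) is referred to a
t distribution on d0 + d_g degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .voom import GeneFit

__all__ = [
    "ModeratedResult",
    "fit_f_dist",
    "squeeze_var",
    "ebayes_moderate",
    "bh_adjust",
    "percent_change",
]


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / np.maximum(y, 1e-12) < 1e-10):
            break
    return y


def fit_f_dist(s2: np.ndarray, df: float | np.ndarray) -> tuple[float, float]:
    """Estimate (d0, s2_0) of the scaled-F model for gene variances.

    Returns d0 = inf when the observed log-variances are no more dispersed
    than sampling noise alone (all shrink fully to the prior).
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("need at least 10 genes to estimate the variance prior")
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if not ok.all():
        s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
        s2_0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s2_0 = float(np.exp(emean))
    return d0, s2_0


def squeeze_var(s2: np.ndarray, df: float | np.ndarray, d0: float | None = None, s2_0: float | None = None):
    """Posterior (squeezed) variances; estimates the prior unless supplied."""
    s2 = np.asarray(s2, dtype=float)
    if d0 is None or s2_0 is None:
        d0, s2_0 = fit_f_dist(s2, df)
    if np.isinf(d0):
        post = np.full_like(s2, s2_0)
    elif d0 == 0:
        post = s2.copy()
    else:
        post = (d0 * s2_0 + df * s2) / (d0 + df)
    return post, d0, s2_0


@dataclass
class ModeratedResult:
    """Per-gene moderated inference for one exposure coefficient.

    ``table`` columns: log2FC, percent_change, t, p, q, mean_logcpm.
    """

    table: pd.DataFrame
    d0: float
    s2_0: float
    coefficient: str
    df_total: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_significant_05(self) -> int:
        return int((self.table["q"] < 0.05).sum())

    @property
    def n_significant_10(self) -> int:
        return int((self.table["q"] < 0.10).sum())

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p")
        lines = [
            f"Moderated differential expression: coefficient {self.coefficient!r}",
            f"  genes tested: {len(t)}   prior df: {self.d0:.3g}   prior variance: {self.s2_0:.4g}",
            f"  FDR<0.05: {self.n_significant_05}   FDR<0.10: {self.n_significant_10}",
            "",
            t.head(top).to_string(
                float_format=lambda v: f"{v:.4g}",
                columns=["log2FC", "percent_change", "t", "p", "q"],
            ),
        ]
        return "\n".join(lines)


def ebayes_moderate(
    fits: GeneFit,
    coefficient: str,
    d0_override: float | None = None,
) -> ModeratedResult:
    """Moderate a gene-fit collection and test one coefficient.

    ``d0_override`` forces the prior df (0 recovers ordinary t-statistics,
    inf full pooling); by default the prior is estimated from the ensemble.
    """
    j = fits.column(coefficient)
    beta = fits.coefficients[:, j]
    v = fits.cov_unscaled_diag[:, j]
    if d0_override is None:
        post, d0, s2_0 = squeeze_var(fits.s2, fits.df)
    else:
        _, _, s2_0 = squeeze_var(fits.s2, fits.df)
        d0 = d0_override
        if np.isinf(d0):
            post = np.full_like(fits.s2, s2_0)
        elif d0 == 0:
            post = fits.s2.copy()
        else:
            post = (d0 * s2_0 + fits.df * fits.s2) / (d0 + fits.df)
    df_total = d0 + fits.df if np.isfinite(d0) else np.inf
    se = np.sqrt(post * v)
    t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2FC": beta,
            "percent_change": percent_change(beta),
            "t": t,
            "p": p,
            "q": q,
            "mean_logcpm": fits.mean_logcpm,
            "s2_post": post,
        },
        index=fits.gene_ids,
    )
    return ModeratedResult(
        table=table, d0=float(d0), s2_0=float(s2_0), coefficient=coefficient,
        df_total=float(df_total) if np.isfinite(df_total) else np.inf,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values passed to BH adjustment")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def percent_change(log2fc) -> np.ndarray | float:
    """Percent expression change per unit exposure: (2**log2fc - 1) * 100."""
    arr = np.asarray(log2fc, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite log2 fold-change")
    out = (2.0**arr - 1.0) * 100.0
    return float(out) if np.isscalar(log2fc) or arr.ndim == 0 else out
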