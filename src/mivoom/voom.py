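"""Precision weights from the mean-variance trend, and weighted gene-wise fits.

Count data on the log-CPM scale are heteroscedastic: low counts are noisier.
The remedy implemented here fits each gene by ordinary least squares, smooths
sqrt(residual SD) against average log2 count with robust lowess, predicts the
sqrt-SD at every observation's fitted log2 count, and uses the inverse fourth
power as an observation-level weight in a per-gene weighted least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .counts import CountMatrix
from .preprocess import NormFactors, log_cpm

__all__ = ["VoomObject", "GeneFit", "estimate_precision_weights", "fit_weighted"]


@dataclass
class VoomObject:
    """Log-CPM matrix E, observation weights W (same shape), design X, and the
    fitted sqrt-SD trend (as interpolation knots)."""

    E: np.ndarray
    weights: np.ndarray
    design: pd.DataFrame
    trend_x: np.ndarray
    trend_y: np.ndarray
    gene_ids: pd.Index
    mean_logcpm: np.ndarray

    def __post_init__(self):
        if self.E.shape != self.weights.shape:
            raise ValueError("E and weights shape mismatch")
        if not np.all(np.isfinite(self.weights)) or (self.weights <= 0).any():
            raise ValueError("weights must be positive and finite")


@dataclass
class GeneFit:
    """Per-gene weighted least-squares summaries.

    ``coefficients``: genes x p; ``cov_unscaled_diag``: genes x p diagonal of
    (X'WX)^-1; ``s2``: residual variance; ``df``: residual degrees of freedom
    (n - rank(X), shared across genes).
    """

    coefficients: np.ndarray
    cov_unscaled_diag: np.ndarray
    s2: np.ndarray
    df: float
    design_columns: pd.Index
    gene_ids: pd.Index
    mean_logcpm: np.ndarray

    def column(self, name: str) -> int:
        loc = self.design_columns.get_loc(name)
        return int(loc)


def _batched_wls(E: np.ndarray, W: np.ndarray, X: np.ndarray):
    """Per-gene WLS with gene-specific weights, vectorized.

    Returns (beta, cov_diag, rss) with beta genes x p and cov_diag the
    diagonal of (X'WX)^-1 per gene.
    """
    n, p = X.shape
    K = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    A = (W @ K).reshape(-1, p, p)          # genes x p x p = X' W_g X
    b = np.einsum("gs,sp->gp", W * E, X)   # genes x p    = X' W_g y
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    Ainv = np.linalg.inv(A)
    cov_diag = np.einsum("gpp->gp", Ainv)
    rss = np.einsum("gs,gs->g", W, E**2) - np.einsum("gp,gp->g", beta, b)
    return beta, cov_diag, np.maximum(rss, 0.0)


def estimate_precision_weights(
    counts: CountMatrix,
    design: pd.DataFrame,
    norm_factors: NormFactors | None = None,
    span: float = 0.5,
    prior: float = 0.5,
    iterations: int = 4,
) -> VoomObject:
    """Compute log-CPM values and per-observation precision weights."""
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if counts.n_samples != n:
        raise ValueError("design rows do not match sample count")
    rank = np.linalg.matrix_rank(X)
    if n - rank < 2:
        raise ValueError("fewer than 2 residual degrees of freedom")

    lib = counts.lib_size
    if norm_factors is not None:
        lib = lib * norm_factors.factors
    E = log_cpm(counts.counts, prior=prior, lib_size=lib)

    # ordinary per-gene fit for the trend
    pinv = np.linalg.pinv(X)
    beta = E @ pinv.T
    resid = E - beta @ X.T
    df = n - rank
    sigma = np.sqrt((resid**2).sum(axis=1) / df)

    # abundance on the log2-count scale
    log2_lib = np.log2(lib + 2.0 * prior)
    mean_logcpm = E.mean(axis=1)
    avg_logcount = mean_logcpm + log2_lib.mean() - np.log2(1e6)

    sqrt_sd = np.sqrt(sigma)
    lo = sm.nonparametric.lowess(
        sqrt_sd, avg_logcount, frac=span, it=iterations, return_sorted=True
    )
    trend_x, trend_y = lo[:, 0], lo[:, 1]
    trend_y = np.maximum(trend_y, 1e-6)

    # predicted sqrt-SD at each observation's fitted log2 count
    fitted_logcount = beta @ X.T + (log2_lib - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, trend_x, trend_y)  # clamped at endpoints
    weights = pred**-4.0

    return VoomObject(
        E=E,
        weights=weights,
        design=design,
        trend_x=trend_x,
        trend_y=trend_y,
        gene_ids=counts.gene_ids,
        mean_logcpm=mean_logcpm,
    )


def fit_weighted(voom: VoomObject) -> GeneFit:
    """Per-gene weighted least squares on the voom object."""
    X = voom.design.to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    df = n - rank
    if df < 1:
        raise ValueError("zero residual degrees of freedom")
    beta, cov_diag, rss = _batched_wls(voom.E, voom.weights, X)
    s2 = rss / df
    return GeneFit(
        coefficients=beta,
        cov_unscaled_diag=cov_diag,
        s2=s2,
        df=float(df),
        design_columns=voom.design.columns,
        gene_ids=voom.gene_ids,
        mean_logcpm=voom.mean_logcpm,
    )
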