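"""Gene filtering, log-CPM, and TMM library-size normalization.

The filtering rules mirror the standard bulk RNA-seq pipeline: keep only
protein-coding genes, processed pseudogenes and lncRNAs; drop genes whose
average log2 counts-per-million across the analysis samples is below 0
(genes exactly at the threshold are retained). Normalization factors are the
weighted trimmed mean of M-values (TMM) against an upper-quartile-matched
reference sample, rescaled to geometric mean 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountMatrix

__all__ = [
    "DEFAULT_BIOTYPES",
    "NormFactors",
    "filter_by_biotype",
    "log_cpm",
    "filter_low_expression",
    "tmm_factors",
]

log = logging.getLogger(__name__)

DEFAULT_BIOTYPES = frozenset({"protein_coding", "processed_pseudogene", "lncRNA"})


@dataclass
class NormFactors:
    """Per-sample positive scale factors with geometric mean 1."""

    factors: np.ndarray
    reference: int

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        logf = np.log(self.factors)
        if abs(logf.mean()) > 1e-12:
            raise ValueError("normalization factors must have geometric mean 1")


def filter_by_biotype(
    counts: CountMatrix,
    annotation: pd.Series | None = None,
    allowed=DEFAULT_BIOTYPES,
) -> CountMatrix:
    """Keep genes whose biotype is in ``allowed``; drop unannotated genes.

    ``annotation`` defaults to the biotype column carried by the count matrix.
    """
    allowed = frozenset(allowed)
    if not allowed:
        raise ValueError("empty set of allowed biotypes")
    if annotation is None:
        annotation = counts.biotype
    if annotation is None:
        raise ValueError("no biotype annotation available")
    biotype = pd.Series(annotation).reindex(counts.gene_ids)
    unannotated = int(biotype.isna().sum())
    if unannotated:
        log.info("dropping %d unannotated genes", unannotated)
    keep = biotype.isin(allowed).to_numpy()
    if not keep.any():
        raise ValueError("biotype filter removed every gene")
    return counts.subset_genes(keep)


def log_cpm(
    counts: CountMatrix | np.ndarray,
    norm_factors: NormFactors | np.ndarray | None = None,
    prior: float = 0.5,
    lib_size: np.ndarray | None = None,
) -> np.ndarray:
    """Smoothed log2 counts-per-million.

    value = log2( (count + prior) / (effective_libsize + 2*prior) * 1e6 ),
    with effective library size = library size times the TMM factor when
    factors are supplied.
    """
    if prior <= 0:
        raise ValueError("prior count must be positive")
    if isinstance(counts, CountMatrix):
        mat = counts.counts
        lib = counts.lib_size if lib_size is None else np.asarray(lib_size, float)
    else:
        mat = np.asarray(counts)
        lib = np.asarray(lib_size, float) if lib_size is not None else mat.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero or negative library size")
    if norm_factors is not None:
        f = norm_factors.factors if isinstance(norm_factors, NormFactors) else np.asarray(norm_factors, float)
        lib = lib * f
    return np.log2((mat + prior) / (lib + 2.0 * prior) * 1e6)


def filter_low_expression(logcpm: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Boolean mask of genes whose mean log-CPM across samples is >= threshold.

    The boundary (mean exactly at the threshold) is retained: the removal rule
    is strictly-below.
    """
    mean = np.asarray(logcpm).mean(axis=1)
    return mean >= threshold


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m: float, trim_a: float) -> float:
    """Single-pair TMM factor on the log2 scale (edgeR-style doubly trimmed,
    inverse-asymptotic-variance weighted mean of M-values)."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        return 0.0
    po, pr = obs / n_obs, ref / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, obs, ref = m[fin], a[fin], obs[fin], ref[fin]
    n = m.size
    if n == 0:
        return 0.0
    if np.abs(m).max() < 1e-6:
        return 0.0
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    # delta-method variance of M: (N-y)/(N*y) summed over the two samples
    var = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])
    w = 1.0 / var
    return float(np.sum(w * m[keep]) / np.sum(w))


def tmm_factors(
    counts: CountMatrix | np.ndarray,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    lib_size: np.ndarray | None = None,
) -> NormFactors:
    """Weighted trimmed mean of M-values normalization factors.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean of those percentiles. With fewer than two samples all factors
    are 1 (with a warning).
    """
    if isinstance(counts, CountMatrix):
        mat = counts.counts
        lib = counts.lib_size if lib_size is None else np.asarray(lib_size, float)
    else:
        mat = np.asarray(counts)
        lib = np.asarray(lib_size, float) if lib_size is not None else mat.sum(axis=0).astype(float)
    n_samples = mat.shape[1]
    if n_samples < 2:
        warnings.warn("fewer than 2 samples: all TMM factors set to 1")
        return NormFactors(np.ones(n_samples), reference=0)
    if (lib <= 0).any():
        raise ValueError("zero or negative library size")

    q75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    logf = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref], lib[j], lib[ref], trim_m, trim_a)
            for j in range(n_samples)
        ]
    )
    logf -= logf.mean()  # geometric mean 1 on the natural scale
    return NormFactors(2.0 ** logf, reference=ref)
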