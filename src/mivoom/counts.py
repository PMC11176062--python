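"""Negative-binomial RNA-seq count simulation with planted exposure effects.

Counts for gene g in sample s are drawn NB with mean

    mu_gs = cpm_g / 1e6 * L_s * 2^( sum_e beta_ge * exposure_es
                                    + sum_c gamma_gc * covariate_cs )

where cpm_g = 2^baseline is the gene's nominal relative abundance, L_s the
sample's library size, and the gene-wise dispersion follows a decreasing
mean-dispersion trend (large-count genes are closer to Poisson) with
log-normal scatter around it, as observed in bulk RNA-seq.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "CountMatrix",
    "SimulationTruth",
    "make_truth",
    "gen_counts",
    "simulate_counts",
    "DEFAULT_SLE_EFFECTS",
    "BIOTYPES",
]

#: Planted log2 fold-changes per SLE event for the three designated genes.
DEFAULT_SLE_EFFECTS = (0.07, -0.04, -0.03)

BIOTYPES = ("protein_coding", "lncRNA", "processed_pseudogene", "rRNA", "misc_RNA")
_BIOTYPE_PROBS = (0.86, 0.08, 0.04, 0.01, 0.01)


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with annotation."""

    counts: np.ndarray
    gene_ids: pd.Index
    sample_ids: pd.Index
    biotype: pd.Series | None = None
    lib_size: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        self.gene_ids = pd.Index(self.gene_ids)
        self.sample_ids = pd.Index(self.sample_ids)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.lib_size is None:
            self.lib_size = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_size = np.asarray(self.lib_size, dtype=float)
            if len(self.lib_size) != len(self.sample_ids):
                raise ValueError("lib_size length mismatch")
        if self.biotype is not None:
            self.biotype = pd.Series(self.biotype).reindex(self.gene_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.gene_ids.get_indexer(keep)
            if (idx < 0).any():
                raise KeyError("unknown gene ids in subset")
        bt = self.biotype.iloc[idx] if self.biotype is not None else None
        return CountMatrix(
            self.counts[idx], self.gene_ids[idx], self.sample_ids, bt, self.lib_size
        )

    def subset_samples(self, keep) -> "CountMatrix":
        idx = self.sample_ids.get_indexer(pd.Index(keep))
        if (idx < 0).any():
            raise KeyError("unknown sample ids in subset")
        return CountMatrix(
            self.counts[:, idx],
            self.gene_ids,
            self.sample_ids[idx],
            self.biotype,
            None,  # library sizes recomputed from the subset columns
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SimulationTruth:
    """Per-gene generating parameters and the generator configuration.

    ``table`` is indexed by gene id with columns ``baseline_log2cpm``,
    ``dispersion``, ``beta_sle``, ``beta_cte`` and ``biotype``; null genes
    carry exactly 0 effect.
    """

    table: pd.DataFrame
    params: dict = field(default_factory=dict)
    covariate_effects: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def effect_genes(self) -> pd.Index:
        t = self.table
        return t.index[(t["beta_sle"] != 0.0) | (t["beta_cte"] != 0.0)]

    def to_json(self) -> str:
        payload = {
            "table": {
                col: self.table[col].tolist() for col in self.table.columns
            },
            "gene_ids": self.table.index.tolist(),
            "params": self.params,
            "covariate_effects": {
                k: np.asarray(v).tolist() for k, v in self.covariate_effects.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        payload = json.loads(text)
        table = pd.DataFrame(
            payload["table"], index=pd.Index(payload["gene_ids"], name="gene_id")
        )
        cov = {k: np.asarray(v) for k, v in payload.get("covariate_effects", {}).items()}
        return cls(table=table, params=payload.get("params", {}), covariate_effects=cov)


def make_truth(
    n_genes: int = 2000,
    sle_effects: tuple[float, ...] = DEFAULT_SLE_EFFECTS,
    cte_effects: tuple[float, ...] = (),
    seed: int = 0,
    baseline_mean: float = 3.5,
    baseline_sd: float = 1.8,
    dispersion_asymptote: float = 0.04,
    dispersion_slope: float = 2.0,
    dispersion_scatter: float = 0.2,
    sex_effect_fraction: float = 0.1,
    sex_effect_sd: float = 0.15,
    batch_effect_sd: float = 0.08,
) -> SimulationTruth:
    """Draw per-gene baselines, dispersions, and planted effects.

    The first ``len(sle_effects)`` genes carry the SLE effects (and the next
    ``len(cte_effects)`` genes the CTE effects); they are forced to
    protein-coding biotype and comfortable expression so that they survive the
    standard filters. All remaining genes are exactly null.
    """
    n_effect = len(sle_effects) + len(cte_effects)
    if n_genes < n_effect:
        raise ValueError(
            f"n_genes={n_genes} smaller than number of designated effect genes {n_effect}"
        )
    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")

    lo, hi = 0.5, 11.0
    u = rng.random(n_genes)
    from scipy import stats as _st

    a, b = (lo - baseline_mean) / baseline_sd, (hi - baseline_mean) / baseline_sd
    baseline = _st.truncnorm.ppf(u, a, b, loc=baseline_mean, scale=baseline_sd)

    cpm = 2.0 ** baseline
    trend = dispersion_asymptote + dispersion_slope / cpm
    dispersion = trend * np.exp(rng.normal(0.0, dispersion_scatter, n_genes))

    beta_sle = np.zeros(n_genes)
    beta_cte = np.zeros(n_genes)
    beta_sle[: len(sle_effects)] = sle_effects
    beta_cte[len(sle_effects) : n_effect] = cte_effects

    biotype = np.asarray(BIOTYPES, dtype=object)[
        rng.choice(len(BIOTYPES), size=n_genes, p=_BIOTYPE_PROBS)
    ]
    biotype[:n_effect] = "protein_coding"
    baseline[:n_effect] = np.maximum(baseline[:n_effect], 4.0)

    sex_mask = rng.random(n_genes) < sex_effect_fraction
    gamma_sex = np.where(sex_mask, rng.normal(0.0, sex_effect_sd, n_genes), 0.0)
    gamma_batch = rng.normal(0.0, batch_effect_sd, (n_genes, 4))

    table = pd.DataFrame(
        {
            "baseline_log2cpm": baseline,
            "dispersion": dispersion,
            "beta_sle": beta_sle,
            "beta_cte": beta_cte,
            "biotype": biotype,
        },
        index=gene_ids,
    )
    params = {
        "n_genes": n_genes,
        "seed": seed,
        "sle_effects": list(sle_effects),
        "cte_effects": list(cte_effects),
        "dispersion_asymptote": dispersion_asymptote,
        "dispersion_slope": dispersion_slope,
    }
    return SimulationTruth(
        table=table,
        params=params,
        covariate_effects={"fetal_sex": gamma_sex, "batch": gamma_batch},
    )


def gen_counts(
    cohort: CohortTable,
    truth: SimulationTruth,
    lib_size_mean: float = 1e6,
    lib_size_cv: float = 0.3,
    seed: int = 0,
) -> CountMatrix:
    """Draw NB counts for every (gene, sample) given a complete cohort.

    Exposure columns must be fully observed in ``cohort`` (generate counts
    before injecting missingness). ``dispersion == 0`` genes fall back to
    Poisson sampling.
    """
    if lib_size_mean <= 0:
        raise ValueError("library size mean must be positive")
    df = cohort.data
    for col in ("sle_sum", "cte_sum"):
        if col not in df or df[col].isna().any():
            raise ValueError(
                f"gen_counts requires fully observed exposure column {col!r}; "
                "inject missingness after generating counts"
            )

    rng = np.random.default_rng(seed)
    t = truth.table
    n_genes, n = len(t), len(df)

    sigma = np.sqrt(np.log1p(lib_size_cv**2))
    lib = lib_size_mean * np.exp(rng.normal(-sigma**2 / 2, sigma, n))
    if (lib <= 0).any():
        raise ValueError("non-positive library size drawn")

    log2fc = np.outer(t["beta_sle"].to_numpy(), df["sle_sum"].to_numpy())
    log2fc += np.outer(t["beta_cte"].to_numpy(), df["cte_sum"].to_numpy())
    gamma_sex = truth.covariate_effects.get("fetal_sex")
    if gamma_sex is not None and "fetal_sex" in df:
        log2fc += np.outer(gamma_sex, df["fetal_sex"].to_numpy(dtype=float))
    gamma_batch = truth.covariate_effects.get("batch")
    if gamma_batch is not None and "batch" in df:
        levels = sorted(df["batch"].dropna().unique().tolist())
        codes = df["batch"].map({lv: i for i, lv in enumerate(levels)}).to_numpy()
        log2fc += np.asarray(gamma_batch)[:, codes]

    cpm = 2.0 ** t["baseline_log2cpm"].to_numpy()
    mu = (cpm[:, None] / 1e6) * lib[None, :] * 2.0**log2fc

    phi = t["dispersion"].to_numpy()
    counts = np.empty((n_genes, n), dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        size = 1.0 / phi[~pois]
        p = size[:, None] / (size[:, None] + mu[~pois])
        counts[~pois] = rng.negative_binomial(size[:, None], p)

    biotype = pd.Series(t["biotype"].to_numpy(), index=t.index, name="biotype")
    return CountMatrix(
        counts=counts,
        gene_ids=t.index,
        sample_ids=df.index,
        biotype=biotype,
        lib_size=None,
    )


def simulate_counts(
    cohort: CohortTable,
    n_genes: int = 2000,
    lib_size_mean: float = 1e6,
    seed: int = 0,
    **truth_kwargs,
) -> tuple[CountMatrix, SimulationTruth]:
    """Convenience wrapper: draw a truth table, then counts under it."""
    truth = make_truth(n_genes=n_genes, seed=seed, **truth_kwargs)
    counts = gen_counts(cohort, truth, lib_size_mean=lib_size_mean, seed=seed + 1)
    return counts, truth
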