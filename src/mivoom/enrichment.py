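"""Ensemble gene-set enrichment over GMT collections.

Five base methods span the competitive/self-contained spectrum:

* ``ora``      over-representation of a set among the top-k genes by raw p
               (hypergeometric upper tail);
* ``camera``   competitive mean comparison of member vs non-member gene
               statistics with a variance-inflation factor for inter-gene
               correlation;
* ``gage``     unequal-variance two-sample t of member vs non-member stats;
* ``zscore``   per-sample set score = standardized member column sum / sqrt(m),
               regressed on the exposure within the full design;
* ``plage``    per-sample score = leading right singular vector of the
               standardized member submatrix, same regression.

Per-set method p-values are combined (Fisher or Wilkinson), BH-adjusted
within the collection, and annotated with a direction (mean member log2FC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .counts import CountMatrix
from .design import DesignSpec
from .ebayes import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora",
    "camera_test",
    "score_based_tests",
    "gage_like",
    "combine_pvalues",
    "ensemble_run",
    "stratified_enrichment",
    "DEFAULT_METHODS",
]

log = logging.getLogger(__name__)

DEFAULT_METHODS = ("ora", "camera", "zscore", "plage", "gage")


@dataclass
class GeneSetCollection:
    """Named gene sets; ``restrict`` intersects with a tested-gene universe."""

    name: str
    sets: dict[str, frozenset] = field(default_factory=dict)

    def restrict(self, universe, min_size: int = 1, max_size: int | None = None) -> "GeneSetCollection":
        universe = frozenset(universe)
        kept = {}
        for set_name, members in self.sets.items():
            inter = members & universe
            if len(inter) < min_size or (max_size is not None and len(inter) > max_size):
                log.info("dropping set %s (size %d after intersection)", set_name, len(inter))
                continue
            kept[set_name] = inter
        return GeneSetCollection(name=self.name, sets=kept)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB member...), deduplicating
    members and rejecting malformed or empty lines with line numbers."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name = fields[0]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = members
    import os

    return GeneSetCollection(name=os.path.splitext(os.path.basename(str(path)))[0], sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def ora(pvalues: pd.Series, members, universe, top_k: int = 500) -> float:
    """Hypergeometric upper-tail p for over-representation of ``members``
    among the ``top_k`` smallest raw p-values within ``universe``."""
    universe = pd.Index(universe)
    G = len(universe)
    if len(frozenset(members)) > G:
        raise ValueError("gene set larger than the universe")
    members = frozenset(members) & frozenset(universe)
    k = min(top_k, G)
    top = pvalues.loc[universe].nsmallest(k).index
    overlap = len(members & frozenset(top))
    return float(stats.hypergeom.sf(overlap - 1, G, len(members), k))


def camera_test(gene_stats: pd.Series, members, intergene_correlation: float = 0.01):
    """Competitive member-vs-rest mean comparison on z-scale statistics with a
    variance-inflation factor 1 + (m-1)*rho applied to the member term.

    Returns (two-sided p, direction sign of the mean difference).
    """
    z = gene_stats.to_numpy(dtype=float)
    idx = gene_stats.index.isin(frozenset(members))
    m = int(idx.sum())
    G = len(z)
    if m < 2:
        raise ValueError("camera needs at least 2 set members in the universe")
    if G - m < 2:
        raise ValueError("camera needs at least 2 non-member genes")
    vif = 1.0 + (m - 1) * intergene_correlation
    mean_in, mean_out = z[idx].mean(), z[~idx].mean()
    df = G - 2
    # pooled residual variance of the two-group comparison
    s2 = ((z[idx] - mean_in) ** 2).sum() + ((z[~idx] - mean_out) ** 2).sum()
    s2 /= df
    var = s2 * (vif / m + 1.0 / (G - m))
    if var <= 0:
        return 1.0, 0.0
    t = (mean_in - mean_out) / np.sqrt(var)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(p), float(np.sign(mean_in - mean_out))


def gage_like(gene_stats: pd.Series, members) -> float:
    """Unequal-variance (Welch) two-sample t of member vs non-member stats."""
    z = gene_stats.to_numpy(dtype=float)
    idx = gene_stats.index.isin(frozenset(members))
    if idx.sum() < 2 or (~idx).sum() < 2:
        raise ValueError("gage needs at least 2 genes in each group")
    res = stats.ttest_ind(z[idx], z[~idx], equal_var=False)
    return float(res.pvalue)


def _exposure_regression_p(score: np.ndarray, design: pd.DataFrame, exposure_col: str) -> float:
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    j = design.columns.get_loc(exposure_col)
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ score)
    resid = score - X @ coef
    df = n - np.linalg.matrix_rank(X)
    if df < 1:
        raise ValueError("no residual degrees of freedom for the score regression")
    s2 = (resid**2).sum() / df
    se = np.sqrt(s2 * np.linalg.inv(XtX)[j, j])
    if se == 0:
        return 1.0
    t = coef[j] / se
    return float(2.0 * stats.t.sf(abs(t), df))


def score_based_tests(
    logcpm: pd.DataFrame,
    design: pd.DataFrame,
    members,
    exposure_col: str,
) -> dict[str, float]:
    """Self-contained sample-score tests: z-score sum and PLAGE (leading
    right singular vector), each regressed on the exposure within the design.

    ``logcpm`` is genes x samples; constant member rows are dropped with a
    warning.
    """
    sub = logcpm.loc[logcpm.index.isin(frozenset(members))]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"dropping {(sd == 0).sum()} constant gene rows from the set")
        sub = sub.loc[sd > 0]
        sd = sd.loc[sd > 0]
    if sub.empty:
        raise ValueError("no non-constant member genes for score tests")
    Z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0).to_numpy()
    m = Z.shape[0]

    zscore_score = Z.sum(axis=0) / np.sqrt(m)
    p_z = _exposure_regression_p(zscore_score, design, exposure_col)

    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    plage_score = vt[0]
    mean_expr = sub.mean(axis=0).to_numpy()
    if np.corrcoef(plage_score, mean_expr)[0, 1] < 0:
        plage_score = -plage_score
    p_plage = _exposure_regression_p(plage_score, design, exposure_col)
    return {"zscore": p_z, "plage": p_plage}


def combine_pvalues(pvals, rule: str = "wilkinson") -> float:
    """Combine method p-values: Fisher (chi-square on -2 sum log p, 2k df) or
    Wilkinson minimum-p (Beta(1, k)). Zero p-values are clamped to 1e-300."""
    p = np.asarray([x for x in pvals if x is not None and np.isfinite(x)], dtype=float)
    if p.size == 0:
        raise ValueError("no valid p-values to combine")
    if (p <= 0).any():
        warnings.warn("zero p-value clamped to 1e-300 before combination")
        p = np.maximum(p, 1e-300)
    if (p > 1).any():
        raise ValueError("p-values above 1")
    k = p.size
    if rule == "fisher":
        x = -2.0 * np.log(p).sum()
        return float(stats.chi2.sf(x, 2 * k))
    if rule == "wilkinson":
        return float(1.0 - (1.0 - p.min()) ** k)
    raise ValueError(f"unknown combination rule {rule!r}")


def ensemble_run(
    de_result,
    collection: GeneSetCollection,
    methods=DEFAULT_METHODS,
    rule: str = "wilkinson",
    expression: pd.DataFrame | None = None,
    design: pd.DataFrame | None = None,
    exposure_col: str | None = None,
    min_size: int = 10,
    max_size: int = 500,
    top_k: int = 500,
    intergene_correlation: float = 0.01,
) -> pd.DataFrame:
    """Run the method ensemble over a collection against one DE result.

    ``de_result`` is a results object (or frame) with per-gene log2FC, t, p.
    The score-based methods need ``expression`` (genes x samples log-CPM) and
    the ``design``/``exposure_col`` of the fitted model; without them those
    methods are skipped with a warning.
    """
    table = de_result.table if hasattr(de_result, "table") else de_result
    universe = table.index
    restricted = collection.restrict(universe, min_size=min_size, max_size=max_size)
    if not restricted.sets:
        raise ValueError("collection is empty after size filtering")

    methods = list(methods)
    if ("zscore" in methods or "plage" in methods) and (expression is None or design is None):
        warnings.warn("no expression/design supplied: skipping score-based methods")
        methods = [m for m in methods if m not in ("zscore", "plage")]

    # moderated t on the z scale for the competitive tests
    t_stats = table["t"]
    nu = getattr(de_result, "df_total", None)
    if nu is not None and np.isfinite(nu):
        z = stats.norm.ppf(stats.t.cdf(t_stats.to_numpy(), nu).clip(1e-15, 1 - 1e-15))
    elif "nu" in table.columns:
        cdf = stats.t.cdf(t_stats.to_numpy(), np.maximum(table["nu"].to_numpy(), 1.0))
        z = stats.norm.ppf(np.clip(cdf, 1e-15, 1 - 1e-15))
    else:
        z = t_stats.to_numpy()
    z_series = pd.Series(z, index=universe)

    rows = []
    for set_name, members in restricted.sets.items():
        row: dict = {"set": set_name, "m": len(members)}
        for method in methods:
            if method == "ora":
                row["p_ora"] = ora(table["p"], members, universe, top_k=top_k)
            elif method == "camera":
                p, _ = camera_test(z_series, members, intergene_correlation)
                row["p_camera"] = p
            elif method == "gage":
                row["p_gage"] = gage_like(z_series, members)
            elif method in ("zscore", "plage"):
                if f"p_{method}" in row:
                    continue
                scores = score_based_tests(expression, design, members, exposure_col)
                for name, p in scores.items():
                    if name in methods:
                        row[f"p_{name}"] = p
            else:
                raise ValueError(f"unknown enrichment method {method!r}")
        pcols = [v for k, v in row.items() if k.startswith("p_")]
        row["combined_p"] = combine_pvalues(pcols, rule=rule)
        row["mean_logfc"] = float(table.loc[table.index.isin(members), "log2FC"].mean())
        rows.append(row)

    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_adjust(out["combined_p"].to_numpy())
    out["significant"] = out["q"] < 0.05
    out = out.sort_values("combined_p")
    out.attrs["collection"] = collection.name
    out.attrs["rule"] = rule
    out.attrs["methods"] = methods
    return out


def stratified_enrichment(
    counts: CountMatrix,
    cohort: CohortTable,
    spec: DesignSpec,
    collection: GeneSetCollection,
    methods=DEFAULT_METHODS,
    rule: str = "wilkinson",
    **kwargs,
):
    """Independent ensemble runs within the male and female strata, plus a
    direction-concordance table for sets reported in both."""
    from .model import prepare_analysis, run_de
    from .design import build_design
    from .preprocess import log_cpm
    from .voom import estimate_precision_weights

    results = {}
    for stratum in ("male", "female"):
        s_spec = spec.with_stratum(stratum)
        de = run_de(counts, cohort, s_spec)
        data = prepare_analysis(counts, cohort, s_spec, complete_case=True)
        X = build_design(data.cohort_df, s_spec, schema=data.schema)
        E = pd.DataFrame(
            log_cpm(data.counts, data.norm_factors),
            index=data.counts.gene_ids,
            columns=data.counts.sample_ids,
        )
        coef = s_spec.exposure_columns[0]
        results[stratum] = ensemble_run(
            de, collection, methods=methods, rule=rule,
            expression=E, design=X, exposure_col=coef, **kwargs,
        )
    male, female = results["male"], results["female"]
    shared = male.index.intersection(female.index)
    concordance = pd.DataFrame(
        {
            "direction_male": male.loc[shared, "mean_logfc"],
            "direction_female": female.loc[shared, "mean_logfc"],
        }
    )
    concordance["concordant"] = (
        np.sign(concordance["direction_male"]) == np.sign(concordance["direction_female"])
    )
    return results, concordance
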