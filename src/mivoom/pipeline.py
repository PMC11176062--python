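"""Stage orchestration for the end-to-end analysis graph.

Stages are plain functions over a :class:`~mivoom.config.RunConfig`; each
writes self-contained TSV/JSON outputs (with the generating config hash in a
header comment) so every stage is independently re-runnable and diffable.
The analysis graph per exposure mirrors the study design: an interaction
screen, the multiple-imputation primary analysis with three covariate-set
variants, complete-case and random-forest single-imputation sensitivity
analyses, cross-method rank concordance, and (on synthetic data) a
truth-recovery report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .config import RunConfig, config_hash
from .counts import CountMatrix
from .design import DesignSpec
from .enrichment import GeneSetCollection, ensemble_run, read_gmt, stratified_enrichment
from .impute import mi_de, rank_concordance, single_impute
from .io import read_fixture, write_fixture
from .model import prepare_analysis, run_de
from .design import build_design, select_samples
from .preprocess import log_cpm

log = logging.getLogger("mivoom.pipeline")

__all__ = ["cmd_simulate", "cmd_analyze", "cmd_enrich", "cmd_report", "write_table", "read_table"]


def write_table(df: pd.DataFrame, path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _variant_spec(exposure: str, variant: str) -> DesignSpec:
    if variant == "primary":
        return DesignSpec(exposure=exposure)
    if variant == "gestational_age":
        return DesignSpec(exposure=exposure, include_gestational_age=True)
    if variant == "no_mediators":
        return DesignSpec(exposure=exposure, include_mediators=False)
    raise ValueError(f"unknown analysis variant {variant!r}")


def _fixture_dir(cfg: RunConfig) -> str:
    return cfg.fixture or os.path.join(cfg.outdir, "fixture")


def cmd_simulate(cfg: RunConfig, force: bool = False) -> str:
    """Generate a synthetic fixture (cohort + counts + truth) with manifest."""
    fixture = _fixture_dir(cfg)
    manifest_path = os.path.join(fixture, "manifest.json")
    if os.path.exists(manifest_path) and not force:
        raise FileExistsError(f"{fixture} already contains a fixture; use --force to overwrite")
    from .cohort import simulate_cohort
    from .counts import simulate_counts

    n = int(cfg.resolved("n_samples"))
    n_genes = int(cfg.resolved("n_genes"))
    complete, masked = simulate_cohort(n, missing=cfg.missing, seed=cfg.seed)
    counts, truth = simulate_counts(
        complete, n_genes=n_genes, lib_size_mean=float(cfg.resolved("lib_size_mean")),
        seed=cfg.seed + 10,
    )
    write_fixture(masked, counts, truth, fixture)
    files = sorted(
        f for f in os.listdir(fixture) if f != "manifest.json"
    )
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "n_samples": n,
        "n_genes": n_genes,
        "checksums": {f: _sha256(os.path.join(fixture, f)) for f in files},
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("simulate: %d samples x %d genes -> %s", n, n_genes, fixture)
    return fixture


def _load_data(cfg: RunConfig):
    if cfg.counts and cfg.metadata:
        from .io import read_annotation, read_counts_tsv, read_metadata

        annotation = read_annotation(cfg.annotation) if cfg.annotation else None
        counts = read_counts_tsv(cfg.counts, annotation)
        cohort = read_metadata(cfg.metadata)
        return cohort, counts, None
    return read_fixture(_fixture_dir(cfg))


def _de_dir(cfg: RunConfig) -> str:
    return os.path.join(cfg.outdir, "de")


def cmd_analyze(cfg: RunConfig, force: bool = False) -> dict:
    """Run the differential-expression analysis graph; returns output paths."""
    cohort, counts, truth = _load_data(cfg)
    de_dir = _de_dir(cfg)
    os.makedirs(de_dir, exist_ok=True)
    h = config_hash(cfg)
    m = int(cfg.resolved("m_imputations"))
    bin_size = int(cfg.resolved("bin_size"))
    max_iter = int(cfg.resolved("max_iter"))
    outputs: dict[str, str] = {}

    def _stage(path):
        return os.path.exists(path) and not force

    # interaction screen (once, when both exposures are analysed)
    if set(cfg.exposures) >= {"sle_sum", "cte_sum"}:
        path = os.path.join(de_dir, "interaction.tsv")
        outputs["interaction"] = path
        if not _stage(path):
            res = run_de(counts, cohort, DesignSpec(exposure="interaction"))
            write_table(res.table, path, h)
            log.info(
                "analyze interaction: n=%d genes=%d fdr05=%d fdr10=%d",
                res.metadata["n_samples"], res.metadata["n_genes"],
                res.n_significant_05, res.n_significant_10,
            )

    for exposure in cfg.exposures:
        results = {}
        for variant in cfg.variants:
            spec = _variant_spec(exposure, variant)
            path = os.path.join(de_dir, f"mi_{exposure}_{variant}.tsv")
            outputs[f"mi_{exposure}_{variant}"] = path
            if not _stage(path):
                res = mi_de(
                    counts, cohort, spec, m_imputations=m, bin_size=bin_size,
                    max_iter=max_iter, seed=cfg.seed + 20,
                )
                write_table(res.table, path, h)
                md = res.metadata
                log.info(
                    "analyze mi %s/%s: n=%d genes=%d fdr05=%d fdr10=%d",
                    exposure, variant, md["n_samples"], md["n_genes"], md["fdr05"], md["fdr10"],
                )
            if variant == "primary":
                results["mi"] = read_table(path)

        spec = _variant_spec(exposure, "primary")
        cc_path = os.path.join(de_dir, f"cc_{exposure}.tsv")
        outputs[f"cc_{exposure}"] = cc_path
        if not _stage(cc_path):
            res = run_de(counts, cohort, spec)
            write_table(res.table, cc_path, h)
            md = res.metadata
            log.info(
                "analyze cc %s: n=%d genes=%d fdr05=%d fdr10=%d",
                exposure, md["n_samples"], md["n_genes"], md["fdr05"], md["fdr10"],
            )
        results["cc"] = read_table(cc_path)

        si_path = os.path.join(de_dir, f"si_{exposure}.tsv")
        outputs[f"si_{exposure}"] = si_path
        if not _stage(si_path):
            sub = select_samples(cohort, spec)
            completed = single_impute(CohortTable(sub.copy(), cohort.schema), seed=cfg.seed + 30)
            res = run_de(counts, completed, spec)
            write_table(res.table, si_path, h)
            md = res.metadata
            log.info(
                "analyze si %s: n=%d genes=%d fdr05=%d fdr10=%d",
                exposure, md["n_samples"], md["n_genes"], md["fdr05"], md["fdr10"],
            )
        results["si"] = read_table(si_path)

        conc_path = os.path.join(de_dir, f"concordance_{exposure}.tsv")
        outputs[f"concordance_{exposure}"] = conc_path
        if not _stage(conc_path):
            shared = results["mi"].index
            for t in results.values():
                shared = shared.intersection(t.index)
            conc = pd.DataFrame(
                {
                    "rank_mi": results["mi"].loc[shared, "p"].rank(),
                    "rank_si": results["si"].loc[shared, "p"].rank(),
                    "rank_cc": results["cc"].loc[shared, "p"].rank(),
                },
                index=shared,
            )
            write_table(conc, conc_path, h)
            log.info(
                "analyze concordance %s: mi-si rho=%.3f mi-cc rho=%.3f",
                exposure,
                conc["rank_mi"].corr(conc["rank_si"], method="spearman"),
                conc["rank_mi"].corr(conc["rank_cc"], method="spearman"),
            )

        if truth is not None:
            rec_path = os.path.join(de_dir, f"recovery_{exposure}.tsv")
            outputs[f"recovery_{exposure}"] = rec_path
            if not _stage(rec_path):
                beta_col = "beta_sle" if exposure == "sle_sum" else "beta_cte"
                mi_tab = results["mi"]
                tt = truth.table.loc[truth.table.index.intersection(mi_tab.index)]
                joined = mi_tab.join(tt[[beta_col]], how="inner")
                joined["bias"] = joined["log2FC"] - joined[beta_col]
                effect = joined[beta_col] != 0
                tpr = float((joined.loc[effect, "q"] < 0.05).mean()) if effect.any() else np.nan
                discoveries = joined["q"] < 0.05
                fdr = (
                    float((joined.loc[discoveries, beta_col] == 0).mean())
                    if discoveries.any()
                    else 0.0
                )
                report = joined.loc[effect, ["log2FC", beta_col, "bias", "p", "q"]].copy()
                report.attrs = {}
                summary_row = pd.DataFrame(
                    {
                        "log2FC": [np.nan],
                        beta_col: [np.nan],
                        "bias": [float(joined.loc[~effect, "bias"].mean())],
                        "p": [tpr],
                        "q": [fdr],
                    },
                    index=pd.Index(["__null_mean_bias__tpr__fdr__"], name=report.index.name),
                )
                write_table(pd.concat([report, summary_row]), rec_path, h)
                log.info("analyze recovery %s: tpr=%.2f empirical_fdr=%.2f", exposure, tpr, fdr)
    return outputs


def _synthetic_collection(gene_ids, seed: int, n_sets: int = 40) -> GeneSetCollection:
    """Random gene sets over the tested universe (synthetic stand-in used when
    no GMT collections are configured)."""
    rng = np.random.default_rng(seed)
    genes = np.asarray(list(gene_ids))
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(15, 80))
        sets[f"RANDOM_{i:03d}"] = frozenset(rng.choice(genes, size=min(size, len(genes)), replace=False))
    return GeneSetCollection("synthetic_random", sets)


def cmd_enrich(cfg: RunConfig, force: bool = False) -> dict:
    """Ensemble enrichment per (exposure, collection), overall and per sex."""
    cohort, counts, _ = _load_data(cfg)
    enr_dir = os.path.join(cfg.outdir, "enrichment")
    os.makedirs(enr_dir, exist_ok=True)
    h = config_hash(cfg)
    outputs: dict[str, str] = {}
    long_rows = []

    for exposure in cfg.exposures:
        spec = _variant_spec(exposure, "primary")
        # single-imputation completion feeds the enrichment stage
        sub = select_samples(cohort, spec)
        completed = single_impute(CohortTable(sub.copy(), cohort.schema), seed=cfg.seed + 30)
        de = run_de(counts, completed, spec)
        data = prepare_analysis(counts, completed, spec, complete_case=True)
        X = build_design(data.cohort_df, spec, schema=data.schema)
        E = pd.DataFrame(
            log_cpm(data.counts, data.norm_factors),
            index=data.counts.gene_ids,
            columns=data.counts.sample_ids,
        )
        collections = (
            [read_gmt(p) for p in cfg.gmt]
            if cfg.gmt
            else [_synthetic_collection(de.table.index, seed=cfg.seed + 40)]
        )
        for coll in collections:
            path = os.path.join(enr_dir, f"{exposure}_{coll.name}.tsv")
            outputs[f"{exposure}_{coll.name}"] = path
            if not (os.path.exists(path) and not force):
                tab = ensemble_run(
                    de, coll, methods=cfg.methods, rule=cfg.rule,
                    expression=E, design=X, exposure_col=spec.exposure_columns[0],
                    min_size=cfg.min_size, max_size=cfg.max_size,
                )
                write_table(tab, path, h)
                log.info(
                    "enrich %s/%s: sets=%d significant=%d",
                    exposure, coll.name, len(tab), int(tab.significant.sum()),
                )
            tab = read_table(path)
            for set_name, row in tab[tab["significant"]].iterrows():
                long_rows.append(
                    {
                        "set": set_name,
                        "exposure": exposure,
                        "collection": coll.name,
                        "stratum": "all",
                        "logFC": row["mean_logfc"],
                        "q": row["q"],
                    }
                )

            strat_path = os.path.join(enr_dir, f"{exposure}_{coll.name}_stratified.tsv")
            outputs[f"{exposure}_{coll.name}_stratified"] = strat_path
            if not (os.path.exists(strat_path) and not force):
                per_stratum, concordance = stratified_enrichment(
                    counts, completed, spec, coll, methods=cfg.methods, rule=cfg.rule,
                    min_size=cfg.min_size, max_size=cfg.max_size,
                )
                frames = []
                for stratum, t in per_stratum.items():
                    t = t.copy()
                    t["stratum"] = stratum
                    frames.append(t)
                write_table(pd.concat(frames), strat_path, h)
                conc_path = os.path.join(enr_dir, f"{exposure}_{coll.name}_sex_concordance.tsv")
                outputs[f"{exposure}_{coll.name}_sex_concordance"] = conc_path
                write_table(concordance, conc_path, h)

    long_path = os.path.join(enr_dir, "significant_long.tsv")
    write_table(pd.DataFrame(long_rows), long_path, h)
    outputs["significant_long"] = long_path
    return outputs


def cmd_report(cfg: RunConfig) -> str:
    """Consolidated markdown + TSV report over completed stage outputs."""
    cohort, counts, truth = _load_data(cfg)
    h = config_hash(cfg)
    os.makedirs(cfg.outdir, exist_ok=True)

    # cohort descriptives with missing counts per variable
    rows = []
    df = cohort.data
    for col in df.columns:
        entry = {"variable": col, "n_missing": int(df[col].isna().sum())}
        if pd.api.types.is_numeric_dtype(df[col]):
            entry["mean"] = float(df[col].mean())
            entry["sd"] = float(df[col].std())
        else:
            top = df[col].mode()
            entry["mode"] = str(top.iloc[0]) if len(top) else ""
        rows.append(entry)
    descriptives = pd.DataFrame(rows).set_index("variable")
    desc_path = os.path.join(cfg.outdir, "descriptives.tsv")
    write_table(descriptives, desc_path, h)

    lines = [
        "# Analysis report",
        "",
        f"config hash: `{h}`",
        f"samples: {len(df)}   genes: {counts.n_genes}",
        "",
        "## Cohort descriptives",
        "",
        descriptives.to_string(),
        "",
    ]
    de_dir = _de_dir(cfg)
    if os.path.isdir(de_dir):
        lines.append("## Differential expression outputs")
        for f in sorted(os.listdir(de_dir)):
            t = read_table(os.path.join(de_dir, f))
            if "q" in t.columns:
                lines.append(f"- {f}: {len(t)} genes, FDR<0.05: {int((t['q'] < 0.05).sum())}")
            else:
                lines.append(f"- {f}: {len(t)} rows")
    enr_dir = os.path.join(cfg.outdir, "enrichment")
    if os.path.isdir(enr_dir):
        lines.append("")
        lines.append("## Enrichment outputs")
        for f in sorted(os.listdir(enr_dir)):
            t = read_table(os.path.join(enr_dir, f))
            if "significant" in t.columns:
                lines.append(f"- {f}: {len(t)} sets, significant: {int(t['significant'].sum())}")
            else:
                lines.append(f"- {f}: {len(t)} rows")
    report_path = os.path.join(cfg.outdir, "report.md")
    with open(report_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return report_path
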