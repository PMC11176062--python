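"""Missing-covariate strategies for differential expression.

Three strategies are provided, mirroring a primary analysis and two
sensitivity analyses:

* gene-binned multiple imputation (primary): genes are shuffled into bins;
  within each bin, chained equations impute the missing covariates using the
  other covariates, the exposure, and the bin's log-CPM values as predictors
  (the outcome must predict missingness-model imputations to avoid bias);
  each completed dataset is analysed with the precision-weighted moderated
  pipeline and the bin's coefficients are pooled by Rubin's rules with
  Barnard-Rubin adjusted degrees of freedom;
* iterative random-forest single imputation (missForest-style);
* complete case.

A rank-concordance utility compares the gene p-value orderings the three
strategies produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, CovariateSchema
from .counts import CountMatrix
from .design import DesignSpec, build_design
from .ebayes import ModeratedResult, bh_adjust, percent_change, squeeze_var
from .model import prepare_analysis
from .preprocess import log_cpm
from .voom import estimate_precision_weights, fit_weighted

__all__ = [
    "bin_genes",
    "ImputationSet",
    "impute_bin",
    "rubin_pool",
    "MIPooledResult",
    "mi_de",
    "single_impute",
    "rank_concordance",
]


def bin_genes(gene_ids, bin_size: int = 50, seed: int = 0) -> list[pd.Index]:
    """Random shuffle by seed, then consecutive chunks of ``bin_size``."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    gene_ids = pd.Index(gene_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(gene_ids))
    shuffled = gene_ids[order]
    return [shuffled[i : i + bin_size] for i in range(0, len(shuffled), bin_size)]


@dataclass
class ImputationSet:
    """M completed covariate tables for one gene bin.

    Observed cells are identical across imputations; only originally missing
    cells differ. Exposure and expression values are never altered.
    """

    bin_id: int
    completed: list[pd.DataFrame]
    seed: int
    trace: list[dict] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.completed)


def _predictor_matrix(
    df: pd.DataFrame,
    schema: CovariateSchema,
    exclude: str,
    exposure_cols: tuple[str, ...],
    expression: pd.DataFrame | None,
) -> np.ndarray:
    """Numeric, standardized predictor matrix from a completed table."""
    parts = []
    for col in schema.continuous + schema.binary:
        if col == exclude or col not in df.columns:
            continue
        parts.append(df[col].to_numpy(dtype=float))
    for col in schema.categorical:
        if col == exclude or col not in df.columns:
            continue
        values = df[col]
        levels = pd.unique(values.dropna())
        for level in levels[1:]:
            parts.append((values == level).to_numpy(dtype=float))
    for col in exposure_cols:
        if col in df.columns:
            parts.append(df[col].to_numpy(dtype=float))
    X = np.column_stack(parts) if parts else np.empty((len(df), 0))
    if expression is not None:
        X = np.column_stack([X, expression.to_numpy(dtype=float)])
    if X.shape[1]:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return X


def _pmm_draw(rng, x_obs, y_obs, x_mis, k: int = 5):
    """Predictive mean matching: bootstrap-refit linear model, match each
    missing case to the k observed cases with nearest predictions, draw one
    donor's observed value."""
    n = len(y_obs)
    boot = rng.integers(0, n, n)
    Xb = np.column_stack([np.ones(len(boot)), x_obs[boot]])
    coef, *_ = np.linalg.lstsq(Xb, y_obs[boot], rcond=None)
    pred_obs = np.column_stack([np.ones(n), x_obs]) @ coef
    pred_mis = np.column_stack([np.ones(len(x_mis)), x_mis]) @ coef
    k = min(k, n)
    d = np.abs(pred_mis[:, None] - pred_obs[None, :])
    nearest = np.argpartition(d, kth=k - 1, axis=1)[:, :k]
    pick = nearest[np.arange(len(x_mis)), rng.integers(0, k, len(x_mis))]
    return y_obs[pick]


def _classifier_draw(rng, x_obs, y_obs, x_mis, seed: int):
    """Bootstrap-refit (multinomial) logistic model, draw labels from the
    predicted class probabilities."""
    from sklearn.linear_model import LogisticRegression

    n = len(y_obs)
    boot = rng.integers(0, n, n)
    yb = y_obs[boot]
    if len(pd.unique(yb)) < 2:
        return np.full(len(x_mis), yb[0], dtype=object)
    clf = LogisticRegression(max_iter=200, tol=1e-3, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(x_obs[boot], yb)
    proba = clf.predict_proba(x_mis)
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(x_mis))[:, None]
    idx = (u > cum).sum(axis=1).clip(0, proba.shape[1] - 1)
    return clf.classes_[idx]


def impute_bin(
    cohort: CohortTable,
    logcpm_bin: pd.DataFrame | None,
    m_imputations: int = 10,
    max_iter: int = 10,
    seed: int = 0,
    bin_id: int = 0,
    pmm_donors: int = 5,
    exposure_cols: tuple[str, ...] | None = None,
) -> ImputationSet:
    """Chained-equation multiple imputation of covariates for one gene bin.

    ``logcpm_bin`` is genes-in-bin x samples (columns aligned with the cohort);
    its transpose joins the predictor matrix of every imputation model along
    with all other covariates and the exposure sums. Continuous covariates use
    predictive mean matching, binary ones a logistic draw, categorical ones a
    multinomial logistic draw. Exposure and expression values are never
    imputed; samples with missing exposure must be excluded beforehand.
    """
    if m_imputations < 2:
        raise ValueError("multiple imputation needs M >= 2")
    schema = cohort.schema
    df = cohort.data
    if exposure_cols is None:
        exposure_cols = tuple(
            c for c in schema.exposures if c in df.columns and df[c].notna().all()
        )
    for col in exposure_cols:
        if df[col].isna().any():
            raise ValueError(
                f"exposure column {col!r} has missing values; drop those samples first"
            )
    expression = logcpm_bin.T.loc[df.index] if logcpm_bin is not None else None

    covars = [c for c in schema.covariates if c in df.columns]
    missing_cols = [c for c in covars if df[c].isna().any()]
    order = sorted(missing_cols, key=lambda c: df[c].isna().sum())

    completed_list: list[pd.DataFrame] = []
    trace: list[dict] = []
    for m in range(m_imputations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, bin_id, m]))
        work = df.copy()
        if not order:
            completed_list.append(work)
            continue
        # initialize missing cells with draws from the observed marginal
        for col in order:
            obs = df[col].dropna().to_numpy()
            mask = df[col].isna().to_numpy()
            if obs.size == 0:
                raise ValueError(f"column {col!r} is entirely missing")
            work.loc[mask, col] = obs[rng.integers(0, obs.size, mask.sum())]

        for it in range(max_iter):
            for col in order:
                mask = df[col].isna().to_numpy()
                obs_mask = ~mask
                frac_missing = mask.mean()
                X = _predictor_matrix(work, schema, col, exposure_cols, expression)
                if X.shape[1] == 0 and frac_missing > 0.5:
                    warnings.warn(
                        f"{col!r}: >50% missing and no informative predictors; "
                        "falling back to marginal draws"
                    )
                    obs = df[col].dropna().to_numpy()
                    work.loc[mask, col] = obs[rng.integers(0, obs.size, mask.sum())]
                    continue
                x_obs, x_mis = X[obs_mask], X[mask]
                if col in schema.continuous:
                    y_obs = df.loc[obs_mask, col].to_numpy(dtype=float)
                    work.loc[mask, col] = _pmm_draw(rng, x_obs, y_obs, x_mis, k=pmm_donors)
                else:
                    y_obs = df.loc[obs_mask, col].to_numpy()
                    draw = _classifier_draw(
                        rng, x_obs, y_obs, x_mis, seed=int(rng.integers(0, 2**31 - 1))
                    )
                    if col in schema.binary:
                        work.loc[mask, col] = draw.astype(float)
                    else:
                        work.loc[mask, col] = draw
        trace.append({"imputation": m, "iterations": max_iter, "variables": list(order)})
        completed_list.append(work)
    return ImputationSet(bin_id=bin_id, completed=completed_list, seed=seed, trace=trace)


def rubin_pool(
    estimates: np.ndarray,
    variances: np.ndarray,
    df_complete: float | np.ndarray,
) -> pd.DataFrame:
    """Pool M x G per-imputation estimates and variances by Rubin's rules.

    Returns a frame with columns qbar, ubar, b_between, t_var, nu, t, p.
    Degrees of freedom follow Barnard-Rubin:
    lambda = (1+1/M) B / T, nu_old = (M-1)/lambda^2,
    nu_obs = ((nu_com+1)/(nu_com+3)) nu_com (1-lambda),
    nu = (1/nu_old + 1/nu_obs)^-1.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    var = np.atleast_2d(np.asarray(variances, dtype=float))
    if est.shape != var.shape:
        raise ValueError("estimates and variances shape mismatch")
    m = est.shape[0]
    if m < 2:
        raise ValueError("Rubin pooling needs M >= 2 imputations")
    qbar = est.mean(axis=0)
    ubar = var.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    t_var = ubar + (1.0 + 1.0 / m) * b
    lam = np.where(t_var > 0, (1.0 + 1.0 / m) * b / np.where(t_var > 0, t_var, 1.0), 0.0)
    nu_com = np.minimum(np.broadcast_to(np.asarray(df_complete, float), qbar.shape), 1e9)
    with np.errstate(divide="ignore"):
        nu_old = np.where(lam > 0, (m - 1) / np.maximum(lam, 1e-300) ** 2, np.inf)
    nu_obs = ((nu_com + 1.0) / (nu_com + 3.0)) * nu_com * (1.0 - lam)
    nu = 1.0 / (1.0 / nu_old + 1.0 / np.maximum(nu_obs, 1e-300))
    se = np.sqrt(t_var)
    t = np.where(se > 0, qbar / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(nu, 1e-3))
    return pd.DataFrame(
        {
            "qbar": qbar,
            "ubar": ubar,
            "b_between": b,
            "t_var": t_var,
            "nu": nu,
            "t": t,
            "p": p,
        }
    )


@dataclass
class MIPooledResult:
    """Rubin's-rules pooled differential expression results.

    ``table`` columns: log2FC (pooled), percent_change, ubar, b_between,
    t_var, nu, t, p, q, mean_logcpm.
    """

    table: pd.DataFrame
    coefficient: str
    metadata: dict = field(default_factory=dict)

    @property
    def n_significant_05(self) -> int:
        return int((self.table["q"] < 0.05).sum())

    @property
    def n_significant_10(self) -> int:
        return int((self.table["q"] < 0.10).sum())

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p")
        md = self.metadata
        lines = [
            f"Multiple-imputation pooled differential expression: coefficient {self.coefficient!r}",
            f"  genes: {len(t)}   samples: {md.get('n_samples', '?')}   "
            f"M: {md.get('m_imputations', '?')}   bin size: {md.get('bin_size', '?')}",
            f"  FDR<0.05: {self.n_significant_05}   FDR<0.10: {self.n_significant_10}",
            "",
            t.head(top).to_string(
                float_format=lambda v: f"{v:.4g}",
                columns=["log2FC", "percent_change", "t", "nu", "p", "q"],
            ),
        ]
        return "\n".join(lines)


def _fit_one_dataset(counts, completed_df, spec, schema, norm_factors, span):
    """Design + voom + WLS + within-dataset moderation for one completed table."""
    X = build_design(completed_df, spec, schema=schema)
    voom = estimate_precision_weights(counts, X, norm_factors, span=span)
    fits = fit_weighted(voom)
    post, d0, s2_0 = squeeze_var(fits.s2, fits.df)
    return fits, post, d0


def mi_de(
    counts: CountMatrix,
    cohort: CohortTable,
    spec: DesignSpec,
    m_imputations: int = 10,
    bin_size: int = 50,
    max_iter: int = 10,
    seed: int = 0,
    span: float = 0.5,
    moderation: str = "within",
    biotype_filter: bool = True,
    coefficient: str | None = None,
) -> MIPooledResult:
    """Gene-binned multiple-imputation differential expression, pooled by
    Rubin's rules.

    ``moderation='within'`` (default) squeezes gene variances within each
    completed dataset before pooling; ``'pooled'`` pools raw variances and
    squeezes the within-imputation component afterwards.
    """
    if moderation not in ("within", "pooled"):
        raise ValueError(f"unknown moderation mode {moderation!r}")
    data = prepare_analysis(counts, cohort, spec, complete_case=False, biotype_filter=biotype_filter)
    coef = coefficient or spec.exposure_columns[-1 if spec.exposure == "interaction" else 0]
    sub_cohort = CohortTable(data.cohort_df.copy(), data.schema)
    covars = [c for c in spec.covariates if c in data.cohort_df.columns]
    any_missing = data.cohort_df[covars].isna().any().any()

    E_full = pd.DataFrame(
        log_cpm(data.counts, data.norm_factors),
        index=data.counts.gene_ids,
        columns=data.counts.sample_ids,
    )
    bins = bin_genes(data.counts.gene_ids, bin_size=bin_size, seed=seed)

    n_genes = data.counts.n_genes
    est = {}
    var = {}
    dfc = {}
    extras = {}

    if not any_missing:
        # degenerate case: every completed dataset equals the observed one
        fits, post, d0 = _fit_one_dataset(
            data.counts, data.cohort_df, spec, data.schema, data.norm_factors, span
        )
        j = fits.column(coef)
        beta = fits.coefficients[:, j]
        if moderation == "within":
            v = post * fits.cov_unscaled_diag[:, j]
            df_com = (d0 if np.isfinite(d0) else 1e9) + fits.df
        else:
            v = fits.s2 * fits.cov_unscaled_diag[:, j]
            df_com = fits.df
        est_mat = np.tile(beta, (m_imputations, 1))
        var_mat = np.tile(v, (m_imputations, 1))
        pooled = _assemble_pooled(
            est_mat, var_mat, df_com, data, coef, moderation, m_imputations
        )
    else:
        est_mat = np.empty((m_imputations, n_genes))
        var_mat = np.empty((m_imputations, n_genes))
        df_com = np.empty(n_genes)
        gene_pos = pd.Series(np.arange(n_genes), index=data.counts.gene_ids)
        cache: dict[bytes, tuple] = {}
        for b_idx, bin_ids in enumerate(bins):
            imp = impute_bin(
                sub_cohort,
                E_full.loc[bin_ids],
                m_imputations=m_imputations,
                max_iter=max_iter,
                seed=seed,
                bin_id=b_idx,
                exposure_cols=spec.base_exposures,
            )
            pos = gene_pos[bin_ids].to_numpy()
            for m, completed in enumerate(imp.completed):
                key = pd.util.hash_pandas_object(completed[covars]).to_numpy().tobytes()
                if key in cache:
                    fits, post, d0 = cache[key]
                else:
                    fits, post, d0 = _fit_one_dataset(
                        data.counts, completed, spec, data.schema, data.norm_factors, span
                    )
                    if len(cache) < 4:
                        cache[key] = (fits, post, d0)
                j = fits.column(coef)
                if moderation == "within":
                    v = post * fits.cov_unscaled_diag[:, j]
                    dcom = (d0 if np.isfinite(d0) else 1e9) + fits.df
                else:
                    v = fits.s2 * fits.cov_unscaled_diag[:, j]
                    dcom = fits.df
                est_mat[m, pos] = fits.coefficients[pos, j]
                var_mat[m, pos] = v[pos]
                df_com[pos] = dcom
        pooled = _assemble_pooled(
            est_mat, var_mat, df_com, data, coef, moderation, m_imputations
        )
    pooled.metadata.update(
        {
            "analysis": spec.label,
            "method": "multiple_imputation",
            "m_imputations": m_imputations,
            "bin_size": bin_size,
            "max_iter": max_iter,
            "seed": seed,
            "moderation": moderation,
            "n_samples": int(data.counts.n_samples),
            "n_genes": int(n_genes),
            "fdr05": pooled.n_significant_05,
            "fdr10": pooled.n_significant_10,
        }
    )
    return pooled


def _assemble_pooled(est_mat, var_mat, df_com, data, coef, moderation, m_imputations):
    pooled = rubin_pool(est_mat, var_mat, df_com)
    if moderation == "pooled":
        post, d0, s2_0 = squeeze_var(
            pooled["ubar"].to_numpy(), np.broadcast_to(np.asarray(df_com, float), (len(pooled),))
        )
        t_var = post + (1.0 + 1.0 / m_imputations) * pooled["b_between"].to_numpy()
        se = np.sqrt(t_var)
        t = pooled["qbar"].to_numpy() / np.where(se > 0, se, 1.0)
        pooled["ubar"] = post
        pooled["t_var"] = t_var
        pooled["t"] = t
        pooled["p"] = 2.0 * stats.t.sf(np.abs(t), np.maximum(pooled["nu"].to_numpy(), 1e-3))
    table = pd.DataFrame(
        {
            "log2FC": pooled["qbar"].to_numpy(),
            "percent_change": percent_change(pooled["qbar"].to_numpy()),
            "ubar": pooled["ubar"].to_numpy(),
            "b_between": pooled["b_between"].to_numpy(),
            "t_var": pooled["t_var"].to_numpy(),
            "nu": pooled["nu"].to_numpy(),
            "t": pooled["t"].to_numpy(),
            "p": pooled["p"].to_numpy(),
            "q": bh_adjust(pooled["p"].to_numpy()),
            "mean_logcpm": log_cpm(data.counts, data.norm_factors).mean(axis=1),
        },
        index=data.counts.gene_ids,
    )
    return MIPooledResult(table=table, coefficient=coef)


def single_impute(
    cohort: CohortTable,
    seed: int = 0,
    max_iter: int = 10,
    n_estimators: int = 100,
) -> CohortTable:
    """Iterative random-forest single imputation of the covariates.

    Variables are visited in increasing-missingness order; each is imputed by
    a random forest fitted on the currently completed other covariates (plus
    any fully observed exposure). Iteration stops when the average
    out-of-bag error increases or after ``max_iter`` rounds. Exposures are
    never imputed.
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    schema = cohort.schema
    df = cohort.data
    covars = [c for c in schema.covariates if c in df.columns]
    missing_cols = [c for c in covars if df[c].isna().any()]
    if not missing_cols:
        return cohort.copy()
    order = sorted(missing_cols, key=lambda c: df[c].isna().sum())
    exposure_cols = tuple(
        c for c in schema.exposures if c in df.columns and df[c].notna().all()
    )
    rng = np.random.default_rng(seed)

    work = df.copy()
    for col in order:
        obs = df[col].dropna()
        mask = df[col].isna()
        if col in schema.continuous:
            work.loc[mask, col] = obs.mean()
        else:
            work.loc[mask, col] = obs.mode().iloc[0]

    prev_err = np.inf
    best = work.copy()
    for it in range(max_iter):
        errs = []
        for col in order:
            mask = df[col].isna().to_numpy()
            X = _predictor_matrix(work, schema, col, exposure_cols, None)
            x_obs, x_mis = X[~mask], X[mask]
            rs = int(rng.integers(0, 2**31 - 1))
            if col in schema.continuous:
                y = df.loc[~mask, col].to_numpy(dtype=float)
                est = RandomForestRegressor(
                    n_estimators=n_estimators, oob_score=True, random_state=rs, n_jobs=1
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(x_obs, y)
                work.loc[mask, col] = est.predict(x_mis)
                errs.append(max(0.0, 1.0 - est.oob_score_))
            else:
                y = df.loc[~mask, col].to_numpy()
                if len(pd.unique(y)) < 2:
                    work.loc[mask, col] = y[0]
                    errs.append(0.0)
                    continue
                est = RandomForestClassifier(
                    n_estimators=n_estimators, oob_score=True, random_state=rs, n_jobs=1
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(x_obs, y)
                pred = est.predict(x_mis)
                if col in schema.binary:
                    pred = pred.astype(float)
                work.loc[mask, col] = pred
                errs.append(max(0.0, 1.0 - est.oob_score_))
        err = float(np.mean(errs)) if errs else 0.0
        if err >= prev_err:
            work = best
            break
        prev_err = err
        best = work.copy()
    return CohortTable(work, schema)


def rank_concordance(result_a, result_b) -> float:
    """Spearman correlation of gene p-value ranks between two result tables."""
    ta = result_a.table if hasattr(result_a, "table") else result_a
    tb = result_b.table if hasattr(result_b, "table") else result_b
    shared = ta.index.intersection(tb.index)
    if len(shared) == 0:
        raise ValueError("result tables share no genes")
    rho = stats.spearmanr(ta.loc[shared, "p"], tb.loc[shared, "p"]).statistic
    return float(rho)
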