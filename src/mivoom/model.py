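"""Model/Results interface for the differential-expression pipeline.

``DifferentialExpressionModel`` fits precision-weighted gene-wise linear
models with empirical-Bayes moderation on complete-case data;
``MIDifferentialExpressionModel`` runs the gene-binned multiple-imputation
variant pooled by Rubin's rules; ``SingleImputationDEModel`` runs the
random-forest single-imputation sensitivity analysis. Each ``.fit()`` returns
a results object carrying the per-gene table, hyperparameters, and metadata,
with a ``summary()`` rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .counts import CountMatrix
from .design import DesignSpec, build_design, select_samples
from .ebayes import ModeratedResult, ebayes_moderate
from .preprocess import (
    filter_by_biotype,
    filter_low_expression,
    log_cpm,
    tmm_factors,
)
from .voom import estimate_precision_weights, fit_weighted

__all__ = [
    "prepare_analysis",
    "run_de",
    "DifferentialExpressionModel",
    "MIDifferentialExpressionModel",
    "SingleImputationDEModel",
]


@dataclass
class AnalysisData:
    """Filtered counts, analysis-sample metadata, and TMM factors for a spec."""

    cohort_df: pd.DataFrame
    counts: CountMatrix
    norm_factors: object
    schema: object


def prepare_analysis(
    counts: CountMatrix,
    cohort: CohortTable,
    spec: DesignSpec,
    complete_case: bool,
    biotype_filter: bool = True,
    expression_threshold: float = 0.0,
) -> AnalysisData:
    """Sample selection and gene filtering for one analysis variant.

    Samples missing the exposure are always dropped (exposures are never
    imputed); ``complete_case`` additionally drops samples missing any design
    covariate. Transcript filtering (biotype, then mean log-CPM below the
    threshold) is applied on the analytic samples, and TMM factors are
    computed on the filtered matrix.
    """
    sub = select_samples(cohort, spec)
    if complete_case:
        used = list(spec.used_columns)
        sub = sub.loc[sub[used].notna().all(axis=1)]
    if sub.empty:
        raise ValueError("no usable samples after selection")
    cm = counts.subset_samples(sub.index)
    if biotype_filter and cm.biotype is not None and cm.biotype.notna().any():
        cm = filter_by_biotype(cm)
    E = log_cpm(cm)
    keep = filter_low_expression(E, threshold=expression_threshold)
    if not keep.any():
        raise ValueError("expression filter removed every gene")
    cm = cm.subset_genes(keep)
    nf = tmm_factors(cm)
    return AnalysisData(cohort_df=sub, counts=cm, norm_factors=nf, schema=cohort.schema)


def run_de(
    counts: CountMatrix,
    cohort: CohortTable,
    spec: DesignSpec,
    span: float = 0.5,
    biotype_filter: bool = True,
    coefficient: str | None = None,
) -> ModeratedResult:
    """Complete-case precision-weighted moderated differential expression."""
    data = prepare_analysis(counts, cohort, spec, complete_case=True, biotype_filter=biotype_filter)
    X = build_design(data.cohort_df, spec, schema=data.schema)
    voom = estimate_precision_weights(data.counts, X, data.norm_factors, span=span)
    fits = fit_weighted(voom)
    coef = coefficient or spec.exposure_columns[-1 if spec.exposure == "interaction" else 0]
    result = ebayes_moderate(fits, coef)
    result.metadata.update(
        {
            "analysis": spec.label,
            "method": "complete_case",
            "n_samples": int(data.counts.n_samples),
            "n_genes": int(data.counts.n_genes),
            "fdr05": result.n_significant_05,
            "fdr10": result.n_significant_10,
        }
    )
    return result


class DifferentialExpressionModel:
    """Precision-weighted moderated linear models on complete cases.

    Parameters
    ----------
    counts
        Gene-level count matrix with biotype annotation.
    cohort
        Sample metadata (exposures + covariates, missing cells NaN).
    spec
        Exposure / covariate-set / stratum specification.
    """

    def __init__(self, counts: CountMatrix, cohort: CohortTable, spec: DesignSpec, span: float = 0.5):
        self.counts = counts
        self.cohort = cohort
        self.spec = spec
        self.span = span

    @classmethod
    def from_fixture(cls, directory, spec: DesignSpec, **kwargs):
        from .io import read_fixture

        cohort, counts, _ = read_fixture(directory)
        return cls(counts, cohort, spec, **kwargs)

    def fit(self) -> ModeratedResult:
        return run_de(self.counts, self.cohort, self.spec, span=self.span)


class MIDifferentialExpressionModel:
    """Gene-binned multiple imputation with Rubin's-rules pooling.

    Genes are shuffled into bins; within each bin the missing covariates are
    multiply imputed by chained equations using the bin's log-CPM values,
    the exposure, and the other covariates as predictors; each completed
    dataset is analysed with the precision-weighted moderated pipeline, and
    the bin's gene coefficients are pooled across imputations by Rubin's
    rules with Barnard-Rubin degrees of freedom.
    """

    def __init__(
        self,
        counts: CountMatrix,
        cohort: CohortTable,
        spec: DesignSpec,
        m_imputations: int = 10,
        bin_size: int = 50,
        max_iter: int = 10,
        span: float = 0.5,
        moderation: str = "within",
    ):
        self.counts = counts
        self.cohort = cohort
        self.spec = spec
        self.m_imputations = m_imputations
        self.bin_size = bin_size
        self.max_iter = max_iter
        self.span = span
        self.moderation = moderation

    def fit(self, seed: int = 0):
        from .impute import mi_de

        return mi_de(
            self.counts,
            self.cohort,
            self.spec,
            m_imputations=self.m_imputations,
            bin_size=self.bin_size,
            max_iter=self.max_iter,
            seed=seed,
            span=self.span,
            moderation=self.moderation,
        )


class SingleImputationDEModel:
    """Iterative random-forest single imputation followed by the
    complete-data pipeline (sensitivity analysis)."""

    def __init__(self, counts: CountMatrix, cohort: CohortTable, spec: DesignSpec,
                 max_iter: int = 10, n_estimators: int = 100, span: float = 0.5):
        self.counts = counts
        self.cohort = cohort
        self.spec = spec
        self.max_iter = max_iter
        self.n_estimators = n_estimators
        self.span = span

    def fit(self, seed: int = 0) -> ModeratedResult:
        from .impute import single_impute

        sub = select_samples(self.cohort, self.spec)
        sub_cohort = CohortTable(sub.copy(), self.cohort.schema)
        completed = single_impute(
            sub_cohort, seed=seed, max_iter=self.max_iter, n_estimators=self.n_estimators
        )
        result = run_de(self.counts, completed, self.spec, span=self.span)
        result.metadata["method"] = "single_imputation"
        return result
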