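"""Design-matrix construction for exposure models.

The covariate sets follow the study's a-priori scheme: confounders (race,
ethnicity, income, household size, education, neighborhood deprivation),
precision variables (fetal sex, gravidity, delivery method, labor type, site,
maternal age, sequencing batch), and potential mediators (pre-pregnancy BMI,
tobacco, alcohol) which are included in the primary model and dropped in the
no-mediators sensitivity variant; gestational age enters only the
gestational-age sensitivity variant. Categorical covariates are dummy coded
against their most frequent level; exposure sums enter untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = ["DesignSpec", "build_design", "RankDeficientError"]

CONFOUNDERS = ("race", "ethnicity", "income", "household_size", "education", "deprivation")
PRECISION = ("fetal_sex", "gravidity", "delivery_method", "labor_type", "site", "maternal_age", "batch")
MEDIATORS = ("bmi", "tobacco", "alcohol")


class RankDeficientError(ValueError):
    """Raised when the design matrix is rank deficient; names aliased columns."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"design matrix is rank deficient; aliased columns: {self.aliased}")


@dataclass(frozen=True)
class DesignSpec:
    """Which exposure, covariates, and stratum a model uses.

    ``exposure`` is ``"sle_sum"``, ``"cte_sum"`` or ``"interaction"`` (both
    sums plus their product). The three covariate toggles map onto the study's
    model variants: primary (mediators in, gestational age out),
    +gestational-age, and no-mediators.
    """

    exposure: str = "sle_sum"
    confounders: tuple[str, ...] = CONFOUNDERS
    precision: tuple[str, ...] = PRECISION
    mediators: tuple[str, ...] = MEDIATORS
    include_mediators: bool = True
    include_gestational_age: bool = False
    stratum: str | None = None  # None | "male" | "female"

    def __post_init__(self):
        if self.exposure not in ("sle_sum", "cte_sum", "interaction"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.stratum not in (None, "male", "female"):
            raise ValueError(f"unknown stratum {self.stratum!r}")
        used = self.covariates
        for col in self.exposure_columns:
            if col in used:
                raise ValueError(f"exposure {col!r} also appears as a covariate")

    @property
    def exposure_columns(self) -> tuple[str, ...]:
        if self.exposure == "interaction":
            return ("sle_sum", "cte_sum", "sle_x_cte")
        return (self.exposure,)

    @property
    def base_exposures(self) -> tuple[str, ...]:
        if self.exposure == "interaction":
            return ("sle_sum", "cte_sum")
        return (self.exposure,)

    @property
    def covariates(self) -> tuple[str, ...]:
        cols = list(self.confounders) + list(self.precision)
        if self.include_mediators:
            cols += list(self.mediators)
        if self.include_gestational_age:
            cols.append("gestational_age")
        if self.stratum is not None and "fetal_sex" in cols:
            cols.remove("fetal_sex")
        return tuple(cols)

    @property
    def used_columns(self) -> tuple[str, ...]:
        return self.base_exposures + self.covariates

    def with_stratum(self, stratum: str | None) -> "DesignSpec":
        return replace(self, stratum=stratum)

    @property
    def label(self) -> str:
        parts = [self.exposure]
        if not self.include_mediators:
            parts.append("no-mediators")
        if self.include_gestational_age:
            parts.append("gestational-age")
        if self.stratum:
            parts.append(self.stratum)
        return "+".join(parts)


def select_samples(cohort: CohortTable, spec: DesignSpec) -> pd.DataFrame:
    """Rows of the cohort usable for this spec: stratum members with the
    exposure observed. Covariates may still be missing (handled by imputation
    or complete-case downstream)."""
    df = cohort.data
    keep = np.ones(len(df), dtype=bool)
    for col in spec.base_exposures:
        keep &= df[col].notna().to_numpy()
    if spec.stratum is not None:
        want = 1.0 if spec.stratum == "male" else 0.0
        keep &= (df["fetal_sex"] == want).to_numpy()
    out = df.loc[keep]
    if spec.stratum is not None and out.empty:
        raise ValueError(f"empty stratum {spec.stratum!r}")
    return out


def build_design(
    data: CohortTable | pd.DataFrame,
    spec: DesignSpec,
    schema=None,
) -> pd.DataFrame:
    """Samples x coefficients design frame: intercept, exposure term(s),
    dummy-coded categoricals (reference = most frequent level), continuous
    covariates untransformed.

    Requires complete data in every used column; raises ``RankDeficientError``
    naming aliased columns when the matrix is not full column rank.
    """
    if isinstance(data, CohortTable):
        schema = schema or data.schema
        df = data.data
    else:
        if schema is None:
            from .cohort import CovariateSchema

            schema = CovariateSchema()
        df = data
    if df.empty:
        raise ValueError("no samples to build a design from")
    used = [c for c in spec.used_columns]
    missing_cols = [c for c in used if c not in df.columns]
    if missing_cols:
        raise KeyError(f"columns absent from cohort: {missing_cols}")
    sub = df[used]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in design columns {bad}; impute or subset first")

    parts: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    for col in spec.base_exposures:
        parts[col] = sub[col].to_numpy(dtype=float)
    if spec.exposure == "interaction":
        parts["sle_x_cte"] = parts["sle_sum"] * parts["cte_sum"]

    categorical = set(schema.categorical)
    for col in spec.covariates:
        if col in categorical:
            counts = sub[col].value_counts()
            ref = counts.index[0]
            for level in counts.index[1:]:
                parts[f"{col}[{level}]"] = (sub[col] == level).to_numpy(dtype=float)
        else:
            parts[col] = sub[col].to_numpy(dtype=float)

    X = pd.DataFrame(parts, index=df.index)
    _check_full_rank(X)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # identify aliased columns by greedy rank growth
    aliased = []
    cur = np.empty((arr.shape[0], 0))
    r = 0
    for j, name in enumerate(X.columns):
        cand = np.column_stack([cur, arr[:, j]])
        rr = np.linalg.matrix_rank(cand)
        if rr > r:
            cur, r = cand, rr
        else:
            aliased.append(name)
    raise RankDeficientError(aliased)
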