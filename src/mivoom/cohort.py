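"""Synthetic pregnancy-cohort generator: covariates, stress exposures, missingness.

The generator emulates the observational structure the differential-expression
pipeline assumes: a table of maternal/fetal covariates with realistic marginals,
two ordinal stress exposures (prenatal stressful life events, SLE, summed 0-14;
maternal childhood traumatic events, CTE, summed over three binary items), a
weak positive rank correlation between them induced by a Gaussian copula on
latent propensities, and per-variable missingness injected either completely at
random (MCAR) or at random given observed data (MAR).

Exposures and covariates are generated jointly complete; missingness is a
separate masking step so that a simulation truth always exists underneath.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _calibration as _cal

__all__ = [
    "CohortTable",
    "CovariateSchema",
    "CovariateParams",
    "MarTerm",
    "gen_covariates",
    "gen_exposures",
    "inject_missingness",
    "simulate_cohort",
    "EXPOSURE_COLUMNS",
    "CTE_ITEM_COLUMNS",
    "STUDY_MISSING_RATES",
]

EXPOSURE_COLUMNS = ("sle_sum", "cte_sum")
CTE_ITEM_COLUMNS = tuple(_cal.CTE_ITEM_NAMES)

#: Per-variable missingness fractions of the study sample (defaults for
#: :func:`inject_missingness`).
STUDY_MISSING_RATES: dict[str, float] = {
    "sle_sum": 0.179,
    "cte_sum": 0.034,
    "maternal_age": 0.019,
    "income": 0.053,
    "deprivation": 0.046,
    "household_size": 0.045,
    "bmi": 0.021,
    "gravidity": 0.008,
    "labor_type": 0.015,
    "race": 0.012,
    "ethnicity": 0.002,
    "education": 0.002,
    "alcohol": 0.008,
    "tobacco": 0.001,
}


@dataclass(frozen=True)
class CovariateSchema:
    """Typing of the cohort columns, used by design building and imputation."""

    continuous: tuple[str, ...] = (
        "maternal_age",
        "bmi",
        "income",
        "gravidity",
        "deprivation",
        "gestational_age",
    )
    binary: tuple[str, ...] = ("fetal_sex", "tobacco", "alcohol")
    categorical: tuple[str, ...] = (
        "race",
        "ethnicity",
        "education",
        "household_size",
        "labor_type",
        "delivery_method",
        "site",
        "batch",
    )
    exposures: tuple[str, ...] = EXPOSURE_COLUMNS
    cte_items: tuple[str, ...] = CTE_ITEM_COLUMNS

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.continuous + self.binary + self.categorical


@dataclass
class CohortTable:
    """Per-sample exposures and covariates with missing cells stored as NaN.

    ``data`` is indexed by unique sample id. The missingness mask is derived
    (``isna``) rather than stored, so masked cells can carry no value by
    construction.
    """

    data: pd.DataFrame
    schema: CovariateSchema = field(default_factory=CovariateSchema)

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("sample ids must be unique")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.schema)

    def validate(self) -> None:
        df = self.data
        if "sle_sum" in df:
            s = df["sle_sum"].dropna()
            if ((s < 0) | (s > _cal.SLE_MAX)).any():
                raise ValueError("sle_sum outside [0, 14]")
        if "cte_sum" in df and all(c in df for c in CTE_ITEM_COLUMNS):
            items = df[list(CTE_ITEM_COLUMNS)]
            full = items.notna().all(axis=1) & df["cte_sum"].notna()
            if not np.allclose(
                df.loc[full, "cte_sum"], items.loc[full].sum(axis=1)
            ):
                raise ValueError("cte_sum != sum of observed cte items")


def _norm(labels: tuple[str, ...], probs: tuple[float, ...]):
    """Categorical level spec, renormalized to sum exactly to 1."""
    p = np.asarray(probs, dtype=float)
    return labels, tuple(p / p.sum())


@dataclass
class CovariateParams:
    """Marginal specification for :func:`gen_covariates`.

    Defaults reproduce the study sample's descriptive statistics: truncated
    normals for age/BMI/deprivation, a truncated lognormal for household
    income, a truncated Poisson for gravidity, and the printed category
    frequencies for the nominal variables. Gestational age and sequencing
    batch are not tabulated in the source and carry plausible conventional
    values.
    """

    # (mean, sd, low, high) truncated normals
    maternal_age: tuple = (27.884, 5.677, 16.0, 43.0)
    bmi: tuple = (27.7, 7.5, 14.0, 62.0)
    deprivation: tuple = (0.171, 0.802, -1.482, 2.804)
    gestational_age: tuple = (38.8, 2.2, 25.0, 42.0)
    # income: lognormal moment-matched to mean 56277, sd 43074, then truncated
    income: tuple = (56277.0, 43074.0, 2493.0, 214975.0)
    # gravidity: Poisson mean, truncated to [0, 12]
    gravidity: tuple = (2.6, 0, 12)

    # binary rates (probability of the "1" level)
    fetal_sex_male: float = 0.499
    tobacco: float = 0.077
    alcohol: float = 0.094

    race: tuple = field(
        default_factory=lambda: _norm(
            ("White", "Black", "Multiple", "Asian", "Other", "AIAN"),
            (0.482, 0.421, 0.057, 0.016, 0.010, 0.004),
        )
    )
    ethnicity: tuple = field(
        default_factory=lambda: _norm(
            ("NotHispanic", "Hispanic"), (0.941, 0.059)
        )
    )
    education: tuple = field(
        default_factory=lambda: _norm(
            ("LessThanHS", "HighSchool", "College", "Graduate"),
            (0.071, 0.396, 0.360, 0.172),
        )
    )
    household_size: tuple = field(
        default_factory=lambda: _norm(
            ("2-3", "4", "5", "6plus"), (0.205, 0.392, 0.236, 0.167)
        )
    )
    labor_type: tuple = field(
        default_factory=lambda: _norm(
            ("Spontaneous", "Augmented", "Induced", "NoLabor"),
            (0.230, 0.279, 0.325, 0.166),
        )
    )
    delivery_method: tuple = field(
        default_factory=lambda: _norm(("Vaginal", "Csection"), (0.617, 0.383))
    )
    site: tuple = field(
        default_factory=lambda: _norm(("SiteA", "SiteB"), (0.746, 0.254))
    )
    batch: tuple = field(
        default_factory=lambda: _norm(
            ("B1", "B2", "B3", "B4"), (0.25, 0.25, 0.25, 0.25)
        )
    )

    def categorical_specs(self) -> dict[str, tuple]:
        return {
            name: getattr(self, name)
            for name in (
                "race",
                "ethnicity",
                "education",
                "household_size",
                "labor_type",
                "delivery_method",
                "site",
                "batch",
            )
        }


def _truncnorm(rng, mean, sd, low, high, n):
    """Truncated normal whose post-truncation mean equals ``mean`` (the
    tabulated statistics describe the observed, range-limited data, so the
    pre-truncation location is solved accordingly)."""
    from scipy.optimize import brentq

    def trunc_mean(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    loc = brentq(lambda l: trunc_mean(l) - mean, low - 10 * sd, high + 10 * sd, xtol=1e-10)
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm.ppf(rng.random(n), a, b, loc=loc, scale=sd)


def gen_covariates(
    n: int,
    params: CovariateParams | None = None,
    seed: int = 0,
) -> CohortTable:
    """Generate ``n`` samples of covariates (exposures absent).

    Deterministic in ``(n, params, seed)``. Raises on negative ``n`` or on a
    categorical probability vector that does not sum to 1 (tolerance 1e-9).
    """
    if n < 0:
        raise ValueError(f"negative sample count: {n}")
    params = params or CovariateParams()
    for name, (labels, probs) in params.categorical_specs().items():
        if len(labels) != len(probs):
            raise ValueError(f"{name}: labels/probabilities length mismatch")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"{name}: category probabilities sum to {sum(probs)!r}, not 1")

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}

    for name in ("maternal_age", "bmi", "deprivation", "gestational_age"):
        mean, sd, low, high = getattr(params, name)
        cols[name] = _truncnorm(rng, mean, sd, low, high, n)

    mean, sd, low, high = params.income
    sigma2 = np.log1p((sd / mean) ** 2)
    sig = np.sqrt(sigma2)
    from scipy.optimize import brentq

    def trunc_lognorm_mean(mu):
        a, b = (np.log(low) - mu) / sig, (np.log(high) - mu) / sig
        # E[exp(X)] for X ~ truncated normal(mu, sig; [log low, log high])
        num = stats.norm.cdf(b - sig) - stats.norm.cdf(a - sig)
        den = stats.norm.cdf(b) - stats.norm.cdf(a)
        return np.exp(mu + sigma2 / 2.0) * num / den

    mu0 = np.log(mean) - sigma2 / 2.0
    mu = brentq(lambda m: trunc_lognorm_mean(m) - mean, mu0 - 3, mu0 + 3, xtol=1e-10)
    a, b = (np.log(low) - mu) / sig, (np.log(high) - mu) / sig
    cols["income"] = np.exp(stats.truncnorm.ppf(rng.random(n), a, b, loc=mu, scale=sig))

    lam, glow, ghigh = params.gravidity
    k = np.arange(glow, ghigh + 1)
    pmf = stats.poisson.pmf(k, lam)
    pmf = pmf / pmf.sum()
    cols["gravidity"] = k[np.searchsorted(np.cumsum(pmf), rng.random(n), side="left").clip(0, len(k) - 1)].astype(float)

    cols["fetal_sex"] = (rng.random(n) < params.fetal_sex_male).astype(float)
    cols["tobacco"] = (rng.random(n) < params.tobacco).astype(float)
    cols["alcohol"] = (rng.random(n) < params.alcohol).astype(float)

    for name, (labels, probs) in params.categorical_specs().items():
        idx = rng.choice(len(labels), size=n, p=np.asarray(probs))
        cols[name] = np.asarray(labels, dtype=object)[idx]

    index = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    df = pd.DataFrame(cols, index=index)
    return CohortTable(df)


def gen_exposures(
    cohort: CohortTable,
    dependence: float = _cal.SLE_CTE_LATENT_CORR,
    seed: int = 0,
) -> CohortTable:
    """Append SLE sum and CTE items/sum drawn from the calibrated copula model.

    ``dependence`` is the Gaussian-copula correlation between the latent SLE
    propensity and each latent CTE item propensity; the default reproduces the
    study's Spearman rho of 0.226 between the two sums.
    """
    if not (-1.0 < dependence < 1.0):
        raise ValueError(f"dependence must lie in (-1, 1), got {dependence}")
    n = cohort.n_samples
    rng = np.random.default_rng(seed)

    r_cc = _cal.CTE_ITEM_LATENT_CORR
    cov = np.eye(4)
    cov[1:, 1:] = np.where(np.eye(3, dtype=bool), 1.0, r_cc)
    cov[0, 1:] = cov[1:, 0] = dependence
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < -1e-10:
        raise ValueError(
            f"dependence={dependence} makes the latent correlation matrix "
            "indefinite given the fixed item-item correlation"
        )

    # SLE marginal: zero-inflated negative binomial truncated to [0, 14]
    k = np.arange(_cal.SLE_MAX + 1)
    pmf = (1 - _cal.SLE_ZINB_PI0) * stats.nbinom.pmf(
        k, _cal.SLE_ZINB_SIZE, _cal.SLE_ZINB_SIZE / (_cal.SLE_ZINB_SIZE + _cal.SLE_ZINB_MU)
    )
    pmf[0] += _cal.SLE_ZINB_PI0
    cdf = np.cumsum(pmf / pmf.sum())

    if n == 0:
        z = np.empty((0, 4))
    else:
        z = rng.multivariate_normal(np.zeros(4), cov, size=n, method="cholesky")
    u = stats.norm.cdf(z[:, 0])
    sle = np.searchsorted(cdf, u, side="left").clip(0, _cal.SLE_MAX)
    thresholds = stats.norm.ppf(1.0 - np.asarray(_cal.CTE_ITEM_RATES))
    items = (z[:, 1:] > thresholds).astype(float)

    out = cohort.copy()
    out.data["sle_sum"] = sle.astype(float)
    for j, name in enumerate(CTE_ITEM_COLUMNS):
        out.data[name] = items[:, j]
    out.data["cte_sum"] = items.sum(axis=1)
    out.validate()
    return out


@dataclass(frozen=True)
class MarTerm:
    """One predictor term of the MAR missingness logit.

    ``column`` names a cohort column or a column of the ``extra`` frame passed
    to :func:`inject_missingness`. For a categorical column ``level`` selects
    the indicator; numeric columns are standardized before applying ``coef``.
    """

    column: str
    coef: float
    level: str | None = None


DEFAULT_MAR_TERMS = (MarTerm("site", 0.5, "SiteB"), MarTerm("fetal_sex", 0.3))


def _mar_linear_predictor(df: pd.DataFrame, terms, extra: pd.DataFrame | None):
    lp = np.zeros(len(df))
    for t in terms:
        if extra is not None and t.column in extra.columns:
            x = extra[t.column].to_numpy(dtype=float)
        elif t.column in df.columns:
            col = df[t.column]
            if t.level is not None:
                x = (col == t.level).to_numpy(dtype=float)
            else:
                x = col.to_numpy(dtype=float)
        else:
            raise KeyError(f"MAR predictor column {t.column!r} not found")
        x = np.nan_to_num(x, nan=float(np.nanmean(x)) if np.isfinite(np.nanmean(x)) else 0.0)
        sd = x.std()
        if t.level is None and sd > 0:
            x = (x - x.mean()) / sd
        lp += t.coef * x
    return lp


def inject_missingness(
    cohort: CohortTable,
    mechanism: str = "MAR",
    rates: dict[str, float] | None = None,
    seed: int = 0,
    terms: tuple[MarTerm, ...] = DEFAULT_MAR_TERMS,
    extra: pd.DataFrame | None = None,
) -> CohortTable:
    """Mask cells of the cohort at the requested per-variable rates.

    ``mechanism='MCAR'`` masks uniformly at random. ``mechanism='MAR'`` draws
    missingness from a logistic model on the (pre-mask, hence observed-at-
    generation) predictor ``terms``, with the intercept calibrated per
    variable so the marginal masked fraction equals the requested rate.
    Masking the key ``cte_sum`` masks the three CTE items together with the
    sum. Exposure columns may be masked; downstream analyses drop such samples
    rather than impute exposures.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    rates = STUDY_MISSING_RATES if rates is None else rates
    for name, rate in rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"rate for {name!r} outside [0, 1]: {rate}")
        if name not in cohort.data.columns:
            raise KeyError(f"no such column to mask: {name!r}")

    out = cohort.copy()
    n = out.n_samples
    if n == 0:
        return out
    rng = np.random.default_rng(seed)

    if mechanism == "MAR":
        lp = _mar_linear_predictor(cohort.data, terms, extra)
    else:
        lp = np.zeros(n)

    from scipy.optimize import brentq
    from scipy.special import expit

    for name, rate in rates.items():
        if rate == 0.0:
            continue
        if mechanism == "MCAR" or np.allclose(lp, 0.0):
            p = np.full(n, rate)
        else:
            # calibrate intercept so mean(sigmoid(a + lp)) == rate
            f = lambda a: expit(a + lp).mean() - rate
            a = brentq(f, -40.0, 40.0)
            p = expit(a + lp)
        mask = rng.random(n) < p
        targets = [name]
        if name == "cte_sum":
            targets += list(CTE_ITEM_COLUMNS)
        for col in targets:
            out.data.loc[mask, col] = np.nan
    return out


def simulate_cohort(
    n: int,
    params: CovariateParams | None = None,
    dependence: float = _cal.SLE_CTE_LATENT_CORR,
    missing: bool = True,
    mechanism: str = "MAR",
    rates: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[CohortTable, CohortTable]:
    """Convenience driver: covariates + exposures, returning (complete, masked).

    The complete table is the simulation truth; the masked table is what the
    analysis sees. With ``missing=False`` both are identical.
    """
    complete = gen_exposures(
        gen_covariates(n, params, seed=seed), dependence=dependence, seed=seed + 1
    )
    if not missing:
        return complete, complete.copy()
    masked = inject_missingness(
        complete, mechanism=mechanism, rates=rates, seed=seed + 2
    )
    return complete, masked
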