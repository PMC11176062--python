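"""Gene binning, chained-equation MI, Rubin pooling, RF single imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mivoom as mv
from mivoom.cohort import CohortTable, inject_missingness
from mivoom.impute import (
    bin_genes,
    impute_bin,
    rank_concordance,
    rubin_pool,
    single_impute,
)


class TestBinGenes:
    def test_exact_division(self):
        bins = bin_genes([f"g{i}" for i in range(100)], bin_size=50, seed=1)
        assert [len(b) for b in bins] == [50, 50]

    def test_remainder_bin(self):
        bins = bin_genes([f"g{i}" for i in range(101)], bin_size=50, seed=1)
        assert [len(b) for b in bins] == [50, 50, 1]

    def test_partition_property_and_determinism(self):
        genes = [f"g{i}" for i in range(137)]
        a = bin_genes(genes, bin_size=10, seed=3)
        b = bin_genes(genes, bin_size=10, seed=3)
        assert all(list(x) == list(y) for x, y in zip(a, b))
        flat = [g for chunk in a for g in chunk]
        assert sorted(flat) == sorted(genes)

    def test_bad_bin_size(self):
        with pytest.raises(ValueError):
            bin_genes(["a"], bin_size=0)


class TestImputeBin:
    def test_no_missing_is_identity(self, complete_cohort):
        out = impute_bin(complete_cohort, None, m_imputations=3, seed=1)
        assert out.m == 3
        for completed in out.completed:
            pd.testing.assert_frame_equal(completed, complete_cohort.data)

    def test_observed_cells_never_modified(self, masked_cohort):
        out = impute_bin(masked_cohort, None, m_imputations=2, max_iter=2, seed=2)
        obs = masked_cohort.data.notna()
        for completed in out.completed:
            for col in masked_cohort.data.columns:
                o = obs[col]
                assert (completed.loc[o, col] == masked_cohort.data.loc[o, col]).all()
            # every covariate cell is filled; masked exposures stay untouched
            covars = [c for c in masked_cohort.schema.covariates if c in completed]
            assert completed[covars].notna().all().all()
            assert completed["sle_sum"].isna().equals(masked_cohort.data["sle_sum"].isna())

    def test_mcar_mean_preserved(self):
        complete, _ = mv.simulate_cohort(500, missing=False, seed=5)
        masked = inject_missingness(
            complete, "MCAR", rates={"maternal_age": 0.2}, seed=6
        )
        out = impute_bin(masked, None, m_imputations=4, max_iter=3, seed=7)
        obs = masked.data["maternal_age"].dropna()
        mis_mask = masked.data["maternal_age"].isna()
        imputed = np.concatenate(
            [c.loc[mis_mask, "maternal_age"].to_numpy() for c in out.completed]
        )
        se = obs.std() / np.sqrt(mis_mask.sum())
        assert abs(imputed.mean() - obs.mean()) < 3 * se

    def test_requires_m_at_least_two(self, masked_cohort):
        with pytest.raises(ValueError, match="M >= 2"):
            impute_bin(masked_cohort, None, m_imputations=1)

    def test_determinism(self, masked_cohort):
        a = impute_bin(masked_cohort, None, m_imputations=2, max_iter=2, seed=9)
        b = impute_bin(masked_cohort, None, m_imputations=2, max_iter=2, seed=9)
        for x, y in zip(a.completed, b.completed):
            pd.testing.assert_frame_equal(x, y)


class TestRubinPool:
    def test_hand_arithmetic(self):
        out = rubin_pool(np.array([[1.0], [2.0], [3.0]]), np.ones((3, 1)), 100.0)
        assert out["qbar"][0] == pytest.approx(2.0, abs=1e-12)
        assert out["b_between"][0] == pytest.approx(1.0, abs=1e-12)
        assert out["t_var"][0] == pytest.approx(1.0 + (4.0 / 3.0), abs=1e-12)

    def test_identical_fits_reduce_to_single_fit(self):
        est = np.tile([1.5, -0.2], (4, 1))
        var = np.tile([0.25, 0.04], (4, 1))
        out = rubin_pool(est, var, 50.0)
        assert np.allclose(out["b_between"], 0.0, atol=1e-14)
        assert np.allclose(out["t_var"], var[0], atol=1e-14)
        assert np.allclose(out["t"], est[0] / np.sqrt(var[0]), atol=1e-12)
        # nu tends to the (Barnard-Rubin capped) complete-data value
        assert np.allclose(out["nu"], (51.0 / 53.0) * 50.0, atol=1e-9)

    def test_nu_monotone_decreasing_in_missing_information(self):
        nus = []
        for b in [0.0, 0.01, 0.05, 0.2, 1.0, 5.0]:
            est = np.array([[0.0], [np.sqrt(b)], [-np.sqrt(b)]]) * np.sqrt(1.5)
            out = rubin_pool(est + 1.0, np.ones((3, 1)), 100.0)
            nus.append(out["nu"][0])
        assert all(x >= y - 1e-9 for x, y in zip(nus, nus[1:]))

    def test_total_variance_at_least_within(self):
        rng = np.random.default_rng(0)
        est = rng.normal(size=(5, 40))
        var = rng.uniform(0.1, 1.0, size=(5, 40))
        out = rubin_pool(est, var, 30.0)
        assert (out["t_var"] >= out["ubar"] - 1e-12).all()
        assert (out["t_var"] > out["ubar"]).all()  # imputations disagree

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError, match="M >= 2"):
            rubin_pool(np.ones((1, 3)), np.ones((1, 3)), 10.0)


class TestSingleImpute:
    def test_no_missing_identity(self, complete_cohort):
        out = single_impute(complete_cohort, seed=1)
        pd.testing.assert_frame_equal(out.data, complete_cohort.data)

    def test_deterministic(self, masked_cohort):
        a = single_impute(masked_cohort, seed=2, n_estimators=20, max_iter=2)
        b = single_impute(masked_cohort, seed=2, n_estimators=20, max_iter=2)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_recovers_deterministic_relationship(self):
        """A covariate that is an exact linear function of another is
        recovered with high fidelity."""
        complete, _ = mv.simulate_cohort(500, missing=False, seed=3)
        truth_dep = 0.1 * complete.data["maternal_age"] - 2.0
        complete.data["deprivation"] = truth_dep
        masked = inject_missingness(
            complete, "MCAR", rates={"deprivation": 0.2}, seed=4
        )
        out = single_impute(masked, seed=5, n_estimators=50, max_iter=3)
        mis = masked.data["deprivation"].isna()
        r = np.corrcoef(out.data.loc[mis, "deprivation"], truth_dep[mis])[0, 1]
        assert r > 0.95


class TestRankConcordance:
    def _tab(self, p):
        return pd.DataFrame({"p": p}, index=[f"g{i}" for i in range(len(p))])

    def test_identical_results(self):
        t = self._tab([0.1, 0.5, 0.01])
        assert rank_concordance(t, t) == pytest.approx(1.0)

    def test_reversed_order(self):
        a = self._tab([0.1, 0.2, 0.3, 0.4])
        b = self._tab([0.4, 0.3, 0.2, 0.1])
        assert rank_concordance(a, b) == pytest.approx(-1.0)

    def test_disjoint_gene_sets_rejected(self):
        a = self._tab([0.1])
        b = pd.DataFrame({"p": [0.2]}, index=["other"])
        with pytest.raises(ValueError, match="no genes"):
            rank_concordance(a, b)
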