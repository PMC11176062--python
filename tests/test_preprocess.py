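"""Filtering, log-CPM arithmetic, and TMM normalization oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mivoom as mv
from mivoom.counts import CountMatrix
from mivoom.preprocess import (
    NormFactors,
    filter_by_biotype,
    filter_low_expression,
    log_cpm,
    tmm_factors,
)


def _cm(arr, biotypes=None):
    arr = np.asarray(arr)
    genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    bt = pd.Series(biotypes, index=genes) if biotypes is not None else None
    return CountMatrix(arr, genes, samples, biotype=bt)


class TestBiotypeFilter:
    def test_mixed_annotation(self):
        cm = _cm(
            np.ones((5, 2), dtype=int),
            ["protein_coding", "protein_coding", "lncRNA", "rRNA", "processed_pseudogene"],
        )
        out = filter_by_biotype(cm)
        assert out.n_genes == 4
        assert "g3" not in out.gene_ids

    def test_all_protein_coding_identity(self):
        cm = _cm(np.arange(10).reshape(5, 2), ["protein_coding"] * 5)
        out = filter_by_biotype(cm)
        assert np.array_equal(out.counts, cm.counts)

    def test_empty_allowed_set_rejected(self):
        cm = _cm(np.ones((2, 2), dtype=int), ["protein_coding"] * 2)
        with pytest.raises(ValueError, match="empty"):
            filter_by_biotype(cm, allowed=set())


class TestLogCpm:
    def test_zero_count_closed_form(self):
        arr = np.array([[0]])
        out = log_cpm(arr, lib_size=np.array([1e6 - 1.0]))
        assert out[0, 0] == pytest.approx(np.log2(0.5 / 1e6 * 1e6), abs=1e-12)
        assert out[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_count_999_closed_form(self):
        out = log_cpm(np.array([[999]]), lib_size=np.array([1e6 - 1.0]))
        assert out[0, 0] == pytest.approx(np.log2(999.5), abs=1e-12)

    def test_depth_scale_invariance(self):
        arr = np.array([[10, 20], [5, 40]])
        lib = arr.sum(axis=0).astype(float)
        a = log_cpm(arr, lib_size=lib)
        b = log_cpm(2 * arr, lib_size=2 * lib)
        # doubling counts and library sizes leaves log-CPM nearly unchanged
        # (exactly, up to the fixed pseudo-count)
        assert np.allclose(a, b, atol=0.15)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            log_cpm(np.array([[1]]), lib_size=np.array([0.0]))


class TestExpressionFilter:
    def test_boundary_retained(self):
        logcpm = np.array([[-1.0, 1.0]])
        assert filter_low_expression(logcpm).tolist() == [True]

    def test_all_zero_gene_removed(self):
        # an all-zero gene has logCPM = log2(0.5e6 / (lib + 1)) < 0 once the
        # library exceeds half a million reads
        arr = np.array([[0, 0], [1_000_000, 2_000_000]])
        out = log_cpm(arr)
        keep = filter_low_expression(out)
        assert keep.tolist() == [False, True]

    def test_minus_inf_threshold_keeps_all(self):
        logcpm = np.array([[-100.0, -50.0], [1.0, 2.0]])
        assert filter_low_expression(logcpm, threshold=-np.inf).all()

    def test_idempotent(self, small_counts):
        counts, _ = small_counts
        E = log_cpm(counts)
        keep = filter_low_expression(E)
        E2 = E[keep]
        assert filter_low_expression(E2).all()


def _naive_tmm(mat, lib, trim_m=0.3, trim_a=0.05):
    """Independent step-by-step reimplementation of the trimmed weighted mean."""
    n = mat.shape[1]
    q75 = [np.quantile(mat[:, j] / lib[j], 0.75) for j in range(n)]
    ref = int(np.argmin(np.abs(np.array(q75) - np.mean(q75))))
    logf = []
    for j in range(n):
        rows = []
        for g in range(mat.shape[0]):
            y, r = mat[g, j], mat[g, ref]
            if y > 0 and r > 0:
                m = np.log2((y / lib[j]) / (r / lib[ref]))
                a = 0.5 * np.log2((y / lib[j]) * (r / lib[ref]))
                w = (lib[j] - y) / (lib[j] * y) + (lib[ref] - r) / (lib[ref] * r)
                rows.append((m, a, w))
        if not rows:
            logf.append(0.0)
            continue
        ms = np.array([r[0] for r in rows])
        if np.abs(ms).max() < 1e-6:
            logf.append(0.0)
            continue
        aa = np.array([r[1] for r in rows])
        ww = np.array([r[2] for r in rows])
        k = len(rows)
        rm = pd.Series(ms).rank().to_numpy()
        ra = pd.Series(aa).rank().to_numpy()
        lo_m, hi_m = np.floor(k * trim_m) + 1, k - np.floor(k * trim_m)
        lo_a, hi_a = np.floor(k * trim_a) + 1, k - np.floor(k * trim_a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            logf.append(0.0)
            continue
        logf.append(np.sum(ms[keep] / ww[keep]) / np.sum(1.0 / ww[keep]))
    logf = np.array(logf) - np.mean(logf)
    return 2.0 ** logf


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 100, 7, 3, 50, 20, 1, 9, 30])
        mat = np.column_stack([col, col, col])
        nf = tmm_factors(mat)
        assert np.allclose(nf.factors, 1.0, atol=1e-12)

    def test_pure_depth_difference(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 500, 200)
        mat = np.column_stack([a, 2 * a])
        nf = tmm_factors(mat)
        assert np.allclose(nf.factors, 1.0, atol=1e-10)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        mat = rng.integers(0, 800, size=(10, 3))
        mat[0] = [500, 20, 30]  # force some asymmetry
        lib = mat.sum(axis=0).astype(float)
        nf = tmm_factors(mat)
        expected = _naive_tmm(mat, lib)
        assert np.allclose(nf.factors, expected, atol=1e-10)

    def test_single_sample_warns_unit(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            nf = tmm_factors(np.array([[5], [10]]))
        assert nf.factors.tolist() == [1.0]

    def test_invariant_to_gene_order_and_zero_genes(self):
        rng = np.random.default_rng(3)
        mat = rng.negative_binomial(2, 0.01, size=(50, 4))
        lib = mat.sum(axis=0).astype(float)
        base = tmm_factors(mat, lib_size=lib).factors
        perm = rng.permutation(50)
        assert np.allclose(tmm_factors(mat[perm], lib_size=lib).factors, base, atol=1e-12)
        padded = np.vstack([mat, np.zeros((5, 4), dtype=int)])
        assert np.allclose(tmm_factors(padded, lib_size=lib).factors, base, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_geometric_mean_one_property(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.negative_binomial(2, 0.02, size=(30, rng.integers(2, 6)))
        mat[0, :] += 1  # avoid all-zero pairs
        nf = tmm_factors(mat)
        assert abs(np.log(nf.factors).mean()) < 1e-12
        assert (nf.factors > 0).all()


def test_norm_factors_validation():
    with pytest.raises(ValueError, match="geometric mean"):
        NormFactors(np.array([2.0, 2.0]), reference=0)
    with pytest.raises(ValueError, match="positive"):
        NormFactors(np.array([-1.0, 1.0]), reference=0)
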