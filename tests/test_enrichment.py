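"""Enrichment methods: exact oracles, planted-set recovery, stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mivoom as mv
from mivoom.counts import CountMatrix, gen_counts, make_truth
from mivoom.design import build_design
from mivoom.enrichment import (
    GeneSetCollection,
    camera_test,
    combine_pvalues,
    ensemble_run,
    gage_like,
    ora,
    read_gmt,
    score_based_tests,
    stratified_enrichment,
    write_gmt,
)
from mivoom.model import prepare_analysis
from mivoom.preprocess import log_cpm


class TestGmt:
    def test_toy_parse(self, tmp_path):
        p = tmp_path / "toy.gmt"
        p.write_text("SET_A\tdesc\tg1\tg2\tg3\nSET_B\tdesc\tg2\tg4\n")
        coll = read_gmt(p)
        assert set(coll.sets) == {"SET_A", "SET_B"}
        assert coll.sets["SET_B"] == frozenset({"g2", "g4"})

    def test_duplicate_member_stored_once(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("S\tdesc\tg1\tg1\tg2\n")
        assert read_gmt(p).sets["S"] == frozenset({"g1", "g2"})

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection("c", {"A": frozenset("xyz"), "B": frozenset("pq")})
        path = tmp_path / "rt.gmt"
        write_gmt(coll, path)
        assert read_gmt(path).sets == coll.sets

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("GOOD\tdesc\tg1\nBADLINE\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(p)


class TestOra:
    def test_exact_small_case(self):
        universe = [f"g{i}" for i in range(10)]
        p = pd.Series(np.linspace(0.01, 0.9, 10), index=universe)
        members = universe[:5]  # the five smallest p-values
        out = ora(p, members, universe, top_k=5)
        assert out == pytest.approx(1.0 / 252.0, rel=1e-12)

    def test_zero_overlap_gives_one(self):
        universe = [f"g{i}" for i in range(10)]
        p = pd.Series(np.linspace(0.01, 0.9, 10), index=universe)
        out = ora(p, universe[5:], universe, top_k=5)
        assert out == pytest.approx(1.0, rel=1e-9)

    def test_matches_combinatorial_enumeration(self):
        """Brute force: enumerate all top-k subsets equally likely under the
        null and count overlap >= observed."""
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(12)]
        p = pd.Series(rng.random(12), index=universe)
        members = frozenset(rng.choice(universe, 5, replace=False))
        k = 4
        top = frozenset(p.nsmallest(k).index)
        observed = len(members & top)
        total = hits = 0
        for subset in itertools.combinations(universe, k):
            total += 1
            if len(members & frozenset(subset)) >= observed:
                hits += 1
        assert ora(p, members, universe, top_k=k) == pytest.approx(hits / total, rel=1e-9)

    def test_set_larger_than_universe_rejected(self):
        p = pd.Series([0.1], index=["g0"])
        with pytest.raises(ValueError, match="larger"):
            ora(p, ["g0", "g1"], ["g0"])


class TestCamera:
    def test_all_equal_stats_give_p_one(self):
        z = pd.Series(np.ones(20), index=[f"g{i}" for i in range(20)])
        p, sign = camera_test(z, [f"g{i}" for i in range(5)])
        assert p == pytest.approx(1.0)
        assert sign == 0.0

    def test_zero_correlation_matches_naive_two_group(self):
        rng = np.random.default_rng(3)
        z = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
        members = [f"g{i}" for i in range(7)]
        p, _ = camera_test(z, members, intergene_correlation=0.0)
        # naive: pooled-variance two-sample comparison on G-2 df
        a = z.iloc[:7].to_numpy()
        b = z.iloc[7:].to_numpy()
        s2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (40 - 2)
        t = (a.mean() - b.mean()) / np.sqrt(s2 * (1 / 7 + 1 / 33))
        expected = 2 * stats.t.sf(abs(t), 38)
        assert p == pytest.approx(expected, abs=1e-10)

    def test_hand_computed_vif(self):
        vals = np.array([2.0, 1.5, 1.0, 0.5, 0.0, -0.5, -1.0, 0.3, -0.3, 0.8])
        z = pd.Series(vals, index=[f"g{i}" for i in range(10)])
        members = ["g0", "g1", "g2"]
        rho = 0.1
        p, sign = camera_test(z, members, intergene_correlation=rho)
        m, G = 3, 10
        vif = 1 + (m - 1) * rho
        a, b = vals[:3], vals[3:]
        s2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (G - 2)
        t = (a.mean() - b.mean()) / np.sqrt(s2 * (vif / m + 1 / (G - m)))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), G - 2), abs=1e-12)
        assert sign == 1.0

    def test_tiny_set_rejected(self):
        z = pd.Series(np.arange(5.0), index=list("abcde"))
        with pytest.raises(ValueError, match="at least 2"):
            camera_test(z, ["a"])


class TestGage:
    def test_matches_textbook_welch(self):
        vals = np.array([3.0, 2.5, 2.8, 0.1, -0.2, 0.3, 0.0, -0.1])
        z = pd.Series(vals, index=[f"g{i}" for i in range(8)])
        a, b = vals[:3], vals[3:]
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 5
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 4)
        expected = 2 * stats.t.sf(abs(t), df)
        assert gage_like(z, [f"g{i}" for i in range(3)]) == pytest.approx(expected, rel=1e-10)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=100)
        vals[:15] += 3.0
        z = pd.Series(vals, index=[f"g{i}" for i in range(100)])
        assert gage_like(z, [f"g{i}" for i in range(15)]) < 1e-6


class TestScoreTests:
    def _context(self):
        complete, _ = mv.simulate_cohort(120, missing=False, seed=51)
        truth = make_truth(n_genes=60, sle_effects=(), seed=52)
        counts = gen_counts(complete, truth, seed=53)
        spec = mv.DesignSpec(exposure="sle_sum")
        data = prepare_analysis(counts, complete, spec, complete_case=True)
        X = build_design(data.cohort_df, spec, schema=data.schema)
        E = pd.DataFrame(
            log_cpm(data.counts, data.norm_factors),
            index=data.counts.gene_ids,
            columns=data.counts.sample_ids,
        )
        return E, X

    def test_single_gene_set_equals_single_gene_lm(self):
        E, X = self._context()
        gene = E.index[5]
        out = score_based_tests(E, X, [gene], "sle_sum")
        # with m=1 the z-score equals the standardized gene itself
        from mivoom.enrichment import _exposure_regression_p

        row = E.loc[gene].to_numpy()
        std = (row - row.mean()) / row.std(ddof=1)
        expected = _exposure_regression_p(std, X, "sle_sum")
        assert out["zscore"] == pytest.approx(expected, rel=1e-12)

    def test_plage_sign_convention(self):
        E, X = self._context()
        members = list(E.index[:8])
        sub = E.loc[members]
        Z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
        u, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
        score = vt[0]
        if np.corrcoef(score, sub.mean(axis=0))[0, 1] < 0:
            score = -score
        assert np.corrcoef(score, sub.mean(axis=0))[0, 1] > 0


class TestCombine:
    def test_fisher_half_half(self):
        assert combine_pvalues([0.5, 0.5], rule="fisher") == pytest.approx(0.5966, abs=5e-4)

    def test_single_p_identity(self):
        assert combine_pvalues([0.37], rule="fisher") == pytest.approx(0.37, rel=1e-12)
        assert combine_pvalues([0.37], rule="wilkinson") == pytest.approx(0.37, rel=1e-12)

    def test_wilkinson_closed_form(self):
        assert combine_pvalues([0.1, 0.1, 0.1], rule="wilkinson") == pytest.approx(0.271, abs=1e-12)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = combine_pvalues([0.0, 0.5], rule="fisher")
        assert 0.0 < out < 1e-10


class TestEnsemble:
    def test_planted_set_ranks_first(self):
        """A coordinately upregulated set tops the ranking in >= 9/10 seeds."""
        wins = 0
        for s in range(10):
            complete, _ = mv.simulate_cohort(250, missing=False, seed=600 + s)
            truth = make_truth(n_genes=300, sle_effects=(0.12,) * 25, seed=700 + s)
            counts = gen_counts(complete, truth, seed=800 + s)
            spec = mv.DesignSpec(exposure="sle_sum")
            res = mv.run_de(counts, complete, spec)
            planted = frozenset(truth.effect_genes) & frozenset(res.table.index)
            rng = np.random.default_rng(900 + s)
            genes = np.asarray(res.table.index)
            sets = {"PLANTED": planted}
            for i in range(20):
                sets[f"R{i}"] = frozenset(rng.choice(genes, 25, replace=False))
            tab = ensemble_run(
                res, GeneSetCollection("toy", sets),
                methods=("ora", "camera", "gage"),
            )
            if tab.index[0] == "PLANTED":
                wins += 1
                assert tab.loc["PLANTED", "mean_logfc"] > 0  # sign consistency
        assert wins >= 9

    def test_empty_after_filtering_rejected(self, de_result):
        coll = GeneSetCollection("tiny", {"S": frozenset(["g1", "g2"])})
        with pytest.raises(ValueError, match="empty"):
            ensemble_run(de_result, coll, methods=("camera",), min_size=10)

    def test_member_counts_within_bounds(self, de_result):
        rng = np.random.default_rng(1)
        genes = np.asarray(de_result.table.index)
        sets = {f"S{i}": frozenset(rng.choice(genes, size, replace=False))
                for i, size in enumerate([5, 15, 60, 200])}
        tab = ensemble_run(
            de_result, GeneSetCollection("c", sets),
            methods=("camera", "gage"), min_size=10, max_size=100,
        )
        assert tab["m"].between(10, 100).all()
        assert len(tab) == 2  # the size-5 and size-200 sets are dropped


class TestStratified:
    def _sex_counts(self, opposite: bool, seed: int):
        """Counts where the first 20 genes respond to SLE with equal or
        opposite sign in the two fetal-sex strata."""
        complete, _ = mv.simulate_cohort(400, missing=False, seed=seed)
        df = complete.data
        male = df["fetal_sex"] == 1.0
        truth_m = make_truth(n_genes=200, sle_effects=(0.25,) * 20, seed=seed + 1)
        truth_f = make_truth(n_genes=200, sle_effects=((-0.25 if opposite else 0.25),) * 20, seed=seed + 1)
        co_m = mv.CohortTable(df.loc[male].copy(), complete.schema)
        co_f = mv.CohortTable(df.loc[~male].copy(), complete.schema)
        cm = gen_counts(co_m, truth_m, seed=seed + 2)
        cf = gen_counts(co_f, truth_f, seed=seed + 3)
        counts = CountMatrix(
            np.column_stack([cm.counts, cf.counts]),
            cm.gene_ids,
            cm.sample_ids.append(cf.sample_ids),
            cm.biotype,
        )
        planted = frozenset(truth_m.effect_genes)
        rng = np.random.default_rng(seed + 4)
        sets = {"PLANTED": planted}
        for i in range(10):
            sets[f"R{i}"] = frozenset(rng.choice(np.asarray(cm.gene_ids), 20, replace=False))
        reordered = counts.subset_samples(df.index)
        return reordered, complete, GeneSetCollection("toy", sets)

    def test_opposite_effect_flagged_discordant(self):
        counts, cohort, coll = self._sex_counts(opposite=True, seed=70)
        spec = mv.DesignSpec(exposure="sle_sum")
        results, conc = stratified_enrichment(
            counts, cohort, spec, coll, methods=("camera", "gage"), min_size=5
        )
        assert set(results) == {"male", "female"}
        assert "PLANTED" in conc.index
        assert not conc.loc["PLANTED", "concordant"]

    def test_homogeneous_effect_concordant(self):
        counts, cohort, coll = self._sex_counts(opposite=False, seed=80)
        spec = mv.DesignSpec(exposure="sle_sum")
        results, conc = stratified_enrichment(
            counts, cohort, spec, coll, methods=("camera", "gage"), min_size=5
        )
        assert conc.loc["PLANTED", "concordant"]

    def test_stratum_results_independent_of_other_stratum(self):
        counts, cohort, coll = self._sex_counts(opposite=False, seed=90)
        spec = mv.DesignSpec(exposure="sle_sum")
        results, _ = stratified_enrichment(
            counts, cohort, spec, coll, methods=("camera", "gage"), min_size=5
        )
        # scramble the female samples' counts; male results must not move
        df = cohort.data
        female_idx = np.flatnonzero((df["fetal_sex"] == 0.0).to_numpy())
        rng = np.random.default_rng(0)
        scrambled = counts.counts.copy()
        scrambled[:, female_idx] = rng.permutation(scrambled[:, female_idx], axis=0)
        counts2 = CountMatrix(scrambled, counts.gene_ids, counts.sample_ids, counts.biotype)
        results2, _ = stratified_enrichment(
            counts2, cohort, spec, coll, methods=("camera", "gage"), min_size=5
        )
        pd.testing.assert_frame_equal(results["male"], results2["male"])
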