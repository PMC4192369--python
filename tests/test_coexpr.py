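"""Guilt-by-association machinery: probe concordance, top-K correlate
lists, overlap permutation tests, and the cis/trans eQTL scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genecross import coexpr, synth


class TestProbeConcordance:
    def test_planted_concordant_probes_recovered(self):
        # focal gene with 6 module-driven and 11 independent probes: the
        # clique filter returns exactly the 6 planted probes in >= 90%
        # of replicates
        exact = 0
        for s in range(20):
            spec = synth.ExprSimSpec(
                n_strains=70, n_genes=10, module_genes=frozenset({"G0000"}),
                module_r=0.85, n_noise_probes=11, focal_probes=6, seed=100 + s,
            )
            expr, probes = synth.gen_expression(spec)
            planted = probes[
                (probes["gene_id"] == "G0000") & (probes["target_class"] != "intron")
            ]["probe_id"].tolist()
            got, _, flag = coexpr.probe_concordance(expr, probes, "G0000")
            exact += got == sorted(planted)
        assert exact >= 18

    def test_identical_probes_both_retained(self):
        strains = [f"s{i}" for i in range(10)]
        row = np.arange(10.0)
        expr = pd.DataFrame([row, row], index=["p1", "p2"], columns=strains)
        probes = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": "g", "target_class": "exon"})
        got, table, flag = coexpr.probe_concordance(expr, probes, "g")
        assert got == ["p1", "p2"] and flag == "ok"
        assert table["r"].iloc[0] == pytest.approx(1.0)

    def test_single_probe_untestable(self):
        expr = pd.DataFrame([np.arange(8.0)], index=["p1"], columns=[f"s{i}" for i in range(8)])
        probes = pd.DataFrame({"probe_id": ["p1"], "gene_id": "g", "target_class": "exon"})
        got, _, flag = coexpr.probe_concordance(expr, probes, "g")
        assert got == ["p1"] and flag == "untestable"

    def test_independent_probes_give_singleton(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 70)), index=[f"p{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(70)])
        probes = pd.DataFrame({"probe_id": [f"p{i}" for i in range(5)],
                               "gene_id": "g", "target_class": "exon"})
        got, _, flag = coexpr.probe_concordance(expr, probes, "g")
        assert len(got) == 1 and flag == "singleton"

    def test_pair_table_mirrors_upper_triangle(self, small_expression):
        expr, probes, module = small_expression
        _, table, _ = coexpr.probe_concordance(expr, probes, module[0])
        n = (probes["gene_id"] == module[0]).sum()
        assert len(table) == n * (n - 1) // 2


class TestTopKCorrelates:
    def test_full_ranking_excludes_focal(self, small_expression):
        expr, probes, _ = small_expression
        focal = expr.index[0]
        out = coexpr.top_k_correlates(expr, focal, k=len(expr) - 1)
        assert len(out) == len(expr) - 1 and focal not in out

    def test_module_probes_occupy_top_ranks(self):
        hits = 0
        for s in range(10):
            module = frozenset({"G0000", "G0001", "G0002", "G0003"})
            spec = synth.ExprSimSpec(
                n_strains=70, n_genes=40, probes_per_gene=2,
                module_genes=module, module_r=0.85, n_noise_probes=0,
                focal_probes=2, seed=200 + s,
            )
            expr, probes = synth.gen_expression(spec)
            mod_probes = set(probes[probes["gene_id"].isin(module)]["probe_id"])
            focal = sorted(mod_probes)[0]
            top = coexpr.top_k_correlates(expr, focal, k=2 * len(mod_probes))
            hits += (mod_probes - {focal}) <= set(top)
        assert hits >= 9

    @given(scale=st.floats(0.1, 20.0), shift=st.floats(-50.0, 50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_to_positive_affine_transform(self, scale, shift):
        rng = np.random.default_rng(77)
        expr = pd.DataFrame(rng.normal(size=(12, 30)), index=[f"p{i:02d}" for i in range(12)])
        base = coexpr.top_k_correlates(expr, "p00", k=5)
        expr2 = expr.copy()
        expr2.loc["p00"] = scale * expr2.loc["p00"] + shift
        assert coexpr.top_k_correlates(expr2, "p00", k=5) == base

    def test_zero_variance_probe_excluded(self, caplog):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(4, 20)), index=list("abcd"))
        expr.loc["c"] = 3.0
        with caplog.at_level("WARNING"):
            out = coexpr.top_k_correlates(expr, "a", k=2)
        assert "c" not in out and "zero-variance" in caplog.text

    def test_k_too_large_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 10)), index=list("abcd"))
        with pytest.raises(ValueError):
            coexpr.top_k_correlates(expr, "a", k=4)


class TestIntersectLists:
    def test_identical_and_disjoint(self):
        a = ["x", "y", "z"]
        assert coexpr.intersect_lists([a, list(a)])[0] == sorted(a)
        assert coexpr.intersect_lists([a, ["q"]])[0] == []

    def test_gene_mapping_deduplicates(self):
        probes = pd.DataFrame(
            {"probe_id": ["p1", "p2", "p3"], "gene_id": ["g1", "g1", "g2"],
             "target_class": "exon"}
        )
        common, genes = coexpr.intersect_lists([["p1", "p2"], ["p2", "p1"]], probes)
        assert common == ["p1", "p2"] and genes == ["g1"]

    def test_single_list_rejected(self):
        with pytest.raises(ValueError):
            coexpr.intersect_lists([["a"]])


class TestMultiListOverlap:
    def test_zero_observed_gives_p_one(self):
        res = coexpr.multi_list_overlap_p(3, 5, 100, 0, n_perm=500, seed=1)
        assert res.p_emp == 1.0

    def test_two_list_sizes_match_hypergeometric_pmf(self):
        # tiny case: intersection of two random 3-subsets of [6] is
        # Hypergeom(6, 3, 3); chi-squared goodness of fit over 1e5 draws
        rng = np.random.default_rng(12)
        sizes = coexpr.intersection_sizes(2, 3, 6, 100_000, rng)
        observed = np.bincount(sizes, minlength=4)
        expected = stats.hypergeom.pmf(np.arange(4), 6, 3, 3) * 100_000
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=3) > 0.001

    def test_sequential_draws_match_brute_force(self):
        # TV distance between the sequential simulator and explicit subset
        # sampling on a small instance
        n_lists, k, N, n = 3, 5, 12, 100_000
        rng = np.random.default_rng(3)
        seq = coexpr.intersection_sizes(n_lists, k, N, n, rng)
        keys = rng.random((n, n_lists, N))
        tops = np.argpartition(keys, k - 1, axis=2)[:, :, :k]
        brute = np.empty(n, dtype=int)
        for i in range(n):
            common = set(tops[i, 0])
            for j in range(1, n_lists):
                common &= set(tops[i, j])
            brute[i] = len(common)
        f_seq = np.bincount(seq, minlength=k + 1) / n
        f_bru = np.bincount(brute, minlength=k + 1) / n
        assert 0.5 * np.abs(f_seq - f_bru).sum() < 0.02

    def test_seed_determinism(self):
        a = coexpr.multi_list_overlap_p(4, 10, 50, 2, n_perm=2000, seed=9)
        b = coexpr.multi_list_overlap_p(4, 10, 50, 2, n_perm=2000, seed=9)
        assert a.p_emp == b.p_emp

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            coexpr.multi_list_overlap_p(2, 10, 5, 1)
        with pytest.raises(ValueError):
            coexpr.multi_list_overlap_p(2, 3, 10, 4)


class TestTwoSetOverlap:
    def test_whole_universe_set_gives_p_one(self):
        res = coexpr.two_set_overlap_p(50, 10, 50, 10, n_perm=1000, seed=2)
        assert res.p_emp == 1.0

    def test_expected_overlap_has_tail_near_half(self):
        nA, nB, N = 300, 200, 1000
        res = coexpr.two_set_overlap_p(nA, nB, N, round(nA * nB / N), n_perm=1000, seed=4)
        assert abs(res.exact_p - 0.5) < 0.05

    def test_permutation_converges_to_exact_tail(self):
        res = coexpr.two_set_overlap_p(40, 30, 200, 10, n_perm=100_000, seed=6)
        se = np.sqrt(res.exact_p * (1 - res.exact_p) / 100_000)
        assert abs(res.p_emp - res.exact_p) < 3 * se


class TestEqtlScan:
    @staticmethod
    def _cross(seed):
        spec = synth.CrossSimSpec(n_chrom=3, markers_per_chrom=20, qtl_marker=10,
                                  recomb_prob=0.1, seed=seed)
        return synth.gen_cross(spec)

    def test_cis_recovery(self):
        # trait driven by the marker nearest the gene: classified cis in
        # >= 90% of replicates
        cis = 0
        for s in range(20):
            markers, genes, geno, _, truth = self._cross(s)
            rng = np.random.default_rng(1000 + s)
            trait = geno[:, truth["qtl_marker"]] + 0.5 * rng.normal(size=geno.shape[0])
            grow = genes.set_index("gene_id").loc[truth["nearest_gene"]]
            res = coexpr.eqtl_scan(
                trait, geno, markers, (grow["chrom"], int(grow["start_bp"])),
                cis_window_bp=5_000_000, n_perm=100, seed=s,
            )
            cis += res.classification == "cis"
        assert cis >= 18

    def test_null_trait_mostly_unclassified(self):
        nones = 0
        for s in range(40):
            markers, genes, geno, _, _ = self._cross(s)
            rng = np.random.default_rng(2000 + s)
            trait = rng.normal(size=geno.shape[0])
            res = coexpr.eqtl_scan(
                trait, geno, markers, ("chr1", 5_000_000),
                cis_window_bp=5_000_000, n_perm=100, seed=s,
            )
            nones += res.classification == "none"
        # threshold controls familywise error at 5%: expect ~95% "none"
        assert nones >= 34

    def test_trans_by_construction(self):
        markers, genes, geno, _, truth = self._cross(7)
        rng = np.random.default_rng(3)
        trait = geno[:, truth["qtl_marker"]] + 0.3 * rng.normal(size=geno.shape[0])
        # gene located on a different chromosome from the driving marker
        other = genes[genes["chrom"] != truth["qtl_chrom"]].iloc[0]
        res = coexpr.eqtl_scan(
            trait, geno, markers, (other["chrom"], int(other["start_bp"])),
            cis_window_bp=5_000_000, n_perm=100, seed=11,
        )
        assert res.classification == "trans"
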