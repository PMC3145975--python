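import numpy as np
import pandas as pd
import pytest

from mkcobind.gsea import (RankedGeneList, enrichment_score, rank_genes,
                           significance)
from oracles import brute_force_es


def _ranked(n=20, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(0, 1, n))[::-1]
    return RankedGeneList([f"g{i:03d}" for i in range(n)], scores)


class TestRankGenes:
    def test_two_gene_order_forced_by_scores(self):
        expr = pd.DataFrame({"MK": [100.0, 1.0], "CD4": [1.0, 100.0]},
                            index=["mk_gene", "cd4_gene"])
        r = rank_genes(expr, "MK")
        assert r.genes == ["mk_gene", "cd4_gene"]
        assert r.scores[0] > 0 > r.scores[1]

    def test_row_order_permutation_invariant(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.lognormal(3, 1, size=(30, 4)),
                            index=[f"g{i}" for i in range(30)],
                            columns=["MK", "a", "b", "c"])
        r1 = rank_genes(expr, "MK")
        r2 = rank_genes(expr.sample(frac=1, random_state=7), "MK")
        assert r1.genes == r2.genes
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_requires_pseudocount_for_nonpositive(self):
        expr = pd.DataFrame({"MK": [0.0, 2.0], "CD4": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            rank_genes(expr, "MK", pseudocount=0.0)
        rank_genes(expr, "MK", pseudocount=1.0)  # fine with offset

    def test_needs_two_cell_types(self):
        expr = pd.DataFrame({"MK": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            rank_genes(expr, "MK")

    def test_planted_genes_occupy_top_ranks_noise_free(self):
        from mkcobind.simulate import (LandscapeConfig, generate_gene_models,
                                       generate_histone_and_expression,
                                       generate_peak_landscape)
        cfg = LandscapeConfig(seed=5, expression_noise_sd=0.0)
        genes = generate_gene_models(cfg)
        _, truth = generate_peak_landscape(cfg, genes)
        _, expr, truth = generate_histone_and_expression(cfg, genes, truth)
        planted = set(truth["planted_genes"])
        r = rank_genes(expr, "MK")
        assert set(r.genes[:len(planted)]) == planted


class TestEnrichmentScore:
    def test_single_top_gene_unweighted_es_is_one(self):
        r = _ranked(10)
        es, running = enrichment_score(r, [r.genes[0]], weight_p=0.0)
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_five_gene_hand_enumeration(self):
        scores = np.array([2.0, 1.0, 0.5, 0.25, 0.125])
        r = RankedGeneList(list("abcde"), scores)
        es, running = enrichment_score(r, ["a", "c"], weight_p=1.0)
        # hits a (2.0) and c (0.5): NR=2.5; misses decrement 1/3
        expect = np.array([0.8, 0.8 - 1 / 3, 1.0 - 1 / 3,
                           1.0 - 2 / 3, 0.0])
        np.testing.assert_allclose(running, expect, atol=1e-12)
        assert es == pytest.approx(0.8)

    def test_running_sum_ends_at_zero(self, rng):
        r = _ranked(50, seed=3)
        gs = list(rng.choice(r.genes, 12, replace=False))
        es, running = enrichment_score(r, gs)
        assert running[-1] == pytest.approx(0.0, abs=1e-9)
        assert -1.0 <= es <= 1.0

    def test_degenerate_sets_rejected(self):
        r = _ranked(10)
        with pytest.raises(ValueError):
            enrichment_score(r, [])
        with pytest.raises(ValueError):
            enrichment_score(r, r.genes)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 2.0])
    def test_matches_brute_force_oracle(self, weight_p):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(5, 21))
            r = _ranked(n, seed=int(rng.integers(1_000_000)))
            size = int(rng.integers(1, n))
            gs = list(rng.choice(r.genes, size, replace=False))
            es, running = enrichment_score(r, gs, weight_p)
            oes, orun = brute_force_es(r.genes, r.scores, gs, weight_p)
            assert es == pytest.approx(oes, abs=1e-12)
            np.testing.assert_allclose(running, orun, atol=1e-12)

    def test_matches_gseapy_reference(self):
        """Independent reference implementation agrees on the weighted ES."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(0)
        r = _ranked(50, seed=0)
        gs = list(rng.choice(r.genes, 12, replace=False))
        es, _ = enrichment_score(r, gs, weight_p=1.0)
        rnk = pd.DataFrame({"gene": r.genes, "score": r.scores})
        pre = gseapy.prerank(rnk=rnk, gene_sets={"s": gs}, permutation_num=10,
                             min_size=1, max_size=100, seed=1, outdir=None,
                             no_plot=True, weight=1.0)
        assert es == pytest.approx(float(pre.res2d["ES"].iloc[0]), abs=1e-9)


class TestSignificance:
    def test_determinism_same_seed(self):
        r = _ranked(60, seed=1)
        rng = np.random.default_rng(4)
        sets = {f"s{i}": list(rng.choice(r.genes, 10, replace=False))
                for i in range(5)}
        a = significance(r, sets, permutations=100, seed=9)
        b = significance(r, sets, permutations=100, seed=9)
        assert [(x.name, x.nes, x.fdr_q) for x in a] == \
            [(x.name, x.nes, x.fdr_q) for x in b]

    def test_random_set_not_significant(self):
        r = _ranked(200, seed=2)
        rng = np.random.default_rng(8)
        sets = {"random": list(rng.choice(r.genes, 20, replace=False))}
        [res] = significance(r, sets, permutations=200, seed=3)
        assert abs(res.nes) < 2.0
        assert res.fdr_q > 0.05

    def test_oversized_set_rejected(self):
        r = _ranked(10)
        with pytest.raises(ValueError):
            significance(r, {"all": r.genes}, permutations=100)

    def test_q_monotone_in_abs_nes(self):
        r = _ranked(100, seed=5)
        rng = np.random.default_rng(5)
        sets = {"planted": r.genes[:10]}
        for i in range(6):
            sets[f"rand{i}"] = list(rng.choice(r.genes, 10, replace=False))
        res = significance(r, sets, permutations=150, seed=6)
        pos = [x for x in res if x.nes >= 0]
        pos.sort(key=lambda x: -abs(x.nes))
        qs = [x.fdr_q for x in pos]
        assert qs == sorted(qs)

    def test_null_fdr_calibration(self):
        """Random sets against a random ranking: few q<0.25 calls."""
        flagged = total = 0
        for seed in range(4):
            r = _ranked(150, seed=100 + seed)
            rng = np.random.default_rng(seed)
            sets = {f"s{i}": list(rng.choice(r.genes, 15, replace=False))
                    for i in range(10)}
            for x in significance(r, sets, permutations=150, seed=seed):
                total += 1
                flagged += x.fdr_q < 0.25
        # binomial tolerance at 40 draws around <=0.25
        assert flagged / total <= 0.25 + 4 * np.sqrt(0.25 * 0.75 / total)
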