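import filecmp
import json
import math

import numpy as np
import pytest

from mkcobind.motifs import ConsensusMotif, count_matches
from mkcobind.occupancy import (assign_patterns, count_exact_patterns,
                                pattern_from_factors)
from mkcobind.simulate import (LandscapeConfig, generate_all,
                               generate_gene_models,
                               generate_histone_and_expression,
                               generate_peak_landscape, generate_sequences,
                               null_config)
from conftest import small_config


class TestGeneModels:
    def test_single_gene(self):
        cfg = small_config(0, n_genes=1)
        [g] = generate_gene_models(cfg)
        assert g.start < g.end

    def test_no_pairwise_overlaps_exhaustive(self):
        cfg = LandscapeConfig(seed=7, n_genes=500)
        genes = generate_gene_models(cfg)
        assert len(genes) == 500
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_infeasible_packing_errors(self):
        cfg = small_config(0, n_genes=200, gene_length=(30_000, 40_000))
        with pytest.raises(ValueError, match="pack"):
            generate_gene_models(cfg)


class TestPeakLandscape:
    def test_realized_marginals_near_targets(self):
        cfg = LandscapeConfig(seed=13)
        genes = generate_gene_models(cfg)
        peaksets, truth = generate_peak_landscape(cfg, genes)
        for f, target in cfg.marginal_targets.items():
            n = len(peaksets[f])
            p = target / (cfg.n_background_sites + cfg.n_complex_regions)
            tol = 4 * math.sqrt(target * (1 - p)) + 10  # + suppression leakage
            assert abs(n - target) <= tol, (f, n, target)

    def test_identity_propensity_gives_singletons(self):
        cfg = small_config(1, n_complex_regions=0,
                           background_emission={"GATA1": 1.0, "GATA2": 0.0,
                                                "RUNX1": 0.0, "FLI1": 0.0,
                                                "SCL": 0.0},
                           suppressed_pattern=None)
        genes = generate_gene_models(cfg)
        peaksets, truth = generate_peak_landscape(cfg, genes)
        regions, order = assign_patterns([peaksets[f] for f in cfg.factors])
        table = count_exact_patterns(regions, order)
        g1 = pattern_from_factors(["GATA1"], order)
        assert table.count(g1) == cfg.n_background_sites
        assert table.n_regions == cfg.n_background_sites

    def test_planted_all_five_count_near_expectation(self):
        cfg = LandscapeConfig(seed=3)
        genes = generate_gene_models(cfg)
        peaksets, truth = generate_peak_landscape(cfg, genes)
        regions, order = assign_patterns([peaksets[f] for f in cfg.factors])
        table = count_exact_patterns(regions, order)
        all5 = table.count(0b11111)
        # planted complexes emitting all five, plus background all-five
        e = cfg.emission_probs()
        p_bg = np.prod([e[f] for f in cfg.factors])
        expect = cfg.n_complex_regions * cfg.complex_emission ** 5 \
            + cfg.n_background_sites * p_bg
        assert abs(all5 - expect) <= 4 * math.sqrt(expect)

    def test_suppressed_pattern_depleted(self):
        cfg = LandscapeConfig(seed=5)
        genes = generate_gene_models(cfg)
        peaksets, _ = generate_peak_landscape(cfg, genes)
        regions, order = assign_patterns([peaksets[f] for f in cfg.factors])
        table = count_exact_patterns(regions, order)
        gf = pattern_from_factors(["GATA1", "FLI1"], order)
        e = cfg.emission_probs()
        unsuppressed = cfg.n_background_sites * e["GATA1"] * e["FLI1"] * \
            np.prod([1 - e[f] for f in ("GATA2", "RUNX1", "SCL")])
        assert table.count(gf) < 0.4 * unsuppressed

    def test_null_config_has_no_structure(self):
        cfg = null_config(seed=2, n_sites=500)
        genes = generate_gene_models(cfg)
        peaksets, truth = generate_peak_landscape(cfg, genes)
        assert all(s["type"] == "background" for s in truth["sites"])
        regions, _ = assign_patterns([peaksets[f] for f in cfg.factors])
        assert len(regions) <= 500  # one region per site at most


class TestHistoneExpression:
    def test_bound_promoters_enriched_for_active(self, default_landscape):
        truth = default_landscape["truth"]
        states = truth["promoter_states"]
        bound = set(truth["bound_promoters"])
        active_bound = sum(1 for g, s in states.items() if s == "active" and g in bound)
        active_unbound = sum(1 for g, s in states.items()
                             if s == "active" and g not in bound)
        n_bound = len(bound)
        n_unbound = len(states) - n_bound
        assert active_bound / n_bound > active_unbound / n_unbound

    def test_zero_noise_puts_planted_on_top(self):
        cfg = LandscapeConfig(seed=19, expression_noise_sd=0.0)
        genes = generate_gene_models(cfg)
        _, truth = generate_peak_landscape(cfg, genes)
        _, expr, truth = generate_histone_and_expression(cfg, genes, truth)
        planted = set(truth["planted_genes"])
        ratio = np.log2(expr["MK"] / expr.drop(columns="MK").mean(axis=1))
        top = set(ratio.sort_values(ascending=False).index[:len(planted)])
        assert top == planted

    def test_zero_effect_no_enrichment(self):
        cfg = LandscapeConfig(seed=23, target_effect=0.0)
        genes = generate_gene_models(cfg)
        _, truth = generate_peak_landscape(cfg, genes)
        _, expr, truth = generate_histone_and_expression(cfg, genes, truth)
        planted = set(truth["planted_genes"])
        ratio = np.log2(expr["MK"] / expr.drop(columns="MK").mean(axis=1))
        ranks = ratio.rank(pct=True)
        mean_rank = ranks.loc[sorted(planted)].mean()
        assert 0.35 < mean_rank < 0.65


class TestSequences:
    def test_embedding_prob_one_every_target_has_composite(self):
        from mkcobind.simulate import EmbeddingRule
        from mkcobind.motifs import DEFAULT_MOTIFS
        cfg = LandscapeConfig(seed=29)
        cfg.embedding_rules = [EmbeddingRule(DEFAULT_MOTIFS[4],
                                             frozenset({"GATA1", "SCL"}),
                                             "exact", 1.0)]
        genes = generate_gene_models(cfg)
        peaksets, _ = generate_peak_landscape(cfg, genes)
        seqs, regions, st = generate_sequences(cfg, peaksets)
        tp = pattern_from_factors({"GATA1", "SCL"}, st["factor_order"])
        comp = DEFAULT_MOTIFS[4]
        targets = [i for i, r in enumerate(regions) if r.pattern == tp]
        assert targets
        for i in targets:
            assert count_matches(seqs[f"region_{i}"], comp) >= 1

    def test_embedding_prob_zero_matches_background_rate(self):
        cfg = LandscapeConfig(seed=31)
        cfg.embedding_rules = []
        genes = generate_gene_models(cfg)
        peaksets, _ = generate_peak_landscape(cfg, genes)
        seqs, regions, st = generate_sequences(cfg, peaksets)
        motif = ConsensusMotif("GATA", "WGATAR")
        # per-position double-strand match probability: 2 * (1/2 * (1/4)^4 * 1/2)
        counts = [count_matches(s, motif) for s in seqs.values()]
        total_positions = sum(len(s) - 5 for s in seqs.values())
        p = 2 * 0.5 * 0.25 ** 4 * 0.5
        expect = total_positions * p
        got = sum(counts)
        assert abs(got - expect) <= 4 * math.sqrt(expect)


class TestDeterminism:
    def test_generate_all_byte_identical(self, tmp_path):
        cfg = small_config(37)
        a = generate_all(cfg, tmp_path / "a")
        b = generate_all(small_config(37), tmp_path / "b")
        for rel in ["genes.gtf", "genes.bed12", "expression.tsv", "regions.fa",
                    "truth.json", "peaks/GATA1.bed", "marks/H3K4me3.bed"]:
            assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel,
                               shallow=False), rel

    def test_truth_json_is_valid(self, tmp_path):
        cfg = small_config(41)
        generate_all(cfg, tmp_path / "x")
        truth = json.loads((tmp_path / "x" / "truth.json").read_text())
        assert set(truth["factors"]) == set(cfg.factors)
        assert truth["realized_marginals"].keys() == cfg.marginal_targets.keys()
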