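"""End-to-end orchestration: intervals -> occupancy -> enrichment ->
annotation -> chromatin -> GSEA -> motifs -> network.

Every stage reads the previous stage's serialized outputs from the
output directory, so stages are individually re-runnable; the full
bundle is deterministic given the config and seed.  Each report header
embeds a hash of the resolved configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation, chromatin, enrichment, gsea, motifs, network, occupancy
from .intervals import (GeneModel, chrom_concordance, read_gene_models,
                        read_peaks, read_scored_bed, write_bed)
from .simulate import (LandscapeConfig, config_from_dict, generate_all,
                       read_expression, read_fasta)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "mkcobind_out"
    seed: int = 0
    # real inputs (paths); left None when running from a synthetic landscape
    peak_paths: dict | None = None          # factor -> BED path
    gene_models: str | None = None          # GTF or BED12
    mark_paths: dict | None = None          # mark name -> scored BED
    expression: str | None = None           # TSV genes x cell types
    sequences: str | None = None            # FASTA per region
    synthetic: dict | None = None           # LandscapeConfig overrides
    factors: tuple = ("GATA1", "GATA2", "RUNX1", "FLI1", "SCL")
    universe_n: int = enrichment.DEFAULT_UNIVERSE_N
    min_overlap: int = 1
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    distance_cap: int = 100_000
    permutations: int = 200
    mc_reps: int = 0                        # >0 adds a Monte-Carlo audit column
    target_cell_type: str = "MK"
    core_edges: list | None = None
    gsea_q_threshold: float = 0.05
    top_k_specific: int = 200

    def __post_init__(self):
        if self.synthetic is None and self.peak_paths is None:
            raise ValueError("config needs either real peak paths or a [synthetic] section")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        # analytic parameters only: where the bundle lands must not
        # change what it contains
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"config_hash={self.config_hash()}", f"seed={self.seed}"]


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Existence, format-sniff and chromosome-concordance checks."""
    rep = ValidationReport()
    if config.synthetic is not None:
        return rep  # synthetic inputs are generated, nothing to validate
    paths = dict(config.peak_paths or {})
    for label, p in [*paths.items(), ("gene_models", config.gene_models)]:
        if p is None:
            continue
        if not Path(p).exists():
            rep.errors.append(f"{label}: missing file {p}")
    if rep.errors:
        return rep
    chrom_sets = []
    for factor, p in paths.items():
        try:
            ps = read_peaks(p, factor)
            chrom_sets.append({iv.chrom for iv in ps.intervals})
        except Exception as exc:  # format violations are enumerated, not raised
            rep.errors.append(f"{factor}: {exc}")
    if config.gene_models:
        try:
            genes = read_gene_models(config.gene_models)
            chrom_sets.append({g.chrom for g in genes})
        except Exception as exc:
            rep.errors.append(f"gene_models: {exc}")
    if chrom_sets:
        for src, extra in chrom_concordance(*chrom_sets).items():
            rep.warnings.append(
                f"{src}: {len(extra)} chromosome name(s) absent from other inputs: "
                f"{sorted(extra)[:5]}")
    return rep


def _load_inputs(config: PipelineConfig, outdir: Path):
    """Load real inputs or generate the synthetic landscape in outdir."""
    if config.synthetic is not None:
        overrides = dict(config.synthetic)
        overrides.setdefault("seed", config.seed)
        lc = config_from_dict(overrides) if "embedding_rules" in overrides \
            else LandscapeConfig(**overrides)
        sim = generate_all(lc, outdir / "inputs")
        config.factors = tuple(lc.factors)
        config.universe_n = lc.universe_n
        return dict(
            peaksets=[sim["peaksets"][f] for f in lc.factors],
            genes=sim["genes"],
            marks={m: ivs for m, ivs in sim["marks"].items()},
            expression=sim["expression"],
            sequences=sim["sequences"],
        )
    peaksets = [read_peaks(config.peak_paths[f], f) for f in config.factors]
    genes = read_gene_models(config.gene_models, config.promoter_upstream,
                             config.promoter_downstream) if config.gene_models else None
    marks = ({m: read_scored_bed(p) for m, p in config.mark_paths.items()}
             if config.mark_paths else None)
    expr = read_expression(config.expression) if config.expression else None
    seqs = read_fasta(config.sequences) if config.sequences else None
    return dict(peaksets=peaksets, genes=genes, marks=marks,
                expression=expr, sequences=seqs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mkcobind")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    hdr = config.header_lines()
    results: dict = {"config_hash": config.config_hash()}
    try:
        inputs = _load_inputs(config, outdir)
        peaksets = inputs["peaksets"]

        # occupancy
        regions, factor_order = occupancy.assign_patterns(
            peaksets, min_overlap=config.min_overlap)
        table = occupancy.count_exact_patterns(regions, factor_order)
        occupancy.write_pattern_table(table, outdir / "pattern_counts.tsv", hdr)
        write_bed([r.region for r in regions], outdir / "union_regions.bed",
                  names=[f"region_{i}" for i in range(len(regions))])
        results.update(regions=regions, factor_order=factor_order, pattern_table=table)
        logger.info("occupancy: %d union regions", table.n_regions)

        # enrichment
        model = enrichment.NullModel.from_table(table, universe_n=config.universe_n)
        stats = enrichment.pattern_zscores(table, model, min_factors=2)
        enrichment.write_zscore_report(stats, outdir / "pattern_zscores.tsv", hdr)
        results.update(null_model=model, pattern_stats=stats)
        if config.mc_reps:
            mc = enrichment.monte_carlo_null(model, reps=config.mc_reps, seed=config.seed)
            results["monte_carlo"] = mc

        genes = inputs["genes"]
        lists = None
        if genes is not None:
            assignments = annotation.assign_all(regions, genes,
                                                distance_cap=config.distance_cap)
            annotation.write_assignments(assignments, outdir / "peak_gene_assignments.tsv", hdr)
            lists = annotation.build_target_gene_lists(
                regions, genes, k=len(factor_order), distance_cap=config.distance_cap)
            annotation.write_target_gene_lists(lists, factor_order,
                                               outdir / "target_gene_lists.tsv", hdr)
            results.update(assignments=assignments, target_gene_lists=lists,
                           location_fractions=annotation.location_fractions(assignments))
        else:
            logger.warning("no gene models: annotation, chromatin, GSEA and network skipped")

        marks = inputs["marks"]
        if genes is not None and marks is not None:
            states = chromatin.classify_promoters(
                marks.get("H3K4me3", []), marks.get("H3K27me3", []), genes,
                h3ac=marks.get("H3ac"))
            bound = chromatin.bound_fraction_by_state(states, regions, genes, factor_order)
            bound.to_csv(outdir / "bound_fraction_by_state.tsv", sep="\t")
            results.update(promoter_states=states, bound_fraction=bound)
            if inputs["expression"] is not None:
                expr_summary = chromatin.expression_by_state(
                    states, inputs["expression"], config.target_cell_type)
                expr_summary.to_csv(outdir / "expression_by_state.tsv", sep="\t")
                results["expression_by_state"] = expr_summary

        gsea_results = None
        ranked = None
        if genes is not None and inputs["expression"] is not None and lists:
            ranked = gsea.rank_genes(inputs["expression"], config.target_cell_type)
            named = {occupancy.pattern_name(p, factor_order): sorted(gs)
                     for p, gs in lists.items() if gs}
            gsea_results = gsea.significance(ranked, named,
                                             permutations=config.permutations,
                                             seed=config.seed)
            gsea.write_gsea_report(gsea_results, outdir / "gsea_results.tsv", hdr)
            results.update(gsea_results=gsea_results, ranking=ranked)
        else:
            logger.warning("GSEA skipped (needs gene models, expression and target lists)")

        if inputs["sequences"] is not None:
            seqs = inputs["sequences"]
            target_pat = occupancy.pattern_from_factors({"GATA1", "SCL"}, factor_order) \
                if {"GATA1", "SCL"} <= set(factor_order) else None
            motif_rows = []
            if target_pat is not None:
                target = {f"region_{i}": seqs[f"region_{i}"]
                          for i, r in enumerate(regions)
                          if r.pattern == target_pat and f"region_{i}" in seqs}
                background = {f"region_{i}": seqs[f"region_{i}"]
                              for i, r in enumerate(regions)
                              if r.pattern != target_pat and f"region_{i}" in seqs}
                if target and background:
                    for motif in motifs.DEFAULT_MOTIFS:
                        motif_rows.append(motifs.motif_enrichment_test(
                            target, background, motif))
                    motifs.write_motif_report(motif_rows,
                                              outdir / "motif_enrichment.tsv", hdr)
                    results["motif_enrichment"] = motif_rows
                else:
                    logger.warning("motif stage: no GATA1+SCL-only regions with sequence")

        if gsea_results is not None:
            name_to_pat = {occupancy.pattern_name(p, factor_order): p for p in lists}
            significant = [name_to_pat[r.name] for r in gsea_results
                           if r.fdr_q <= config.gsea_q_threshold and r.nes > 0]
            net = network.build_network(significant, lists, factor_order,
                                        core_edges=config.core_edges)
            network.export_network(net, outdir / "network.graphml", "graphml")
            network.export_network(net, outdir / "network.sif", "sif")
            network.write_degree_summary(net, outdir / "network_degrees.json")
            top_k = ranked.genes[: config.top_k_specific]
            hit, frac = network.coverage_stat(net, top_k)
            results.update(network=net, significant_patterns=significant,
                           coverage=(hit, frac))

        with open(outdir / "provenance.json", "w") as fh:
            json.dump({
                "config_hash": config.config_hash(), "seed": config.seed,
                "n_regions": table.n_regions,
                "stages_run": sorted(k for k in results if k not in ("config_hash",)),
            }, fh, indent=1, default=str)
        return results
    finally:
        root.removeHandler(handler)
        handler.close()
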