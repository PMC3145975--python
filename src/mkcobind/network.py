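"""Core-circuit -> pattern -> effector-gene network construction and export.

The model is a typed directed graph: TF nodes wired by the configured
core-circuit edges (cross- and auto-regulation among the five
factors), pattern nodes for each significant occupancy pattern with
membership in-edges from their TFs, and pattern->gene targeting edges
from the deduplicated target lists.  The core TF->TF connectivity is
configuration, not inference: it represents established regulatory
links, while self-binding detected from the data is offered only as an
optional cross-check.
"""

from __future__ import annotations

import json
import logging
import warnings
from typing import Mapping, Sequence

import networkx as nx

from .occupancy import pattern_name

logger = logging.getLogger(__name__)

#: Established cross/auto-regulatory links of the five-factor core
#: circuit (every factor autoregulates and cross-links are dense).
DEFAULT_CORE_EDGES = [
    (a, b)
    for a in ("GATA1", "GATA2", "RUNX1", "FLI1", "SCL")
    for b in ("GATA1", "GATA2", "RUNX1", "FLI1", "SCL")
]

NODE_TYPES = ("TF", "pattern", "gene")
EDGE_TYPES = ("core", "membership", "targeting")


def build_network(significant_patterns: Sequence[int],
                  target_gene_lists: Mapping[int, set[str]],
                  factor_order: Sequence[str],
                  core_edges: Sequence[tuple[str, str]] | None = None) -> nx.DiGraph:
    """Assemble the typed pattern/gene graph.

    Patterns with empty gene lists are omitted with a warning.  Edges
    are deduplicated per (pattern, gene).
    """
    if core_edges is None:
        core_edges = [(a, b) for a in factor_order for b in factor_order]
    g = nx.DiGraph()
    for f in factor_order:
        g.add_node(f, node_type="TF")
    for a, b in core_edges:
        g.add_edge(a, b, edge_type="core")
    for pat in significant_patterns:
        genes = target_gene_lists.get(pat, set())
        if not genes:
            warnings.warn(f"pattern {pattern_name(pat, factor_order)} has an empty "
                          "gene list; node omitted")
            continue
        pname = pattern_name(pat, factor_order)
        g.add_node(pname, node_type="pattern", pattern=int(pat))
        for i, f in enumerate(factor_order):
            if pat >> i & 1:
                g.add_edge(f, pname, edge_type="membership")
        for gene in sorted(genes):
            if gene not in g:
                g.add_node(gene, node_type="gene")
            g.add_edge(pname, gene, edge_type="targeting")
    return g


def pattern_degree_distribution(g: nx.DiGraph) -> dict[str, int]:
    """Per-gene count of distinct pattern nodes targeting it."""
    out = {}
    for n, data in g.nodes(data=True):
        if data.get("node_type") == "gene":
            out[n] = sum(1 for u, _ in g.in_edges(n)
                         if g.nodes[u].get("node_type") == "pattern")
    return out


def degree_summary(g: nx.DiGraph) -> dict:
    dist = pattern_degree_distribution(g)
    n_genes = len(dist)
    single = sum(1 for d in dist.values() if d == 1)
    return {
        "n_tf": sum(1 for _, d in g.nodes(data=True) if d.get("node_type") == "TF"),
        "n_patterns": sum(1 for _, d in g.nodes(data=True) if d.get("node_type") == "pattern"),
        "n_genes": n_genes,
        "n_targeting_edges": sum(1 for _, _, d in g.edges(data=True)
                                 if d.get("edge_type") == "targeting"),
        "genes_single_pattern": single,
        "fraction_single_pattern": single / n_genes if n_genes else float("nan"),
    }


def coverage_stat(g: nx.DiGraph, specific_genes: Sequence[str]) -> tuple[int, float]:
    """How many of the top-k lineage-specific genes the model contains."""
    model_genes = {n for n, d in g.nodes(data=True) if d.get("node_type") == "gene"}
    k = len(specific_genes)
    hit = sum(1 for gene in specific_genes if gene in model_genes)
    return hit, (hit / k if k else float("nan"))


# ---------------------------------------------------------------------------
# export / import

FORMATS = ("sif", "graphml", "dot")


def export_network(g: nx.DiGraph, path, fmt: str) -> None:
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{d.get('edge_type', 'edge')}\t{v}\n")
            for n in sorted(g.nodes):
                if g.degree(n) == 0:
                    fh.write(f"{n}\n")
    else:  # dot (self-contained writer; reader below parses this subset)
        with open(path, "w") as fh:
            fh.write("digraph network {\n")
            for n, d in sorted(g.nodes(data=True)):
                fh.write(f'  "{n}" [node_type="{d.get("node_type", "")}"];\n')
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f'  "{u}" -> "{v}" [edge_type="{d.get("edge_type", "")}"];\n')
            fh.write("}\n")


def import_network(path, fmt: str) -> nx.DiGraph:
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        out = nx.DiGraph()
        for n, d in g.nodes(data=True):
            out.add_node(n, **d)
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, **d)
        return out
    g = nx.DiGraph()
    if fmt == "sif":
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if len(f) == 1 and f[0]:
                    g.add_node(f[0])
                elif len(f) >= 3:
                    g.add_edge(f[0], f[2], edge_type=f[1])
        return g
    # dot subset emitted by export_network
    import re
    node_re = re.compile(r'^\s*"(.+)" \[node_type="(.*)"\];$')
    edge_re = re.compile(r'^\s*"(.+)" -> "(.+)" \[edge_type="(.*)"\];$')
    with open(path) as fh:
        for line in fh:
            m = edge_re.match(line)
            if m:
                g.add_edge(m.group(1), m.group(2), edge_type=m.group(3))
                continue
            m = node_re.match(line)
            if m:
                if m.group(1) not in g:
                    g.add_node(m.group(1))
                g.nodes[m.group(1)]["node_type"] = m.group(2)
    return g


def self_binding_check(regions, factor_order: Sequence[str],
                       genes, tf_gene_ids: Mapping[str, str]) -> dict[str, bool]:
    """Optional check: does each TF have a peak at its own gene locus?

    ``tf_gene_ids`` maps factor label -> gene_id of the locus encoding
    it.  This audits the configured autoregulation edges against the
    data; it never replaces them.
    """
    from .annotation import GeneIndex, map_region_to_genes
    index = GeneIndex(genes)
    bound: dict[str, set[str]] = {f: set() for f in factor_order}
    for i, r in enumerate(regions):
        a = map_region_to_genes(r.region, index, region_id=f"region_{i}")
        for j, f in enumerate(factor_order):
            if r.pattern >> j & 1:
                bound[f].update(a.gene_ids)
    return {f: tf_gene_ids.get(f) in bound[f] for f in factor_order}


def write_degree_summary(g: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump({"summary": degree_summary(g),
                   "pattern_degree": pattern_degree_distribution(g)}, fh, indent=2)
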