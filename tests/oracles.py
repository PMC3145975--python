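"""Brute-force reference implementations used only by the test suite.

These deliberately use the dumbest possible algorithm (per-base
vectors, exhaustive scans) and share no code paths with the package.
"""

from __future__ import annotations

import numpy as np

from mkcobind.intervals import GeneModel, GenomicInterval, PeakSet
from mkcobind.motifs import IUPAC


def per_base_union(peaksets, genome_sizes: dict[str, int], min_overlap: int = 1):
    """Union regions + bound factor sets from per-base coverage vectors."""
    out = []
    for chrom in sorted(genome_sizes):
        size = genome_sizes[chrom]
        cover = np.zeros((len(peaksets), size), dtype=bool)
        for fi, ps in enumerate(peaksets):
            for iv in ps.intervals:
                if iv.chrom == chrom:
                    cover[fi, iv.start:iv.end] = True
        union = cover.any(axis=0)
        # maximal covered runs
        padded = np.concatenate([[False], union, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            bound = frozenset(
                peaksets[fi].factor
                for fi in range(len(peaksets))
                if cover[fi, s:e].sum() >= min_overlap
            )
            out.append((GenomicInterval(chrom, int(s), int(e)), bound))
    return out


def exhaustive_gene_assignment(region: GenomicInterval, genes: list[GeneModel],
                               cap: int = 100_000):
    """(category, [(gene_id, distance)]) by scanning every gene."""
    promoter = sorted(g.gene_id for g in genes
                      if g.chrom == region.chrom and region.overlaps(g.promoter))
    if promoter:
        return "promoter", [(g, 0) for g in promoter]
    body = sorted(g.gene_id for g in genes
                  if g.chrom == region.chrom and region.overlaps(g.body))
    if body:
        return "intragenic", [(g, 0) for g in body]
    left = [(region.start - g.tss, g.gene_id) for g in genes
            if g.chrom == region.chrom and g.tss < region.start]
    right = [(g.tss - (region.end - 1), g.gene_id) for g in genes
             if g.chrom == region.chrom and g.tss >= region.end]
    assigned = []
    if left and min(left)[0] <= cap:
        assigned.append((min(left)[1], min(left)[0]))
    if right and min(right)[0] <= cap:
        assigned.append((min(right)[1], min(right)[0]))
    return "intergenic", assigned


def brute_force_es(genes_ranked: list[str], scores, gene_set, weight_p: float):
    """Running-sum ES by direct loop (no numpy vectorization tricks)."""
    gene_set = set(gene_set)
    n = len(genes_ranked)
    hits = [g in gene_set for g in genes_ranked]
    nh = sum(hits)
    nr = sum(abs(scores[i]) ** weight_p for i in range(n) if hits[i])
    running = []
    cur = 0.0
    for i in range(n):
        if hits[i]:
            cur += (abs(scores[i]) ** weight_p / nr) if nr > 0 else 1.0 / nh
        else:
            cur -= 1.0 / (n - nh)
        running.append(cur)
    # signed extremum; ties on |value| go to the earliest rank
    best = running[0]
    for v in running[1:]:
        if abs(v) > abs(best):
            best = v
    return best, running


def iupac_compatible(base: str, code: str) -> bool:
    return base in IUPAC[code]


def brute_force_matches(seq: str, motif) -> set[tuple[int, int]]:
    """All match spans of a motif by direct per-position checking."""

    def simple(s: str, pat: str):
        m = len(pat)
        return [i for i in range(len(s) - m + 1)
                if all(iupac_compatible(s[i + j], pat[j]) for j in range(m))]

    def rc(s):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        return "".join(comp[c] for c in reversed(s))

    def rc_iupac(p):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}
        return "".join(comp[c] for c in reversed(p))

    seq = seq.upper()
    spans = set()
    if motif.is_composite:
        for p1, p2 in [(motif.part1, motif.part2),
                       (rc_iupac(motif.part2), rc_iupac(motif.part1))]:
            for i in simple(seq, p1):
                for gap in range(motif.spacer_min, motif.spacer_max + 1):
                    j = i + len(p1) + gap
                    if j + len(p2) <= len(seq) and j in simple(seq, p2):
                        spans.add((i, j + len(p2)))
    else:
        m = len(motif.iupac)
        for i in simple(seq, motif.iupac):
            spans.add((i, i + m))
        for i in simple(rc(seq), motif.iupac):
            spans.add((len(seq) - i - m, len(seq) - i))
    return spans


def random_peaksets(rng, factors, genome_sizes, n_peaks=30, max_len=400):
    """Small random peak landscapes for oracle-equivalence tests."""
    out = []
    for f in factors:
        ivs = []
        for _ in range(int(rng.integers(1, n_peaks + 1))):
            chrom = str(rng.choice(sorted(genome_sizes)))
            size = genome_sizes[chrom]
            start = int(rng.integers(0, size - max_len))
            length = int(rng.integers(50, max_len))
            ivs.append(GenomicInterval(chrom, start, start + length))
        out.append(PeakSet(f, ivs))
    return out
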