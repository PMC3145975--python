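"""Synthetic regulatory landscapes with ground truth.

The generator emulates the statistical structure a five-factor
co-occupancy analysis assumes, at desk scale:

* a latent-site mixture: background sites emit each factor's peak
  independently with per-factor propensities, while a small set of
  planted "complex" sites emits all five factors with high
  probability — the analogue of genuine multi-TF complex regions;
* an optional suppressed pattern (default GATA1+FLI1 with no other
  factor): background sites realizing exactly that pattern are
  resampled with a configurable probability, creating a deficit
  relative to the independence null;
* non-overlapping gene models; promoter chromatin states coupled to
  TF binding (bound promoters are drawn active-rich) and to
  expression; an expression matrix in which genes near complex sites
  are boosted in the target cell type;
* region sequences with consensus motifs embedded according to the
  region's occupancy pattern, including the E-box/GATA composite in
  regions bound by exactly GATA1 and SCL.

All randomness flows from ``config.seed``; every generator is
byte-deterministic given the config.  Ground truth (site types,
emitted patterns, promoter states, planted genes, embedding positions)
is returned and serialized for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, PeakSet, write_bed, \
    write_gene_bed12, write_gene_gtf
from .motifs import ConsensusMotif, DEFAULT_MOTIFS, IUPAC, revcomp_seq

FACTORS = ("GATA1", "GATA2", "RUNX1", "FLI1", "SCL")

CELL_TYPES = ("MK", "CD4", "CD8", "CD14", "CD19", "CD56", "CD66b", "Erythroblast")


@dataclass(frozen=True)
class EmbeddingRule:
    """Embed ``motif`` with probability ``prob`` in regions whose exact
    pattern matches ``factors`` (mode 'exact') or contains any of them
    (mode 'any')."""

    motif: ConsensusMotif
    factors: frozenset
    mode: str = "any"
    prob: float = 0.5

    def applies(self, bound: frozenset) -> bool:
        if self.mode == "exact":
            return bound == self.factors
        return bool(bound & self.factors)


def default_embedding_rules() -> list[EmbeddingRule]:
    gata, ebox, ets, runx, composite = DEFAULT_MOTIFS
    return [
        EmbeddingRule(composite, frozenset({"GATA1", "SCL"}), "exact", 0.9),
        EmbeddingRule(gata, frozenset({"GATA1", "GATA2"}), "any", 0.5),
        EmbeddingRule(ebox, frozenset({"SCL"}), "any", 0.5),
        EmbeddingRule(ets, frozenset({"FLI1"}), "any", 0.5),
        EmbeddingRule(runx, frozenset({"RUNX1"}), "any", 0.5),
    ]


@dataclass
class LandscapeConfig:
    """All knobs of the synthetic landscape; defaults are the package's
    standard study conditions (two 5-Mb chromosomes, 300 genes,
    ~400–900 peaks per factor, 40 planted complex regions)."""

    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    factors: tuple = FACTORS
    n_genes: int = 300
    gene_length: tuple = (2_000, 20_000)
    # keeps neighboring promoter windows (and the mark peaks emitted in
    # them, jitter included) disjoint, so state recovery is identifiable
    min_gene_gap: int = 2_500
    marginal_targets: dict = field(default_factory=lambda: {
        "GATA1": 600, "GATA2": 420, "RUNX1": 780, "FLI1": 900, "SCL": 520})
    n_complex_regions: int = 40
    complex_emission: float = 0.95
    n_background_sites: int = 1500
    background_emission: dict | None = None  # derived from marginals when None
    suppressed_pattern: tuple | None = ("GATA1", "FLI1")
    suppression_strength: float = 0.9
    peak_length: tuple = (200, 600)
    peak_jitter: int = 100
    min_site_spacing: int = 2_000
    promoter_upstream: int = 1_000
    promoter_downstream: int = 500
    universe_n: int = 20_000
    # chromatin / expression
    state_probs_bound: dict = field(default_factory=lambda: {
        "active": 0.70, "bivalent": 0.20, "inactive": 0.10})
    state_probs_unbound: dict = field(default_factory=lambda: {
        "active": 0.25, "bivalent": 0.15, "inactive": 0.60})
    mark_dropout: float = 0.05
    mark_spurious: float = 0.02
    cell_types: tuple = CELL_TYPES
    target_cell_type: str = "MK"
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    state_effect: dict = field(default_factory=lambda: {
        "inactive": 0.0, "bivalent": 0.5, "active": 2.0})
    target_effect: float = 2.5  # log2 boost of planted genes in the target type
    expression_noise_sd: float = 0.6
    distance_cap: int = 100_000
    embedding_rules: list = field(default_factory=default_embedding_rules)

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for p in (self.complex_emission, self.suppression_strength,
                  self.mark_dropout, self.mark_spurious):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.target_cell_type not in self.cell_types:
            raise ValueError("target cell type must be one of cell_types")

    def emission_probs(self) -> dict[str, float]:
        """Per-factor background emission probabilities.

        Derived so that expected realized marginals hit the configured
        targets: n_background * e_i + n_complex * complex_emission =
        target_i.
        """
        if self.background_emission is not None:
            return dict(self.background_emission)
        out = {}
        for f in self.factors:
            target = self.marginal_targets[f]
            e = (target - self.n_complex_regions * self.complex_emission) / self.n_background_sites
            if not 0 < e < 1:
                raise ValueError(f"infeasible marginal target for {f}: emission {e:.3f}")
            out[f] = e
        return out

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


def null_config(seed: int = 0, n_sites: int = 3000,
                emission: Mapping[str, float] | None = None) -> LandscapeConfig:
    """A landscape in which binding is exactly independent across factors.

    No complex regions, no suppression; the independence null holds by
    construction with universe N equal to the latent-site count.
    """
    if emission is None:
        rng = np.random.default_rng([seed, 99])
        emission = {f: float(rng.uniform(0.3, 0.5)) for f in FACTORS}
    return LandscapeConfig(
        seed=seed,
        n_complex_regions=0,
        n_background_sites=n_sites,
        background_emission=dict(emission),
        suppressed_pattern=None,
        universe_n=n_sites,
    )


# ---------------------------------------------------------------------------
# placement helpers


def _spaced_positions(rng, length: int, n: int, spacing: int) -> np.ndarray:
    """n sorted positions in [0, length) with pairwise gaps >= spacing."""
    slack = length - n * spacing
    if slack <= 0:
        raise ValueError(f"cannot place {n} sites with {spacing} bp spacing in {length} bp")
    u = np.sort(rng.integers(0, slack, size=n))
    return u + np.arange(n) * spacing + spacing // 2


def _partition_counts(rng, sizes: Sequence[int], n: int) -> list[int]:
    """Split n items across chromosomes proportionally to size."""
    probs = np.asarray(sizes, dtype=float)
    probs /= probs.sum()
    return list(rng.multinomial(n, probs))


# ---------------------------------------------------------------------------
# gene models


def generate_gene_models(config: LandscapeConfig) -> list[GeneModel]:
    """Non-overlapping, strand-balanced gene bodies with TSS/TES."""
    rng = config.rng(1)
    chroms = list(config.chrom_sizes)
    counts = _partition_counts(rng, list(config.chrom_sizes.values()), config.n_genes)
    genes: list[GeneModel] = []
    gid = 0
    lo, hi = config.gene_length
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        size = config.chrom_sizes[chrom]
        for _ in range(50):  # bounded retries for infeasible packings
            lengths = rng.integers(lo, hi + 1, size=n_c)
            free = size - int(lengths.sum()) - n_c * config.min_gene_gap
            if free > n_c:
                break
        else:
            raise ValueError(f"cannot pack {n_c} genes into {chrom} ({size} bp)")
        gaps = np.sort(rng.integers(0, free, size=n_c))
        starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])]) \
            + (np.arange(n_c) + 1) * config.min_gene_gap
        strands = rng.choice(["+", "-"], size=n_c)
        for s, l, st in zip(starts, lengths, strands):
            genes.append(GeneModel(f"gene_{gid:04d}", chrom, int(s), int(s + l), str(st),
                                   promoter_upstream=config.promoter_upstream,
                                   promoter_downstream=config.promoter_downstream))
            gid += 1
    return genes


# ---------------------------------------------------------------------------
# peak landscape


def generate_peak_landscape(config: LandscapeConfig, genes: Sequence[GeneModel]
                            ) -> tuple[dict[str, PeakSet], dict]:
    """Latent sites -> per-factor peaks, with a ground-truth table.

    Complex sites emit all factors with ``complex_emission`` each;
    background sites emit independently with the derived propensities;
    background sites realizing exactly the suppressed pattern are
    resampled with probability ``suppression_strength``.
    """
    rng = config.rng(2)
    factors = list(config.factors)
    k = len(factors)
    emis = config.emission_probs() if config.n_background_sites else {}
    e_vec = np.array([emis.get(f, 0.0) for f in factors])
    sup_mask = 0
    if config.suppressed_pattern:
        for f in config.suppressed_pattern:
            sup_mask |= 1 << factors.index(f)

    n_sites = config.n_complex_regions + config.n_background_sites
    chroms = list(config.chrom_sizes)
    counts = _partition_counts(rng, list(config.chrom_sizes.values()), n_sites)
    sites = []  # (chrom, pos)
    for chrom, n_c in zip(chroms, counts):
        if n_c:
            for pos in _spaced_positions(rng, config.chrom_sizes[chrom], n_c,
                                         config.min_site_spacing):
                sites.append((chrom, int(pos)))
    order = rng.permutation(n_sites)
    complex_ix = set(order[: config.n_complex_regions].tolist())

    peaks: dict[str, list[GenomicInterval]] = {f: [] for f in factors}
    truth_sites = []
    lo, hi = config.peak_length
    for s_ix, (chrom, pos) in enumerate(sites):
        is_complex = s_ix in complex_ix
        if is_complex:
            emit = rng.random(k) < config.complex_emission
        else:
            emit = rng.random(k) < e_vec
            if sup_mask and _mask_of(emit) == sup_mask and rng.random() < config.suppression_strength:
                while _mask_of(emit) == sup_mask:
                    emit = rng.random(k) < e_vec
        site_peaks = {}
        for i, f in enumerate(factors):
            if not emit[i]:
                continue
            center = pos + int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
            length = int(rng.integers(lo, hi + 1))
            start = max(0, center - length // 2)
            end = min(config.chrom_sizes[chrom], start + length)
            peaks[f].append(GenomicInterval(chrom, start, end))
            site_peaks[f] = (start, end)
        truth_sites.append({
            "chrom": chrom, "pos": pos,
            "type": "complex" if is_complex else "background",
            "pattern": sorted(site_peaks),
            "peaks": site_peaks,
        })

    peaksets = {f: PeakSet(f, ivs) for f, ivs in peaks.items()}
    planted = _planted_genes(truth_sites, genes, config.distance_cap)
    truth = {
        "factors": factors,
        "sites": truth_sites,
        "planted_genes": sorted(planted),
        "realized_marginals": {f: len(ps) for f, ps in peaksets.items()},
    }
    return peaksets, truth


def _mask_of(emit: np.ndarray) -> int:
    return int((emit * (1 << np.arange(len(emit)))).sum())


def _planted_genes(truth_sites, genes: Sequence[GeneModel], cap: int) -> set[str]:
    """Genes allocated to complex sites, by brute-force application of
    the promoter/body/nearest-TSS rule (independent of the annotation
    module's indexed implementation)."""
    planted: set[str] = set()
    for site in truth_sites:
        if site["type"] != "complex" or not site["peaks"]:
            continue
        start = min(s for s, _ in site["peaks"].values())
        end = max(e for _, e in site["peaks"].values())
        chrom = site["chrom"]
        direct = set()
        for g in genes:
            if g.chrom != chrom:
                continue
            p = g.promoter
            if start < p.end and p.start < end:
                direct.add(g.gene_id)
            elif start < g.end and g.start < end:
                direct.add(g.gene_id)
        if direct:
            planted |= direct
            continue
        left = [(start - g.tss, g.gene_id) for g in genes
                if g.chrom == chrom and g.tss < start and start - g.tss <= cap]
        right = [(g.tss - (end - 1), g.gene_id) for g in genes
                 if g.chrom == chrom and g.tss >= end and g.tss - (end - 1) <= cap]
        if left:
            planted.add(min(left)[1])
        if right:
            planted.add(min(right)[1])
    return planted


# ---------------------------------------------------------------------------
# chromatin and expression


def generate_histone_and_expression(config: LandscapeConfig,
                                    genes: Sequence[GeneModel],
                                    truth: dict,
                                    peaksets: Mapping[str, PeakSet] | None = None
                                    ) -> tuple[dict[str, list[GenomicInterval]],
                                               pd.DataFrame, dict]:
    """Histone-mark peaks and an expression matrix coupled to truth.

    Promoter states are drawn conditionally on TF binding (bound
    promoters active-rich), marks are emitted per state (K4 for
    active, K4+K27 for bivalent, K27-or-nothing for inactive) with
    dropout/spurious noise, and expression couples to both state and
    planted-gene status.
    """
    rng = config.rng(3)
    bound_ids = _bound_promoters(truth, genes)

    states = {}
    state_names = ("active", "bivalent", "inactive")
    pb = np.array([config.state_probs_bound[s] for s in state_names])
    pu = np.array([config.state_probs_unbound[s] for s in state_names])
    pb, pu = pb / pb.sum(), pu / pu.sum()
    for g in genes:
        probs = pb if g.gene_id in bound_ids else pu
        states[g.gene_id] = state_names[rng.choice(3, p=probs)]

    marks: dict[str, list[GenomicInterval]] = {"H3K4me3": [], "H3K27me3": [], "H3ac": []}
    for g in genes:
        st = states[g.gene_id]
        want = {"H3K4me3": st in ("active", "bivalent"),
                "H3K27me3": st == "bivalent" or (st == "inactive" and rng.random() < 0.5),
                "H3ac": (st == "active" and rng.random() < 0.9)
                        or (st == "bivalent" and rng.random() < 0.3)}
        for mark, present in want.items():
            if present and rng.random() < config.mark_dropout:
                present = False
            elif not present and rng.random() < config.mark_spurious:
                present = True
            if present:
                win = g.promoter
                jit = int(rng.integers(-200, 201))
                start = max(0, win.start + jit)
                end = max(start + 1, win.end + jit)
                score = float(rng.lognormal(2.0, 0.5))
                marks[mark].append(GenomicInterval(g.chrom, start, end, score=score))
    for mark in marks:
        marks[mark].sort(key=lambda iv: (iv.chrom, iv.start))

    planted = set(truth.get("planted_genes", ()))
    gene_ids = [g.gene_id for g in genes]
    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=len(genes))
    expr = np.zeros((len(genes), len(config.cell_types)))
    for i, g in enumerate(genes):
        eff = config.state_effect[states[g.gene_id]]
        for j, ct in enumerate(config.cell_types):
            mu = base[i] + eff
            if ct == config.target_cell_type and g.gene_id in planted:
                mu += config.target_effect
            expr[i, j] = mu + rng.normal(0.0, config.expression_noise_sd)
    expression = pd.DataFrame(np.power(2.0, expr), index=gene_ids,
                              columns=list(config.cell_types))
    expression.index.name = "gene"

    truth = dict(truth)
    truth["promoter_states"] = states
    truth["bound_promoters"] = sorted(bound_ids)
    return marks, expression, truth


def _bound_promoters(truth: dict, genes: Sequence[GeneModel]) -> set[str]:
    peaks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for site in truth["sites"]:
        for start, end in site["peaks"].values():
            peaks_by_chrom.setdefault(site["chrom"], []).append((start, end))
    for v in peaks_by_chrom.values():
        v.sort()
    bound = set()
    for g in genes:
        win = g.promoter
        for start, end in peaks_by_chrom.get(g.chrom, ()):
            if start >= win.end:
                break
            if win.start < end and start < win.end:
                bound.add(g.gene_id)
                break
    return bound


# ---------------------------------------------------------------------------
# sequences


_BASES = np.array(list("ACGT"))


def _instantiate(rng, iupac: str) -> str:
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in iupac.upper())


def generate_sequences(config: LandscapeConfig, peaksets: Mapping[str, PeakSet]
                       ) -> tuple[dict[str, str], list, dict]:
    """Sequences for every union region, with pattern-driven motif planting.

    Returns ``(sequences, regions, embedding_truth)`` where ``regions``
    is the ``assign_patterns`` output the sequence ids refer to.
    """
    from .occupancy import assign_patterns
    rng = config.rng(4)
    ordered = [peaksets[f] for f in config.factors]
    regions, factor_order = assign_patterns(ordered)
    sequences: dict[str, str] = {}
    embeddings: dict[str, list] = {}
    for i, r in enumerate(regions):
        name = f"region_{i}"
        n = max(len(r.region), 60)
        seq = list(rng.choice(_BASES, size=n))
        embedded = []
        for rule in config.embedding_rules:
            if not rule.applies(r.factors) or rng.random() >= rule.prob:
                continue
            m = rule.motif
            if m.is_composite:
                gap = int(rng.integers(m.spacer_min, m.spacer_max + 1))
                inst = (_instantiate(rng, m.part1)
                        + "".join(rng.choice(_BASES, size=gap))
                        + _instantiate(rng, m.part2))
            else:
                inst = _instantiate(rng, m.iupac)
            if rng.random() < 0.5:
                inst = revcomp_seq(inst)
            if len(inst) >= n:
                continue
            pos = int(rng.integers(0, n - len(inst) + 1))
            seq[pos:pos + len(inst)] = list(inst)
            embedded.append({"motif": m.name, "pos": pos, "instance": inst})
        sequences[name] = "".join(seq)
        if embedded:
            embeddings[name] = embedded
    return sequences, regions, {"embeddings": embeddings,
                                "factor_order": factor_order}


# ---------------------------------------------------------------------------
# one-call generation and serialization


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def generate_all(config: LandscapeConfig, outdir) -> dict:
    """Generate and write every input the pipeline consumes.

    Layout: ``peaks/<factor>.bed``, ``genes.gtf``/``genes.bed12``,
    ``marks/<mark>.bed``, ``expression.tsv``, ``regions.fa``,
    ``truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "marks").mkdir(exist_ok=True)

    genes = generate_gene_models(config)
    write_gene_gtf(genes, outdir / "genes.gtf")
    write_gene_bed12(genes, outdir / "genes.bed12")

    peaksets, truth = generate_peak_landscape(config, genes)
    for f, ps in peaksets.items():
        write_bed(ps.intervals, outdir / "peaks" / f"{f}.bed",
                  names=[f"{f}_{i}" for i in range(len(ps))])

    marks, expression, truth = generate_histone_and_expression(config, genes, truth)
    for mark, ivs in marks.items():
        write_bed(ivs, outdir / "marks" / f"{mark}.bed",
                  names=[f"{mark}_{i}" for i in range(len(ivs))])
    write_expression(expression, outdir / "expression.tsv")

    sequences, regions, seq_truth = generate_sequences(config, peaksets)
    write_fasta(sequences, outdir / "regions.fa")
    truth["sequence_embeddings"] = seq_truth["embeddings"]

    with open(outdir / "truth.json", "w") as fh:
        json.dump(_jsonable(truth), fh, indent=1)
    return {
        "genes": genes, "peaksets": peaksets, "marks": marks,
        "expression": expression, "sequences": sequences,
        "regions": regions, "truth": truth, "outdir": outdir,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_to_dict(config: LandscapeConfig) -> dict:
    d = dataclasses.asdict(config)
    d["embedding_rules"] = [
        {"motif": r.motif.name, "iupac": r.motif.iupac, "part1": r.motif.part1,
         "part2": r.motif.part2, "spacer_min": r.motif.spacer_min,
         "spacer_max": r.motif.spacer_max, "factors": sorted(r.factors),
         "mode": r.mode, "prob": r.prob}
        for r in config.embedding_rules
    ]
    return _jsonable(d)


def config_from_dict(d: Mapping) -> LandscapeConfig:
    d = dict(d)
    rules = d.pop("embedding_rules", None)
    cfg = LandscapeConfig(**{k: v for k, v in d.items()})
    if rules is not None:
        cfg.embedding_rules = [
            EmbeddingRule(
                ConsensusMotif(r["motif"], r.get("iupac"), r.get("part1"),
                               r.get("part2"), r.get("spacer_min", 0),
                               r.get("spacer_max", 0)),
                frozenset(r["factors"]), r.get("mode", "any"), r.get("prob", 0.5))
            for r in rules
        ]
    return cfg
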