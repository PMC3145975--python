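"""Genomic intervals, peak sets and gene models.

All coordinates are 0-based half-open (BED convention) internally; GTF
input (1-based inclusive) is converted on read.  Chromosome names are
matched verbatim — no ``chr`` prefix normalization is attempted, but
:func:`chrom_concordance` reports mismatches between inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for a malformed BED/GTF line; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.score is not None and self.score < 0:
            raise ValueError(f"negative score {self.score}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    """Sorted, internally non-overlapping peaks for one factor.

    Overlapping same-factor input peaks are merged at construction: in
    the pattern logic a factor either binds a region or it does not,
    so multiplicity within a factor carries no information.
    """

    factor: str
    intervals: list[GenomicInterval]
    n_merged_away: int = 0

    def __post_init__(self):
        merged, dropped = _merge_sorted(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )
        if dropped:
            logger.info("PeakSet %s: merged away %d overlapping records", self.factor, dropped)
        self.intervals = merged
        self.n_merged_away = dropped

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def _merge_sorted(ivs: Sequence[GenomicInterval]) -> tuple[list[GenomicInterval], int]:
    """Merge overlapping or bookended sorted intervals.

    Bookended ([0,10) + [10,20)) intervals merge so that merged peaks
    coincide with maximal covered runs of a per-base coverage vector.
    """
    out: list[GenomicInterval] = []
    dropped = 0
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out[-1]
            out[-1] = GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end),
                                      score=prev.score, strand=prev.strand)
            dropped += 1
        else:
            out.append(iv)
    return out, dropped


@dataclass
class GeneModel:
    """A gene with TSS/TES and a strand-aware promoter window."""

    gene_id: str
    chrom: str
    start: int  # gene body [start, end), half-open
    end: int
    strand: str
    promoter_upstream: int = 1000
    promoter_downstream: int = 500

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: empty body")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: gene strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, strand=self.strand)

    @property
    def promoter(self) -> GenomicInterval:
        """Window around the TSS: upstream bp before, downstream bp after, strand-aware."""
        if self.strand == "+":
            lo = self.tss - self.promoter_upstream
            hi = self.tss + self.promoter_downstream
        else:
            lo = self.tss - self.promoter_downstream + 1
            hi = self.tss + self.promoter_upstream + 1
        return GenomicInterval(self.chrom, max(0, lo), max(1, hi), strand=self.strand)


# ---------------------------------------------------------------------------
# readers / writers


def _split_fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_peaks(path, factor: str) -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet` for one factor.

    ``track``/``browser``/comment lines are skipped.  Malformed lines
    raise :class:`BedParseError` naming the line number.  An empty file
    yields an empty PeakSet with a warning.
    """
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("track", "browser", "#")):
                continue
            fields = _split_fields(s)
            if len(fields) < 3:
                raise BedParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(path, lineno, f"non-integer coordinates {fields[1]!r}/{fields[2]!r}") from None
            if start < 0 or start >= end:
                raise BedParseError(path, lineno, f"invalid interval [{start}, {end})")
            score = None
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            ivs.append(GenomicInterval(chrom, start, end, score=score, strand=strand))
    if not ivs:
        logger.warning("read_peaks(%s): no records for factor %s", path, factor)
    return PeakSet(factor, ivs)


def read_scored_bed(path) -> list[GenomicInterval]:
    """Read a scored BED (e.g. a histone-mark peak file); score defaults to 1."""
    ps = read_peaks(path, factor=str(path))
    # re-read scores: PeakSet merging keeps the first score, which is fine
    # for presence/absence marks; callers needing raw records use this list.
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("track", "browser", "#")):
                continue
            f = _split_fields(s)
            if len(f) < 3:
                raise BedParseError(path, lineno, "expected >=3 columns")
            score = float(f[4]) if len(f) >= 5 else 1.0
            ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), score=score))
    del ps
    return sorted(ivs, key=lambda iv: (iv.chrom, iv.start))


def write_bed(records: Iterable[GenomicInterval], path, names: Sequence[str] | None = None) -> None:
    """Write intervals as tab-separated BED; round-trips through read_peaks."""
    records = list(records)
    with open(path, "w") as fh:
        for i, iv in enumerate(records):
            name = names[i] if names is not None else f"region_{i}"
            score = 0 if iv.score is None else iv.score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_gene_models(path, promoter_upstream: int = 1000,
                     promoter_downstream: int = 500) -> list[GeneModel]:
    """Read gene models from GTF (``gene_id`` attribute) or BED12/BED6.

    Format is sniffed from the extension (.gtf/.gff) and, failing that,
    from the column count.  GTF 1-based inclusive coordinates are
    converted to half-open.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        return _read_gtf(path, promoter_upstream, promoter_downstream)
    return _read_bed_genes(path, promoter_upstream, promoter_downstream)


def _read_gtf(path, up, down) -> list[GeneModel]:
    spans: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            f = s.split("\t")
            if len(f) < 9:
                raise BedParseError(path, lineno, f"expected 9 GTF columns, got {len(f)}")
            chrom, feature, start, end, strand, attrs = f[0], f[2], f[3], f[4], f[6], f[8]
            try:
                start_i, end_i = int(start) - 1, int(end)  # to half-open
            except ValueError:
                raise BedParseError(path, lineno, "non-integer coordinates") from None
            if start_i < 0 or start_i >= end_i:
                raise BedParseError(path, lineno, f"invalid interval [{start}, {end}]")
            gid = None
            for token in attrs.split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gid = token.split(None, 1)[1].strip().strip('"')
                    break
            if gid is None:
                raise BedParseError(path, lineno, "missing gene_id attribute")
            rec = spans.setdefault(gid, [chrom, start_i, end_i, strand])
            if feature == "gene":
                spans[gid] = [chrom, start_i, end_i, strand]
            else:
                rec[1] = min(rec[1], start_i)
                rec[2] = max(rec[2], end_i)
    return [
        GeneModel(gid, c, s, e, st, promoter_upstream=up, promoter_downstream=down)
        for gid, (c, s, e, st) in sorted(spans.items())
    ]


def _read_bed_genes(path, up, down) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("track", "browser", "#")):
                continue
            f = _split_fields(s)
            if len(f) < 6:
                raise BedParseError(path, lineno, "gene BED needs >=6 columns (name, strand)")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise BedParseError(path, lineno, "non-integer coordinates") from None
            if start < 0 or start >= end:
                raise BedParseError(path, lineno, f"invalid interval [{start}, {end})")
            genes.append(GeneModel(f[3], f[0], start, end, f[5],
                                   promoter_upstream=up, promoter_downstream=down))
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def write_gene_bed12(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as BED12 (single-block genes)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            size = g.end - g.start
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{size},\t0,\n"
            )


def write_gene_gtf(genes: Sequence[GeneModel], path, source: str = "mkcobind") -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


# ---------------------------------------------------------------------------
# interval algebra


def merge_union(peaksets: Sequence[PeakSet], min_overlap: int = 1
                ) -> list[tuple[GenomicInterval, frozenset[str]]]:
    """Union regions over all peak sets, annotated with bound factors.

    A union region is a maximal interval covered by >=1 peak of any
    factor — exactly a maximal covered run of the per-base coverage
    vector, so bookended peaks fall in one region.  A factor is
    annotated on a region when its peaks intersect
    the region by at least ``min_overlap`` bp in total.  Regions
    partition the union of all input peaks.
    """
    if not peaksets:
        raise ValueError("need at least one PeakSet")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    labels = [ps.factor for ps in peaksets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate factor labels in {labels}")

    tagged: list[tuple[str, int, int, str]] = []
    for ps in peaksets:
        for iv in ps.intervals:
            tagged.append((iv.chrom, iv.start, iv.end, ps.factor))
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))

    out: list[tuple[GenomicInterval, frozenset[str]]] = []
    cur: list[tuple[str, int, int, str]] = []

    def flush():
        if not cur:
            return
        chrom = cur[0][0]
        lo = min(t[1] for t in cur)
        hi = max(t[2] for t in cur)
        region = GenomicInterval(chrom, lo, hi)
        bp: dict[str, int] = {}
        for _, s, e, fac in cur:
            bp[fac] = bp.get(fac, 0) + (min(e, hi) - max(s, lo))
        bound = frozenset(f for f, n in bp.items() if n >= min_overlap)
        out.append((region, bound))

    cur_end = None
    cur_chrom = None
    for chrom, start, end, fac in tagged:
        if cur and chrom == cur_chrom and start <= cur_end:
            cur.append((chrom, start, end, fac))
            cur_end = max(cur_end, end)
        else:
            flush()
            cur = [(chrom, start, end, fac)]
            cur_chrom, cur_end = chrom, end
    flush()
    return out


def chrom_concordance(*chrom_sets: set[str]) -> dict[str, set[str]]:
    """Report chromosome names missing from the intersection of inputs."""
    if not chrom_sets:
        return {}
    common = set.intersection(*[set(cs) for cs in chrom_sets])
    report = {}
    for i, cs in enumerate(chrom_sets):
        extra = set(cs) - common
        if extra:
            report[f"input_{i}"] = extra
    return report
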