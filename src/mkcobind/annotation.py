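"""Peak-to-gene assignment and promoter/intragenic/intergenic breakdown.

The allocation rule: regions overlapping a promoter window or a gene
body are allocated to that gene (all such genes when several overlap);
remaining (intergenic) regions go to the nearest gene on each side by
TSS distance, each side only within a 100 kb cap.  Location categories
are a partition with precedence promoter > intragenic > intergenic.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Sequence

from .intervals import GeneModel, GenomicInterval
from .occupancy import OccupancyRegion, nonempty_patterns

DISTANCE_CAP = 100_000

CATEGORIES = ("promoter", "intragenic", "intergenic")


@dataclass
class PeakGeneAssignment:
    region_id: str
    category: str
    genes: list[tuple[str, int]] = field(default_factory=list)  # (gene_id, distance bp)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in ("promoter", "intragenic"):
            assert all(d == 0 for _, d in self.genes)
        else:
            if len(self.genes) > 2:
                raise ValueError("intergenic region assigned to more than two genes")
            if any(d > DISTANCE_CAP for _, d in self.genes):
                raise ValueError(f"assignment beyond {DISTANCE_CAP} bp cap")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]


class GeneIndex:
    """Per-chromosome gene lookup used by the assignment rule."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        self.tss_sorted: dict[str, list[tuple[int, str, GeneModel]]] = {}
        for chrom, gs in self.by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.gene_id))
            # ties on TSS broken toward the alphabetically first gene_id
            self.tss_sorted[chrom] = sorted(((g.tss, g.gene_id, g) for g in gs),
                                            key=lambda t: (t[0], t[1]))


def classify_location(region: GenomicInterval, index: GeneIndex) -> str:
    """promoter > intragenic > intergenic, by overlap with windows/bodies."""
    genes = index.by_chrom.get(region.chrom, ())
    hit_body = False
    for g in genes:
        if region.overlaps(g.promoter):
            return "promoter"
        if region.overlaps(g.body):
            hit_body = True
    return "intragenic" if hit_body else "intergenic"


def map_region_to_genes(region: GenomicInterval, index: GeneIndex,
                        region_id: str = "region",
                        distance_cap: int = DISTANCE_CAP) -> PeakGeneAssignment:
    """Apply the allocation rule to one region.

    Distances are measured from the nearest region edge to the TSS.
    Intergenic assignment may be empty when no TSS lies within the cap
    on either side.
    """
    genes = index.by_chrom.get(region.chrom, ())
    promoter_hits = sorted(g.gene_id for g in genes if region.overlaps(g.promoter))
    if promoter_hits:
        return PeakGeneAssignment(region_id, "promoter", [(g, 0) for g in promoter_hits])
    body_hits = sorted(g.gene_id for g in genes if region.overlaps(g.body))
    if body_hits:
        return PeakGeneAssignment(region_id, "intragenic", [(g, 0) for g in body_hits])

    tsses = index.tss_sorted.get(region.chrom, [])
    assigned: list[tuple[str, int]] = []
    # nearest TSS strictly left of the region start
    i = bisect_left(tsses, (region.start, "", None)) - 1
    if i >= 0:
        while i > 0 and tsses[i - 1][0] == tsses[i][0]:
            i -= 1  # equal-TSS tie goes to the alphabetically first gene_id
        tss, gid, _ = tsses[i]
        d = region.start - tss
        if d <= distance_cap:
            assigned.append((gid, d))
    # nearest TSS at or right of the region end
    j = bisect_left(tsses, (region.end, "", None))
    if j < len(tsses):
        tss, gid, _ = tsses[j]
        d = tss - (region.end - 1)
        if d <= distance_cap:
            assigned.append((gid, d))
    return PeakGeneAssignment(region_id, "intergenic", assigned)


def assign_all(regions: Sequence[OccupancyRegion], genes: Sequence[GeneModel],
               distance_cap: int = DISTANCE_CAP) -> list[PeakGeneAssignment]:
    index = GeneIndex(genes)
    return [
        map_region_to_genes(r.region, index, region_id=f"region_{i}",
                            distance_cap=distance_cap)
        for i, r in enumerate(regions)
    ]


def location_fractions(assignments: Sequence[PeakGeneAssignment]) -> dict[str, float]:
    n = len(assignments)
    return {c: (sum(a.category == c for a in assignments) / n if n else 0.0)
            for c in CATEGORIES}


def build_target_gene_lists(regions: Sequence[OccupancyRegion],
                            genes: Sequence[GeneModel],
                            k: int | None = None,
                            distance_cap: int = DISTANCE_CAP) -> dict[int, set[str]]:
    """One gene set per exact occupancy pattern (31 lists for 5 factors).

    A gene joins the list of pattern S when >=1 region with exact
    pattern S is allocated to it; genes may appear on several lists.
    """
    index = GeneIndex(genes)
    if k is None:
        k = max(r.pattern for r in regions).bit_length() if regions else 0
    lists: dict[int, set[str]] = {p: set() for p in nonempty_patterns(k)}
    for i, r in enumerate(regions):
        a = map_region_to_genes(r.region, index, region_id=f"region_{i}",
                                distance_cap=distance_cap)
        lists.setdefault(r.pattern, set()).update(a.gene_ids)
    return lists


def write_assignments(assignments: Sequence[PeakGeneAssignment], path,
                      header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("region\tgene\tcategory\tdistance\n")
        for a in assignments:
            if a.genes:
                for g, d in a.genes:
                    fh.write(f"{a.region_id}\t{g}\t{a.category}\t{d}\n")
            else:
                fh.write(f"{a.region_id}\t.\t{a.category}\t.\n")


def write_target_gene_lists(lists: dict[int, set[str]], factor_order: Sequence[str],
                            path, header_lines: Sequence[str] = ()) -> None:
    from .occupancy import pattern_name
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("pattern\tgene\n")
        for p in sorted(lists):
            for g in sorted(lists[p]):
                fh.write(f"{pattern_name(p, factor_order)}\t{g}\n")
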