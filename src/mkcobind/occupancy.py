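"""Occupancy patterns: which exact subset of factors binds each union region.

A *pattern* is a bitmask over the ordered factor list (bit ``i`` set =
factor ``i`` bound).  Exact-pattern counts (region bound by precisely
the subset S) and at-least counts (bound by S and possibly more) are
both first-class: published co-binding figures mix the two conventions,
so each is computed explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, PeakSet, merge_union


@dataclass(frozen=True)
class OccupancyRegion:
    region: GenomicInterval
    pattern: int  # bitmask, != 0
    factors: frozenset[str] = field(default=frozenset())

    def __post_init__(self):
        if self.pattern == 0:
            raise ValueError("union region must be bound by at least one factor")


@dataclass
class PatternTable:
    """Exact-pattern counts over the ordered factor list."""

    factor_order: list[str]
    exact_counts: dict[int, int]
    n_regions: int

    def __post_init__(self):
        if sum(self.exact_counts.values()) != self.n_regions:
            raise ValueError("exact counts must sum to the number of regions")

    @property
    def k(self) -> int:
        return len(self.factor_order)

    def count(self, pattern: int) -> int:
        return self.exact_counts.get(pattern, 0)


def pattern_name(pattern: int, factor_order: Sequence[str], sep: str = "+") -> str:
    if pattern <= 0:
        raise ValueError("pattern must be a nonempty bitmask")
    return sep.join(f for i, f in enumerate(factor_order) if pattern >> i & 1)


def pattern_from_factors(factors: Iterable[str], factor_order: Sequence[str]) -> int:
    index = {f: i for i, f in enumerate(factor_order)}
    mask = 0
    for f in factors:
        mask |= 1 << index[f]
    return mask


def nonempty_patterns(k: int) -> list[int]:
    """All 2^k - 1 nonempty patterns (for k=5: the 31 target-list patterns)."""
    return list(range(1, 1 << k))


def multi_factor_patterns(k: int) -> list[int]:
    """Patterns with >=2 factors (for k=5: the 26 reported combinations)."""
    return [p for p in nonempty_patterns(k) if bin(p).count("1") >= 2]


def assign_patterns(peaksets: Sequence[PeakSet], min_overlap: int = 1
                    ) -> tuple[list[OccupancyRegion], list[str]]:
    """Union regions with their exact binding pattern over K ordered factors.

    Returns ``(regions, factor_order)``; factor order is the input
    PeakSet order and fixes the bitmask convention downstream.
    """
    k = len(peaksets)
    if not 1 <= k <= 16:
        raise ValueError(f"need 1..16 factors, got {k}")
    factor_order = [ps.factor for ps in peaksets]
    if len(set(factor_order)) != k:
        raise ValueError(f"duplicate factor labels: {factor_order}")
    regions = []
    for region, bound in merge_union(peaksets, min_overlap=min_overlap):
        mask = pattern_from_factors(bound, factor_order)
        if mask == 0:
            # possible only when min_overlap exceeds every peak's overlap;
            # such a region is not bound under the co-binding criterion.
            continue
        regions.append(OccupancyRegion(region, mask, frozenset(bound)))
    return regions, factor_order


def count_exact_patterns(regions: Sequence[OccupancyRegion],
                         factor_order: Sequence[str]) -> PatternTable:
    """Tabulate every realized pattern; unrealized patterns count 0."""
    counts = {p: 0 for p in nonempty_patterns(len(factor_order))}
    for r in regions:
        counts[r.pattern] += 1
    return PatternTable(list(factor_order), counts, n_regions=len(regions))


def count_at_least(table: PatternTable, subset: int) -> int:
    """Regions bound by at least the factors in ``subset`` (any superset)."""
    if subset == 0:
        raise ValueError("subset must be nonempty")
    if subset >= 1 << table.k:
        raise ValueError(f"subset {subset:#b} uses bits outside the {table.k}-factor order")
    return sum(c for p, c in table.exact_counts.items() if p & subset == subset)


def marginal_counts(table: PatternTable) -> dict[str, int]:
    """Per-factor region counts (at-least singleton counts)."""
    return {f: count_at_least(table, 1 << i) for i, f in enumerate(table.factor_order)}


# ---------------------------------------------------------------------------
# serialization


def write_pattern_table(table: PatternTable, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("pattern\tn_factors\tcount\n")
        for p in nonempty_patterns(table.k):
            fh.write(f"{pattern_name(p, table.factor_order)}\t{bin(p).count('1')}\t{table.count(p)}\n")


def read_pattern_table(path, factor_order: Sequence[str]) -> PatternTable:
    counts: dict[int, int] = {p: 0 for p in nonempty_patterns(len(factor_order))}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("pattern\t"):
                continue
            name, _, count = line.rstrip("\n").split("\t")
            counts[pattern_from_factors(name.split("+"), factor_order)] = int(count)
    return PatternTable(list(factor_order), counts, n_regions=sum(counts.values()))


def pattern_table_to_json(table: PatternTable) -> str:
    return json.dumps(
        {
            "factor_order": table.factor_order,
            "n_regions": table.n_regions,
            "exact_counts": {
                pattern_name(p, table.factor_order): c
                for p, c in sorted(table.exact_counts.items())
            },
        },
        indent=2,
    )
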