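"""Promoter chromatin-state classification from histone-mark signal.

Promoters are classified three ways from H3K4me3 (activating) and
H3K27me3 (repressive) signal in the promoter window:

* ``active``   — K4 present, K27 absent
* ``bivalent`` — K4 and K27 both present
* ``inactive`` — K4 absent (with or without K27)

Marks arrive as called peak regions (scored BED).  In the default
``called`` mode a mark is present when any called peak overlaps the
promoter window with positive score; in ``quantile`` mode the summed
score in the window is thresholded at a quantile of the nonzero
genome-wide distribution (default 75th percentile).  H3 acetylation is
accepted and reported alongside but does not enter the 3-way rule.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval
from .occupancy import OccupancyRegion

logger = logging.getLogger(__name__)

STATES = ("inactive", "bivalent", "active")


@dataclass
class PromoterState:
    gene_id: str
    k4_signal: float
    k27_signal: float
    k9k14ac_signal: float | None
    state: str

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")


def _window_signal(window: GenomicInterval, marks: Sequence[GenomicInterval]) -> float:
    """Sum of score x overlap-fraction for mark peaks hitting the window."""
    total = 0.0
    # marks sorted by (chrom, start); linear scan per window is fine at
    # the scales this package targets (hundreds of genes)
    for m in marks:
        if m.chrom != window.chrom:
            continue
        ov = window.overlap_bp(m)
        if ov > 0:
            total += (m.score if m.score is not None else 1.0) * ov / len(m)
    return total


def classify_promoters(k4: Sequence[GenomicInterval], k27: Sequence[GenomicInterval],
                       genes: Sequence[GeneModel],
                       h3ac: Sequence[GenomicInterval] | None = None,
                       mode: str = "called",
                       quantile: float = 0.75) -> list[PromoterState]:
    """Classify every gene promoter as inactive / bivalent / active.

    Genes without any mark record get zero signal and are inactive.
    """
    if mode not in ("called", "quantile"):
        raise ValueError("mode must be 'called' or 'quantile'")
    k4_sig = np.array([_window_signal(g.promoter, k4) for g in genes])
    k27_sig = np.array([_window_signal(g.promoter, k27) for g in genes])
    ac_sig = (np.array([_window_signal(g.promoter, h3ac) for g in genes])
              if h3ac is not None else None)

    if mode == "called":
        tau4 = tau27 = 0.0
    else:
        tau4 = float(np.quantile(k4_sig[k4_sig > 0], quantile)) if (k4_sig > 0).any() else 0.0
        tau27 = float(np.quantile(k27_sig[k27_sig > 0], quantile)) if (k27_sig > 0).any() else 0.0

    out = []
    for i, g in enumerate(genes):
        has4 = k4_sig[i] > tau4
        has27 = k27_sig[i] > tau27
        state = "active" if (has4 and not has27) else "bivalent" if (has4 and has27) else "inactive"
        out.append(PromoterState(g.gene_id, float(k4_sig[i]), float(k27_sig[i]),
                                 None if ac_sig is None else float(ac_sig[i]), state))
    return out


def bound_fraction_by_state(states: Sequence[PromoterState],
                            regions: Sequence[OccupancyRegion],
                            genes: Sequence[GeneModel],
                            factor_order: Sequence[str]
                            ) -> pd.DataFrame:
    """Fraction of promoters bound, per chromatin state.

    A promoter is "bound" (column ``any``) when any union region
    overlaps its window; per-factor columns require the overlapping
    region's pattern to include that factor.  Empty state classes
    yield NaN, never a fabricated 0.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    by_chrom: dict[str, list[OccupancyRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.region.chrom, []).append(r)
    for rs in by_chrom.values():
        rs.sort(key=lambda r: r.region.start)

    def bound_mask(g: GeneModel) -> int:
        win = g.promoter
        mask = 0
        for r in by_chrom.get(win.chrom, ()):
            if r.region.start >= win.end:
                break
            if win.overlaps(r.region):
                mask |= r.pattern
        return mask

    rows = {}
    masks = {s.gene_id: bound_mask(gene_by_id[s.gene_id])
             for s in states if s.gene_id in gene_by_id}
    for state in STATES:
        members = [s.gene_id for s in states if s.state == state and s.gene_id in gene_by_id]
        if not members:
            rows[state] = {"n": 0, "any": np.nan,
                           **{f: np.nan for f in factor_order}}
            logger.warning("state class %r is empty; fractions undefined", state)
            continue
        ms = [masks[g] for g in members]
        row = {"n": len(members), "any": float(np.mean([m != 0 for m in ms]))}
        for i, f in enumerate(factor_order):
            row[f] = float(np.mean([(m >> i) & 1 for m in ms]))
        rows[state] = row
    return pd.DataFrame(rows).T


def expression_by_state(states: Sequence[PromoterState], expression: pd.DataFrame,
                        cell_type: str) -> pd.DataFrame:
    """Median and IQR of expression in ``cell_type``, per promoter state."""
    if cell_type not in expression.columns:
        raise KeyError(f"cell type {cell_type!r} not in expression matrix "
                       f"(have {list(expression.columns)})")
    ids = {s.gene_id for s in states}
    common = ids & set(expression.index)
    if not common:
        raise ValueError("no genes shared between promoter states and expression matrix")
    dropped = len(ids) - len(common)
    if dropped:
        logger.info("expression_by_state: %d genes missing from expression matrix", dropped)
    col = expression[cell_type]
    rows = {}
    for state in STATES:
        members = [s.gene_id for s in states if s.state == state and s.gene_id in common]
        if not members:
            rows[state] = {"n": 0, "median": np.nan, "q25": np.nan, "q75": np.nan}
            continue
        vals = col.loc[members].to_numpy(dtype=float)
        rows[state] = {
            "n": len(vals),
            "median": float(np.median(vals)),
            "q25": float(np.quantile(vals, 0.25)),
            "q75": float(np.quantile(vals, 0.75)),
        }
    return pd.DataFrame(rows).T
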