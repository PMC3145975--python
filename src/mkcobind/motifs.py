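"""IUPAC consensus-motif scanning and enrichment in sequence subsets.

Scanning is exact consensus matching (no PWM scores): a motif matches
wherever every position is compatible with the IUPAC code, on either
strand.  Composite motifs are two parts in fixed order separated by a
bounded spacer on the same strand.  A match is counted once per start
position — overlapping matches at different offsets count separately,
while a palindromic site matching both strands at the same start
counts once.

The default library holds the consensus elements relevant to the
GATA1/GATA2/RUNX1/FLI1/SCL circuit: GATA (WGATAR), E-box (CANNTG),
ETS (GGAW), RUNX (TGYGGT) and the E-box/GATA composite that marks
SCL:GATA complex docking sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_iupac(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def revcomp_seq(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _validate_iupac(s: str) -> None:
    bad = set(s.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC characters {sorted(bad)} in {s!r}")


def iupac_regex(motif: str) -> re.Pattern:
    _validate_iupac(motif)
    return re.compile("".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in motif.upper()
    ))


@dataclass(frozen=True)
class ConsensusMotif:
    name: str
    iupac: str | None = None
    part1: str | None = None
    part2: str | None = None
    spacer_min: int = 0
    spacer_max: int = 0

    def __post_init__(self):
        if self.is_composite:
            _validate_iupac(self.part1)
            _validate_iupac(self.part2)
            if self.spacer_min > self.spacer_max or self.spacer_min < 0:
                raise ValueError("invalid spacer range")
        elif self.iupac is None:
            raise ValueError("motif needs either iupac or part1+part2")
        else:
            _validate_iupac(self.iupac)

    @property
    def is_composite(self) -> bool:
        return self.part1 is not None and self.part2 is not None

    @property
    def min_length(self) -> int:
        if self.is_composite:
            return len(self.part1) + self.spacer_min + len(self.part2)
        return len(self.iupac)


DEFAULT_MOTIFS = [
    ConsensusMotif("GATA", "WGATAR"),
    ConsensusMotif("Ebox", "CANNTG"),
    ConsensusMotif("ETS", "GGAW"),
    ConsensusMotif("RUNX", "TGYGGT"),
    ConsensusMotif("Ebox_GATA_composite", part1="CANNTG", part2="WGATAR",
                   spacer_min=2, spacer_max=10),
]


def _simple_starts(seq: str, motif: str) -> list[int]:
    """Forward-strand start positions (overlapping allowed)."""
    pat = iupac_regex(motif)
    return [m.start() for m in re.finditer(f"(?={pat.pattern})", seq)]


def _composite_spans(seq: str, part1: str, part2: str,
                     smin: int, smax: int) -> list[tuple[int, int]]:
    """(start, end) spans of every part1-spacer-part2 arrangement."""
    p1 = _simple_starts(seq, part1)
    p2 = set(_simple_starts(seq, part2))
    l1, l2 = len(part1), len(part2)
    out = []
    for i in p1:
        for gap in range(smin, smax + 1):
            j = i + l1 + gap
            if j in p2:
                out.append((i, j + l2))
    return out


def match_positions(seq: str, motif: ConsensusMotif) -> list[tuple[int, int, str]]:
    """All matches as (start, end, strand) in forward coordinates.

    Overlapping matches at different spans count separately; a
    palindromic site matching both strands over the same span is
    collapsed to a single '+' entry.  The span set is invariant under
    reverse complementation of the sequence.
    """
    seq = seq.upper()
    n = len(seq)
    if motif.is_composite:
        fwd = _composite_spans(seq, motif.part1, motif.part2,
                               motif.spacer_min, motif.spacer_max)
        # reverse-strand composite reads revcomp(part2)-spacer-revcomp(part1)
        # on the forward strand, so scan it directly in forward coordinates
        rev = _composite_spans(seq, revcomp_iupac(motif.part2),
                               revcomp_iupac(motif.part1),
                               motif.spacer_min, motif.spacer_max)
    else:
        m = len(motif.iupac)
        fwd = [(i, i + m) for i in _simple_starts(seq, motif.iupac)]
        rev = [(n - i - m, n - i) for i in _simple_starts(revcomp_seq(seq), motif.iupac)]
    out = {(s, e, "+") for s, e in fwd}
    for s, e in rev:
        if (s, e, "+") not in out:
            out.add((s, e, "-"))
    return sorted(out)


def count_matches(seq: str, motif: ConsensusMotif) -> int:
    return len(match_positions(seq, motif))


def scan_consensus(sequences: Mapping[str, str], motif: ConsensusMotif
                   ) -> dict[str, list[tuple[int, int, str]]]:
    """Per-sequence match (start, end, strand) lists for one motif."""
    return {name: match_positions(s, motif) for name, s in sequences.items()}


@dataclass
class MotifEnrichment:
    motif: str
    target_with: int
    target_total: int
    background_with: int
    background_total: int
    fold: float
    odds_ratio: float
    p_value: float

    @property
    def target_fraction(self) -> float:
        return self.target_with / self.target_total

    @property
    def background_fraction(self) -> float:
        return self.background_with / self.background_total


def motif_enrichment_test(target: Mapping[str, str], background: Mapping[str, str],
                          motif: ConsensusMotif) -> MotifEnrichment:
    """Fisher exact test on sequences with >=1 match, target vs background.

    Fold is the ratio of with-motif fractions; the odds ratio uses a
    Haldane 0.5 continuity correction when the 2x2 table is degenerate.
    """
    if not target or not background:
        raise ValueError("target and background sets must be non-empty")
    a = sum(1 for s in target.values() if count_matches(s, motif) > 0)
    b = len(target) - a
    c = sum(1 for s in background.values() if count_matches(s, motif) > 0)
    d = len(background) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    tf = a / len(target)
    bf = c / len(background)
    fold = tf / bf if bf > 0 else float("inf") if tf > 0 else 1.0
    return MotifEnrichment(motif.name, a, len(target), c, len(background),
                           fold, odds, float(p))


def write_motif_report(results: Sequence[MotifEnrichment], path,
                       header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("motif\ttarget_frac\tbackground_frac\tfold\todds_ratio\tp_value\n")
        for r in results:
            fh.write(f"{r.motif}\t{r.target_fraction:.4g}\t{r.background_fraction:.4g}\t"
                     f"{r.fold:.4g}\t{r.odds_ratio:.4g}\t{r.p_value:.4g}\n")
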