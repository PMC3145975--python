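"""Running-sum gene-set enrichment against a cell-type expression ranking.

Genes are ranked by log2 ratio of the target cell type over the mean of
the other cell types (pseudocount-offset).  For a gene set S of size
Nh in a ranking of N genes with scores s_r, the weighted
Kolmogorov-Smirnov running sum increments by |s_r|^p / NR at hits
(NR = sum of |s|^p over hits) and decrements by 1/(N - Nh) at misses;
the enrichment score ES is the signed extremum.  Significance uses
gene-set permutation (random same-size sets), normalization by the
mean same-sign null ES, and the pooled-null FDR q computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GSEA_HEADER = ("ranking=log2(target/mean(others)) with pseudocount; "
               "null=gene-set permutation (one expression profile per cell type); weight p=1")


@dataclass
class RankedGeneList:
    genes: list[str]          # descending by score; ties broken by gene id
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranking scores must be finite")
        order = np.diff(self.scores)
        if (order > 1e-12).any():
            raise ValueError("scores must be in descending order")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class GseaResult:
    name: str
    size: int
    es: float
    nes: float
    fdr_q: float
    running_sum: np.ndarray = field(repr=False)


def rank_genes(expression: pd.DataFrame, target: str,
               pseudocount: float = 1.0) -> RankedGeneList:
    """Rank all genes by target-vs-rest log2 expression ratio.

    ``expression`` is genes x cell types (linear scale).  Requires >=2
    cell types.  Non-positive expression with ``pseudocount=0`` is an
    error.  Deterministic: ties are broken by gene id, so input row
    order never changes the output.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    if target not in expression.columns:
        raise KeyError(f"target cell type {target!r} not in matrix")
    others = expression.drop(columns=[target])
    t = expression[target].to_numpy(dtype=float)
    rest = others.to_numpy(dtype=float).mean(axis=1)
    if pseudocount == 0 and ((t <= 0).any() or (rest <= 0).any()):
        raise ValueError("non-positive expression requires a pseudocount")
    score = np.log2((t + pseudocount) / (rest + pseudocount))
    df = pd.DataFrame({"gene": expression.index.astype(str), "score": score})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return RankedGeneList(df["gene"].tolist(), df["score"].to_numpy())


def enrichment_score(ranked: RankedGeneList, gene_set: Sequence[str],
                     weight_p: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted KS running sum and its signed extremum ES.

    The set must have a proper, nonempty intersection with the ranking.
    The running sum ends at 0 by construction.  When the positive and
    negative extrema tie in absolute value, the earlier rank wins.
    """
    idx = ranked.index
    hit_pos = sorted(idx[g] for g in set(gene_set) if g in idx)
    n = len(ranked)
    nh = len(hit_pos)
    if nh == 0 or nh == n:
        raise ValueError(f"degenerate gene set: {nh} of {n} genes in ranking")
    hits = np.zeros(n, dtype=bool)
    hits[hit_pos] = True
    w = np.abs(ranked.scores) ** weight_p
    nr = w[hits].sum()
    steps = np.where(hits, (w / nr if nr > 0 else 1.0 / nh), -1.0 / (n - nh))
    if nr == 0:
        # all hit scores are exactly 0 (possible at p>0): fall back to
        # unweighted increments so the statistic stays defined
        steps = np.where(hits, 1.0 / nh, -1.0 / (n - nh))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _nes(es: float, null_es: np.ndarray) -> float:
    same = null_es[null_es > 0] if es >= 0 else null_es[null_es < 0]
    denom = np.abs(same).mean() if same.size else np.abs(null_es).mean()
    if denom == 0:
        return 0.0
    return float(es / denom)


def significance(ranked: RankedGeneList, gene_sets: Mapping[object, Sequence[str]],
                 permutations: int = 200, seed: int = 0,
                 weight_p: float = 1.0) -> list[GseaResult]:
    """ES/NES/FDR-q for each gene set via gene-set permutation.

    Null ES values come from random gene sets of matched size; NES
    normalizes by the mean same-sign null ES; q for a set is the
    pooled-null tail fraction at its NES divided by the observed tail
    fraction, clipped to [0, 1] and made monotone in |NES| within each
    sign.  Sets with no genes in the ranking are skipped.
    """
    if permutations < 100:
        raise ValueError("permutations must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    names, sizes, es_obs, runnings = [], [], [], []
    for name in gene_sets:
        gs = [g for g in set(gene_sets[name]) if g in ranked.index]
        if not gs:
            continue
        if len(gs) >= n:
            raise ValueError(f"gene set {name!r} spans the whole ranking")
        es, run = enrichment_score(ranked, gs, weight_p)
        names.append(name)
        sizes.append(len(gs))
        es_obs.append(es)
        runnings.append(run)

    # shared null ES per distinct set size
    null_by_size: dict[int, np.ndarray] = {}
    w = np.abs(ranked.scores) ** weight_p
    for size in sorted(set(sizes)):
        null = np.empty(permutations)
        for b in range(permutations):
            pos = rng.choice(n, size=size, replace=False)
            hits = np.zeros(n, dtype=bool)
            hits[pos] = True
            nr = w[hits].sum()
            steps = np.where(hits, (w / nr if nr > 0 else 1.0 / size), -1.0 / (n - size))
            running = np.cumsum(steps)
            null[b] = running[int(np.argmax(np.abs(running)))]
        null_by_size[size] = null

    nes_obs = np.array([_nes(es_obs[i], null_by_size[sizes[i]]) for i in range(len(names))])
    null_nes = np.concatenate([
        np.array([_nes(e, null_by_size[size]) for e in null_by_size[size]])
        for size in sorted(set(sizes))
    ]) if names else np.array([])

    qs = np.ones(len(names))
    for i, nes in enumerate(nes_obs):
        if nes >= 0:
            tail_null = np.mean(null_nes >= nes) if null_nes.size else 1.0
            tail_obs = np.mean(nes_obs >= nes)
        else:
            tail_null = np.mean(null_nes <= nes) if null_nes.size else 1.0
            tail_obs = np.mean(nes_obs <= nes)
        qs[i] = min(1.0, tail_null / tail_obs) if tail_obs > 0 else 1.0
    # q must not decrease as |NES| drops (BH-style monotonicity per sign)
    for sign in (1, -1):
        ix = [i for i in range(len(names)) if (nes_obs[i] >= 0) == (sign > 0)]
        ix.sort(key=lambda i: -abs(nes_obs[i]))  # most extreme first
        prev = 0.0
        for i in ix:
            qs[i] = max(qs[i], prev)
            prev = qs[i]

    results = [
        GseaResult(names[i], sizes[i], es_obs[i], float(nes_obs[i]), float(qs[i]), runnings[i])
        for i in range(len(names))
    ]
    results.sort(key=lambda r: -abs(r.nes))
    return results


def write_gsea_report(results: Sequence[GseaResult], path,
                      header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {GSEA_HEADER}\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_set\tsize\tes\tnes\tfdr_q\n")
        for r in results:
            fh.write(f"{r.name}\t{r.size}\t{r.es:.6g}\t{r.nes:.6g}\t{r.fdr_q:.6g}\n")
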