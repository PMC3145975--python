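"""Independence null model and Z-scores for co-occupancy patterns.

The null assumes a fixed universe of N bindable regions and independent
per-region binding of factor i with probability p_i = n_i / N, where
n_i is the factor's marginal region count.  Each region then shows the
exact pattern S with probability

    p_S = prod_{i in S} p_i * prod_{j not in S} (1 - p_j)

so the exact count O_S is Binomial(N, p_S): E_S = N p_S and
V_S = N p_S (1 - p_S), and Z_S = (O_S - E_S) / sqrt(V_S) under the
normal approximation.  A Monte-Carlo simulator of the same per-region
Bernoulli process is provided so the analytic approximation is
auditable; the simulator draws raw indicator columns and never reuses
the closed-form p_S.

The variance form (binomial vs. permutation) of the original analysis
is not published; every report written from this module states the
model used in its header.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .occupancy import (PatternTable, multi_factor_patterns, nonempty_patterns,
                        pattern_name)

#: The study-scale default for the count of genomic regions potentially
#: available for binding (a published lower-end estimate).
DEFAULT_UNIVERSE_N = 80_000

NULL_MODEL_HEADER = (
    "null=per-region independent Bernoulli (binomial variance, normal approximation); "
    "not a permutation scheme"
)


@dataclass
class NullModel:
    universe_n: int
    marginals: dict[str, int]

    def __post_init__(self):
        for f, n in self.marginals.items():
            if not 0 < n <= self.universe_n:
                raise ValueError(
                    f"marginal for {f} is {n}, outside (0, N={self.universe_n}]: "
                    "universe too small")

    @property
    def factor_order(self) -> list[str]:
        return list(self.marginals)

    @property
    def probs(self) -> np.ndarray:
        return np.array([n / self.universe_n for n in self.marginals.values()])

    @classmethod
    def from_table(cls, table: PatternTable, universe_n: int = DEFAULT_UNIVERSE_N) -> "NullModel":
        """Marginals taken from the realized region-level pattern table."""
        from .occupancy import marginal_counts
        return cls(universe_n, marginal_counts(table))


@dataclass
class PatternStats:
    pattern: int
    name: str
    observed: int
    expected: float
    variance: float
    zscore: float


def pattern_probability(pattern: int, probs: np.ndarray) -> float:
    p = 1.0
    for i, pi in enumerate(probs):
        p *= pi if pattern >> i & 1 else (1.0 - pi)
    return p


def expected_pattern_counts(model: NullModel) -> dict[int, tuple[float, float]]:
    """Analytic (E_S, V_S) for every nonempty exact pattern."""
    probs = model.probs
    n = model.universe_n
    out = {}
    for pat in nonempty_patterns(len(probs)):
        p = pattern_probability(pat, probs)
        out[pat] = (n * p, n * p * (1.0 - p))
    return out


def pattern_zscores(observed: PatternTable, model: NullModel,
                    min_factors: int = 2) -> list[PatternStats]:
    """Z-scores for observed vs expected pattern counts, sorted by |Z| desc.

    By default only multi-factor (>=2) patterns are reported, matching
    the convention of reporting the 26 combinations for five factors;
    pass ``min_factors=1`` to include singletons.
    """
    if list(observed.factor_order) != model.factor_order:
        raise ValueError(
            f"factor sets differ: {observed.factor_order} vs {model.factor_order}")
    ev = expected_pattern_counts(model)
    stats = []
    for pat, (e, v) in ev.items():
        if bin(pat).count("1") < min_factors:
            continue
        o = observed.count(pat)
        if v > 0:
            z = (o - e) / math.sqrt(v)
        elif o == e:
            z = 0.0
        else:
            z = math.inf if o > e else -math.inf
            warnings.warn(
                f"pattern {pattern_name(pat, observed.factor_order)}: zero variance "
                f"with observed {o} != expected {e}; Z reported as infinite")
        stats.append(PatternStats(pat, pattern_name(pat, observed.factor_order), o, e, v, z))
    stats.sort(key=lambda s: (-abs(s.zscore), s.pattern))
    return stats


def monte_carlo_null(model: NullModel, reps: int = 5000, seed: int = 0,
                     chunk: int = 256) -> dict[int, tuple[float, float]]:
    """Empirical per-pattern mean and sd of exact counts under the null.

    Each rep draws N x K independent Bernoulli(p_i) indicators and
    tabulates exact patterns.  Deterministic given ``seed``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    probs = model.probs
    k = len(probs)
    n = model.universe_n
    n_pat = 1 << k
    weights = (1 << np.arange(k)).astype(np.int64)
    counts = np.empty((reps, n_pat), dtype=np.int64)
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        u = rng.random((m, n, k))
        codes = ((u < probs) @ weights)
        for j in range(m):
            counts[done + j] = np.bincount(codes[j], minlength=n_pat)
        done += m
    out = {}
    for pat in nonempty_patterns(k):
        col = counts[:, pat]
        out[pat] = (float(col.mean()), float(col.std(ddof=1)))
    return out


def write_zscore_report(stats: Sequence[PatternStats], path,
                        header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {NULL_MODEL_HEADER}\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("pattern\tobserved\texpected\tvariance\tzscore\n")
        for s in stats:
            fh.write(f"{s.name}\t{s.observed}\t{s.expected:.6g}\t{s.variance:.6g}\t{s.zscore:.6g}\n")
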