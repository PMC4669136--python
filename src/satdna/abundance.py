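"""Satellite abundance per library and male/female proportion testing.

A read counts as positive for a family when it carries at least one
monomer-length stretch matching the family consensus at or above an identity
threshold (default 0.70).  Abundance per library is the positive-read
fraction; libraries are compared with a two-proportion z-test (pooled
variance, no continuity correction), falling back to Fisher's exact test when
any expected cell of the 2x2 table drops below 5.  The squared z statistic
equals the Pearson chi-square statistic of the same table, so both are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from satdna.align import Scoring, align
from satdna.core import SeqRecord, reverse_complement

__all__ = [
    "ProportionTest",
    "AbundanceResult",
    "classify_read",
    "classify_reads",
    "proportion_test",
    "compare_libraries",
]


def _edlib_identity(read: str, consensus: str) -> float:
    """Best identity of the consensus as an infix of the read (edit-distance
    based, span = one monomer)."""
    import edlib

    best = 0.0
    for q in (consensus, reverse_complement(consensus)):
        r = edlib.align(q, read, mode="HW", task="distance")
        d = r["editDistance"]
        if d >= 0:
            best = max(best, 1.0 - d / len(q))
    return best


def _wraparound_identity(read: str, consensus: str,
                         scoring: Scoring | None = None) -> float:
    best = 0.0
    for seq in (read, reverse_complement(read)):
        aln = align(seq, consensus, mode="wraparound", scoring=scoring)
        comparable = aln.matches + aln.mismatches
        if comparable:
            best = max(best, aln.matches / comparable)
    return best


def classify_read(read: SeqRecord, consensus: str,
                  min_identity: float = 0.70,
                  min_span: int | None = None,
                  engine: str = "edlib") -> bool:
    """True iff the read contains the family at >= ``min_identity`` over a
    span of at least ``min_span`` (default: one monomer length).

    ``engine="edlib"`` (default) matches one consensus copy as an infix of
    the read in C — the fast path for 10^5-read libraries.  The
    ``"wraparound"`` engine uses the package's wraparound DP over the whole
    read; both strands are always tried.
    """
    if not consensus:
        raise ValueError("empty consensus")
    span = min_span if min_span is not None else len(consensus)
    if len(read.seq) < span:
        return False
    if engine == "edlib":
        return _edlib_identity(read.seq, consensus) >= min_identity
    if engine == "wraparound":
        return _wraparound_identity(read.seq, consensus) >= min_identity
    raise ValueError(f"unknown engine {engine!r}")


def classify_reads(reads: list[SeqRecord], consensus: str,
                   min_identity: float = 0.70,
                   min_span: int | None = None,
                   engine: str = "edlib") -> tuple[list[bool], int, int]:
    """Flags per read plus (positive count, total count)."""
    flags = [classify_read(r, consensus, min_identity, min_span, engine)
             for r in reads]
    return flags, sum(flags), len(flags)


@dataclass(frozen=True)
class ProportionTest:
    """Two-sided comparison of two binomial proportions."""

    statistic: float
    p_value: float
    method: str  # "z" or "fisher"
    chi_square: float | None = None


def proportion_test(x1: int, n1: int, x2: int, n2: int,
                    method: str = "auto") -> ProportionTest:
    """Two-proportion z-test (pooled variance, no continuity correction),
    with automatic Fisher's-exact fallback when any expected cell < 5.

    ``z**2`` equals the Pearson chi-square statistic of the 2x2 table.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("library size must be >= 1")
        if not 0 <= x <= n:
            raise ValueError("count outside [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    use_fisher = method == "fisher" or (
        method == "auto" and (expected < 5).any())
    if use_fisher and method != "z":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return ProportionTest(statistic=odds, p_value=float(p),
                              method="fisher")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return ProportionTest(0.0, 1.0, "z", 0.0)
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ProportionTest(statistic=float(z), p_value=float(p), method="z",
                          chi_square=float(z * z))


@dataclass
class AbundanceResult:
    """Per-(library, family) positive counts/fractions and per-family tests."""

    counts: dict[tuple[str, str], tuple[int, int]]  # (lib, fam) -> (pos, tot)
    tests: dict[str, ProportionTest]

    def fraction(self, library: str, family: str) -> float:
        pos, tot = self.counts[(library, family)]
        return pos / tot


def compare_libraries(libraries: dict[str, list[SeqRecord]],
                      consensuses: dict[str, str],
                      min_identity: float = 0.70,
                      min_span: int | None = None,
                      engine: str = "edlib") -> AbundanceResult:
    """Classify every read of every library against every family consensus
    and test the two libraries' positive fractions per family."""
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    for lib, reads in libraries.items():
        for fam, cons in consensuses.items():
            _, pos, tot = classify_reads(reads, cons, min_identity,
                                         min_span, engine)
            counts[(lib, fam)] = (pos, tot)
    tests: dict[str, ProportionTest] = {}
    libs = sorted(libraries)
    if len(libs) == 2:
        a, b = libs
        for fam in consensuses:
            xa, na = counts[(a, fam)]
            xb, nb = counts[(b, fam)]
            tests[fam] = proportion_test(xa, na, xb, nb)
    return AbundanceResult(counts, tests)
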