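"""Pairwise alignment: global, semiglobal, and wraparound dynamic programming.

The wraparound mode aligns a read against a *circular* (tandemly repeated)
monomer consensus: the alignment path may traverse the consensus origin any
number of times, and each traversal is reported as a monomer boundary in read
coordinates.  This gives monomer boundaries and phase in a single pass and is
the substrate of monomer extraction.

Scoring is linear (match / mismatch / gap, no affine extension), which is
sufficient at the 40-180 bp monomer scale this package targets.  Ties among
equal-scoring alignments are broken deterministically: diagonal moves are
preferred over gaps, and gaps in ``b`` over gaps in ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from satdna.core import Undefined, UNDEFINED

__all__ = [
    "Scoring",
    "PairwiseAlignment",
    "align",
    "pairwise_identity",
    "identity_from_aligned",
    "GAP",
]

GAP = "-"

_NEG = float("-inf")


@dataclass(frozen=True)
class Scoring:
    """Linear alignment scoring (defaults: match +1, mismatch -1, gap -2)."""

    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def s(self, x: str, y: str) -> int:
        return self.match if x == y else self.mismatch


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment.

    ``aligned_a`` / ``aligned_b`` are equal-length gapped strings; no column is
    gap-gap, and removing gaps from ``aligned_a`` recovers ``a`` (likewise for
    ``b``, except that in wraparound mode ``aligned_b`` is the *unrolled*
    traversal of the circular consensus).  ``origin_crossings`` holds, for
    wraparound alignments, the read (``a``) coordinates at which the path
    crossed the consensus origin — i.e. the inferred monomer boundaries.
    ``b_start_phase`` is the consensus column at which the path began.
    """

    aligned_a: str
    aligned_b: str
    score: int
    mode: str
    matches: int = 0
    mismatches: int = 0
    gap_columns: int = 0
    origin_crossings: list[int] = field(default_factory=list)
    b_start_phase: int = 0
    b_end_phase: int = 0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        m = mm = g = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == GAP and y == GAP:
                raise ValueError("gap-gap column")
            if x == GAP or y == GAP:
                g += 1
            elif x == y:
                m += 1
            else:
                mm += 1
        self.matches, self.mismatches, self.gap_columns = m, mm, g

    def __len__(self) -> int:
        return len(self.aligned_a)


def _check_inputs(a: str, b: str) -> tuple[str, str]:
    if not a or not b:
        raise ValueError("empty input sequence")
    return a.upper(), b.upper()


def _global_dp(a: str, b: str, sc: Scoring) -> list[list[int]]:
    la, lb = len(a), len(b)
    dp = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        dp[i][0] = i * sc.gap
    for j in range(1, lb + 1):
        dp[0][j] = j * sc.gap
    for i in range(1, la + 1):
        ai = a[i - 1]
        row, prev = dp[i], dp[i - 1]
        for j in range(1, lb + 1):
            d = prev[j - 1] + sc.s(ai, b[j - 1])
            u = prev[j] + sc.gap  # gap in b (consumes a)
            l = row[j - 1] + sc.gap  # gap in a (consumes b)
            row[j] = d if d >= u and d >= l else (u if u >= l else l)
    return dp


def _traceback_global(a: str, b: str, sc: Scoring, dp: list[list[int]],
                      i: int, j: int, i_stop: int = 0) -> tuple[str, str, int, int]:
    """Trace from (i, j) back to row ``i_stop``/column 0 with the standard
    preference diagonal > gap-in-b > gap-in-a.  Returns aligned strings and the
    (i, j) where tracing stopped."""
    ra: list[str] = []
    rb: list[str] = []
    while i > i_stop or j > 0:
        if i > i_stop and j > 0 and dp[i][j] == dp[i - 1][j - 1] + sc.s(a[i - 1], b[j - 1]):
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif i > i_stop and dp[i][j] == dp[i - 1][j] + sc.gap:
            ra.append(a[i - 1]); rb.append(GAP); i -= 1
        elif j > 0 and dp[i][j] == dp[i][j - 1] + sc.gap:
            ra.append(GAP); rb.append(b[j - 1]); j -= 1
        elif i > i_stop:  # free vertical region (semiglobal init rows)
            ra.append(a[i - 1]); rb.append(GAP); i -= 1
        else:
            ra.append(GAP); rb.append(b[j - 1]); j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), i, j


def _align_global(a: str, b: str, sc: Scoring) -> PairwiseAlignment:
    dp = _global_dp(a, b, sc)
    aa, ab, _, _ = _traceback_global(a, b, sc, dp, len(a), len(b))
    return PairwiseAlignment(aa, ab, dp[len(a)][len(b)], "global")


def _align_semiglobal(a: str, b: str, sc: Scoring) -> PairwiseAlignment:
    """End gaps of ``b`` are free: ``b`` aligns as a (possibly partial)
    interval inside ``a`` without penalizing the overhangs of ``a``."""
    la, lb = len(a), len(b)
    dp = [[0] * (lb + 1) for _ in range(la + 1)]
    for j in range(1, lb + 1):
        dp[0][j] = j * sc.gap
    for i in range(1, la + 1):
        ai = a[i - 1]
        row, prev = dp[i], dp[i - 1]
        row[0] = 0  # leading overhang of a is free
        for j in range(1, lb + 1):
            d = prev[j - 1] + sc.s(ai, b[j - 1])
            u = prev[j] + sc.gap
            l = row[j - 1] + sc.gap
            row[j] = d if d >= u and d >= l else (u if u >= l else l)
    # trailing overhang of a free: best over last column, largest i on ties
    best_i = max(range(la + 1), key=lambda i: (dp[i][lb], i))
    score = dp[best_i][lb]
    aa, ab, i0, _ = _traceback_global(a, b, sc, dp, best_i, lb)
    # i0 is where the scored path left the free leading region
    lead_a = a[:i0]
    trail_a = a[best_i:]
    aa = lead_a + aa + trail_a
    ab = GAP * len(lead_a) + ab + GAP * len(trail_a)
    return PairwiseAlignment(aa, ab, score, "semiglobal")


def _wraparound_dp(a: str, b: str, sc: Scoring) -> np.ndarray:
    """Score matrix for read ``a`` vs circular consensus ``b``.

    ``dp[i, j]`` = best score having consumed ``a[:i]`` with the next consensus
    base to consume being ``b[j]`` (phase ``j``).  Start phase is free
    (``dp[0, :] = 0``); the path wraps whenever it consumes ``b[L-1]``.
    Horizontal (gap-in-``a``) moves are cyclic within a row; because the gap
    penalty is negative, two relaxation sweeps around the circle suffice.
    """
    la, lb = len(a), len(b)
    barr = np.frombuffer(b.encode(), dtype=np.uint8)
    dp = np.empty((la + 1, lb), dtype=np.float64)
    dp[0, :] = 0.0
    gap = float(sc.gap)
    for i in range(1, la + 1):
        ai = ord(a[i - 1])
        # substitution score of a[i-1] vs b[(j-1) % lb], laid out per target j
        sub = np.where(np.roll(barr, 1) == ai, float(sc.match), float(sc.mismatch))
        prev = dp[i - 1]
        cur = np.maximum(np.roll(prev, 1) + sub, prev + gap)
        # cyclic horizontal relaxation (gap in a), two sweeps
        for _ in range(2):
            for j in range(lb):
                c = cur[j - 1] + gap if j else cur[lb - 1] + gap
                if c > cur[j]:
                    cur[j] = c
        dp[i] = cur
    return dp


def _traceback_wraparound(a: str, b: str, sc: Scoring, dp: np.ndarray
                          ) -> PairwiseAlignment:
    la, lb = len(a), len(b)
    gap = float(sc.gap)
    j = int(np.argmax(dp[la]))  # smallest phase on ties (argmax returns first)
    score = dp[la][j]
    end_phase = j
    i = la
    ra: list[str] = []
    rb: list[str] = []
    crossings: list[int] = []
    while i > 0:
        jm1 = (j - 1) % lb
        diag = dp[i - 1][jm1] + (sc.match if a[i - 1] == b[jm1] else sc.mismatch)
        vert = dp[i - 1][j] + gap
        horiz = dp[i][jm1] + gap
        cur = dp[i][j]
        if np.isclose(cur, diag):
            ra.append(a[i - 1]); rb.append(b[jm1])
            if j == 0:
                crossings.append(i)
            i -= 1; j = jm1
        elif np.isclose(cur, vert):
            ra.append(a[i - 1]); rb.append(GAP)
            i -= 1
        elif np.isclose(cur, horiz):
            ra.append(GAP); rb.append(b[jm1])
            if j == 0:
                crossings.append(i)
            j = jm1
        else:  # pragma: no cover - DP/traceback mismatch would be a bug
            raise AssertionError("wraparound traceback lost the optimal path")
    aln = PairwiseAlignment(
        "".join(reversed(ra)), "".join(reversed(rb)), int(round(score)),
        "wraparound", origin_crossings=sorted(crossings), b_start_phase=j,
        b_end_phase=end_phase,
    )
    return aln


def align(a: str, b: str, mode: str = "global",
          scoring: Scoring | None = None) -> PairwiseAlignment:
    """Optimal pairwise alignment of ``a`` and ``b`` under linear scoring.

    Parameters
    ----------
    mode : {"global", "semiglobal", "wraparound"}
        ``semiglobal`` leaves end gaps of ``b`` free (``b`` as a fragment
        inside ``a``); ``wraparound`` treats ``b`` as circular/tandemly
        repeated and reports each origin traversal as a monomer boundary.
    """
    a, b = _check_inputs(a, b)
    sc = scoring or Scoring()
    if mode == "global":
        return _align_global(a, b, sc)
    if mode == "semiglobal":
        return _align_semiglobal(a, b, sc)
    if mode == "wraparound":
        return _traceback_wraparound(a, b, sc, _wraparound_dp(a, b, sc))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class IdentityValue:
    """A pairwise identity: fraction of matching compared columns."""

    value: float
    n_compared_columns: int


def identity_from_aligned(row_a: str, row_b: str,
                          gap_policy: str = "exclude_gap_columns"
                          ) -> IdentityValue | Undefined:
    """Identity between two already-aligned (gapped) rows.

    With the default pairwise-deletion policy, columns where either row has a
    gap are excluded from the denominator; ``count_gaps_as_mismatch`` divides
    by all columns that are not gap-gap.  Zero comparable columns yields
    :data:`~satdna.core.UNDEFINED`, not 0.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    matches = compared = total = 0
    for x, y in zip(row_a.upper(), row_b.upper()):
        if x == GAP and y == GAP:
            continue
        total += 1
        if x != GAP and y != GAP:
            compared += 1
            if x == y:
                matches += 1
    denom = compared if gap_policy == "exclude_gap_columns" else total
    if gap_policy not in ("exclude_gap_columns", "count_gaps_as_mismatch"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    if denom == 0:
        return UNDEFINED
    return IdentityValue(matches / denom, denom)


def pairwise_identity(a: str, b: str, gap_policy: str = "exclude_gap_columns",
                      scoring: Scoring | None = None
                      ) -> IdentityValue | Undefined:
    """Identity between two unaligned sequences via global alignment.

    Symmetric in its arguments and invariant under simultaneous
    reverse-complementation of both inputs.  Both invariances are guaranteed
    by aligning a canonical representative of the pair (DP tie-breaking is
    direction-dependent, and co-optimal alignments can differ in match count).
    """
    from satdna.core import reverse_complement

    a, b = a.upper(), b.upper()
    a, b = min((a, b), (b, a),
               (reverse_complement(a), reverse_complement(b)),
               (reverse_complement(b), reverse_complement(a)))
    aln = align(a, b, mode="global", scoring=scoring)
    return identity_from_aligned(aln.aligned_a, aln.aligned_b, gap_policy)
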