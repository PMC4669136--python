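"""Reference-anchored multiple alignment, majority consensus, internal motifs.

Monomers arriving from extraction are already phase-rotated to consensus
coordinates, so a star alignment to the anchor consensus is deterministic and
adequate at the 40-180 bp scale: each monomer is aligned globally to the
anchor and the pairwise gap patterns are merged into one coordinate system.

The internal-repeat scan is exhaustive over equal-length substring pairs
(direct and inverted), which is affordable at monomer scale and guarantees
that the planted/printed motifs (a 9 bp direct+inverted motif in a 43 bp
monomer; 18-23 bp direct pairs at ~67-70% identity in a ~177 bp monomer) are
found whenever they exceed the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from satdna.align import GAP, Scoring, align, identity_from_aligned
from satdna.core import reverse_complement
from satdna.monomerize import MonomerRecord

__all__ = [
    "MultipleAlignment",
    "MotifHit",
    "build_msa",
    "majority_consensus",
    "find_internal_repeats",
]


@dataclass
class MultipleAlignment:
    """Gapped monomer rows in a common (anchor-derived) coordinate system."""

    ids: list[str]
    rows: list[str]
    labels: list[str | None]
    excluded: list[tuple[str, float]]  # (id, identity-to-anchor) of rejects

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def as_array(self) -> np.ndarray:
        return np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                         for r in self.rows])


def build_msa(monomers: list[MonomerRecord], anchor: str,
              min_anchor_identity: float = 0.5,
              scoring: Scoring | None = None) -> MultipleAlignment:
    """Star alignment of phase-aligned monomers to an anchor consensus.

    Each monomer is aligned globally to the anchor; insertions relative to the
    anchor are merged by taking, per anchor position, the maximum insertion
    length seen in any pairwise alignment.  Monomers with identity to the
    anchor below ``min_anchor_identity`` are excluded and reported.
    """
    if not anchor:
        raise ValueError("empty anchor")
    pairwise = []
    excluded: list[tuple[str, float]] = []
    for m in monomers:
        aln = align(m.seq, anchor, mode="global", scoring=scoring)
        ident = identity_from_aligned(aln.aligned_a, aln.aligned_b)
        val = ident.value if ident else 0.0
        if val < min_anchor_identity:
            excluded.append((m.monomer_id, val))
            continue
        pairwise.append((m, aln))

    # per anchor-gap slot: max insertion length across monomers.
    # slot g = number of anchor characters consumed before the insertion.
    La = len(anchor)
    ins = np.zeros(La + 1, dtype=int)
    for _, aln in pairwise:
        g = 0
        run = 0
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if cb == GAP:
                run += 1
            else:
                ins[g] = max(ins[g], run)
                run = 0
                g += 1
        ins[La] = max(ins[La], run)

    ids, rows, labels = [], [], []
    for m, aln in pairwise:
        out: list[str] = []
        g = 0
        run: list[str] = []
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if cb == GAP:
                run.append(ca)
            else:
                out.append("".join(run) + GAP * (ins[g] - len(run)))
                run = []
                out.append(ca)
                g += 1
        out.append("".join(run) + GAP * (ins[La] - len(run)))
        ids.append(m.monomer_id)
        rows.append("".join(out))
        labels.append(m.family or None)
    return MultipleAlignment(ids, rows, labels, excluded)


def msa_from_rows(ids: list[str], rows: list[str],
                  labels: list[str | None] | None = None) -> MultipleAlignment:
    """Wrap pre-aligned rows (e.g. identical-length monomers) as an MSA."""
    return MultipleAlignment(ids, rows, labels or [None] * len(rows), [])


def majority_consensus(msa: MultipleAlignment, tie_rule: str = "alphabetical"
                       ) -> str:
    """Per-column most frequent non-gap state; columns with a gap majority are
    dropped.  Ties resolve alphabetically among the tied bases (recorded
    choice, deterministic)."""
    if len(msa.rows) < 2:
        raise ValueError("need >= 2 rows")
    if tie_rule != "alphabetical":
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    out = []
    for j in range(msa.n_columns):
        col = [r[j] for r in msa.rows]
        n_gap = col.count(GAP)
        if n_gap * 2 > len(col):
            continue
        states = sorted(set(col) - {GAP})
        if not states:
            continue
        counts = {s: col.count(s) for s in states}
        best = max(counts.values())
        out.append(min(s for s, c in counts.items() if c == best))
    return "".join(out)


@dataclass(frozen=True)
class MotifHit:
    """Two internally repeated copies within a monomer.

    Coordinates are 0-based half-open in monomer-local space; for inverted
    hits the identity is computed against the reverse complement of the second
    copy.  ``short`` marks direct hits below the short-repeat length cutoff.
    """

    kind: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    length: int
    identity: float

    @property
    def short(self) -> bool:
        return self.kind == "direct" and self.length < 12


def _window_identities(eq: np.ndarray, length: int) -> np.ndarray:
    """Sliding mean of a boolean match vector over windows of ``length``."""
    c = np.concatenate(([0], np.cumsum(eq)))
    return (c[length:] - c[:-length]) / length


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    if a[1] <= a[0] or b[1] <= b[0]:  # wrapped circular interval: no check
        return 0.0
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return inter / min(a[1] - a[0], b[1] - b[0])


def find_internal_repeats(monomer: str, min_len: int = 8,
                          min_identity: float = 0.65,
                          kinds: tuple[str, ...] = ("direct", "inverted"),
                          max_overlap: float = 0.5,
                          circular: bool = False) -> list[MotifHit]:
    """Exhaustive scan for direct and inverted internal repeats.

    All equal-length substring pairs of length >= ``min_len`` are compared by
    positional (Hamming) identity; inverted pairs are compared against the
    reverse complement of the second copy.  The two copies of a hit must be
    disjoint: pairs whose windows overlap are degenerate restatements of
    local periodicity or palindromicity, not two repeat copies.  Candidates
    are reduced greedily by matches-minus-mismatches, i.e.
    ``(2*identity - 1) * length`` with identity breaking ties — the
    alignment-score-like key that lets an exact planted motif outrank its
    noisy extensions; a candidate is dropped when either of its copies
    overlaps a kept hit's copies by more than ``max_overlap`` of the shorter
    interval.  With ``circular=True`` the monomer is scanned as a circle
    (doubled sequence).
    """
    if min_len < 5:
        raise ValueError("min_len must be >= 5")
    L = len(monomer)
    if L < 2 * min_len:
        raise ValueError("monomer shorter than 2*min_len")
    s = monomer.upper()
    text = s + s[:L - 1] if circular else s
    arr = np.frombuffer(text.encode(), dtype=np.uint8)
    rc = np.frombuffer(reverse_complement(text).encode(), dtype=np.uint8)
    n = len(arr)

    candidates: list[MotifHit] = []
    max_len = L // 1  # copies live within the monomer
    if "direct" in kinds:
        for d in range(1, n):
            eq = arr[:n - d] == arr[d:]
            for ln in range(min_len, min(max_len, n - d) + 1):
                if len(eq) < ln:
                    break
                idents = _window_identities(eq, ln)
                for i in np.flatnonzero(idents >= min_identity):
                    a0, b0 = int(i), int(i) + d
                    if a0 >= L or (not circular and b0 + ln > L):
                        continue
                    candidates.append(MotifHit(
                        "direct", a0 % L, (a0 + ln - 1) % L + 1,
                        b0 % L if circular else b0,
                        (b0 + ln - 1) % L + 1 if circular else b0 + ln,
                        ln, float(idents[i])))
    if "inverted" in kinds:
        # text[i..i+ln) vs revcomp(text[j..j+ln)) matches where
        # arr[i+k] == comp[j+ln-1-k]; with u = i+k, v = j+ln-1-k the
        # compared pairs satisfy u + v = i + j + ln - 1, i.e. they lie on one
        # anti-diagonal of the arr-vs-complement match matrix, so each
        # anti-diagonal reduces to a sliding-window scan.
        comp = rc[::-1].copy()  # complement without reversal
        for c in range(2 * min_len - 1, 2 * n - 1):
            k_lo, k_hi = max(0, c - n + 1), min(c, n - 1)
            ks = np.arange(k_lo, k_hi + 1)
            eq = arr[ks] == comp[c - ks]
            for ln in range(min_len, len(eq) + 1):
                idents = _window_identities(eq, ln)
                for w in np.flatnonzero(idents >= min_identity):
                    i = k_lo + int(w)
                    j = c - i - ln + 1
                    if j <= i:  # symmetric pair / self-palindrome: keep one
                        continue
                    if i >= L or (not circular and j + ln > L):
                        continue
                    candidates.append(MotifHit(
                        "inverted", i % L, (i + ln - 1) % L + 1,
                        j % L if circular else j,
                        (j + ln - 1) % L + 1 if circular else j + ln,
                        ln, float(idents[w])))

    candidates = [h for h in candidates
                  if _overlap_frac((h.start_a, h.end_a),
                                   (h.start_b, h.end_b)) == 0.0]
    candidates.sort(key=lambda h: (-(2 * h.identity - 1) * h.length,
                                   -h.identity, h.kind, h.start_a, h.start_b))
    kept: list[MotifHit] = []
    for h in candidates:
        clash = False
        for k in kept:
            for hc in ((h.start_a, h.end_a), (h.start_b, h.end_b)):
                for kc in ((k.start_a, k.end_a), (k.start_b, k.end_b)):
                    if hc[1] > hc[0] and kc[1] > kc[0] \
                            and _overlap_frac(hc, kc) > max_overlap:
                        clash = True
        if not clash:
            kept.append(h)
    return kept
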