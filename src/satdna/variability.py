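"""Variability statistics and higher-order-repeat (HOR) inference.

Three analyses on a set of aligned monomers:

* identity report — mean pairwise identity overall, within each labelled
  group (e.g. sex of the source individual) and between groups;
* diagnostic positions — alignment columns monomorphic across both groups
  (shared identical positions) and *fixed diagnostic* columns, monomorphic
  within each group but different between them;
* HOR scan — the contiguity statistic: for each monomer with an adjacent
  neighbour on the same read, is its nearest neighbour (highest identity) an
  adjacent monomer or a non-contiguous one?  A dimeric HOR manifests as a
  high non-contiguous fraction together with a clean two-class partition
  whose classes alternate along reads: every second monomer belongs to the
  same class, so the most similar unit is two steps away, not one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from satdna.align import GAP, identity_from_aligned
from satdna.consensus import MultipleAlignment, build_msa
from satdna.core import Undefined, UNDEFINED
from satdna.monomerize import MonomerRecord

__all__ = [
    "GroupIdentityReport",
    "DiagnosticReport",
    "HorReport",
    "pairwise_identity_matrix",
    "identity_report",
    "diagnostic_positions",
    "hor_scan",
]


def pairwise_identity_matrix(msa: MultipleAlignment,
                             gap_policy: str = "exclude_gap_columns"
                             ) -> np.ndarray:
    """Symmetric matrix of pairwise identities between MSA rows.

    Pairwise deletion by default (columns with a gap in either row excluded
    from that pair's denominator).  A pair with no comparable columns is NaN.
    """
    arr = msa.as_array()
    n = arr.shape[0]
    gap = ord(GAP)
    ident = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            both = (a != gap) & (b != gap)
            either = (a != gap) | (b != gap)
            denom = int(both.sum()) if gap_policy == "exclude_gap_columns" \
                else int(either.sum())
            if denom == 0:
                ident[i, j] = ident[j, i] = np.nan
                continue
            matches = int(((a == b) & both).sum())
            ident[i, j] = ident[j, i] = matches / denom
    return ident


@dataclass
class GroupIdentityReport:
    """Mean pairwise identities overall / within groups / between groups.

    ``overall`` is the mean over all unordered pairs (not the mean of group
    means); a group with fewer than 2 members gets an undefined within value.
    """

    overall: float
    within: dict[str, float | Undefined]
    between: float | Undefined
    n_per_group: dict[str, int]
    gap_policy: str


def identity_report(msa: MultipleAlignment,
                    labels: list[str | None] | None = None,
                    gap_policy: str = "exclude_gap_columns"
                    ) -> GroupIdentityReport:
    """Mean pairwise identity over all pairs, within and between labels."""
    if len(msa.rows) < 2:
        raise ValueError("need >= 2 rows")
    labels = labels if labels is not None else msa.labels
    ident = pairwise_identity_matrix(msa, gap_policy)
    n = len(msa.rows)
    iu = np.triu_indices(n, k=1)
    overall = float(np.nanmean(ident[iu]))

    groups = sorted({l for l in labels if l is not None})
    within: dict[str, float | Undefined] = {}
    n_per: dict[str, int] = {}
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        n_per[g] = len(idx)
        if len(idx) < 2:
            within[g] = UNDEFINED
            continue
        sub = ident[np.ix_(idx, idx)]
        within[g] = float(np.nanmean(sub[np.triu_indices(len(idx), k=1)]))
    between: float | Undefined = UNDEFINED
    if len(groups) >= 2:
        vals = []
        for ga, gb in itertools.combinations(groups, 2):
            ia = [i for i, l in enumerate(labels) if l == ga]
            ib = [i for i, l in enumerate(labels) if l == gb]
            if ia and ib:
                vals.append(np.nanmean(ident[np.ix_(ia, ib)]))
        if vals:
            between = float(np.mean(vals))
    return GroupIdentityReport(overall, within, between, n_per, gap_policy)


@dataclass
class DiagnosticReport:
    """Shared identical positions and fixed diagnostic columns between two
    groups (gap counts as a state)."""

    identical_fraction: float
    fixed_diagnostic: list[tuple[int, str, str]]
    n_columns: int


def diagnostic_positions(msa: MultipleAlignment,
                         labels: list[str | None] | None = None
                         ) -> DiagnosticReport:
    """Columns identical across both groups, and fixed diagnostic columns.

    A column is *identical* when a single state (gap included) is shared by
    every row of both groups; *fixed diagnostic* when monomorphic within each
    group but with different states between the groups.
    """
    labels = labels if labels is not None else msa.labels
    groups = sorted({l for l in labels if l is not None})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ia = [i for i, l in enumerate(labels) if l == groups[0]]
    ib = [i for i, l in enumerate(labels) if l == groups[1]]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both groups need >= 2 members")
    if msa.n_columns == 0:
        raise ValueError("no analyzable columns")

    identical = 0
    fixed: list[tuple[int, str, str]] = []
    for j in range(msa.n_columns):
        col_a = {msa.rows[i][j] for i in ia}
        col_b = {msa.rows[i][j] for i in ib}
        if len(col_a) == 1 and len(col_b) == 1:
            sa, sb = next(iter(col_a)), next(iter(col_b))
            if sa == sb:
                identical += 1
            else:
                fixed.append((j, sa, sb))
    return DiagnosticReport(identical / msa.n_columns, fixed, msa.n_columns)


@dataclass
class HorReport:
    """Outcome of the contiguity/two-class HOR analysis."""

    non_contiguous_fraction: float
    n_eligible: int
    classes: dict[str, int]  # monomer_id -> class (0/1)
    within_class_identity: list[float]
    between_class_identity: float
    alternation_consistency: float | Undefined
    hor_order: int
    low_confidence: bool = False


def hor_scan(monomers: list[MonomerRecord],
             anchor: str | None = None,
             msa: MultipleAlignment | None = None,
             non_contiguous_threshold: float = 0.5,
             alternation_threshold: float = 0.7) -> HorReport:
    """Infer dimeric HOR structure from monomer similarity vs read adjacency.

    A monomer is *eligible* when an adjacent monomer (same read, ordinal ± 1)
    is present in the set.  Its nearest neighbour is the other monomer with
    the highest pairwise identity, ties broken in favour of adjacency (the
    conservative direction: divergence-free data can never signal HOR).  The
    non-contiguous fraction is the share of eligible monomers whose nearest
    neighbour is not adjacent.  Monomers are then partitioned into two
    classes by average-linkage clustering on (1 - identity); order 2 is
    called when the non-contiguous fraction exceeds
    ``non_contiguous_threshold``, the between-class identity is below both
    within-class identities, and class alternation along reads exceeds
    ``alternation_threshold``.
    """
    if len(monomers) < 10:
        raise ValueError("need >= 10 monomers")
    by_read: dict[str, set[int]] = {}
    for m in monomers:
        by_read.setdefault(m.read_id, set()).add(m.ordinal)
    n_contig_reads = sum(
        1 for r, o in by_read.items()
        if any(x + 1 in o for x in o))
    if n_contig_reads < 3:
        raise ValueError("need >= 3 reads contributing contiguous monomers")

    if msa is None:
        anchor = anchor or max((m.seq for m in monomers), key=len)
        # no anchor-identity exclusion here: the opposite HOR class may sit
        # far below any sensible family floor and must stay in the analysis
        msa = build_msa(monomers, anchor, min_anchor_identity=0.0)
    kept_ids = set(msa.ids)
    monomers = [m for m in monomers if m.monomer_id in kept_ids]
    order = {mid: k for k, mid in enumerate(msa.ids)}
    ident = pairwise_identity_matrix(msa)

    index = {(m.read_id, m.ordinal): i for i, m in enumerate(monomers)}
    row_of = [order[m.monomer_id] for m in monomers]

    n_eligible = 0
    n_non_contig = 0
    for i, m in enumerate(monomers):
        adj = [index[(m.read_id, m.ordinal + d)] for d in (-1, 1)
               if (m.read_id, m.ordinal + d) in index]
        if not adj:
            continue
        n_eligible += 1
        sims = ident[row_of[i]].copy()
        sims[row_of[i]] = -np.inf
        best = np.nanmax(sims)
        adj_best = max(sims[row_of[j]] for j in adj)
        if not np.isclose(adj_best, best) and adj_best < best:
            n_non_contig += 1
    non_contig = n_non_contig / n_eligible if n_eligible else 0.0

    # two-class partition on 1 - identity
    d = 1.0 - np.nan_to_num(ident, nan=0.0)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    assign = fcluster(z, t=2, criterion="maxclust") - 1
    classes = {m.monomer_id: int(assign[row_of[i]])
               for i, m in enumerate(monomers)}

    within: list[float] = []
    for c in (0, 1):
        idx = [row_of[i] for i, m in enumerate(monomers)
               if assign[row_of[i]] == c]
        if len(idx) >= 2:
            sub = ident[np.ix_(idx, idx)]
            within.append(float(np.nanmean(sub[np.triu_indices(len(idx), 1)])))
    i0 = [r for r in range(len(assign)) if assign[r] == 0]
    i1 = [r for r in range(len(assign)) if assign[r] == 1]
    between = float(np.nanmean(ident[np.ix_(i0, i1)])) if i0 and i1 else 1.0

    adj_pairs = [(i, index[(m.read_id, m.ordinal + 1)])
                 for i, m in enumerate(monomers)
                 if (m.read_id, m.ordinal + 1) in index]
    if adj_pairs:
        alt = float(np.mean([assign[row_of[i]] != assign[row_of[j]]
                             for i, j in adj_pairs]))
    else:
        alt = UNDEFINED

    separable = len(within) == 2 and all(between < w for w in within)
    called = (non_contig > non_contiguous_threshold and separable
              and isinstance(alt, float) and alt > alternation_threshold)
    return HorReport(
        non_contiguous_fraction=non_contig,
        n_eligible=n_eligible,
        classes=classes,
        within_class_identity=within,
        between_class_identity=between,
        alternation_consistency=alt,
        hor_order=2 if called else 1,
        low_confidence=not separable,
    )
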