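"""p-distance matrices, neighbor joining, bootstrap support, newick output.

Neighbor joining follows the Saitou-Nei agglomeration: at each step the pair
minimizing ``Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`` is joined,
with the standard branch-length and distance-update formulas.  Ties at the
argmin are broken by the lexicographically smallest pair of cluster
representatives (a cluster is represented by its smallest leaf id), making
trees bit-reproducible.  Negative branch lengths are clamped to zero and the
clamped deficit recorded.

Bootstrap support is classical Felsenstein column resampling: alignment
columns are resampled with replacement, the tree rebuilt per replicate, and
each internal bipartition of the original tree receives the percentage of
replicates in which it reappears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from satdna.align import GAP
from satdna.consensus import MultipleAlignment

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "group_support",
]

_GAP_BYTE = ord(GAP)


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix (1 - identity, pairwise deletion)."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if (m < 0).any():
            raise ValueError("negative distances")
        self.matrix = m

    def to_phylip(self) -> str:
        lines = [f" {len(self.ids)}"]
        for i, name in enumerate(self.ids):
            row = " ".join(f"{x:.6f}" for x in self.matrix[i])
            lines.append(f"{name[:10]:<12s}{row}")
        return "\n".join(lines) + "\n"


def _weighted_identity(arr: np.ndarray, weights: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(match counts, comparable counts) per pair, columns weighted."""
    n, L = arr.shape
    match = np.zeros((n, n))
    comp = np.zeros((n, n))
    nongap = arr != _GAP_BYTE
    for j in range(L):
        w = weights[j]
        if w == 0:
            continue
        ng = nongap[:, j]
        both = np.outer(ng, ng)
        eq = np.equal.outer(arr[:, j], arr[:, j]) & both
        match += w * eq
        comp += w * both
    return match, comp


def p_distance_matrix(msa: MultipleAlignment,
                      column_weights: np.ndarray | None = None
                      ) -> DistanceMatrix:
    """d(i,j) = 1 - identity with gap-excluded (pairwise deletion) identity.

    Raises if any pair shares no comparable column (naming the pair).
    """
    if len(msa.rows) < 3:
        raise ValueError("need >= 3 rows")
    arr = msa.as_array()
    w = column_weights if column_weights is not None \
        else np.ones(arr.shape[1], dtype=int)
    match, comp = _weighted_identity(arr, w)
    n = len(msa.ids)
    bad = np.argwhere(comp == 0)
    bad = [(i, j) for i, j in bad if i < j]
    if bad:
        i, j = bad[0]
        raise ValueError(
            f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}")
    d = 1.0 - match / comp
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return DistanceMatrix(list(msa.ids), d)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored as a rooted structure with a trifurcating root.

    Bipartitions are canonicalized as the edge-side *not* containing the
    lexicographically smallest leaf; only internal edges (both sides >= 2
    leaves) are reported, of which a binary unrooted tree on n taxa has
    exactly n - 3.
    """

    root: TreeNode
    clamped_deficit: float = 0.0

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        ref = min(self.leaf_names())
        n = len(self.leaf_names())
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= n - 2:
                side = below if ref not in below else \
                    frozenset(self.leaf_names()) - below
                out[side] = node
            return below

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.9f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None \
                else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.9f}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)

        def conv(nd) -> TreeNode:
            children = [conv(c) for c in nd.child_nodes()]
            name = nd.taxon.label.replace(" ", "_") if nd.taxon else None
            support = None
            if children and nd.label not in (None, ""):
                support = float(nd.label)
            return TreeNode(name=name,
                            length=nd.edge.length or 0.0,
                            support=support, children=children)

        return cls(root=conv(dt.seed_node))


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    d = {(*sorted((a, b)),): float(dm.matrix[i, j])
         for i, a in enumerate(dm.ids) for j, b in enumerate(dm.ids) if i < j}
    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in dm.ids}
    # cluster key = lexicographically smallest member leaf
    active = sorted(dm.ids)
    deficit = 0.0

    def dist(a: str, b: str) -> float:
        return d[(*sorted((a, b)),)]

    while len(active) > 3:
        r = len(active)
        sums = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for x in range(len(active)):
            for y in range(x + 1, len(active)):
                a, b = active[x], active[y]
                q = (r - 2) * dist(a, b) - sums[a] - sums[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist(a, b)
        la = dab / 2.0 + (sums[a] - sums[b]) / (2.0 * (r - 2))
        lb = dab - la
        for l in (la, lb):
            if l < 0:
                deficit += -l
        la, lb = max(la, 0.0), max(lb, 0.0)
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        parent = TreeNode(children=[na, nb])
        newd = {}
        for c in active:
            if c in (a, b):
                continue
            newd[c] = (dist(a, c) + dist(b, c) - dab) / 2.0
        active = [c for c in active if c not in (a, b)]
        key = min(a, b)
        nodes[key] = parent
        for c in active:
            d[(*sorted((key, c)),)] = max(newd[c], 0.0)
        active.append(key)
        active.sort()

    a, b, c = active
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2.0
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2.0
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2.0
    for l in (la, lb, lc):
        if l < 0:
            deficit += -l
    na, nb, nc = nodes[a], nodes[b], nodes[c]
    na.length, nb.length, nc.length = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    root = TreeNode(children=[na, nb, nc])
    return Tree(root=root, clamped_deficit=deficit)


# ---------------------------------------------------------------------------
# bootstrap and group support


def bootstrap_support(msa: MultipleAlignment, n_replicates: int = 1000,
                      seed: int = 0) -> Tree:
    """NJ tree with Felsenstein bootstrap supports (percentages).

    Columns are resampled with replacement ``n_replicates`` times; support of
    each internal bipartition of the original tree is the percentage of
    replicate trees containing it.  Supports are attached to the original
    (non-resampled) tree's internal nodes.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = neighbor_joining(p_distance_matrix(msa))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = msa.n_columns
    for _ in range(n_replicates):
        weights = np.bincount(rng.integers(0, L, size=L), minlength=L)
        try:
            dm = p_distance_matrix(msa, column_weights=weights)
        except ValueError:  # a pair lost all comparable columns: skip
            continue
        rep = neighbor_joining(dm)
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    for bp, node in target.items():
        node.support = 100.0 * counts[bp] / n_replicates
    return tree


def group_support(tree: Tree, labels: dict[str, str],
                  threshold: float = 70.0) -> dict[str, str]:
    """Per-label verdict: does an edge separate exactly that label's leaves?

    A label is ``"supported"`` iff some internal bipartition's side equals
    exactly the set of leaves carrying the label and its support meets the
    threshold; ``"not supported"`` otherwise; ``"not assessable"`` when the
    label covers < 2 leaves or all leaves.
    """
    leaves = set(tree.leaf_names())
    bps = tree.bipartitions()
    verdicts: dict[str, str] = {}
    for lab in sorted(set(labels.values())):
        members = frozenset(l for l in leaves if labels.get(l) == lab)
        if len(members) < 2 or members == leaves:
            verdicts[lab] = "not assessable"
            continue
        verdict = "not supported"
        for side, node in bps.items():
            other = frozenset(leaves) - side
            if members in (side, other):
                sup = node.support
                if sup is None or sup >= threshold:
                    verdict = "supported"
                break
        verdicts[lab] = verdict
    return verdicts
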