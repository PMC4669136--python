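"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (exhaustive recursion, hand counting)
and shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def enumerate_best_alignment_score(a: str, b: str, match: int = 1,
                                   mismatch: int = -1, gap: int = -2) -> int:
    """Best global alignment score by exhaustive recursion over all monotone
    alignments (no memoization: this is the enumeration oracle, feasible for
    sequences up to ~8 bases)."""
    def best(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def random_additive_matrix(n_taxa: int, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths and its
    additive (path-length) distance matrix.

    Built by sequential taxon insertion on random edges; distances computed
    by brute-force path walking on the explicit graph.  Returns
    ``(ids, matrix, edges)`` where ``edges`` is a dict
    ``frozenset({u, v}) -> length`` over an arbitrary node numbering with
    leaves named "t0".."t{n-1}".
    """
    ids = [f"t{i}" for i in range(n_taxa)]
    # start from a 3-star
    edges: dict[frozenset, float] = {}
    next_node = [n_taxa]  # internal node ids start after leaves

    def el() -> float:
        return float(rng.uniform(0.5, 3.0))

    center = next_node[0]
    next_node[0] += 1
    for leaf in range(3):
        edges[frozenset((leaf, center))] = el()
    for leaf in range(3, n_taxa):
        # split a random edge with a new internal node, attach the leaf
        edge = list(edges)[rng.integers(0, len(edges))]
        u, v = tuple(edge)
        length = edges.pop(edge)
        w = next_node[0]
        next_node[0] += 1
        split = float(rng.uniform(0.2, 0.8)) * length
        edges[frozenset((u, w))] = split
        edges[frozenset((v, w))] = length - split
        edges[frozenset((leaf, w))] = el()

    # adjacency + brute-force path distances
    adj: dict[int, list[tuple[int, float]]] = {}
    for e, l in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, l))
        adj.setdefault(v, []).append((u, l))

    def dist(u: int, v: int) -> float:
        stack = [(u, 0.0, -1)]
        while stack:
            node, d, prev = stack.pop()
            if node == v:
                return d
            for nxt, l in adj[node]:
                if nxt != prev:
                    stack.append((nxt, d + l, node))
        raise AssertionError("disconnected tree")

    m = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            m[i, j] = m[j, i] = dist(i, j)
    return ids, m, edges


def true_bipartitions(n_taxa: int, edges: dict) -> set[frozenset]:
    """Internal bipartitions of the oracle tree, canonicalized as the side
    not containing leaf 't0'."""
    adj: dict[int, list[int]] = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def side(u: int, v: int) -> frozenset:
        # leaves reachable from v without passing through u
        out = set()
        stack = [(v, u)]
        while stack:
            node, prev = stack.pop()
            if node < n_taxa:
                out.add(f"t{node}")
            for nxt in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node))
        return frozenset(out)

    all_leaves = frozenset(f"t{i}" for i in range(n_taxa))
    bps = set()
    for e in edges:
        u, v = tuple(e)
        if u < n_taxa or v < n_taxa:
            continue  # pendant edge
        s = side(u, v)
        if not 2 <= len(s) <= n_taxa - 2:
            continue
        if "t0" in s:
            s = all_leaves - s
        bps.add(s)
    return bps
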