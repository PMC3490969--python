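"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: trees are random
additive constructions checked by the four-point/additivity theorem, and the
MaxChi oracle evaluates every partition table explicitly.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import shortest_path


def random_additive_tree(rng, n_taxa: int):
    """A random unrooted binary tree; returns (labels, distance matrix,
    true non-trivial bipartitions as canonical frozensets).

    Built by attaching leaves to random edges with strictly positive branch
    lengths; pairwise distances are exact path sums, so neighbor joining
    must recover the generating topology (additivity theorem).
    """
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    # node 0..n_taxa-1 are leaves; internal nodes appended after
    edges: dict[tuple[int, int], float] = {}

    def add_edge(u, v, w):
        edges[(min(u, v), max(u, v))] = w

    def blen():
        return float(rng.uniform(0.05, 1.0))

    next_node = n_taxa
    add_edge(0, next_node, blen())
    add_edge(1, next_node, blen())
    add_edge(2, next_node, blen())
    next_node += 1
    for leaf in range(3, n_taxa):
        u, v = list(edges)[rng.integers(0, len(edges))]
        w = edges.pop((u, v))
        mid = next_node
        next_node += 1
        split = float(rng.uniform(0.25, 0.75))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(leaf, mid, blen())

    n_nodes = next_node
    g = lil_matrix((n_nodes, n_nodes))
    for (u, v), w in edges.items():
        g[u, v] = w
        g[v, u] = w
    full = shortest_path(g.tocsr(), method="D", directed=False)
    dm = full[:n_taxa, :n_taxa]

    # true bipartitions: drop each internal edge, collect one side's leaves
    adj: dict[int, list[int]] = {}
    for (u, v) in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def side_leaves(start, banned_edge):
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if {x, y} == set(banned_edge) or y in seen:
                    continue
                seen.add(y)
                stack.append(y)
        return frozenset(labels[i] for i in seen if i < n_taxa)

    all_set = frozenset(labels)
    biparts = set()
    for (u, v) in edges:
        if u < n_taxa or v < n_taxa:
            continue  # pendant or leaf edge -> trivial
        side = side_leaves(u, (u, v))
        if labels[0] in side:
            side = all_set - side
        if 2 <= len(side) <= n_taxa - 2:
            biparts.add(side)
    return labels, dm, biparts


def brute_force_maxchi(x: np.ndarray):
    """Explicit 2x2 table at every partition point; returns (chi2 array,
    max, first argmax partition point)."""
    m = len(x)
    out = []
    for k in range(1, m):
        a = int(np.sum(x[:k]))
        b = k - a
        c = int(np.sum(x[k:]))
        d = (m - k) - c
        margins = [(a + b), (c + d), (a + c), (b + d)]
        if 0 in margins:
            out.append(0.0)
            continue
        out.append(m * (a * d - b * c) ** 2 / np.prod(margins, dtype=float))
    out = np.array(out)
    arg = int(np.argmax(out))
    return out, float(out[arg]), arg + 1
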