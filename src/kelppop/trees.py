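"""Distance-matrix neighbor-joining with bootstrap support and comparison.

The agglomeration is the Saitou–Nei Q-criterion with deterministic
tie-breaking (lowest row-major index pair), negative branch lengths clamped
to zero with the deficit moved to the adjacent branch (switchable), and
newick serialisation.  Bootstrap support is the percentage of
column-resampled replicate trees containing each bipartition of the point
tree.  Robinson–Foulds distance counts the symmetric difference of
non-trivial bipartitions.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .alignment import Alignment
from .divergence import MODELS, _correct
from .errors import ArgumentError, SaturationError, UndefinedPairError

_NEWICK_UNSAFE = set("();:, '\"[]")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ArgumentError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ArgumentError("distance matrix not symmetric")
        if (m < 0).any():
            raise ArgumentError("negative distances on input")
        if not np.allclose(np.diag(m), 0.0):
            raise ArgumentError("nonzero diagonal")
        self.matrix = m


@dataclass
class Tree:
    """Unrooted tree as newick plus cached bipartitions.

    ``supports`` maps canonical bipartition sides (frozenset of labels, the
    side not containing the first label) to percent bootstrap support.
    """

    newick: str
    labels: tuple[str, ...]
    supports: dict[frozenset, float] | None = None
    _biparts: set | None = field(default=None, repr=False, compare=False)

    def bipartitions(self) -> set[frozenset]:
        if self._biparts is None:
            self._biparts = _bipartitions_of_newick(self.newick, self.labels)
        return self._biparts


def _check_labels(labels: Sequence[str]) -> None:
    for lab in labels:
        if set(lab) & _NEWICK_UNSAFE:
            raise ArgumentError(f"label not newick-safe: {lab!r}")


def distance_matrix_from_alignment(
    aln: Alignment, model: str = "p"
) -> DistanceMatrix:
    """All-pairs model distances under pairwise deletion."""
    if model not in MODELS:
        raise ArgumentError(f"unknown model {model!r}")
    codes = aln.codes
    n = codes.shape[0]
    m = np.zeros((n, n))
    valid_all = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            v = valid_all[i] & valid_all[j]
            sites = int(v.sum())
            if sites == 0:
                raise UndefinedPairError(
                    f"pair ({aln.ids[i]}, {aln.ids[j]}) shares no comparable sites"
                )
            diff = v & (codes[i] != codes[j])
            ts = diff & ((codes[i] % 2) == (codes[j] % 2))
            P = ts.sum() / sites
            Q = (diff.sum() - ts.sum()) / sites
            h = None
            if model == "T92":
                gc = ((codes[i] == 1) | (codes[i] == 2))[v].sum() + (
                    (codes[j] == 1) | (codes[j] == 2)
                )[v].sum()
                theta = gc / (2 * sites)
                h = 2 * theta * (1 - theta)
            m[i, j] = m[j, i] = _correct(
                P + Q, P, Q, model, h, label=f"({aln.ids[i]}, {aln.ids[j]})"
            )
    return DistanceMatrix(list(aln.ids), m)


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> Tree:
    """Saitou–Nei neighbor joining.

    Joins the pair minimising ``Q_ij = (r-2) D_ij - R_i - R_j``; ties break on
    the lowest row-major ``(i, j)`` pair.  With ``clamp_negative`` a negative
    pendant branch is set to zero and its deficit moved to the sibling branch
    (their sum, the joined pair's distance, is preserved).
    """
    n = len(dm.labels)
    if n < 3:
        raise ArgumentError("neighbor joining needs at least 3 labels")
    _check_labels(dm.labels)

    d = dm.matrix.copy()
    nodes: list[str] = list(dm.labels)

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if not clamp_negative:
            return li, lj
        if li < 0:
            lj, li = max(lj + li, 0.0), 0.0
        if lj < 0:
            li, lj = max(li + lj, 0.0), 0.0
        return li, lj

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # first minimum in row-major order: i < j
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        new_node = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d_new = np.empty((r - 1, r - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = du[keep]
        d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new_node]

    # three-point closed form for the final star
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    if clamp_negative:
        l0, l1, l2 = (max(x, 0.0) for x in (l0, l1, l2))
    newick = (
        f"({nodes[0]}:{l0:.10g},{nodes[1]}:{l1:.10g},{nodes[2]}:{l2:.10g});"
    )
    return Tree(newick=newick, labels=tuple(dm.labels))


def _parse(newick: str, labels: Sequence[str]) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace([str(x) for x in labels])
    return dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=tns,
        suppress_internal_node_taxa=True,
    )


def _bipartitions_of_newick(newick: str, labels: Sequence[str]) -> set[frozenset]:
    """Non-trivial bipartitions, each as the canonical side (the side not
    containing the first label)."""
    tree = _parse(newick, labels)
    all_labels = frozenset(labels)
    ref = labels[0]
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    if set(t1.labels) != set(t2.labels):
        raise ArgumentError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def sister_group(tree: Tree, leaf: str) -> frozenset:
    """Labels of the smallest clade joined to *leaf* (its sister group).

    Taken over all edge sides containing the leaf, the minimal side with at
    least two members, minus the leaf itself.
    """
    if leaf not in tree.labels:
        raise ArgumentError(f"{leaf!r} not among tree labels")
    dtree = _parse(tree.newick, tree.labels)
    all_labels = frozenset(tree.labels)
    best: frozenset | None = None
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        for candidate in (side, all_labels - side):
            if leaf in candidate and len(candidate) >= 2:
                if best is None or len(candidate) < len(best):
                    best = candidate
    assert best is not None
    return best - {leaf}


def leaf_distances(tree: Tree, leaf: str) -> dict[str, float]:
    """Patristic (path-length) distances from *leaf* to every other leaf.

    Unlike the purely topological :func:`sister_group`, this resolves the
    placement of a taxon attached near the unrooted tree's central node,
    where sister sets tie.
    """
    if leaf not in tree.labels:
        raise ArgumentError(f"{leaf!r} not among tree labels")
    dtree = _parse(tree.newick, tree.labels)
    pdm = dtree.phylogenetic_distance_matrix()
    tns = dtree.taxon_namespace
    t0 = tns.get_taxon(leaf)
    return {
        t.label: float(pdm.patristic_distance(t0, t))
        for t in tns if t.label != leaf
    }


def _resampled_counts(codes: np.ndarray, weights: np.ndarray):
    """Per-pair (valid, transition, transversion) counts under column weights."""
    n, L = codes.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    valid = np.empty((len(pairs), L))
    ts = np.empty((len(pairs), L))
    tv = np.empty((len(pairs), L))
    vmask = codes >= 0
    for k, (i, j) in enumerate(pairs):
        v = vmask[i] & vmask[j]
        diff = v & (codes[i] != codes[j])
        t = diff & ((codes[i] % 2) == (codes[j] % 2))
        valid[k], ts[k], tv[k] = v, t, diff & ~t
    return pairs, valid @ weights, ts @ weights, tv @ weights


def bootstrap_support(
    aln: Alignment,
    model: str = "p",
    n_reps: int = 1000,
    seed: int | None = None,
    clamp_negative: bool = True,
) -> Tree:
    """NJ point tree with percent bootstrap support on its bipartitions.

    Columns are resampled with replacement *n_reps* times; each replicate
    tree's bipartitions are matched against the point tree's.  Replicates
    whose distances saturate are skipped; a warning is issued when more than
    1% are.
    """
    if n_reps < 1:
        raise ArgumentError("n_reps must be >= 1")
    point_dm = distance_matrix_from_alignment(aln, model)
    point = neighbor_joining(point_dm, clamp_negative)
    target = point.bipartitions()

    h_pairs: dict[tuple[int, int], float] | None = None
    if model == "T92":
        # GC content is stable under column resampling; reuse full-data h
        h_pairs = {}
        cds, vall = aln.codes, aln.codes >= 0
        for i in range(aln.n):
            for j in range(i + 1, aln.n):
                v = vall[i] & vall[j]
                gc = ((cds[i] == 1) | (cds[i] == 2))[v].sum() + (
                    (cds[j] == 1) | (cds[j] == 2)
                )[v].sum()
                theta = gc / (2 * max(int(v.sum()), 1))
                h_pairs[(i, j)] = 2 * theta * (1 - theta)

    rng = np.random.default_rng(seed)
    codes = aln.codes
    n, L = codes.shape
    weights = rng.multinomial(L, np.full(L, 1.0 / L), size=n_reps).T.astype(float)
    pairs, vn, tn, qn = _resampled_counts(codes, weights)

    counts = {bp: 0 for bp in target}
    skipped = 0
    for r in range(n_reps):
        m = np.zeros((n, n))
        try:
            for k, (i, j) in enumerate(pairs):
                sites = vn[k, r]
                if sites == 0:
                    raise UndefinedPairError(
                        f"pair ({aln.ids[i]}, {aln.ids[j]}): no sites in replicate"
                    )
                P, Q = tn[k, r] / sites, qn[k, r] / sites
                h = h_pairs[(i, j)] if h_pairs is not None else None
                m[i, j] = m[j, i] = _correct(P + Q, P, Q, model, h)
        except (SaturationError, UndefinedPairError):
            skipped += 1
            continue
        rep_tree = neighbor_joining(
            DistanceMatrix(list(aln.ids), m), clamp_negative
        )
        for bp in rep_tree.bipartitions() & target:
            counts[bp] += 1
    used = n_reps - skipped
    if used == 0:
        raise SaturationError("every bootstrap replicate saturated")
    if skipped > 0.01 * n_reps:
        warnings.warn(
            f"{skipped}/{n_reps} bootstrap replicates skipped (saturation)",
            stacklevel=2,
        )
    supports = {bp: 100.0 * c / used for bp, c in counts.items()}
    return Tree(
        newick=_annotate_supports(point, supports),
        labels=point.labels,
        supports=supports,
    )


def _annotate_supports(point: Tree, supports: dict[frozenset, float]) -> str:
    """Write supports as internal node labels on the point tree's newick."""
    dtree = _parse(point.newick, point.labels)
    all_labels = frozenset(point.labels)
    ref = point.labels[0]
    for node in dtree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if side in supports:
            node.label = f"{supports[side]:.0f}"
    buf = io.StringIO()
    dtree.write(file=buf, schema="newick", suppress_rooting=True,
                unquoted_underscores=True)
    return buf.getvalue().strip()


def write_newick(tree: Tree, path) -> None:
    from pathlib import Path

    Path(path).write_text(tree.newick + "\n")


def read_newick(path, labels: Iterable[str] | None = None) -> Tree:
    from pathlib import Path

    newick = Path(path).read_text().strip()
    if labels is None:
        tmp = dendropy.Tree.get(data=newick, schema="newick")
        labels = [t.label for t in tmp.taxon_namespace]
    return Tree(newick=newick, labels=tuple(labels))
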