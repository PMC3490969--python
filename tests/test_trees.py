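"""Neighbor joining, bootstrap supports and tree comparison."""

import numpy as np
import pytest

from kelppop.alignment import Alignment
from kelppop.errors import ArgumentError
from kelppop.simulate import PartitionSpec, SimulationConfig, simulate_two_lineages
from kelppop.trees import (
    DistanceMatrix,
    Tree,
    bootstrap_support,
    distance_matrix_from_alignment,
    leaf_distances,
    neighbor_joining,
    robinson_foulds,
    sister_group,
)

from _oracles import random_additive_tree


class TestNeighborJoining:
    def test_additive_four_taxon_example(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4))
        m = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        t = neighbor_joining(DistanceMatrix(list("ABCD"), m))
        assert t.bipartitions() == {frozenset("CD")}
        # pendant branch lengths recovered exactly on additive input
        import re
        for leaf, want in zip("ABCD", (1, 2, 3, 4)):
            assert re.search(rf"{leaf}:{want}[,):]", t.newick)

    def test_three_taxon_closed_form(self):
        m = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        t = neighbor_joining(DistanceMatrix(list("XYZ"), m))
        # three-point formulas: x = (2+3-5)/2 = 0, y = 2, z = 3
        assert t.newick == "(X:0,Y:2,Z:3);"

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ArgumentError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            labels, dm, truth = random_additive_tree(rng, int(rng.integers(4, 11)))
            t = neighbor_joining(DistanceMatrix(labels, dm))
            assert t.bipartitions() == truth

    def test_leafset_and_edge_count(self):
        rng = np.random.default_rng(8)
        labels, dm, _ = random_additive_tree(rng, 8)
        t = neighbor_joining(DistanceMatrix(labels, dm))
        assert set(t.labels) == set(labels)
        # unrooted binary: n-3 internal edges = n-3 non-trivial bipartitions
        assert len(t.bipartitions()) == 8 - 3

    def test_matches_scikit_bio_on_random_matrices(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 8
            noise = rng.uniform(0.1, 1.0, size=(n, n))
            m = (noise + noise.T) / 2
            np.fill_diagonal(m, 0.0)
            labels = [f"t{i}" for i in range(n)]
            mine = neighbor_joining(DistanceMatrix(labels, m),
                                    clamp_negative=False)
            ref = skbio.tree.nj(skbio.DistanceMatrix(m, ids=labels))
            ref_tree = Tree(newick=str(ref), labels=tuple(labels))
            assert mine.bipartitions() == ref_tree.bipartitions()


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        rng = np.random.default_rng(1)
        labels, dm, _ = random_additive_tree(rng, 6)
        t = neighbor_joining(DistanceMatrix(labels, dm))
        assert robinson_foulds(t, t) == 0

    def test_conflicting_quartets(self):
        t1 = Tree("((A:1,B:1):1,(C:1,D:1):1);", tuple("ABCD"))
        t2 = Tree("((A:1,C:1):1,(B:1,D:1):1);", tuple("ABCD"))
        assert robinson_foulds(t1, t2) == 2

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        labels, dm1, _ = random_additive_tree(rng, 7)
        _, dm2, _ = random_additive_tree(rng, 7)
        a = neighbor_joining(DistanceMatrix(labels, dm1))
        b = neighbor_joining(DistanceMatrix(labels, dm2))
        assert robinson_foulds(a, b) == robinson_foulds(b, a)

    def test_unequal_leafsets_rejected(self):
        t1 = Tree("((A:1,B:1):1,(C:1,D:1):1);", tuple("ABCD"))
        t2 = Tree("((A:1,B:1):1,(C:1,E:1):1);", tuple("ABCE"))
        with pytest.raises(ArgumentError):
            robinson_foulds(t1, t2)


@pytest.fixture(scope="module")
def clade_sim():
    cfg = SimulationConfig(
        partitions=[PartitionSpec("COI", 800, 0.05, 0.001)],
        n_a=4, n_b=4, fixed_indels=[], seed=77,
    )
    return simulate_two_lineages(cfg)


class TestBootstrap:
    def test_separated_clades_get_full_support(self, clade_sim):
        aln, _, groups, _ = clade_sim
        t = bootstrap_support(aln, n_reps=100, seed=4)
        side = frozenset(groups.members("SHA"))  # canonical side (no TYP01)
        assert side in t.supports
        assert t.supports[side] >= 99.0

    def test_single_replicate_degenerate(self, clade_sim):
        aln, _, _, _ = clade_sim
        t = bootstrap_support(aln, n_reps=1, seed=9)
        assert set(t.supports.values()) <= {0.0, 100.0}

    def test_same_seed_same_supports(self, clade_sim):
        aln, _, _, _ = clade_sim
        t1 = bootstrap_support(aln, n_reps=50, seed=13)
        t2 = bootstrap_support(aln, n_reps=50, seed=13)
        assert t1.supports == t2.supports
        assert all(0.0 <= v <= 100.0 for v in t1.supports.values())

    def test_supports_written_into_newick(self, clade_sim):
        aln, _, groups, _ = clade_sim
        t = bootstrap_support(aln, n_reps=100, seed=4)
        side = frozenset(groups.members("SHA"))
        assert f"{t.supports[side]:.0f}" in t.newick


class TestPlacementHelpers:
    def test_sister_group_of_nested_leaf(self):
        t = Tree("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);", tuple("ABCDE"))
        assert sister_group(t, "A") == frozenset({"B"})
        assert sister_group(t, "C") == frozenset({"A", "B"})

    def test_leaf_distances_match_additive_input(self):
        rng = np.random.default_rng(3)
        labels, dm, _ = random_additive_tree(rng, 6)
        t = neighbor_joining(DistanceMatrix(labels, dm))
        d = leaf_distances(t, labels[0])
        for j, lab in enumerate(labels[1:], start=1):
            assert d[lab] == pytest.approx(dm[0, j], abs=1e-6)


def test_distance_matrix_from_alignment_symmetric(default_sim):
    aln, _, _, _ = default_sim
    sub = aln.subset(aln.ids[:6])
    dm = distance_matrix_from_alignment(sub, "K2P")
    assert np.allclose(dm.matrix, dm.matrix.T)
    assert (np.diag(dm.matrix) == 0).all()
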