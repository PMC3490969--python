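"""Segregating sites, fixed differences, indels and nucleotide diversity."""

import itertools

import numpy as np
import pytest

from kelppop.alignment import Alignment
from kelppop.errors import ArgumentError, UndefinedPairError
from kelppop.variation import (
    fixed_differences,
    fixed_indels,
    indel_events,
    nucleotide_diversity,
    segregating_sites,
)


def aln_of(*rows):
    return Alignment([f"s{i}" for i in range(len(rows))], list(rows))


class TestSegregatingSites:
    def test_monomorphic(self):
        assert segregating_sites(aln_of("AAAA", "AAAA")).positions == []

    def test_case_fold_and_position(self):
        assert segregating_sites(aln_of("AAca", "AAAA")).positions == [3]

    def test_gaps_and_ambiguity_not_alleles(self):
        # '-' and 'N' are missing, never a second allele
        assert segregating_sites(aln_of("A-NA", "AANA", "AA-A")).positions == []

    def test_simulated_truth_recovered(self, default_sim):
        aln, _, groups, truth = default_sim
        ids = groups.members("TYP") + groups.members("SHA")
        cat = segregating_sites(aln, ids)
        # planted fixed positions are a subset of all segregating positions
        assert set(truth.fixed_difference_positions) <= set(cat.positions)

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ArgumentError):
            segregating_sites(aln_of("AA", "AA"), samples=["s0"])


class TestFixedDifferences:
    def test_single_fixed_site(self):
        aln = Alignment(["a1", "a2", "b1", "b2"], ["AC", "AC", "AT", "AT"])
        assert fixed_differences(aln, ["a1", "a2"], ["b1", "b2"]) == [
            (2, "C", "T")
        ]

    def test_shared_polymorphism_not_fixed(self):
        aln = Alignment(["a1", "a2", "b1", "b2"], ["A", "C", "A", "C"])
        assert fixed_differences(aln, ["a1", "a2"], ["b1", "b2"]) == []

    def test_fully_missing_group_column_skipped(self):
        aln = Alignment(["a1", "b1"], ["NA", "CA"])
        assert fixed_differences(aln, ["a1"], ["b1"]) == []

    def test_overlapping_groups_rejected(self):
        aln = aln_of("AC", "AT")
        with pytest.raises(ArgumentError):
            fixed_differences(aln, ["s0"], ["s0", "s1"])

    def test_simulation_recovers_exactly_planted_sites(self, default_sim):
        aln, _, groups, truth = default_sim
        found = fixed_differences(aln, groups.members("TYP"),
                                  groups.members("SHA"))
        assert [p for p, _, _ in found] == truth.fixed_difference_positions

    def test_monomorphic_groups_equal_hamming(self, random_alignment):
        # two internally monomorphic groups: count == Hamming distance of reps
        rng = np.random.default_rng(42)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        aln = Alignment(["a1", "a2", "b1", "b2"], [a, a, b, b])
        ham = sum(x != y for x, y in zip(a, b))
        assert len(fixed_differences(aln, ["a1", "a2"], ["b1", "b2"])) == ham

    def test_subset_of_segregating_sites(self, default_sim):
        aln, _, groups, _ = default_sim
        ids_a, ids_b = groups.members("TYP"), groups.members("SHA")
        seg = set(segregating_sites(aln, ids_a + ids_b).positions)
        fixed = {p for p, _, _ in fixed_differences(aln, ids_a, ids_b)}
        assert fixed <= seg


class TestIndelEvents:
    def test_single_deletion(self):
        rows = ["A" * 20, "A" * 9 + "----" + "A" * 7, "A" * 20]
        aln = Alignment(["ref", "x", "y"], rows)
        (ev,) = indel_events(aln, "ref")
        assert (ev.start, ev.length, ev.kind, ev.gapped) == (10, 4, "deletion",
                                                             ("x",))

    def test_no_gaps_empty(self):
        assert indel_events(aln_of("ACGT", "ACGT"), "s0") == []

    def test_reference_gap_is_insertion_in_others(self):
        aln = Alignment(["ref", "x"], ["A--A", "ACCA"])
        (ev,) = indel_events(aln, "ref")
        assert ev.kind == "insertion" and ev.length == 2

    def test_adjacent_runs_different_patterns_split(self):
        aln = Alignment(["r", "x", "y"], ["AAAA", "A--A", "AA-A"])
        events = indel_events(aln, "r")
        assert [(e.start, e.length, e.gapped) for e in events] == [
            (2, 1, ("x",)), (3, 1, ("x", "y")),
        ]

    def test_three_group_fixed_deletions(self):
        # 13-, 4- and 8-bp runs fixed in one group, as in the study's lineages
        L = 120
        base = "ACGT" * 30
        gapped = list(base)
        for start, length in ((10, 13), (40, 4), (60, 8)):
            gapped[start - 1 : start - 1 + length] = "-" * length
        gapped = "".join(gapped)
        aln = Alignment(["b1", "b2", "a1", "a2"],
                        [base, base, gapped, gapped])
        events = indel_events(aln, "b1")
        assert sorted(e.length for e in events) == [4, 8, 13]
        fixed = fixed_indels(events, ["a1", "a2"], ["b1", "b2"])
        assert len(fixed) == 3 and all(e.kind == "deletion" for e in fixed)


class TestFixedIndels:
    def test_half_present_dropped(self):
        aln = Alignment(["a1", "a2", "b1"], ["A-A", "AAA", "AAA"])
        events = indel_events(aln, "b1")
        assert fixed_indels(events, ["a1", "a2"], ["b1"]) == []

    def test_simulation_recovers_planted_count(self, default_sim):
        aln, _, groups, truth = default_sim
        events = indel_events(aln, groups.members("SHA")[0])
        fixed = fixed_indels(events, groups.members("TYP"),
                             groups.members("SHA"))
        assert len(fixed) == len(truth.indel_events) == 7
        assert sorted(e.length for e in fixed) == sorted(
            t["length"] for t in truth.indel_events
        )


class TestNucleotideDiversity:
    def test_two_sequences_one_diff(self):
        a = "A" * 100
        b = "C" + "A" * 99
        assert nucleotide_diversity(aln_of(a, b)).pi == pytest.approx(0.01)

    def test_identical_group_zero(self):
        assert nucleotide_diversity(aln_of("ACGT", "ACGT", "ACGT")).pi == 0.0

    def test_matches_bruteforce_pair_enumeration(self, random_alignment):
        rng = np.random.default_rng(7)
        aln = random_alignment(rng, 4, 60, missing_rate=0.1)
        res = nucleotide_diversity(aln)
        props = []
        for r1, r2 in itertools.combinations(aln.rows, 2):
            comp = diff = 0
            for x, y in zip(r1, r2):
                if x in "ACGT" and y in "ACGT":
                    comp += 1
                    diff += x != y
            props.append(diff / comp)
        assert res.pi == pytest.approx(np.mean(props))
        assert len(props) == 6

    def test_invariant_under_row_reordering(self, random_alignment):
        rng = np.random.default_rng(9)
        aln = random_alignment(rng, 5, 40)
        shuffled = Alignment(aln.ids[::-1], aln.rows[::-1])
        assert nucleotide_diversity(aln).pi == pytest.approx(
            nucleotide_diversity(shuffled).pi
        )

    def test_incomparable_pair_is_an_error(self):
        aln = aln_of("A-", "-A")
        with pytest.raises(UndefinedPairError):
            nucleotide_diversity(aln)

    def test_simulated_pi_magnitude(self, default_sim):
        aln, _, groups, _ = default_sim
        pi = nucleotide_diversity(aln, groups.members("TYP")).pi
        assert 0.0 <= pi < 1e-3  # configured within-lineage pi is 1e-4
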