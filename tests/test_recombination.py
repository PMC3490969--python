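"""Informative sites, MaxChi, PHYLPRO profile, triplet search, parents."""

import numpy as np
import pytest

from kelppop.alignment import Alignment
from kelppop.errors import ArgumentError, InsufficientSignalError
from kelppop.recombination import (
    InformativeSiteVector,
    assign_parents,
    informative_sites,
    maxchi_scan,
    maxchi_significance,
    phylpro_profile,
    triplet_search,
)
from kelppop.simulate import PartitionSpec, SimulationConfig, simulate_two_lineages

from _oracles import brute_force_maxchi


def isv_from(bits):
    x = np.array(bits, dtype=bool)
    return InformativeSiteVector(
        "t", "p1", "p2", positions=np.arange(1, x.size + 1), indicator=x
    )


class TestInformativeSites:
    def test_target_equals_parent1(self):
        aln = Alignment(["t", "p1", "p2"], ["ACGTAC", "ACGTAC", "GCGTTC"])
        isv = informative_sites(aln, "t", "p1", "p2")
        assert isv.indicator.all()
        assert list(isv.positions) == [1, 5]

    def test_hand_built_switch_vector(self):
        # 8 informative sites: first 4 match p1, last 4 match p2
        p1 = "AAAAAAAA"
        p2 = "CCCCCCCC"
        t = "AAAACCCC"
        aln = Alignment(["t", "p1", "p2"], [t, p1, p2])
        isv = informative_sites(aln, "t", "p1", "p2")
        assert list(isv.indicator.astype(int)) == [1, 1, 1, 1, 0, 0, 0, 0]

    def test_missing_and_third_state_excluded(self):
        aln = Alignment(["t", "p1", "p2"], ["ATN-GT", "ACAAGA", "GCCCTC"])
        isv = informative_sites(aln, "t", "p1", "p2")
        # col1: t==p1; col2: parents equal; col3/4: missing; col5: t==p1;
        # col6: t matches neither
        assert list(isv.positions) == [1, 5]

    def test_too_few_sites_rejected(self):
        aln = Alignment(["t", "p1", "p2"], ["AAAA", "AAAA", "AAAA"])
        with pytest.raises(InsufficientSignalError):
            informative_sites(aln, "t", "p1", "p2")

    def test_switch_point_near_planted_breakpoint(self, recomb_sim):
        aln, _, groups, truth = recomb_sim(seed=21)
        rec = truth.recombinants[0]
        isv = informative_sites(aln, "REC1", groups.members("TYP")[0],
                                groups.members("SHA")[0])
        inside = (isv.positions >= rec["begin"]) & (isv.positions <= rec["end"])
        # inside the donor segment the target matches the SHA parent (p2)
        assert (~isv.indicator[inside]).mean() > 0.95
        assert isv.indicator[~inside].mean() > 0.95


class TestMaxChi:
    def test_clean_switch_max(self):
        prof = maxchi_scan(isv_from([1, 1, 1, 1, 0, 0, 0, 0]))
        assert prof.max_chi2 == pytest.approx(8.0)
        assert prof.argmax == 4

    def test_constant_vector_zero(self):
        prof = maxchi_scan(isv_from([1, 1, 1, 1]))
        assert prof.max_chi2 == 0.0

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            m = int(rng.integers(4, 21))
            x = rng.integers(0, 2, size=m)
            prof = maxchi_scan(isv_from(x))
            chi_ref, max_ref, arg_ref = brute_force_maxchi(x)
            assert np.allclose(prof.chi2, chi_ref)
            assert prof.max_chi2 == pytest.approx(max_ref)
            assert prof.argmax == arg_ref

    def test_insufficient_sites_rejected(self):
        with pytest.raises(InsufficientSignalError):
            maxchi_scan(isv_from([1, 0, 1]))


class TestMaxChiSignificance:
    def test_clean_switch_significant(self):
        p = maxchi_significance(isv_from([1] * 6 + [0] * 6), n_perm=999, seed=3)
        assert p <= 0.05

    def test_deterministic_given_seed(self):
        isv = isv_from([1, 0, 1, 1, 0, 0, 1, 0, 1, 1])
        assert maxchi_significance(isv, 499, seed=5) == \
            maxchi_significance(isv, 499, seed=5)

    def test_p_in_valid_range(self):
        rng = np.random.default_rng(1)
        isv = isv_from(rng.integers(0, 2, 20))
        p = maxchi_significance(isv, n_perm=199, seed=0)
        assert 1 / 200 <= p <= 1.0


class TestPhylpro:
    def test_clocklike_profile_high(self):
        cfg = SimulationConfig(
            partitions=[PartitionSpec("COI", 1500, 0.12, 0.01)],
            n_a=4, n_b=4, fixed_indels=[], seed=31,
        )
        aln, _, groups, _ = simulate_two_lineages(cfg)
        cols, corr = phylpro_profile(aln, groups.members("TYP")[0], window=20)
        assert np.nanmin(corr) > 0.8

    def test_spliced_recombinant_minimum_near_breakpoint(self, recomb_sim):
        aln, _, _, truth = recomb_sim(seed=41)
        rec = truth.recombinants[0]
        cols, corr = phylpro_profile(aln, "REC1", window=15)
        min_col = cols[np.nanargmin(corr)]
        near_either = min(abs(min_col - rec["begin"]), abs(min_col - rec["end"]))
        assert np.nanmin(corr) < 0.2
        # minimum within one window's worth of variable sites of a breakpoint
        assert near_either < 120

    def test_degenerate_window_flagged_missing_not_error(self):
        # target equidistant from identical others -> zero-variance vectors
        rows = ["ACGT" * 30, "TGCA" * 30, "TGCA" * 30, "TGCA" * 30]
        aln = Alignment(["t", "a", "b", "c"], rows)
        cols, corr = phylpro_profile(aln, "t", window=5)
        assert np.isnan(corr).all()


class TestTripletSearchAndParents:
    def test_spliced_event_recovered(self, recomb_sim):
        aln, _, groups, truth = recomb_sim(seed=51)
        rec = truth.recombinants[0]
        events = triplet_search(aln, n_perm=4999, seed=8)
        assert [e.recombinant for e in events] == ["REC1"]
        ev = events[0]
        assert abs(ev.begin - rec["begin"]) <= 30
        assert abs(ev.end - rec["end"]) <= 30
        # background lineage contributes the flanks -> major parent;
        # donor lineage contributes the segment -> minor parent
        assert ev.major_parent.startswith("TYP")
        assert ev.minor_parent.startswith("SHA")

    def test_no_recombination_no_events(self):
        cfg = SimulationConfig(
            partitions=[PartitionSpec("COI", 1200, 0.12, 0.002)],
            n_a=4, n_b=4, fixed_indels=[], seed=61,
        )
        aln, _, _, _ = simulate_two_lineages(cfg)
        assert triplet_search(aln, n_perm=999, seed=2) == []

    def test_row_order_invariance(self, recomb_sim):
        aln, _, _, _ = recomb_sim(seed=71)
        reordered = Alignment(aln.ids[::-1], aln.rows[::-1])
        e1 = triplet_search(aln, n_perm=999, seed=9)
        e2 = triplet_search(reordered, n_perm=999, seed=9)
        assert [(e.recombinant, e.begin, e.end) for e in e1] == \
            [(e.recombinant, e.begin, e.end) for e in e2]

    def test_duplicate_recombinant_both_flagged(self, recomb_sim):
        aln, _, _, truth = recomb_sim(seed=81)
        dup = Alignment(aln.ids + ["REC2"], aln.rows + [aln.row("REC1")])
        # the extra sequence enlarges the Bonferroni family, so the
        # permutation p floor needs more resolution
        events = triplet_search(dup, n_perm=19999, seed=10)
        assert {e.recombinant for e in events} >= {"REC1", "REC2"}

    def test_assign_parents_recovers_donors(self, recomb_sim):
        aln, _, groups, truth = recomb_sim(seed=91)
        rec = truth.recombinants[0]
        pa = assign_parents(aln, "REC1", rec["begin"], rec["end"])
        assert pa.minor.startswith("SHA") and pa.major.startswith("TYP")

    def test_non_recombinant_same_nearest_both_sides(self, recomb_sim):
        aln, _, groups, _ = recomb_sim(seed=91)
        target = groups.members("TYP")[0]
        pa = assign_parents(aln, target, 500, 900)
        assert pa.major.startswith("TYP") and pa.minor.startswith("TYP")

    def test_invalid_segment_rejected(self, recomb_sim):
        aln, _, _, _ = recomb_sim(seed=91)
        with pytest.raises(ArgumentError):
            assign_parents(aln, "REC1", 0, 50)
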