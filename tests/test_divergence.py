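"""Distance models, Dxy and sliding-window profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kelppop.alignment import Alignment
from kelppop.divergence import (
    DivergenceProfile,
    WindowSpec,
    dxy,
    pairwise_distance,
    sliding_window_divergence,
)
from kelppop.errors import ArgumentError, SaturationError, UndefinedPairError
from kelppop.variation import nucleotide_diversity


def seq_pair_with(p_ts: int, p_tv: int, same: int):
    """Two rows with exact transition/transversion/identical site counts."""
    a = "A" * (p_ts + p_tv + same)
    b = "G" * p_ts + "C" * p_tv + "A" * same  # A->G transition, A->C transversion
    return a, b


class TestPairwiseDistance:
    @pytest.mark.parametrize("model", ["p", "JC69", "K2P", "T92"])
    def test_identical_sequences_zero(self, model):
        r = pairwise_distance("ACGTACGT", "ACGTACGT", model)
        assert r.p == 0.0 and r.d == 0.0

    def test_jc69_quarter(self):
        # p = 0.25 -> d = -(3/4) ln(2/3)
        a, b = seq_pair_with(3, 2, 15)  # 5/20 differ
        r = pairwise_distance(a, b, "JC69")
        assert r.p == 0.25
        assert r.d == pytest.approx(-0.75 * math.log(2 / 3), abs=1e-10)
        assert r.d == pytest.approx(0.3041, abs=5e-5)

    def test_k2p_example(self):
        # P = 0.10, Q = 0.05 -> d = -0.5 ln 0.75 - 0.25 ln 0.9
        a, b = seq_pair_with(2, 1, 17)  # 2/20 ts, 1/20 tv
        r = pairwise_distance(a, b, "K2P")
        assert (r.P, r.Q) == (0.10, 0.05)
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.9)
        assert r.d == pytest.approx(expected, abs=1e-10)
        assert r.d == pytest.approx(0.1702, abs=5e-5)

    def test_p_equals_P_plus_Q(self):
        a, b = seq_pair_with(4, 3, 13)
        r = pairwise_distance(a, b, "p")
        assert r.p == pytest.approx(r.P + r.Q) and r.d == r.p

    def test_t92_uses_pair_gc(self):
        a, b = seq_pair_with(2, 1, 17)
        r = pairwise_distance(a, b, "T92")
        assert r.h == pytest.approx(2 * r.theta_gc * (1 - r.theta_gc))
        assert r.d > r.p  # correction inflates

    def test_saturation_raises(self):
        a = "A" * 10
        b = "G" * 10  # p = 1 saturates JC
        with pytest.raises(SaturationError):
            pairwise_distance(a, b, "JC69")

    def test_no_comparable_sites(self):
        with pytest.raises(UndefinedPairError):
            pairwise_distance("--", "AA")

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(1, 60), st.integers(0, 40))
    def test_jc_correction_monotone(self, ndiff, nsame):
        total = ndiff + nsame
        p = ndiff / total
        if p >= 0.75:
            return
        a = "A" * total
        b = "G" * ndiff + "A" * nsame
        r = pairwise_distance(a, b, "JC69")
        assert r.d >= r.p
        assert (r.d == r.p) == (p == 0.0)


class TestDxy:
    def test_single_pair_equals_pairwise(self):
        aln = Alignment(["a", "b"], ["AAAA", "AAAC"])
        res = dxy(aln, ["a"], ["b"], bootstrap_reps=0)
        assert res.dxy == pytest.approx(0.25)

    def test_fixed_difference_structure(self):
        # two monomorphic groups differing at 109 of 4,178 comparable sites
        L, n_fixed, n_missing = 4286, 109, 108
        base = ["A"] * L
        other = list(base)
        for i in range(n_fixed):
            other[i] = "C"
        for i in range(n_fixed, n_fixed + n_missing):
            base[i] = "N"
            other[i] = "N"
        aln = Alignment(["a1", "a2", "b1", "b2"],
                        ["".join(base)] * 2 + ["".join(other)] * 2)
        res = dxy(aln, ["a1", "a2"], ["b1", "b2"], bootstrap_reps=0)
        assert res.dxy == pytest.approx(109 / 4178)
        assert round(res.dxy, 4) == 0.0261

    def test_planted_divergence_recovered(self, default_sim):
        aln, pm, groups, truth = default_sim
        lo, hi = pm.interval("COI")
        res = dxy(aln.slice(lo, hi), groups.members("TYP"),
                  groups.members("SHA"), bootstrap_reps=200, seed=3)
        assert abs(res.dxy - 0.048) <= 3 * max(res.se, 1e-4)

    def test_bootstrap_se_deterministic(self, default_sim):
        aln, _, groups, _ = default_sim
        a, b = groups.members("TYP")[:3], groups.members("SHA")[:3]
        r1 = dxy(aln, a, b, bootstrap_reps=50, seed=11)
        r2 = dxy(aln, a, b, bootstrap_reps=50, seed=11)
        assert r1.se == r2.se and r1.se > 0

    def test_self_split_approximates_pi(self, default_sim):
        # Dxy of a group split in half ~ pi of the group
        aln, _, groups, _ = default_sim
        ids = groups.members("TYP")
        pi = nucleotide_diversity(aln, ids).pi
        res = dxy(aln, ids[:8], ids[8:], bootstrap_reps=0)
        assert abs(res.dxy - pi) < 5e-4


class TestSlidingWindows:
    def test_window_grid_enumeration(self):
        aln = Alignment(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"])
        prof = sliding_window_divergence(aln, ["a"], ["b"], WindowSpec(4, 2))
        starts = prof.midpoints - (4 - 1) / 2
        assert list(starts) == [1, 3, 5, 7]

    def test_uniform_divergence_flat(self):
        a = "ACGT" * 25
        b = "AGGT" * 25  # every 4-column block has exactly one difference
        aln = Alignment(["a", "b"], [a, b])
        prof = sliding_window_divergence(aln, ["a"], ["b"], WindowSpec(4, 4))
        assert np.allclose(prof.values, 0.25)

    def test_full_window_reproduces_global(self, default_sim):
        aln, _, groups, _ = default_sim
        a, b = groups.members("TYP")[:4], groups.members("SHA")[:4]
        spec = WindowSpec(aln.length, aln.length)
        prof = sliding_window_divergence(aln, a, b, spec)
        ref = dxy(aln, a, b, bootstrap_reps=0)
        assert prof.values.size == 1
        assert prof.values[0] == pytest.approx(ref.dxy)

    def test_recombinant_profile_contrast(self, recomb_sim):
        aln, _, groups, truth = recomb_sim(seed=5)
        rec = truth.recombinants[0]
        prof = sliding_window_divergence(
            aln, ["REC1"], [groups.members("TYP")[0]], WindowSpec(50, 10))
        inside = (prof.midpoints >= rec["begin"]) & (prof.midpoints <= rec["end"])
        assert np.nanmean(prof.values[inside]) > np.nanmean(prof.values[~inside])

    def test_window_larger_than_region_rejected(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(ArgumentError):
            sliding_window_divergence(aln, ["a"], ["b"], WindowSpec(10, 1))

    def test_no_comparable_sites_flagged_missing(self):
        aln = Alignment(["a", "b"], ["AANN", "AANN"])
        prof = sliding_window_divergence(aln, ["a"], ["b"], WindowSpec(2, 2))
        assert not np.isnan(prof.values[0]) and np.isnan(prof.values[1])
        assert isinstance(prof, DivergenceProfile)
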