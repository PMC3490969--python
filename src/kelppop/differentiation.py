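"""Two-group differentiation statistics with permutation significance.

Fst follows the Hudson–Slatkin–Maddison construction ``1 - Hw/Hb`` where Hw
and Hb are mean per-site pairwise differences within and between groups; Kst
follows Hudson–Boos–Kaplan, ``1 - Ks/Kt`` with sample-size-weighted
within-group diversity Ks against the pooled diversity Kt.  Significance
comes from shuffling group labels over the pooled sample, preserving group
sizes, with the never-zero ``(1+k)/(1+N)`` p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._pairwise import p_distance_matrix
from .alignment import Alignment
from .errors import ArgumentError, UndefinedPairError, UndefinedStatisticError


@dataclass
class DifferentiationResult:
    statistic_name: str
    value: float
    hw: float | None = None
    hb: float | None = None
    ks: float | None = None
    kt: float | None = None
    permutations: int = 0
    p_value: float | None = None
    seed: int | None = None
    hw_weighting: str = "pooled"


def _prepare(aln: Alignment, group_a: Iterable[str], group_b: Iterable[str]):
    a_ids, b_ids = list(group_a), list(group_b)
    if not a_ids or not b_ids:
        raise ArgumentError("both groups must be non-empty")
    if set(a_ids) & set(b_ids):
        raise ArgumentError("groups overlap")
    pooled = a_ids + b_ids
    sub = aln.subset(pooled)
    # label vector in sub's row order
    labels = np.array([sid in set(a_ids) for sid in sub.ids], dtype=bool)
    dist = p_distance_matrix(sub.codes)
    iu = np.triu_indices(sub.n, k=1)
    dvec = dist[iu]
    if np.isnan(dvec).any():
        k = int(np.argmax(np.isnan(dvec)))
        raise UndefinedPairError(
            f"pair ({sub.ids[iu[0][k]]}, {sub.ids[iu[1][k]]}) shares no "
            "comparable sites"
        )
    return labels, dvec, iu


def _fst_from_pairs(dvec, same_mask, weighting="pooled", lab=None, iu=None):
    within = dvec[same_mask]
    between = dvec[~same_mask]
    if between.size == 0:
        raise UndefinedStatisticError("no between-group pairs")
    hb = float(between.mean())
    if hb == 0.0:
        raise UndefinedStatisticError("Hb = 0: Fst undefined")
    if weighting == "pooled":
        hw = float(within.mean()) if within.size else 0.0
    elif weighting == "group_mean":
        in_a = lab[iu[0]] & lab[iu[1]]
        in_b = ~lab[iu[0]] & ~lab[iu[1]]
        means = [dvec[m].mean() for m in (in_a, in_b) if m.any()]
        hw = float(np.mean(means)) if means else 0.0
    else:
        raise ArgumentError(f"unknown hw weighting {weighting!r}")
    return 1.0 - hw / hb, hw, hb


def _kst_from_pairs(dvec, lab, iu, n_a, n_b):
    in_a = lab[iu[0]] & lab[iu[1]]
    in_b = ~lab[iu[0]] & ~lab[iu[1]]
    k1 = float(dvec[in_a].mean()) if in_a.any() else 0.0
    k2 = float(dvec[in_b].mean()) if in_b.any() else 0.0
    ks = (n_a * k1 + n_b * k2) / (n_a + n_b)
    kt = float(dvec.mean())
    if kt == 0.0:
        raise UndefinedStatisticError("Kt = 0: Kst undefined")
    return 1.0 - ks / kt, ks, kt


def hudson_fst(
    aln: Alignment,
    group_a: Iterable[str],
    group_b: Iterable[str],
    hw_weighting: str = "pooled",
) -> DifferentiationResult:
    """Fst = 1 - Hw/Hb over per-site pairwise differences (p-distances).

    ``hw_weighting="pooled"`` averages all within-group pairs together
    (default); ``"group_mean"`` averages the two group means.
    """
    lab, dvec, iu = _prepare(aln, group_a, group_b)
    same = lab[iu[0]] == lab[iu[1]]
    value, hw, hb = _fst_from_pairs(dvec, same, hw_weighting, lab, iu)
    return DifferentiationResult("Fst", value, hw=hw, hb=hb,
                                 hw_weighting=hw_weighting)


def kst(
    aln: Alignment, group_a: Iterable[str], group_b: Iterable[str]
) -> DifferentiationResult:
    """Kst = 1 - Ks/Kt with Ks the n-weighted mean of within-group diversities."""
    a_ids, b_ids = list(group_a), list(group_b)
    lab, dvec, iu = _prepare(aln, a_ids, b_ids)
    value, ks, kt = _kst_from_pairs(dvec, lab, iu, len(a_ids), len(b_ids))
    return DifferentiationResult("Kst", value, ks=ks, kt=kt)


def permutation_test(
    aln: Alignment,
    group_a: Iterable[str],
    group_b: Iterable[str],
    statistic: str = "Fst",
    n_perm: int = 1000,
    seed: int | None = None,
    hw_weighting: str = "pooled",
) -> DifferentiationResult:
    """Label-permutation significance for Fst or Kst.

    Group labels are shuffled across the pooled sample preserving group
    sizes; ``p = (1 + #{permuted >= observed}) / (1 + n_perm)``.  A permuted
    arrangement whose statistic is undefined (zero denominator) never
    exceeds the observed value.  Deterministic given *seed*.
    """
    if n_perm < 1:
        raise ArgumentError("n_perm must be >= 1")
    a_ids, b_ids = list(group_a), list(group_b)
    lab, dvec, iu = _prepare(aln, a_ids, b_ids)
    n_a, n_b = len(a_ids), len(b_ids)

    def stat(lab_vec) -> float:
        if statistic == "Fst":
            same = lab_vec[iu[0]] == lab_vec[iu[1]]
            return _fst_from_pairs(dvec, same, hw_weighting, lab_vec, iu)[0]
        if statistic == "Kst":
            return _kst_from_pairs(dvec, lab_vec, iu, n_a, n_b)[0]
        raise ArgumentError(f"unknown statistic {statistic!r}")

    observed = stat(lab)  # errors propagate (undefined on observed data)
    rng = np.random.default_rng(seed)
    exceed = 0
    template = lab.copy()
    for _ in range(n_perm):
        perm = rng.permutation(template)
        try:
            if stat(perm) >= observed:
                exceed += 1
        except UndefinedStatisticError:
            continue
    p = (1 + exceed) / (1 + n_perm)
    base = hudson_fst(aln, a_ids, b_ids, hw_weighting) if statistic == "Fst" \
        else kst(aln, a_ids, b_ids)
    base.permutations = n_perm
    base.p_value = p
    base.seed = seed
    return base
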