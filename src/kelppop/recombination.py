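"""Interspecific recombination detection in a gene alignment.

Three methods over a common informative-site substrate:

* **MaxChi** (Maynard Smith): for a target and two candidate parents, the
  2x2 chi-square of parent-match counts left/right of a sliding partition of
  the informative sites, maximised over partitions, with permutation
  significance.
* **Triplet search** (Chimaera-style): exhaustive (target, parent1, parent2)
  triplets, each scanned with MaxChi and Bonferroni-corrected over the number
  of evaluated triplets; per-target events keep the best-supported breakpoint
  pair, localised by an exhaustive two-changepoint chi-square maximisation.
* **PHYLPRO-style profile**: at each candidate position, the Pearson
  correlation between the target's distance vectors (to every other
  sequence) computed from the flanking windows of variable sites; minima
  flag breakpoints.

An informative site for a triplet is a column where the two parents differ
and the target matches exactly one of them; columns with any missing state
among the three are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .alignment import Alignment
from .errors import ArgumentError, InsufficientSignalError


@dataclass
class InformativeSiteVector:
    """Ordered informative sites for (target, parent1, parent2).

    ``positions`` are 1-based alignment columns (strictly increasing);
    ``indicator`` is True where the target matches parent1.
    """

    target: str
    parent1: str
    parent2: str
    positions: np.ndarray
    indicator: np.ndarray

    @property
    def m(self) -> int:
        return int(self.positions.size)


@dataclass
class MaxChiProfile:
    """Chi-square over all partitions of the informative-site order."""

    partition_points: np.ndarray  # k = 1..m-1 (sites left of the cut)
    chi2: np.ndarray
    max_chi2: float
    argmax: int  # partition point k attaining the max (first on ties)
    breakpoint_column: int  # alignment column between sites k and k+1


@dataclass
class RecombinationEvent:
    recombinant: str
    major_parent: str
    minor_parent: str
    begin: int
    end: int
    segment_length: int
    statistic: float
    p_value: float
    p_corrected: float
    method: str = "maxchi_triplet"
    breakpoint_column: int | None = None
    parents_tie: bool = False
    scan_parent1: str | None = None
    scan_parent2: str | None = None


class ParentAssignment(NamedTuple):
    major: str
    minor: str
    tie: bool


def informative_sites(
    aln: Alignment, target: str, parent1: str, parent2: str
) -> InformativeSiteVector:
    """Columns where the parents differ and the target matches exactly one."""
    if len({target, parent1, parent2}) != 3:
        raise ArgumentError("target and parents must be three distinct ids")
    ct = aln.codes[aln.index(target)]
    c1 = aln.codes[aln.index(parent1)]
    c2 = aln.codes[aln.index(parent2)]
    ok = (ct >= 0) & (c1 >= 0) & (c2 >= 0) & (c1 != c2)
    match1 = ok & (ct == c1)
    match2 = ok & (ct == c2)
    informative = match1 | match2  # target matching neither is excluded
    cols = np.nonzero(informative)[0]
    if cols.size < 2:
        raise InsufficientSignalError(
            f"only {cols.size} informative site(s) for "
            f"({target}, {parent1}, {parent2})"
        )
    return InformativeSiteVector(
        target=target,
        parent1=parent1,
        parent2=parent2,
        positions=cols + 1,
        indicator=match1[cols],
    )


def _chi2_partitions(x: np.ndarray) -> np.ndarray:
    """Chi-square at every partition point of a binary vector.

    For the cut after site k (1 <= k < m): a/b = left matches-p1/p2 counts,
    c/d = right counts; chi2 = m (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); a
    zero margin scores 0 (no continuity correction).
    """
    m = x.size
    ones = int(x.sum())
    if ones in (0, m):  # a zero margin at every partition
        return np.zeros(m - 1)
    a = np.cumsum(x)[:-1].astype(np.int64)
    k = np.arange(1, m, dtype=np.int64)
    b = k - a
    c = ones - a
    d = (m - k) - c
    num = m * (a * d - b * c).astype(np.float64) ** 2
    den = (k * (m - k) * ones * (m - ones)).astype(np.float64)
    return num / den


def _chi2_partitions_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise maximum partition chi-square (one binary vector per row)."""
    r, m = mat.shape
    ones = mat.sum(axis=1, keepdims=True).astype(np.int64)
    a = np.cumsum(mat, axis=1)[:, :-1].astype(np.int64)
    k = np.arange(1, m, dtype=np.int64)[None, :]
    b = k - a
    c = ones - a
    d = (m - k) - c
    num = m * (a * d - b * c).astype(np.float64) ** 2
    den = (k * (m - k) * ones * (m - ones)).astype(np.float64)
    chi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return chi.max(axis=1)


def maxchi_scan(isv: InformativeSiteVector) -> MaxChiProfile:
    """Maximise the partition chi-square over the informative-site order."""
    if isv.m < 4:
        raise InsufficientSignalError(
            f"MaxChi needs >= 4 informative sites, got {isv.m}"
        )
    x = isv.indicator.astype(np.int64)
    chi = _chi2_partitions(x)
    arg = int(np.argmax(chi))  # first occurrence: lowest partition point
    k = arg + 1
    left_col = int(isv.positions[k - 1])
    right_col = int(isv.positions[k])
    return MaxChiProfile(
        partition_points=np.arange(1, isv.m),
        chi2=chi,
        max_chi2=float(chi[arg]),
        argmax=k,
        breakpoint_column=(left_col + right_col) // 2,
    )


def maxchi_significance(
    isv: InformativeSiteVector, n_perm: int = 1000, seed: int | None = None
) -> float:
    """Permutation p-value for the MaxChi maximum.

    The null permutes the order of the informative sites;
    ``p = (1 + #{permuted maxima >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ArgumentError("n_perm must be >= 1")
    observed = maxchi_scan(isv).max_chi2
    rng = np.random.default_rng(seed)
    exceed = _count_exceeding(isv.indicator, observed, n_perm, rng)
    return (1 + exceed) / (1 + n_perm)


def _count_exceeding(indicator, observed, n_perm, rng, chunk=2000) -> int:
    x = indicator.astype(np.int8)
    exceed = 0
    done = 0
    while done < n_perm:
        r = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(x, (r, 1)), axis=1)
        exceed += int((_chi2_partitions_rows(perms) >= observed - 1e-12).sum())
        done += r
    return exceed


def _sequential_significance(
    isv: InformativeSiteVector,
    observed: float,
    n_perm: int,
    rng,
    batch: int = 100,
    early_exceed: int = 30,
) -> tuple[float, int]:
    """Early-stopping permutation p.

    Draws permutations in batches and stops once *early_exceed* permuted
    maxima have reached the observed value — at that point the p-value is
    already far above any Bonferroni threshold and extra permutations cannot
    change the verdict.  Returns ``(p, permutations_used)``.
    """
    x = isv.indicator.astype(np.int8)
    exceed = 0
    done = 0
    while done < n_perm:
        r = min(batch, n_perm - done)
        perms = rng.permuted(np.tile(x, (r, 1)), axis=1)
        exceed += int((_chi2_partitions_rows(perms) >= observed - 1e-12).sum())
        done += r
        if exceed >= early_exceed:
            break
        batch = min(batch * 4, 4000)
    return (1 + exceed) / (1 + done), done


def _best_segment(x: np.ndarray) -> tuple[int, int, float]:
    """Exhaustive two-changepoint chi-square maximisation.

    Over all 0 <= k1 < k2 <= m (excluding the full vector), contrasts
    parent-match counts inside sites [k1, k2) against outside; returns
    (k1, k2, chi2).  Single-breakpoint solutions appear as k1 = 0 or k2 = m.
    """
    m = x.size
    ones = int(x.sum())
    if ones in (0, m):
        return 0, m, 0.0
    s = np.concatenate([[0], np.cumsum(x)]).astype(np.int64)
    k1 = np.arange(m + 1)[:, None]
    k2 = np.arange(m + 1)[None, :]
    size = k2 - k1
    a = s[None, :] - s[:, None]  # ones inside [k1, k2)
    b = size - a
    c = ones - a
    d = (m - size) - c
    num = m * (a * d - b * c).astype(np.float64) ** 2
    den = (size * (m - size) * ones * (m - ones)).astype(np.float64)
    valid = (size >= 1) & (size <= m - 1)
    chi = np.where(valid & (den > 0), num / np.where(den > 0, den, 1.0), -1.0)
    flat = int(np.argmax(chi))
    i, j = divmod(flat, m + 1)
    return int(i), int(j), float(chi[i, j])


def phylpro_profile(
    aln: Alignment, target: str, window: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Phylogenetic-profile correlation scan for *target*.

    At each boundary between consecutive variable sites, correlates the
    vector of target-to-other p-distances computed from the *window* variable
    sites on the left with the same vector from the right window.  Returns
    ``(columns, correlations)`` where ``columns`` is the 1-based alignment
    column of the boundary site; NaN marks zero-variance (undefined)
    positions.  Low correlation flags candidate breakpoints.
    """
    if window < 2:
        raise ArgumentError("window must be >= 2 variable sites")
    t_idx = aln.index(target)
    codes = aln.codes
    valid = codes >= 0
    # variable columns among all sequences
    hi = np.where(valid, codes, -10).max(axis=0)
    lo = np.where(valid, codes, 10).min(axis=0)
    var_cols = np.nonzero(valid.any(axis=0) & (hi != lo))[0]
    m = var_cols.size
    if m < 2 * window:
        raise InsufficientSignalError(
            f"need >= {2 * window} variable sites, found {m}"
        )
    others = [i for i in range(aln.n) if i != t_idx]
    ct = codes[t_idx, var_cols]
    # per other sequence, per variable site: differ / comparable
    diff = np.zeros((len(others), m))
    comp = np.zeros((len(others), m))
    for r, j in enumerate(others):
        cj = codes[j, var_cols]
        v = (ct >= 0) & (cj >= 0)
        comp[r] = v
        diff[r] = v & (ct != cj)
    cs_diff = np.concatenate([np.zeros((len(others), 1)), diff.cumsum(1)], axis=1)
    cs_comp = np.concatenate([np.zeros((len(others), 1)), comp.cumsum(1)], axis=1)

    ks = np.arange(window, m - window + 1)
    cols = var_cols[ks - 1] + 1  # boundary after this variable site
    corrs = np.full(ks.size, np.nan)
    for idx, k in enumerate(ks):
        dl_n = cs_diff[:, k] - cs_diff[:, k - window]
        dl_c = cs_comp[:, k] - cs_comp[:, k - window]
        dr_n = cs_diff[:, k + window] - cs_diff[:, k]
        dr_c = cs_comp[:, k + window] - cs_comp[:, k]
        use = (dl_c > 0) & (dr_c > 0)
        if use.sum() < 3:
            continue
        dl = dl_n[use] / dl_c[use]
        dr = dr_n[use] / dr_c[use]
        if dl.std() == 0.0 or dr.std() == 0.0:
            continue  # undefined: flagged missing (NaN)
        corrs[idx] = float(np.corrcoef(dl, dr)[0, 1])
    return cols, corrs


def assign_parents(
    aln: Alignment,
    target: str,
    begin: int,
    end: int,
    candidates: Iterable[str] | None = None,
) -> ParentAssignment:
    """Nearest candidates inside and outside the segment [begin, end].

    The minor parent minimises the p-distance to the target inside the
    segment; the major parent minimises it outside (the major contributes
    the longer remainder of the sequence).  Ties break on label order and
    are reported via ``tie``.
    """
    if not (1 <= begin <= end <= aln.length):
        raise ArgumentError(f"invalid segment ({begin}, {end})")
    cand = sorted(set(candidates) if candidates is not None
                  else set(aln.ids) - {target})
    cand = [c for c in cand if c != target]
    if not cand:
        raise ArgumentError("no candidate parents")
    ct = aln.codes[aln.index(target)]
    inside = np.zeros(aln.length, dtype=bool)
    inside[begin - 1 : end] = True

    def nearest(mask: np.ndarray) -> tuple[str, bool]:
        best_label, best_d = None, np.inf
        tie = False
        for c in cand:
            cc = aln.codes[aln.index(c)]
            v = (ct >= 0) & (cc >= 0) & mask
            n = int(v.sum())
            if n == 0:
                continue
            d = float((v & (ct != cc)).sum()) / n
            if d < best_d - 1e-12:
                best_label, best_d, tie = c, d, False
            elif abs(d - best_d) <= 1e-12:
                tie = True
        if best_label is None:
            raise ArgumentError("no candidate comparable over the segment")
        return best_label, tie

    minor, tie_in = nearest(inside)
    major, tie_out = nearest(~inside)
    return ParentAssignment(major=major, minor=minor, tie=tie_in or tie_out)


def triplet_search(
    aln: Alignment,
    n_perm: int = 4999,
    seed: int | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    min_informative: int = 4,
) -> list[RecombinationEvent]:
    """Exhaustive triplet MaxChi scan with family-wise control.

    Every ordered target with every unordered candidate-parent pair is
    scanned; permutation p-values (early-stopping, seeded) are Bonferroni
    corrected over the number of triplets actually evaluated.  Events are
    merged per target, keeping the smallest raw p (ties: larger chi-square,
    then label order); the reported breakpoint pair comes from the
    two-changepoint chi-square maximisation on the winning triplet, and
    parents are re-assigned over all candidates via :func:`assign_parents`.

    Secondary echoes are suppressed: a true recombinant's splice leaves a
    clustered minority signal in triplets that use the recombinant itself as
    a parent, so an event whose winning triplet names a better-supported
    event's recombinant among its parents is dropped.

    Iteration order is sorted by id, so results do not depend on the input
    row order.
    """
    if correction != "bonferroni":
        raise ArgumentError("only bonferroni correction is supported")
    if aln.n < 3:
        raise ArgumentError("need at least 3 sequences")
    ids = sorted(aln.ids)
    rng = np.random.default_rng(seed)

    scanned: list[tuple[str, InformativeSiteVector, MaxChiProfile]] = []
    n_evaluated = 0
    for t in ids:
        others = [x for x in ids if x != t]
        for i in range(len(others)):
            for j in range(i + 1, len(others)):
                try:
                    isv = informative_sites(aln, t, others[i], others[j])
                    prof = maxchi_scan(isv)
                except InsufficientSignalError:
                    continue
                n_evaluated += 1
                scanned.append((t, isv, prof))

    best_per_target: dict[str, tuple[float, float, InformativeSiteVector,
                                     MaxChiProfile]] = {}
    for t, isv, prof in scanned:
        if prof.max_chi2 <= 0.0:
            p_raw = 1.0
        else:
            p_raw, _ = _sequential_significance(
                isv, prof.max_chi2, n_perm,
                np.random.default_rng(rng.integers(0, 2**31 - 1)),
            )
        cur = best_per_target.get(t)
        key = (p_raw, -prof.max_chi2)
        if cur is None or key < (cur[0], -cur[1]):
            best_per_target[t] = (p_raw, prof.max_chi2, isv, prof)

    events: list[RecombinationEvent] = []
    for t in ids:
        if t not in best_per_target:
            continue
        p_raw, chi, isv, prof = best_per_target[t]
        p_corr = min(1.0, p_raw * max(n_evaluated, 1))
        if p_corr > alpha:
            continue
        begin, end = _segment_columns(aln, isv)
        parents = assign_parents(aln, t, begin, end)
        events.append(
            RecombinationEvent(
                recombinant=t,
                major_parent=parents.major,
                minor_parent=parents.minor,
                begin=begin,
                end=end,
                segment_length=end - begin + 1,
                statistic=chi,
                p_value=p_raw,
                p_corrected=p_corr,
                breakpoint_column=prof.breakpoint_column,
                parents_tie=parents.tie,
                scan_parent1=isv.parent1,
                scan_parent2=isv.parent2,
            )
        )
    return _suppress_echoes(events)


def _suppress_echoes(events: list[RecombinationEvent]) -> list[RecombinationEvent]:
    """Drop events whose winning triplet used a better-supported event's
    recombinant as a parent (ordering: smaller raw p, then larger chi2)."""

    def strength(e: RecombinationEvent):
        return (e.p_value, -e.statistic)

    kept: list[RecombinationEvent] = []
    for e in sorted(events, key=strength):
        parents = {e.scan_parent1, e.scan_parent2}
        if any(f.recombinant in parents and strength(f) < strength(e)
               for f in kept):
            continue
        kept.append(e)
    order = {e.recombinant: i for i, e in enumerate(events)}
    return sorted(kept, key=lambda e: order[e.recombinant])


def _segment_columns(aln: Alignment, isv: InformativeSiteVector) -> tuple[int, int]:
    """Alignment-column interval of the donor segment for a triplet.

    The two-changepoint solution picks the contiguous informative-site run
    [k1, k2) most different from its flanks; boundaries map to the midpoint
    between the bracketing informative sites (region edges when the run
    touches an end of the vector).
    """
    x = isv.indicator.astype(np.int64)
    k1, k2, _ = _best_segment(x)
    pos = isv.positions
    m = isv.m
    if k1 == 0:
        begin = 1
    else:
        begin = (int(pos[k1 - 1]) + int(pos[k1])) // 2 + 1
    if k2 == m:
        end = aln.length
    else:
        end = (int(pos[k2 - 1]) + int(pos[k2])) // 2
    return begin, end


def events_frame(events: list[RecombinationEvent]):
    import pandas as pd

    return pd.DataFrame.from_records(
        [
            {
                "recombinant": e.recombinant,
                "major_parent": e.major_parent,
                "minor_parent": e.minor_parent,
                "begin": e.begin,
                "end": e.end,
                "segment_length": e.segment_length,
                "statistic": e.statistic,
                "p_value": e.p_value,
                "p_corrected": e.p_corrected,
                "method": e.method,
            }
            for e in events
        ],
        columns=[
            "recombinant", "major_parent", "minor_parent", "begin", "end",
            "segment_length", "statistic", "p_value", "p_corrected", "method",
        ],
    )
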