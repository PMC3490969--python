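"""Site-level catalogue of variation.

Segregating sites, fixed differences between groups, indel events and fixed
length polymorphisms, and nucleotide diversity (pi).  Gap and ambiguity
characters are missing states throughout — they are never counted as alleles,
and divergence statistics drop them pairwise ("ignoring indels").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._pairwise import diff_and_comparable
from .alignment import Alignment, GroupAssignment
from .errors import ArgumentError, UndefinedPairError

_BASES = "ACGT"


@dataclass
class SiteCatalogue:
    """Segregating positions with per-group allele counts.

    ``positions`` are 1-based alignment columns; ``allele_counts[pos][group]``
    maps base -> count over the analysed samples (group ``"all"`` when no
    grouping was supplied).
    """

    positions: list[int]
    allele_counts: dict[int, dict[str, dict[str, int]]]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for pos in self.positions:
            for group, counts in self.allele_counts[pos].items():
                alleles = ",".join(f"{b}:{c}" for b, c in sorted(counts.items()))
                records.append({"position": pos, "group": group, "alleles": alleles})
        return pd.DataFrame.from_records(
            records, columns=["position", "group", "alleles"]
        )


@dataclass
class IndelEvent:
    """A maximal gap run with a constant presence pattern.

    ``start`` is the 1-based first column of the run, ``length`` its width in
    columns, ``gapped`` the ids carrying the gap, and ``kind`` the inferred
    state relative to a reference row: ``"deletion"`` when the reference is
    ungapped at the run (the gapped samples lost the segment), ``"insertion"``
    when the reference itself is gapped (the ungapped samples carry extra
    sequence).
    """

    start: int
    length: int
    gapped: tuple[str, ...]
    kind: str

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class DiversityResult:
    """Nucleotide diversity pi (per site) for a sample set."""

    pi: float
    n_sequences: int
    sites_used: float


def _group_codes(aln: Alignment, samples: Iterable[str]) -> np.ndarray:
    sub = aln.subset(samples)
    return sub.codes


def segregating_sites(
    aln: Alignment,
    samples: Iterable[str] | None = None,
    gap_policy: str = "pairwise",
    groups: GroupAssignment | None = None,
) -> SiteCatalogue:
    """Columns with at least two distinct non-missing residues.

    ``gap_policy="pairwise"`` simply ignores missing states per column;
    ``"exclude_column"`` drops any column where some analysed row is missing.
    """
    sample_list = list(samples) if samples is not None else list(aln.ids)
    if len(sample_list) < 2:
        raise ArgumentError("need at least two samples for a site catalogue")
    sub = aln.subset(sample_list)
    codes = sub.codes
    valid = codes >= 0
    if gap_policy == "exclude_column":
        usable = valid.all(axis=0)
    elif gap_policy == "pairwise":
        usable = valid.any(axis=0)
    else:
        raise ArgumentError(f"unknown gap_policy {gap_policy!r}")

    positions: list[int] = []
    counts: dict[int, dict[str, dict[str, int]]] = {}
    n_cols = codes.shape[1]
    # A column segregates iff >= 2 distinct base codes among valid rows.
    masked = np.where(valid, codes, -1)
    for col in range(n_cols):
        if not usable[col]:
            continue
        vals = masked[:, col]
        present = np.unique(vals[vals >= 0])
        if present.size < 2:
            continue
        pos = col + 1
        positions.append(pos)
        per_group: dict[str, dict[str, int]] = {}
        for row_i, sid in enumerate(sub.ids):
            v = vals[row_i]
            if v < 0:
                continue
            g = groups.group_of(sid) if groups is not None else "all"
            per_group.setdefault(g, {}).setdefault(_BASES[v], 0)
            per_group[g][_BASES[v]] += 1
        counts[pos] = per_group
    return SiteCatalogue(positions, counts)


def fixed_differences(
    aln: Alignment,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> list[tuple[int, str, str]]:
    """Columns where the two groups are each monomorphic for different bases.

    Returns ``(position, allele_a, allele_b)`` triples.  Columns where either
    group carries no unambiguous base at all are skipped (unequal coverage
    must not produce artifact calls); missing states within a group do not
    break fixation as long as every observed base agrees.
    """
    a_ids, b_ids = list(group_a), list(group_b)
    if not a_ids or not b_ids:
        raise ArgumentError("both groups must be non-empty")
    if set(a_ids) & set(b_ids):
        raise ArgumentError("groups overlap")
    codes_a = _group_codes(aln, a_ids)
    codes_b = _group_codes(aln, b_ids)

    def mono(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        valid = codes >= 0
        any_valid = valid.any(axis=0)
        hi = np.where(valid, codes, -10).max(axis=0)
        lo = np.where(valid, codes, 10).min(axis=0)
        return any_valid & (hi == lo), hi

    mono_a, val_a = mono(codes_a)
    mono_b, val_b = mono(codes_b)
    fixed = mono_a & mono_b & (val_a != val_b)
    return [
        (int(col) + 1, _BASES[val_a[col]], _BASES[val_b[col]])
        for col in np.nonzero(fixed)[0]
    ]


def indel_events(aln: Alignment, reference_id: str) -> list[IndelEvent]:
    """Maximal contiguous gap runs with identical presence patterns.

    Adjacent gap columns belong to one event iff exactly the same samples are
    gapped at each; a change in the presence pattern starts a new event.  The
    event ``kind`` is read off the reference row: a gap run absent from the
    reference is a deletion in the gapped samples, a run present in the
    reference marks an insertion carried by the ungapped samples.
    """
    ref_idx = aln.index(reference_id)
    gaps = aln.codes == -2  # GAP
    n, length = gaps.shape
    events: list[IndelEvent] = []
    col = 0
    while col < length:
        pattern = gaps[:, col]
        if not pattern.any():
            col += 1
            continue
        start = col
        while col < length and (gaps[:, col] == pattern).all() and gaps[:, col].any():
            col += 1
        gapped = tuple(aln.ids[i] for i in np.nonzero(pattern)[0])
        kind = "insertion" if pattern[ref_idx] else "deletion"
        events.append(IndelEvent(start + 1, col - start, gapped, kind))
    return events


def fixed_indels(
    events: Sequence[IndelEvent],
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> list[IndelEvent]:
    """Events whose gap presence is uniform within each group and differs
    between the groups (fixed length polymorphisms)."""
    a_ids, b_ids = set(group_a), set(group_b)
    if not a_ids or not b_ids:
        raise ArgumentError("both groups must be non-empty")
    if a_ids & b_ids:
        raise ArgumentError("groups overlap")
    kept = []
    for ev in events:
        gapped = set(ev.gapped)
        in_a = a_ids & gapped
        in_b = b_ids & gapped
        uniform_a = in_a in (set(), a_ids)
        uniform_b = in_b in (set(), b_ids)
        if uniform_a and uniform_b and (bool(in_a) != bool(in_b)):
            kept.append(ev)
    return kept


def nucleotide_diversity(
    aln: Alignment,
    samples: Iterable[str] | None = None,
    gap_policy: str = "pairwise",
) -> DiversityResult:
    """Nucleotide diversity: mean over unordered pairs of the per-pair
    proportion of differing sites, sites compared pairwise-complete."""
    if gap_policy != "pairwise":
        raise ArgumentError("only pairwise gap handling is supported for pi")
    sample_list = list(samples) if samples is not None else list(aln.ids)
    if len(sample_list) < 2:
        raise ArgumentError("need at least two sequences for pi")
    sub = aln.subset(sample_list)
    ndiff, ncomp = diff_and_comparable(sub.codes)
    iu = np.triu_indices(sub.n, k=1)
    comp = ncomp[iu]
    if (comp == 0).any():
        i, j = [int(x[np.argmax(comp == 0)]) for x in iu]
        raise UndefinedPairError(
            f"pair ({sub.ids[i]}, {sub.ids[j]}) shares no comparable sites"
        )
    props = ndiff[iu] / comp
    return DiversityResult(
        pi=float(props.mean()),
        n_sequences=sub.n,
        sites_used=float(comp.mean()),
    )


def indel_table(events: Sequence[IndelEvent]) -> pd.DataFrame:
    """Indel events as a tidy table (mirrors the supplementary indel list)."""
    return pd.DataFrame.from_records(
        [
            {
                "start": ev.start,
                "end": ev.end,
                "length": ev.length,
                "kind": ev.kind,
                "gapped_samples": ",".join(ev.gapped),
            }
            for ev in events
        ],
        columns=["start", "end", "length", "kind", "gapped_samples"],
    )
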