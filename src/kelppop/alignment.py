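"""Alignments, partitions and group assignments.

The central container is :class:`Alignment`: an ordered set of equal-length
nucleotide rows over ``A C G T``, the alignment gap ``-`` and the IUPAC
ambiguity letters.  Coordinates are 1-based inclusive in every file, report
and public function signature, and 0-based half-open internally
(``start_internal = start_report - 1``).

Gaps and ambiguity codes are retained on read; downstream statistics treat
them as missing states (pairwise deletion), never as alleles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    ArgumentError,
    CoordinateError,
    DuplicateIdError,
    EmptyInputError,
    IdMismatchError,
)

# Integer codes used by the numeric kernels.  Bases are 0..3; GAP and MISSING
# are both "missing" for distance purposes but gaps must stay recognisable for
# the indel catalogue.
CODE_A, CODE_C, CODE_G, CODE_T = 0, 1, 2, 3
GAP = -2
MISSING = -1

_AMBIGUITY = set("RYSWKMBDHVN")
_BASE_CODES = {"A": CODE_A, "C": CODE_C, "G": CODE_G, "T": CODE_T, "U": CODE_T}

_ALLOWED = set("ACGTU-") | _AMBIGUITY

# Fast translation table: byte value -> int8 code.
_LUT = np.full(256, MISSING, dtype=np.int8)
for _ch, _code in _BASE_CODES.items():
    _LUT[ord(_ch)] = _code
_LUT[ord("-")] = GAP


def encode(row: str) -> np.ndarray:
    """Encode an upper-case residue string as an int8 vector."""
    return _LUT[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]


@dataclass
class Alignment:
    """An in-memory multiple sequence alignment.

    Parameters
    ----------
    ids
        Ordered, unique sequence identifiers.
    rows
        Equal-length residue strings; stored upper-case.
    """

    ids: list[str]
    rows: list[str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise EmptyInputError("alignment holds no sequences")
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate sequence ids: {dupes}")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"rows differ in length: {sorted(lengths)}"
            )
        if self.length < 1:
            raise AlignmentShapeError("alignment has zero columns")
        bad = set(itertools.chain.from_iterable(self.rows)) - _ALLOWED
        if bad:
            raise AlignmentShapeError(f"unexpected residue characters: {sorted(bad)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def codes(self) -> np.ndarray:
        """(n, length) int8 matrix; bases 0..3, gap -2, ambiguity/N -1."""
        if self._codes is None:
            self._codes = np.vstack([encode(r) for r in self.rows])
        return self._codes

    def row(self, seq_id: str) -> str:
        return self.rows[self.index(seq_id)]

    def index(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"sequence id not in alignment: {seq_id!r}") from None

    # -- derived alignments ---------------------------------------------
    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Rows for *ids*, in alignment order (not request order)."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        keep = [i for i, sid in enumerate(self.ids) if sid in wanted]
        return Alignment([self.ids[i] for i in keep], [self.rows[i] for i in keep])

    def slice(self, start: int, end: int) -> "Alignment":
        """Columns ``start..end`` (1-based inclusive) for all rows."""
        if not (1 <= start <= end <= self.length):
            raise CoordinateError(
                f"slice ({start}, {end}) outside [1, {self.length}]"
            )
        return Alignment(list(self.ids), [r[start - 1 : end] for r in self.rows])


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    All records must have equal length; identifiers must be unique; residues
    are upper-cased.  Raises :class:`EmptyInputError` on an empty file and
    :class:`AlignmentShapeError` on ragged rows.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError(f"duplicate ids in {path}")
    return Alignment(ids, [str(r.seq) for r in records])


def write_fasta_alignment(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    """Write *aln* as FASTA, wrapping sequence lines at *wrap* columns."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(records)


@dataclass
class PartitionMap:
    """Named, non-overlapping coordinate intervals over a concatenate.

    Entries are ``(name, start, end)`` with 1-based inclusive coordinates,
    the convention used in every file and report.
    """

    entries: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ArgumentError("partition names not unique")
        for name, start, end in self.entries:
            if not (1 <= start <= end):
                raise CoordinateError(f"partition {name}: bad interval ({start}, {end})")
        spans = sorted((s, e) for _, s, e in self.entries)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise CoordinateError("partition intervals overlap")

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.entries]

    def interval(self, name: str) -> tuple[int, int]:
        """1-based inclusive (start, end) of partition *name*."""
        for n, s, e in self.entries:
            if n == name:
                return s, e
        raise KeyError(f"no partition named {name!r}")

    def internal(self, name: str) -> tuple[int, int]:
        """0-based half-open (start, stop) of partition *name*."""
        s, e = self.interval(name)
        return s - 1, e

    @property
    def total_span(self) -> int:
        return max(e for _, _, e in self.entries)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PartitionMap":
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, start, end = line.split("\t")
            entries.append((name, int(start), int(end)))
        if not entries:
            raise EmptyInputError(f"no partitions in {path}")
        return cls(entries)

    def write_tsv(self, path: str | Path) -> None:
        lines = [f"{n}\t{s}\t{e}" for n, s, e in self.entries]
        Path(path).write_text("\n".join(lines) + "\n")


# Helper lineage sets used throughout the morphological-form analysis:
# the "TYP lineage" pools typical Saccharina japonica with its first-year
# (TYPF), adjacent (TYPA), no-midline (TYPW) and deep-water longipes (LON)
# samples; the "SHA lineage" pools the shallow-water form with the
# morphologically distinct but genetically identical CHE sample.
TYP_LINEAGE = frozenset({"TYP", "TYPF", "TYPA", "TYPW", "LON"})
SHA_LINEAGE = frozenset({"SHA", "CHE"})


@dataclass
class GroupAssignment:
    """Mapping of sample id to group label (e.g. TYP, LON, SHA, CHE)."""

    mapping: dict[str, str]

    def group_of(self, seq_id: str) -> str:
        return self.mapping[seq_id]

    def members(self, *groups: str) -> list[str]:
        """Ids labelled with any of *groups*, in insertion order."""
        want = set(groups)
        return [sid for sid, g in self.mapping.items() if g in want]

    def lineage_members(self, lineage: Iterable[str]) -> list[str]:
        return self.members(*lineage)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g)
        return list(seen)

    def check_covers(self, aln: Alignment) -> None:
        missing = [i for i in aln.ids if i not in self.mapping]
        if missing:
            raise ArgumentError(f"ids without a group label: {missing}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroupAssignment":
        mapping: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, group = line.split("\t")
            mapping[sid] = group
        if not mapping:
            raise EmptyInputError(f"no group assignments in {path}")
        return cls(mapping)

    def write_tsv(self, path: str | Path) -> None:
        lines = [f"{sid}\t{g}" for sid, g in self.mapping.items()]
        Path(path).write_text("\n".join(lines) + "\n")


def concatenate(
    alignments: Sequence[tuple[str, Alignment]],
    id_policy: str = "strict",
) -> tuple[Alignment, PartitionMap]:
    """Join per-gene alignments into one concatenate plus its partition map.

    Parameters
    ----------
    alignments
        Ordered ``(partition_name, Alignment)`` pairs; the order fixes the
        partition layout.
    id_policy
        ``"strict"`` requires identical id sets everywhere; ``"intersect"``
        keeps the ids shared by every alignment (at least one required).
    """
    if not alignments:
        raise EmptyInputError("nothing to concatenate")
    if id_policy not in ("strict", "intersect"):
        raise ArgumentError(f"unknown id_policy {id_policy!r}")

    id_sets = [set(a.ids) for _, a in alignments]
    first_order = alignments[0][1].ids
    if id_policy == "strict":
        for (name, _), ids in zip(alignments[1:], id_sets[1:]):
            if ids != id_sets[0]:
                raise IdMismatchError(
                    f"partition {name!r} id set differs under strict policy"
                )
        keep = list(first_order)
    else:
        shared = set.intersection(*id_sets)
        if not shared:
            raise IdMismatchError("no ids shared by all alignments")
        keep = [i for i in first_order if i in shared]

    rows = {sid: [] for sid in keep}
    entries = []
    offset = 0
    for name, aln in alignments:
        for sid in keep:
            rows[sid].append(aln.row(sid))
        entries.append((name, offset + 1, offset + aln.length))
        offset += aln.length
    concat = Alignment(keep, ["".join(rows[sid]) for sid in keep])
    return concat, PartitionMap(entries)


def slice_region(aln: Alignment, start: int, end: int) -> Alignment:
    """Columns ``start..end`` (1-based inclusive) of *aln*; id order kept."""
    return aln.slice(start, end)
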