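"""Aligned-MSA data model, FASTA I/O, and reference-coordinate mapping.

Alignment columns are 1-based throughout the package, as are reference
positions. Reference numbering is the ungapped coordinate system of one
designated row of the alignment (for eqolisins, the mature SCP-B chain);
hallmark positions such as the catalytic dyad Q53/E136 are expressed in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentShapeError, ContentError, IdentityError, IndexingError

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: 'X' is tolerated (low-quality gene models) but matches no conservation
#: group and no rule's allowed set.
ALLOWED_CHARS = frozenset(AA20) | {"X", GAP}


@dataclass(frozen=True)
class AlignedSequence:
    """One aligned row: id, free-text description, gapped residue string."""

    id: str
    description: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise IdentityError("sequence id must be non-empty")
        if not self.residues:
            raise ContentError(f"sequence {self.id!r} has no residues")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in ALLOWED_CHARS:
                raise ContentError(
                    f"sequence {self.id!r}: disallowed character {ch!r} at column {i}"
                )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


def _normalize(raw: str, seq_id: str) -> str:
    """Upper-case and map the '.' gap dialect onto '-'."""
    s = raw.upper()
    if "." in s:
        logger.info("sequence %s: normalizing '.' gaps to '-'", seq_id)
        s = s.replace(".", GAP)
    return s


@dataclass
class AlignmentMatrix:
    """An MSA: ordered rows of equal length, unique ids, 1-based columns."""

    sequences: list[AlignedSequence]
    _array: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise AlignmentShapeError("an alignment needs at least 2 sequences")
        n = len(self.sequences[0].residues)
        seen: set[str] = set()
        for rec in self.sequences:
            if len(rec.residues) != n:
                raise AlignmentShapeError(
                    f"record {rec.id!r} has length {len(rec.residues)}, expected {n}"
                )
            if rec.id in seen:
                raise IdentityError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def n_cols(self) -> int:
        return len(self.sequences[0].residues)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def array(self) -> np.ndarray:
        """(n_rows, n_cols) array of single characters (cached)."""
        if self._array is None:
            self._array = np.array(
                [list(s.residues) for s in self.sequences], dtype="<U1"
            )
        return self._array

    def row(self, seq_id: str) -> AlignedSequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise IdentityError(f"sequence id {seq_id!r} not present in alignment")

    def column(self, col: int) -> str:
        """Residues of one 1-based column, top to bottom."""
        self.check_col(col)
        return "".join(s.residues[col - 1] for s in self.sequences)

    def check_col(self, col: int) -> None:
        if not isinstance(col, (int, np.integer)) or col < 1 or col > self.n_cols:
            raise IndexingError(
                f"column index {col!r} out of range 1..{self.n_cols} (1-based)"
            )

    def subset(self, ids: list[str]) -> "AlignmentMatrix":
        """Row subset in the given order."""
        by_id = {s.id: s for s in self.sequences}
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise IdentityError(f"ids not in alignment: {missing}")
        return AlignmentMatrix([by_id[i] for i in ids])

    def __eq__(self, other) -> bool:
        if not isinstance(other, AlignmentMatrix):
            return NotImplemented
        return self.sequences == other.sequences

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.sequences)


def read_fasta(path: str | Path) -> AlignmentMatrix:
    """Read an aligned (gapped) FASTA file.

    Input is case-insensitive; '.' gaps are normalized to '-'. Unequal record
    lengths, duplicate ids and disallowed characters are rejected with the
    offending record named.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            AlignedSequence(
                id=rec.id,
                description=rec.description[len(rec.id):].strip(),
                residues=_normalize(str(rec.seq), rec.id),
            )
        )
    if not records:
        raise AlignmentShapeError(f"no FASTA records found in {path}")
    return AlignmentMatrix(records)


def write_fasta(msa: AlignmentMatrix, path: str | Path) -> None:
    """Write the alignment; round-trips through :func:`read_fasta`."""
    recs = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in msa.sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


@dataclass(frozen=True)
class ReferenceMap:
    """Bijection between mapped alignment columns and reference positions.

    The k-th non-gap residue of the reference row maps to reference position
    k; columns where the reference row has a gap are unmapped.
    """

    ref_id: str
    col_to_ref: dict[int, int]
    ref_to_col: dict[int, int]

    def col_of(self, ref_pos: int) -> int:
        if ref_pos < 1:
            raise IndexingError(f"reference positions are 1-based, got {ref_pos}")
        if ref_pos not in self.ref_to_col:
            raise IndexingError(
                f"reference position {ref_pos} beyond ungapped length "
                f"{len(self.ref_to_col)} of {self.ref_id!r}"
            )
        return self.ref_to_col[ref_pos]

    def ref_of(self, col: int) -> int | None:
        """Reference position of a column, or None where the reference is gapped."""
        if col < 1:
            raise IndexingError(f"columns are 1-based, got {col}")
        return self.col_to_ref.get(col)


def map_reference(msa: AlignmentMatrix, ref_id: str) -> ReferenceMap:
    """Build the column <-> reference-position map from one row of the MSA."""
    row = msa.row(ref_id)  # raises IdentityError if absent
    col_to_ref: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(row.residues, start=1):
        if ch != GAP:
            k += 1
            col_to_ref[col] = k
    ref_to_col = {r: c for c, r in col_to_ref.items()}
    return ReferenceMap(ref_id=ref_id, col_to_ref=col_to_ref, ref_to_col=ref_to_col)
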