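"""Alignment input/output and the reference coordinate system.

Alignments are read with Biopython (aligned FASTA, Clustal, Stockholm) and
normalized into a light :class:`MSA` container: residues upper-cased, ``.``
gaps rewritten to ``-``, alphabet and shape validated up front so downstream
code never re-checks.  Internally alignment columns are 0-based; everything a
user sees (mutation notation, masks, reports) is 1-based on the ungapped
reference, which :class:`ReferenceMapping` mediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO

from .errors import (
    AlphabetError,
    DuplicateIdError,
    RaggedAlignmentError,
    UnknownReferenceError,
)

logger = logging.getLogger(__name__)

#: the 20 standard amino acids, alphabetical
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguity / non-standard codes accepted on input but never counted
AMBIGUITY_CODES: frozenset[str] = frozenset("BZXUO")
GAP: str = "-"

_ALLOWED = frozenset(AMINO_ACIDS) | AMBIGUITY_CODES | {GAP}

#: formats understood by :func:`read_alignment`
FORMATS = ("aligned-fasta", "clustal", "stockholm")

# Biopython format names for the non-FASTA formats
_BIO_FORMAT = {"clustal": "clustal", "stockholm": "stockholm"}


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned (or ungapped) protein sequence with its identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise AlphabetError("sequence record has an empty id")
        if not self.residues:
            raise AlphabetError(f"record {self.id!r} has an empty sequence")

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class MSA:
    """A validated multiple sequence alignment.

    Invariants enforced on construction: at least two records, all of equal
    length, unique ids, residues drawn from the 20 standard amino acids plus
    gap ``-`` and the ambiguity codes B/Z/X/U/O.
    """

    records: tuple[SequenceRecord, ...]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise RaggedAlignmentError(
                f"an alignment needs at least 2 records, got {len(self.records)}"
            )
        length = len(self.records[0].residues)
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            if len(rec.residues) != length:
                raise RaggedAlignmentError(
                    f"record {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {length} (ragged alignment)"
                )
            for pos, ch in enumerate(rec.residues):
                if ch not in _ALLOWED:
                    raise AlphabetError(
                        f"record {rec.id!r}: illegal character {ch!r} at "
                        f"column {pos + 1}"
                    )
        object.__setattr__(self, "n_columns", length)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise UnknownReferenceError(
            f"no record named {record_id!r} in the alignment "
            f"(ids: {', '.join(self.ids()[:5])}{'...' if len(self) > 5 else ''})"
        )

    def column(self, index: int) -> str:
        """All residues of alignment column *index* (0-based), top to bottom."""
        return "".join(rec.residues[index] for rec in self.records)


@dataclass(frozen=True)
class ReferenceMapping:
    """Map between alignment columns and ungapped reference numbering.

    ``column_to_residue`` covers exactly the columns where the reference row
    is not a gap, sending 0-based column index to 1-based residue number;
    its image is exactly ``1..ref_length``.
    """

    ref_id: str
    column_to_residue: dict[int, int]
    ref_length: int

    def residue_to_column(self) -> dict[int, int]:
        """Inverse map, 1-based residue number -> 0-based column."""
        return {r: c for c, r in self.column_to_residue.items()}


def _normalize(raw: str, record_id: str) -> str:
    """Upper-case and canonicalize gaps; log if lower-case was present."""
    if raw != raw.upper():
        logger.info("record %r: lower-case residues up-cased", record_id)
    return raw.upper().replace(".", GAP)


def _build_msa(pairs: Iterable[tuple[str, str]]) -> MSA:
    records = tuple(
        SequenceRecord(id=rid, residues=_normalize(seq, rid)) for rid, seq in pairs
    )
    return MSA(records=records)


def read_alignment(path: str | Path, format: str = "aligned-fasta") -> MSA:
    """Read an alignment file and return a validated :class:`MSA`.

    Parameters
    ----------
    path:
        File in the given format.
    format:
        One of ``aligned-fasta``, ``clustal``, ``stockholm``.  ``fasta`` is
        accepted as an alias for ``aligned-fasta``.
    """
    fmt = "aligned-fasta" if format == "fasta" else format
    if fmt not in FORMATS:
        raise ValueError(f"unknown alignment format {format!r}; choose from {FORMATS}")
    path = Path(path)
    if fmt == "aligned-fasta":
        # SeqIO rather than AlignIO so ragged files are reported with the
        # offending record id instead of a generic parser error
        pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        alignment = AlignIO.read(str(path), _BIO_FORMAT[fmt])
        pairs = [(rec.id, str(rec.seq)) for rec in alignment]
    if not pairs:
        raise RaggedAlignmentError(f"{path}: no sequences found")
    return _build_msa(pairs)


def write_alignment(msa: MSA, path: str | Path) -> None:
    """Write an MSA as aligned FASTA, 60 residues per line, ``-`` gaps."""
    with open(path, "w") as fh:
        for rec in msa.records:
            fh.write(f">{rec.id}\n")
            for start in range(0, len(rec.residues), 60):
                fh.write(rec.residues[start : start + 60] + "\n")


def map_reference(msa: MSA, ref_id: str) -> ReferenceMapping:
    """Build the column/residue-number mapping for the reference row."""
    ref = msa.get(ref_id)
    column_to_residue: dict[int, int] = {}
    residue_number = 0
    for col, ch in enumerate(ref.residues):
        if ch != GAP:
            residue_number += 1
            column_to_residue[col] = residue_number
    return ReferenceMapping(
        ref_id=ref_id, column_to_residue=column_to_residue, ref_length=residue_number
    )
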