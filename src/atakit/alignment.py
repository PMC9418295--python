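"""Aligned sequence sets and reference-anchored position maps.

A multiple sequence alignment (MSA) is consumed as an aligned FASTA file.  A
:class:`PositionMap` anchors a *unified* residue numbering — a structure-based
numbering shared across a protein superfamily — onto alignment columns via a
single reference sequence whose unified numbering is known.  Homologs of
different lengths can then be compared position-by-position by reading the
anchored columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, MappingError

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues tolerated in an alignment: the 20 amino acids, gap, and X (unknown)
ALIGNMENT_ALPHABET = frozenset(AMINO_ACIDS) | {GAP, "X"}


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An ordered set of equal-length gapped protein sequences.

    Parameters
    ----------
    records:
        Ordered ``(id, gapped_sequence)`` pairs.  Sequence ids must be unique
        and all gapped sequences must have the same length.
    gap_char:
        Gap character, ``"-"`` by default.
    """

    records: tuple[tuple[str, str], ...]
    gap_char: str = GAP

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple((i, s.upper()) for i, s in self.records))
        if not self.records:
            raise FormatError("alignment contains no sequences")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dupes}")
        allowed = ALIGNMENT_ALPHABET | {self.gap_char}
        for sid, seq in self.records:
            bad = set(seq) - allowed
            if bad:
                raise FormatError(f"sequence {sid!r} contains invalid characters {sorted(bad)}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.records)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0][1])

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sequence_id: str) -> str:
        for sid, seq in self.records:
            if sid == sequence_id:
                return seq
        raise KeyError(sequence_id)

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self.ids

    def ungapped(self, sequence_id: str) -> str:
        """Sequence with gap characters removed."""
        return self[sequence_id].replace(self.gap_char, "")


def read_alignment(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned FASTA file.

    Raises
    ------
    FormatError
        If sequences have unequal lengths, ids repeat, or the file is empty.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return AlignedSequenceSet(tuple(records))


def write_alignment(aln: AlignedSequenceSet, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (gap character kept)."""
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records]
    SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class PositionMap:
    """Anchor of unified numbering onto alignment columns.

    ``unified_to_column`` maps each unified position to the 0-based alignment
    column that holds the reference's anchor residue; ``anchor_offsets`` keeps
    the original 0-based *ungapped* reference indices the map was built from.
    ``validation_warnings`` records anchor residues that disagreed with the
    reference's library fingerprint (drift guard); it is empty when validation
    passed or was not requested.
    """

    reference_id: str
    unified_to_column: Mapping[int, int]
    anchor_offsets: Mapping[int, int]
    validation_warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        cols = list(self.unified_to_column.values())
        if len(set(cols)) != len(cols):
            raise MappingError("unified positions map to duplicate alignment columns")

    def column(self, unified_position: int) -> int:
        try:
            return self.unified_to_column[unified_position]
        except KeyError:
            raise MappingError(f"unified position {unified_position} is not mapped") from None


def build_position_map(
    aln: AlignedSequenceSet,
    reference_id: str,
    anchors: Mapping[int, int],
    expected_reference_residues: Mapping[int, str] | None = None,
) -> PositionMap:
    """Map unified positions to alignment columns through a reference sequence.

    Parameters
    ----------
    aln:
        The alignment holding the reference.
    reference_id:
        Id of the sequence whose unified numbering is known.
    anchors:
        ``unified position -> 0-based ungapped reference index``.
    expected_reference_residues:
        Optional ``unified position -> residue`` check (typically the
        reference's known fingerprint).  Disagreement does not fail the build;
        it raises a :class:`UserWarning` and is recorded on the map, since a
        shifted anchor table is a data-curation bug worth surfacing loudly.

    Raises
    ------
    MappingError
        If the reference is absent or an anchor lies beyond its ungapped length.
    """
    if reference_id not in aln:
        raise MappingError(f"reference {reference_id!r} not in alignment")
    gapped = aln[reference_id]
    # column index for each ungapped reference position
    ungapped_to_col = [c for c, ch in enumerate(gapped) if ch != aln.gap_char]
    n = len(ungapped_to_col)
    unified_to_column: dict[int, int] = {}
    for pos, idx in sorted(anchors.items()):
        if not 0 <= idx < n:
            raise MappingError(
                f"anchor for unified position {pos} is ungapped index {idx}, "
                f"but reference {reference_id!r} has only {n} residues"
            )
        unified_to_column[pos] = ungapped_to_col[idx]

    notes: list[str] = []
    if expected_reference_residues is not None:
        for pos, expected in sorted(expected_reference_residues.items()):
            if pos not in unified_to_column:
                continue
            found = gapped[unified_to_column[pos]]
            if found != expected.upper():
                msg = (
                    f"anchor validation: reference {reference_id!r} shows {found!r} at "
                    f"unified position {pos}, expected {expected!r}"
                )
                notes.append(msg)
                warnings.warn(msg, UserWarning, stacklevel=2)
    return PositionMap(
        reference_id=reference_id,
        unified_to_column=unified_to_column,
        anchor_offsets=dict(sorted(anchors.items())),
        validation_warnings=tuple(notes),
    )
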