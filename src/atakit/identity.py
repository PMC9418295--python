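"""Pairwise percent identity from a multiple sequence alignment.

Percent identity depends on the denominator convention, which published
alignments rarely state.  Three are offered:

``both_ungapped`` (default)
    Identical residue pairs / columns where *both* sequences are ungapped.
``alignment_length``
    Identical residue pairs / total alignment columns.
``shorter_ungapped``
    Identical residue pairs / ungapped length of the shorter sequence.

``X`` never counts as a match.  Values are percentages rounded to one
decimal, matching how identity matrices are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AlignedSequenceSet
from .errors import AtakitError

CONVENTIONS = ("both_ungapped", "alignment_length", "shorter_ungapped")


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix with its convention label."""

    ids: tuple[str, ...]
    percent_identity: np.ndarray  # shape (n, n), NaN where undefined
    convention: str

    def __post_init__(self) -> None:
        m = self.percent_identity
        n = len(self.ids)
        if m.shape != (n, n):
            raise AtakitError("identity matrix shape does not match ids")

    def value(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.percent_identity[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.percent_identity, index=self.ids, columns=self.ids)


def percent_identity_pair(
    seq_a: str, seq_b: str, convention: str = "both_ungapped", gap_char: str = "-"
) -> float:
    """Percent identity of two equal-length gapped sequences.

    Returns NaN (``both_ungapped``) when the two sequences share no ungapped
    column, leaving the pair explicitly undefined rather than 0.
    """
    if convention not in CONVENTIONS:
        raise AtakitError(f"unknown identity convention {convention!r}; choose from {CONVENTIONS}")
    if len(seq_a) != len(seq_b):
        raise AtakitError("sequences must come from one alignment (equal lengths)")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    gap = gap_char.encode()
    both = (a != gap) & (b != gap)
    matches = int(np.sum((a == b) & both & (a != b"X")))
    if convention == "both_ungapped":
        denom = int(both.sum())
        if denom == 0:
            return float("nan")
    elif convention == "alignment_length":
        denom = len(seq_a)
    else:  # shorter_ungapped
        denom = min(int((a != gap).sum()), int((b != gap).sum()))
        if denom == 0:
            return float("nan")
    return round(100.0 * matches / denom, 1)


def pairwise_identity(
    aln: AlignedSequenceSet, convention: str = "both_ungapped"
) -> IdentityMatrix:
    """All-vs-all percent identity under the named convention.

    The matrix is symmetric with a diagonal of 100 and is invariant under
    record reordering (up to the same permutation).  Undefined pairs (no
    shared ungapped column) are NaN.
    """
    if len(aln) < 2:
        raise AtakitError("pairwise identity needs at least 2 sequences")
    ids = aln.ids
    n = len(ids)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = percent_identity_pair(
                aln.records[i][1], aln.records[j][1], convention, aln.gap_char
            )
            m[i, j] = m[j, i] = v
    return IdentityMatrix(ids=ids, percent_identity=m, convention=convention)
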