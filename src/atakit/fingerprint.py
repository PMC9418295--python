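"""Active-site fingerprints: extraction, library comparison, trait rules.

The *active-site fingerprint* of a PLP fold-type I transaminase is the tuple
of residues found at a handful of structurally aligned (unified-numbered)
active-site positions.  For the amine-transaminase superfamily the canonical
seven positions are 16, 47, 129, 145, 185, 346 and 348.  Known reference
fingerprints (e.g. the highly active amine transaminases ``FWYMARV`` /
``FWYNARL``, the beta-alanine:pyruvate subfamily parent ``MWYRGGN``) let a new
sequence's likely substrate scope be read off its fingerprint:

* an arginine at 346 is the "flipping arginine" that lets typical amine
  transaminases accept carboxylate co-substrates;
* the beta-alanine:pyruvate subfamily instead coordinates carboxylate
  substrates via R145;
* an extra arginine at the remote position 16 suggests affinity for substrates
  with a distal carboxylate (omega-amino acids);
* high amine activity tracks with an aromatic W/Y at 47 plus a small A/G at
  185 (together with R346), while hydrophilic S/T at 185 and non-aromatic
  residues at 47 mark low-activity enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import AlignedSequenceSet, PositionMap
from .errors import AtakitError, MappingError

#: canonical unified active-site positions
DEFAULT_POSITIONS = (16, 47, 129, 145, 185, 346, 348)

#: residues counted as aromatic at position 47
AROMATIC_47 = frozenset("WYF")
#: residues counted as hydrophilic at position 185
HYDROPHILIC_185 = frozenset("ST")

GAP = "-"
UNDETERMINED = "X"


@dataclass(frozen=True)
class FingerprintSchema:
    """The ordered unified positions a fingerprint is read at."""

    positions: tuple[int, ...] = DEFAULT_POSITIONS

    def __post_init__(self) -> None:
        if not self.positions:
            raise AtakitError("fingerprint schema must be nonempty")
        if list(self.positions) != sorted(set(self.positions)):
            raise AtakitError("fingerprint schema positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


DEFAULT_SCHEMA = FingerprintSchema()


@dataclass(frozen=True)
class Fingerprint:
    """Residues one sequence shows at the schema positions.

    A gap at a mapped column is kept as ``-`` (flagged through
    :attr:`gap_positions`), never silently dropped.
    """

    sequence_id: str
    residues: tuple[str, ...]
    schema: FingerprintSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(r.upper() for r in self.residues))
        if len(self.residues) != len(self.schema):
            raise AtakitError(
                f"fingerprint {self.sequence_id!r} has {len(self.residues)} residues "
                f"for a {len(self.schema)}-position schema"
            )

    @classmethod
    def from_string(
        cls, sequence_id: str, residues: str, schema: FingerprintSchema = DEFAULT_SCHEMA
    ) -> "Fingerprint":
        return cls(sequence_id, tuple(residues), schema)

    def __str__(self) -> str:
        return "".join(self.residues)

    @property
    def gap_positions(self) -> tuple[int, ...]:
        """Unified positions where the sequence is gapped."""
        return tuple(p for p, r in zip(self.schema.positions, self.residues) if r == GAP)

    def residue_at(self, unified_position: int) -> str:
        try:
            i = self.schema.positions.index(unified_position)
        except ValueError:
            raise MappingError(f"position {unified_position} not in schema") from None
        return self.residues[i]


@dataclass(frozen=True)
class LibraryEntry:
    id: str
    fingerprint: Fingerprint
    annotation: str = ""
    activity_class: str = ""
    role: str = "reference"


@dataclass(frozen=True)
class FingerprintLibrary:
    """Known fingerprints to compare new sequences against.

    The default library ships as an editable TSV
    (``atakit/data/reference_library.tsv``) holding the five characterized
    reference enzymes plus the ten investigated subfamily members.
    """

    entries: tuple[LibraryEntry, ...]
    schema: FingerprintSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise AtakitError("library ids must be unique")
        for e in self.entries:
            if e.fingerprint.schema != self.schema:
                raise AtakitError(f"library entry {e.id!r} uses a different schema")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, entry_id: str) -> LibraryEntry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)

    def subset(self, roles: Iterable[str]) -> "FingerprintLibrary":
        roles = set(roles)
        return FingerprintLibrary(
            tuple(e for e in self.entries if e.role in roles), self.schema
        )

    def fingerprints(self) -> dict[str, str]:
        return {e.id: str(e.fingerprint) for e in self.entries}


def load_library(path: str | Path | None = None) -> FingerprintLibrary:
    """Load a fingerprint library from TSV (columns: id, fingerprint, role,
    activity_class, annotation).  With no path, the bundled default library is
    loaded."""
    if path is None:
        source = resources.files("atakit.data").joinpath("reference_library.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = tuple(
        LibraryEntry(
            id=row["id"],
            fingerprint=Fingerprint.from_string(row["id"], row["fingerprint"]),
            annotation=row.get("annotation", ""),
            activity_class=row.get("activity_class", ""),
            role=row.get("role", "reference"),
        )
        for _, row in df.iterrows()
    )
    return FingerprintLibrary(entries)


def default_anchors(schema: FingerprintSchema = DEFAULT_SCHEMA) -> dict[int, int]:
    """Anchor table for a reference whose ungapped numbering *is* the unified
    numbering (unified position p at 0-based ungapped index p-1).

    This is how the bundled synthetic alignments are built; for a real
    reference the curated anchor table must be supplied instead.
    """
    return {p: p - 1 for p in schema.positions}


def extract_fingerprint(
    aln: AlignedSequenceSet,
    position_map: PositionMap,
    sequence_id: str,
    schema: FingerprintSchema = DEFAULT_SCHEMA,
) -> Fingerprint:
    """Read one sequence's residues at the mapped schema positions.

    Raises
    ------
    MappingError
        If a schema position is missing from the map.
    KeyError
        If the sequence is not in the alignment.
    """
    seq = aln[sequence_id]
    residues = []
    for pos in schema.positions:
        col = position_map.column(pos)
        residues.append(seq[col])
    return Fingerprint(sequence_id, tuple(residues), schema)


def extract_all_fingerprints(
    aln: AlignedSequenceSet,
    position_map: PositionMap,
    schema: FingerprintSchema = DEFAULT_SCHEMA,
) -> dict[str, Fingerprint]:
    """Fingerprints for every sequence in the alignment, in record order."""
    return {sid: extract_fingerprint(aln, position_map, sid, schema) for sid in aln.ids}


@dataclass(frozen=True)
class Match:
    """Comparison of a query fingerprint against one library entry."""

    library_id: str
    mismatches: int
    mismatch_positions: tuple[int, ...]


def compare_fingerprints(fp: Fingerprint, library: FingerprintLibrary) -> tuple[Match, ...]:
    """Hamming-compare a fingerprint against every library entry.

    Gap or ``X`` slots on either side count as mismatches (the residue is not
    demonstrably identical).  Matches are ranked ascending by mismatch count;
    ties keep library order (stable sort).
    """
    if fp.schema != library.schema:
        raise AtakitError("fingerprint and library use different schemas")
    matches = []
    for entry in library:
        mm = tuple(
            pos
            for pos, (a, b) in zip(fp.schema.positions, zip(fp.residues, entry.fingerprint.residues))
            if a != b or a in (GAP, UNDETERMINED)
        )
        matches.append(Match(entry.id, len(mm), mm))
    return tuple(sorted(matches, key=lambda m: m.mismatches))


#: trait flag names, in report order
TRAIT_FLAGS = (
    "flipping_arginine_346",
    "carboxylate_R145",
    "distal_carboxylate_R16",
    "high_amine_activity_motif",
    "hydrophilic_185_low_activity",
    "nonaromatic_47_reduced_activity",
)


@dataclass(frozen=True)
class TraitPrediction:
    """Rule-based functional annotation of one fingerprint.

    ``flags`` holds the triggered trait names; ``undetermined`` holds rules
    that could not be evaluated because a required position is gapped or X.
    Every flag carries its provenance: the position/residue observation that
    triggered it.
    """

    sequence_id: str
    flags: frozenset[str]
    rule_provenance: Mapping[str, str]
    nearest_library_matches: tuple[Match, ...]
    undetermined: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = self.flags - set(self.rule_provenance)
        if missing:
            raise AtakitError(f"flags without provenance: {sorted(missing)}")


def _known(residue: str) -> bool:
    return residue not in (GAP, UNDETERMINED)


def predict_traits(fp: Fingerprint, library: FingerprintLibrary) -> TraitPrediction:
    """Apply the residue -> trait rules to one fingerprint.

    Rules (all on the default 7-position schema):

    * ``flipping_arginine_346``      — R at 346
    * ``carboxylate_R145``           — R at 145
    * ``distal_carboxylate_R16``     — R at 16
    * ``high_amine_activity_motif``  — (W or Y) at 47 AND (A or G) at 185 AND R at 346
    * ``hydrophilic_185_low_activity`` — S or T at 185
    * ``nonaromatic_47_reduced_activity`` — residue at 47 outside {W, Y, F}

    A gap or ``X`` at a rule position makes that rule *undetermined*, not
    false.
    """
    for pos in (16, 47, 145, 185, 346):
        if pos not in fp.schema.positions:
            raise MappingError(f"trait rules need unified position {pos} in the schema")

    r16 = fp.residue_at(16)
    r47 = fp.residue_at(47)
    r145 = fp.residue_at(145)
    r185 = fp.residue_at(185)
    r346 = fp.residue_at(346)

    flags: set[str] = set()
    undetermined: set[str] = set()
    provenance: dict[str, str] = {}

    def simple_rule(flag: str, pos: int, residue: str, hit: bool) -> None:
        if not _known(residue):
            undetermined.add(flag)
        elif hit:
            flags.add(flag)
            provenance[flag] = f"{residue}@{pos}"

    simple_rule("flipping_arginine_346", 346, r346, r346 == "R")
    simple_rule("carboxylate_R145", 145, r145, r145 == "R")
    simple_rule("distal_carboxylate_R16", 16, r16, r16 == "R")
    simple_rule("hydrophilic_185_low_activity", 185, r185, r185 in HYDROPHILIC_185)
    simple_rule("nonaromatic_47_reduced_activity", 47, r47, r47 not in AROMATIC_47)

    if not (_known(r47) and _known(r185) and _known(r346)):
        undetermined.add("high_amine_activity_motif")
    elif r47 in "WY" and r185 in "AG" and r346 == "R":
        flags.add("high_amine_activity_motif")
        provenance["high_amine_activity_motif"] = f"{r47}@47+{r185}@185+{r346}@346"

    return TraitPrediction(
        sequence_id=fp.sequence_id,
        flags=frozenset(flags),
        rule_provenance=provenance,
        nearest_library_matches=compare_fingerprints(fp, library),
        undetermined=frozenset(undetermined),
    )


def fingerprint_report(
    fingerprints: Mapping[str, Fingerprint], library: FingerprintLibrary
) -> pd.DataFrame:
    """Tabular fingerprint + trait report (one row per sequence).

    Columns: id, pos<16..348>, flags, best_match, mismatches.
    """
    rows = []
    for sid, fp in fingerprints.items():
        pred = predict_traits(fp, library)
        best = pred.nearest_library_matches[0]
        row: dict[str, object] = {"id": sid}
        for pos, res in zip(fp.schema.positions, fp.residues):
            row[f"pos{pos}"] = res
        row["flags"] = ";".join(f for f in TRAIT_FLAGS if f in pred.flags)
        row["best_match"] = best.library_id
        row["mismatches"] = best.mismatches
        rows.append(row)
    return pd.DataFrame(rows)
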