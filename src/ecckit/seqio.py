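"""Sequence and table I/O with the coordinate conventions used package-wide.

Residue coordinates are 1-based with the initiator Met at position 1, so
literature residue labels (Gly-2, C21, G158, ...) map directly onto record
positions.  Segments are 1-based *inclusive* ``[start, end]``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

#: per-species ordinal response scales: 0 = no response; the top category in
#: Arabidopsis (6) is full resistance, in N. benthamiana / lettuce it is 3.
PHENOTYPE_SCALES = {"At": (0, 6), "Nb": (0, 3), "Ls": (0, 3)}


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class ResidueError(ValueError):
    """A residue outside the 20-letter amino-acid alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence (typically an ECC fragment).

    ``residues`` must use the unambiguous 20-letter alphabet; ambiguity
    codes (B/J/O/U/X/Z) are rejected so every downstream scanner can assume
    a clean alphabet.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        validate_residues(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Residues in the 1-based inclusive segment [start, end]."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(
                f"segment [{start}, {end}] outside sequence {self.id!r} "
                f"of length {len(self.residues)}"
            )
        return self.residues[start - 1 : end]


def validate_residues(residues: str, record_id: str = "?") -> None:
    if not residues:
        raise ResidueError(f"record {record_id!r}: empty sequence")
    for pos, aa in enumerate(residues, start=1):
        if aa not in AA_ALPHABET:
            raise ResidueError(
                f"record {record_id!r}: illegal residue {aa!r} at position {pos}"
            )


@dataclass(frozen=True)
class AlignedBlock:
    """A gapped alignment block; rows use '-' as the only gap character."""

    ids: tuple
    rows: tuple

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if not self.rows:
            raise ValueError("alignment block is empty")
        ncol = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise ValueError(f"row {rid!r} has length {len(row)}, expected {ncol}")
            for pos, ch in enumerate(row, start=1):
                if ch != GAP and ch not in AA_ALPHABET:
                    raise ValueError(
                        f"row {rid!r}: illegal alignment character {ch!r} at column {pos}"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def ungapped(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)].replace(GAP, "")


@dataclass(frozen=True)
class PhenotypeRecord:
    """Ordinal plant-response category for one ECC in one species."""

    ecc_id: str
    species: str
    category: int

    def __post_init__(self) -> None:
        if self.species not in PHENOTYPE_SCALES:
            raise ValueError(
                f"unknown species {self.species!r}; expected one of "
                f"{sorted(PHENOTYPE_SCALES)}"
            )
        lo, hi = PHENOTYPE_SCALES[self.species]
        if not (lo <= self.category <= hi):
            raise ValueError(
                f"category {self.category} out of range [{lo}, {hi}] for "
                f"species {self.species!r} (ecc {self.ecc_id!r})"
            )


def read_fasta(path) -> list:
    """Read a protein FASTA file into validated :class:`SequenceRecord` s.

    The header token before the first whitespace becomes the id; order is
    preserved; duplicate ids and illegal residues raise.
    """
    with open(path, "r", encoding="utf-8") as handle:
        text = handle.read()
    if text.strip() and not text.lstrip().startswith(">"):
        first = text.strip().splitlines()[0]
        raise FastaParseError(f"not FASTA: first line {first!r} does not start with '>'")
    records = []
    seen = set()
    for bio in SeqIO.parse(io.StringIO(text), "fasta"):
        desc = bio.description[len(bio.id) :].strip() if bio.description else ""
        rec = SequenceRecord(id=bio.id, residues=str(bio.seq).upper(), description=desc)
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA with ``width``-column wrapping (round-trips)."""
    bio_records = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio_records)


def read_phenotypes(path) -> list:
    """Read a phenotype TSV with columns ecc_id, species, category."""
    df = pd.read_csv(path, sep="\t", dtype={"ecc_id": str, "species": str})
    required = {"ecc_id", "species", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    dups = df.duplicated(subset=["ecc_id", "species"])
    if dups.any():
        first = df[dups].iloc[0]
        raise ValueError(
            f"duplicate phenotype record for ({first['ecc_id']!r}, {first['species']!r})"
        )
    return [
        PhenotypeRecord(ecc_id=row.ecc_id, species=row.species, category=int(row.category))
        for row in df.itertuples()
    ]


def write_phenotypes(records, path) -> None:
    df = pd.DataFrame(
        {
            "ecc_id": [r.ecc_id for r in records],
            "species": [r.species for r in records],
            "category": [r.category for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
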