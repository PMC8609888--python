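"""Protein sequence records and FASTA / sample-sheet I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with a species label.

    ``residues`` uses the 20-letter amino-acid alphabet plus ``X``; gap
    characters are rejected.
    """

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"{self.id}: residues must be non-empty")
        bad = set(self.residues.upper()) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: invalid residue characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


def _check_unique(records: list[SequenceRecord]) -> list[SequenceRecord]:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


def read_fasta(path: str | Path, sample_sheet: str | Path | None = None) -> list[SequenceRecord]:
    """Read protein FASTA into :class:`SequenceRecord` objects.

    Species labels come from a ``species=<name>`` token in the header
    description, or from an (id, species) TSV sample sheet, which takes
    precedence.
    """
    species_map: dict[str, str] = {}
    if sample_sheet is not None:
        species_map = read_sample_sheet(sample_sheet)
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        species = ""
        for token in bio.description.split()[1:]:
            if token.startswith("species="):
                species = token[len("species="):]
        species = species_map.get(bio.id, species)
        records.append(SequenceRecord(id=bio.id, residues=str(bio.seq), species=species))
    return _check_unique(records)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(
            Seq(r.residues),
            id=r.id,
            description=f"species={r.species}" if r.species else "",
        )
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Parse a two-column (id, species) TSV; a header line is optional."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"sample sheet line lacks two columns: {line!r}")
            if parts[0].lower() in {"id", "seq_id"}:
                continue
            mapping[parts[0]] = parts[1]
    return mapping
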