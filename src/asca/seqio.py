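"""FASTA input/output and family-set assembly.

A family analysis starts from one or more FASTA files of homologous protein
sequences (for the motivating use case: fungal vanillyl alcohol oxidases plus
bacterial eugenol oxidases).  This module reads and writes those files,
validates the residue alphabet, and merges several retrieval sets into one
deduplicated family set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

# 20 canonical amino acids plus X as ambiguity.  B/J/O/U/Z are rejected so
# that substitution-matrix lookups and fingerprint comparisons stay defined.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """One unaligned protein sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header,
    ``description`` the remainder (may be empty).  ``residues`` is upper-case
    and gap-free.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch == GAP:
                raise ValueError(
                    f"record {self.id!r}: gap character at position {pos} "
                    "(unaligned records must be gap-free)"
                )
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Residues are upper-cased; CR/LF and internal whitespace are stripped.
    Raises ``ValueError`` on an empty file, a duplicated id, or an illegal
    residue character.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        # rec.description includes the id; keep only the remainder
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        residues = "".join(str(rec.seq).split()).upper()
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as plain FASTA, sequence lines wrapped at ``width``."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def merge_and_deduplicate(
    sets: Sequence[Sequence[SequenceRecord]],
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Combine several record sets and remove duplicates.

    A duplicate is an *exact* residue-string match; the first-encountered
    record (in input order) is kept.  Returns the unique records plus a map
    from each kept id to the ids collapsed into it.  Two records sharing an
    id but disagreeing in sequence are an error: the same accession cannot
    denote two different proteins.
    """
    unique: list[SequenceRecord] = []
    by_residues: dict[str, SequenceRecord] = {}
    id_to_residues: dict[str, str] = {}
    dropped: dict[str, list[str]] = {}
    for record_set in sets:
        for rec in record_set:
            prior = id_to_residues.get(rec.id)
            if prior is not None and prior != rec.residues:
                raise ValueError(
                    f"id {rec.id!r} appears with two different sequences"
                )
            keeper = by_residues.get(rec.residues)
            if keeper is None:
                by_residues[rec.residues] = rec
                id_to_residues[rec.id] = rec.residues
                unique.append(rec)
            else:
                if keeper.id != rec.id or prior is None:
                    id_to_residues[rec.id] = rec.residues
                dropped.setdefault(keeper.id, []).append(rec.id)
    return unique, dropped
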