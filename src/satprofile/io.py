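"""FASTA input/output for monomer consensus records.

Accession labels in this dataset contain spaces ("D. antarctica KEW-0522816"),
so the full FASTA description line — not just the first token — is the record
identifier on both read and write.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .align import MonomerRecord
from .iupac import clean_sequence


def read_fasta(path: str | Path, family: str = "", species: str = "") -> list[MonomerRecord]:
    """Read a multi-FASTA of consensus sequences; validates the IUPAC alphabet."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = rec.description.strip() or rec.id
        records.append(
            MonomerRecord(
                accession_id=label,
                species=species or label,
                family=family,
                sequence=clean_sequence(str(rec.seq), label),
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_reference(path: str | Path) -> tuple[str, str]:
    """Read a single-record reference FASTA; returns (id, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one reference record, found {len(records)}")
    rec = records[0]
    label = rec.description.strip() or rec.id
    return label, clean_sequence(str(rec.seq), label)


def write_fasta(records, path: str | Path) -> None:
    """Write (id, sequence) pairs or MonomerRecords as unwrapped FASTA.

    The header line is the full label, spaces included.
    """
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, MonomerRecord):
                name, seq = rec.accession_id, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n{seq}\n")
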