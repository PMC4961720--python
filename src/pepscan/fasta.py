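"""FASTA input/output for peptide sequences (thin wrapper over Biopython)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .physchem import PeptideSequence

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path: str | Path) -> list[PeptideSequence]:
    """Read single- or multi-record FASTA into validated peptide sequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return [
        PeptideSequence(residues=str(rec.seq).upper(), id=rec.id or "peptide")
        for rec in records
    ]


def write_fasta(sequences: Iterable[PeptideSequence], path: str | Path) -> None:
    """Write peptide sequences as FASTA."""
    records = [
        SeqRecord(Seq(seq.residues), id=seq.id, description="") for seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")
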