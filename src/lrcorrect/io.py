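"""FASTA/FASTQ plumbing (gzip-aware) on top of Biopython."""

from __future__ import annotations

import gzip
from typing import Iterator, Tuple

from Bio import SeqIO

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def sniff_format(path) -> str:
    """'fasta' or 'fastq', judged from the first non-blank character."""
    with _open_text(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return "fasta"
            if stripped.startswith("@"):
                return "fastq"
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {stripped[0]!r})")
    return "fasta"  # empty file: harmless either way


def read_sequences(path) -> Iterator[Tuple[str, str]]:
    """Yield (id, uppercased sequence) records from FASTA/FASTQ(.gz)."""
    fmt = sniff_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def write_fasta(path, records, width: int = 80) -> None:
    """Write (id, seq) pairs as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if len(seq) == 0:
                fh.write("\n")
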