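"""Thin FASTA/FASTQ/TSV I/O helpers (Biopython-backed parsing)."""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO

from .seqs import normalize


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, normalized_sequence), ...]``."""
    return [(rec.id, normalize(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield ``(id, normalized_sequence)`` from a 4-line-record FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, normalize(str(rec.seq))


def write_fastq(path: str | os.PathLike, records: Iterable[tuple[str, str]], qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


def read_collapsed_fasta(path: str | os.PathLike) -> list[tuple[str, int]]:
    """Read the collapsed dialect: FASTA whose headers end in a read count.

    Headers may be ``>tag123_x42`` or ``>tag123 42``; a trailing integer is
    taken as the count, otherwise the count is 1.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        token = rec.description.split()[-1] if rec.description else rec.id
        if "_x" in rec.id:
            tail = rec.id.rsplit("_x", 1)[-1]
            if tail.isdigit():
                count = int(tail)
        elif token.isdigit():
            count = int(token)
        out.append((normalize(str(rec.seq)), count))
    return out
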