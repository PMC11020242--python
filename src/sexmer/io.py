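"""FASTA/FASTQ streaming with transparent gzip, via Biopython.

Format is decided by extension first and file content second; gzip is
detected by magic bytes so mislabelled files still open.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

_FASTQ_EXT = {".fq", ".fastq"}
_FASTA_EXT = {".fa", ".fasta", ".fna"}


def _is_gzip(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def open_text(path, mode: str = "r"):
    """Open a possibly-gzipped text file for reading or writing."""
    path = str(path)
    if "r" in mode:
        if _is_gzip(path):
            return gzip.open(path, mode if "t" in mode else mode + "t")
        return open(path, mode)
    if path.endswith(".gz"):
        return gzip.open(path, mode if "t" in mode else mode + "t")
    return open(path, mode)


def sniff_format(path) -> str:
    """Return 'fasta' or 'fastq' from the extension, else from the first byte."""
    suffixes = [s.lower() for s in Path(path).suffixes]
    stem_ext = [s for s in suffixes if s != ".gz"]
    if stem_ext:
        if stem_ext[-1] in _FASTQ_EXT:
            return "fastq"
        if stem_ext[-1] in _FASTA_EXT:
            return "fasta"
    with open_text(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    raise ValueError(f"{path}: cannot determine sequence format")


def read_seqs(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs from a FASTA or FASTQ file (gzip ok)."""
    from Bio import SeqIO

    fmt = sniff_format(path)
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq)


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with open_text(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str] | tuple[str, str, str]], path) -> None:
    """Write records as FASTQ; a constant 'I' quality is used when absent."""
    with open_text(path, "w") as fh:
        for rec in records:
            rid, seq = rec[0], rec[1]
            qual = rec[2] if len(rec) > 2 else "I" * len(seq)
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
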