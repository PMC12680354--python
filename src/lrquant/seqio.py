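"""FASTA/FASTQ streaming with gzip auto-detection (via Biopython).

Sequences are uppercased and U is normalized to T so direct-RNA style
inputs index and map like cDNA.
"""

from __future__ import annotations

import gzip

from Bio import SeqIO

__all__ = ["parse_fasta", "parse_fastq", "parse_reads_auto", "write_fasta", "write_fastq"]

_GZIP_MAGIC = b"\x1f\x8b"


def _open_auto(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def parse_fasta(path):
    """Yield (id, sequence) in input order."""
    with _open_auto(path) as fh:
        n = 0
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                n += 1
                yield rec.id, _norm(str(rec.seq))
        except ValueError as e:
            raise ValueError(f"{path}: malformed FASTA near record {n + 1}: {e}") from e


def parse_fastq(path):
    """Yield (id, sequence, quality) in input order."""
    with _open_auto(path) as fh:
        n = 0
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                n += 1
                yield (
                    rec.id,
                    _norm(str(rec.seq)),
                    "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
                )
        except ValueError as e:
            raise ValueError(f"{path}: malformed FASTQ near record {n + 1}: {e}") from e


def parse_reads_auto(path):
    """Yield (id, sequence) from FASTA or FASTQ, sniffing the first byte."""
    with _open_auto(path) as fh:
        first = fh.read(1)
    if first == "@":
        for rid, seq, _ in parse_fastq(path):
            yield rid, seq
    elif first == ">":
        yield from parse_fasta(path)
    else:
        raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(records, path, quality_char: str = "I") -> None:
    """Write (id, sequence) records with a constant placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
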