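"""FASTQ/FASTA plumbing: gzip-transparent readers and writers.

FASTQ qualities are decoded as Sanger Phred+33 by default; pass
``offset=64`` for old Illumina Phred+64 files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, TextIO, Union

from Bio import SeqIO

from .corrector import CorrectionResult, ReadRecord

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "results_to_records",
]

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: PathLike, offset: int = 33) -> List[ReadRecord]:
    """Read a (possibly gzipped) FASTQ file into ReadRecords."""
    fmt = {33: "fastq", 64: "fastq-illumina"}.get(offset)
    if fmt is None:
        raise ValueError("quality offset must be 33 or 64")
    with _open_text(path) as handle:
        return [
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
            for rec in SeqIO.parse(handle, fmt)
        ]


def write_fastq(records: Iterable[ReadRecord], path: PathLike) -> int:
    """Write ReadRecords as Sanger FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            quals = "".join(chr(min(q, 93) + 33) for q in rec.qualities)
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{quals}\n")
            n += 1
    return n


def results_to_records(results: Iterable[CorrectionResult]) -> Iterator[ReadRecord]:
    """Corrected (non-discarded) results as ReadRecords, qualities passed
    through from the retained region of the input read."""
    for res in results:
        if res.status != "corrected":
            continue
        quals = res.qualities or (30,) * len(res.corrected_sequence)
        yield ReadRecord(res.id, res.corrected_sequence, quals)


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a (possibly gzipped, possibly multi-line) FASTA into an ordered
    mapping id -> uppercase sequence."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: Dict[str, str], path: PathLike, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
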