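"""End-to-end helpers: build databases, correct a read set, evaluate it.

These functions tie the modules together for library users and the CLI,
and are what the test corpora and the reproduction script drive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .corrector import CorrectionParams, CorrectionResult, ReadRecord, correct_read
from .evaluation import (
    AlignmentParams,
    ContigStats,
    KmerEvalReport,
    PerfectReadStats,
    ReferenceIndex,
    chimera_count,
    false_missing_kmers,
    idealized_contigs,
    perfect_read_stats,
)
from .kmer_db import KmerDatabases, build_databases

__all__ = ["correct_reads", "CorrectionSummary", "evaluate_all", "EvaluationReport"]


@dataclass
class CorrectionSummary:
    """Aggregate statistics of a correction run."""

    reads_in: int
    reads_out: int
    reads_discarded: int
    bases_in: int
    bases_out: int
    substitutions: int
    bases_trimmed: int

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


def correct_reads(
    reads: Sequence[ReadRecord],
    params: Optional[CorrectionParams] = None,
    db: Optional[KmerDatabases] = None,
) -> Tuple[List[CorrectionResult], CorrectionSummary]:
    """Build the k-mer databases from ``reads`` (unless given) and correct
    every read; discarded reads stay in the result list with their status."""
    params = params or CorrectionParams()
    if db is None:
        db = build_databases(reads, params.kmer_params)
    results = [correct_read(r, db, params) for r in reads]
    bases_in = sum(len(r) for r in reads)
    kept = [r for r in results if r.status == "corrected"]
    bases_out = sum(len(r.corrected_sequence) for r in kept)
    summary = CorrectionSummary(
        reads_in=len(reads),
        reads_out=len(kept),
        reads_discarded=len(results) - len(kept),
        bases_in=bases_in,
        bases_out=bases_out,
        substitutions=sum(len(r.substitutions) for r in kept),
        bases_trimmed=bases_in - bases_out,
    )
    return results, summary


@dataclass
class EvaluationReport:
    """All reference-based metrics for one corrected read set."""

    kmers: KmerEvalReport
    perfect: PerfectReadStats
    contigs: ContigStats
    chimera_per_10k: float


def evaluate_all(
    corrected: Sequence[ReadRecord],
    original: Sequence[ReadRecord],
    reference: Mapping[str, str],
    k: int = 31,
    align_params: Optional[AlignmentParams] = None,
) -> EvaluationReport:
    """Compute every evaluation metric, sharing one reference index."""
    index = ReferenceIndex(reference, align_params)
    return EvaluationReport(
        kmers=false_missing_kmers(corrected, original, reference, k),
        perfect=perfect_read_stats(corrected, original, reference, index=index),
        contigs=idealized_contigs(corrected, reference, index=index),
        chimera_per_10k=chimera_count(corrected, reference, index=index),
    )
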