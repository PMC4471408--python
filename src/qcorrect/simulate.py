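"""Seeded Illumina-like read simulator with per-read ground truth.

The generator emulates the salient properties of short-read whole-genome
shotgun data: ~45-fold uniform coverage in ~100 bp single-end reads drawn
from both strands, a per-base substitution error rate that is low at the 5'
end and rises toward the 3' end (linearly interpolated between
``error_rate_5p`` and ``error_rate_3p``), Phred quality strings that track
the position's error probability but carry integer jitter (so some errors
sit under high quality scores and some correct bases under low ones), and a
small fraction of chimeric reads splicing two independent loci.  Indels,
GC-dependent coverage bias and paired-end structure are not modelled.

Every read carries a ground-truth record (origin locus, strand, injected
error positions, chimera fields) so that a corrector's output can be scored
base by base.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from .corrector import CorrectionResult, ReadRecord
from .kmer_db import revcomp

__all__ = [
    "SimParams",
    "SimTruth",
    "make_reference",
    "simulate_reads",
    "score_against_truth",
    "TruthScore",
    "write_truth",
    "read_truth",
]

_BASES = np.array(list("ACGT"))
_QUAL_MIN, _QUAL_MAX = 2, 40
_JITTER = 3
_CHIMERA_MIN_PIECE = 20


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    genome_length   reference length in bases
    gc_content      fraction of G+C bases (i.i.d. model)
    coverage        mean fold coverage; read count = round(cov * L / read_length)
    read_length     read length in bases
    error_rate_5p   per-base substitution probability at the first base
    error_rate_3p   per-base substitution probability at the last base
    chimera_fraction  fraction of reads spliced from two independent loci
    repeat_count / repeat_length  optional exact repeats planted verbatim
    """

    genome_length: int = 100_000
    gc_content: float = 0.5
    coverage: float = 45.0
    read_length: int = 100
    error_rate_5p: float = 0.002
    error_rate_3p: float = 0.03
    chimera_fraction: float = 0.001
    repeat_count: int = 0
    repeat_length: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate_5p <= 1 or not 0 <= self.error_rate_3p <= 1:
            raise ValueError("error rates must be in [0, 1]")
        if self.error_rate_5p > self.error_rate_3p:
            raise ValueError("error rate must not decrease toward the 3' end")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")

    def error_profile(self) -> np.ndarray:
        """Per-position error probability along a read (linear ramp)."""
        return np.linspace(self.error_rate_5p, self.error_rate_3p, self.read_length)


@dataclass
class SimTruth:
    """Ground truth for one simulated read."""

    read_id: str
    ref_id: str
    origin_start: int
    strand: str  # "+" or "-"
    error_positions: List[int] = field(default_factory=list)
    chimera: bool = False
    ref_id2: Optional[str] = None
    origin_start2: Optional[int] = None
    strand2: Optional[str] = None
    junction: Optional[int] = None  # read offset where the second piece starts

    def true_sequence(self, reference: Dict[str, str], read_length: int) -> str:
        """The error-free read this record describes, in read orientation."""
        if not self.chimera:
            return _extract(reference[self.ref_id], self.origin_start, read_length, self.strand)
        first = _extract(reference[self.ref_id], self.origin_start, self.junction, self.strand)
        second = _extract(
            reference[self.ref_id2], self.origin_start2, read_length - self.junction, self.strand2
        )
        return first + second


def _extract(ref: str, start: int, length: int, strand: str) -> str:
    piece = ref[start : start + length]
    return piece if strand == "+" else revcomp(piece)


def make_reference(params: SimParams) -> Dict[str, str]:
    """Generate a random reference (i.i.d. bases at the requested GC),
    optionally planting exact repeat copies; deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    gc = params.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=params.genome_length, p=probs)
    if params.repeat_count > 0:
        if params.repeat_length <= 0:
            raise ValueError("repeat_length must be positive when planting repeats")
        n_slots = params.repeat_count + 1  # template + copies
        if n_slots * params.repeat_length > params.genome_length:
            raise ValueError("repeats do not fit in the genome without overlap")
        starts = _nonoverlapping_starts(
            rng, n_slots, params.repeat_length, params.genome_length
        )
        template = seq[starts[0] : starts[0] + params.repeat_length].copy()
        for s in starts[1:]:
            seq[s : s + params.repeat_length] = template
    return {"ref1": "".join(seq)}


def _nonoverlapping_starts(rng, n: int, length: int, genome: int, tries: int = 1000) -> List[int]:
    for _ in range(tries):
        starts = sorted(rng.integers(0, genome - length + 1, size=n))
        if all(b - a >= length for a, b in zip(starts, starts[1:])):
            return starts
    raise ValueError("could not place repeats without overlap")


def simulate_reads(
    reference: Dict[str, str], params: SimParams
) -> Tuple[List[ReadRecord], List[SimTruth]]:
    """Simulate reads from a reference, returning reads and ground truth.

    The read count is round(coverage * genome_length / read_length); origins
    and strands are uniform.  Qualities are the Phred score of each
    position's error probability plus integer jitter in ±3, clamped to
    [2, 40].  Chimeric reads splice two independently drawn origins at a
    uniform junction with both pieces >= 20 bases.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    rl = params.read_length
    total_len = sum(len(s) for s in reference.values())
    n_reads = int(round(params.coverage * total_len / rl))
    profile = params.error_profile()
    base_qual = np.rint(-10 * np.log10(np.maximum(profile, 1e-9))).astype(int)

    ref_ids = list(reference)
    weights = np.array([max(len(reference[r]) - rl + 1, 0) for r in ref_ids], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("reference shorter than read length")
    weights /= weights.sum()

    reads: List[ReadRecord] = []
    truths: List[SimTruth] = []
    for idx in range(n_reads):
        is_chimera = params.chimera_fraction > 0 and rng.random() < params.chimera_fraction
        rid = f"read{idx}"
        if is_chimera and rl >= 2 * _CHIMERA_MIN_PIECE:
            junction = int(rng.integers(_CHIMERA_MIN_PIECE, rl - _CHIMERA_MIN_PIECE + 1))
            r1, s1, o1 = _draw_origin(rng, reference, ref_ids, weights, rl)
            r2, s2, o2 = _draw_origin(rng, reference, ref_ids, weights, rl)
            truth = SimTruth(
                rid, r1, o1, s1, chimera=True,
                ref_id2=r2, origin_start2=o2, strand2=s2, junction=junction,
            )
        else:
            r1, s1, o1 = _draw_origin(rng, reference, ref_ids, weights, rl)
            truth = SimTruth(rid, r1, o1, s1)
        true_seq = truth.true_sequence(reference, rl)

        bases = np.array(list(true_seq))
        err_mask = rng.random(rl) < profile
        err_pos = np.flatnonzero(err_mask)
        for p in err_pos:
            alternatives = [b for b in "ACGT" if b != bases[p]]
            bases[p] = alternatives[rng.integers(3)]
        truth.error_positions = [int(p) for p in err_pos]

        quals = base_qual + rng.integers(-_JITTER, _JITTER + 1, size=rl)
        quals = np.clip(quals, _QUAL_MIN, _QUAL_MAX)
        reads.append(ReadRecord(rid, "".join(bases), tuple(int(q) for q in quals)))
        truths.append(truth)
    return reads, truths


def _draw_origin(rng, reference, ref_ids, weights, rl) -> Tuple[str, str, int]:
    r = ref_ids[int(rng.choice(len(ref_ids), p=weights))]
    start = int(rng.integers(0, len(reference[r]) - rl + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    return r, strand, start


@dataclass
class TruthScore:
    """Classification of injected errors after correction.

    Each injected error is corrected (base now matches the origin), trimmed
    (position falls outside the retained region, or the read was discarded),
    or remaining.  False substitutions are logged changes at positions where
    no error was injected.
    """

    injected: int = 0
    corrected: int = 0
    trimmed: int = 0
    remaining: int = 0
    false_substitutions: int = 0
    reads_discarded: int = 0

    @property
    def removed_fraction(self) -> float:
        """(corrected + trimmed) / injected; 1.0 for an error-free input."""
        if self.injected == 0:
            return 1.0
        return (self.corrected + self.trimmed) / self.injected


def score_against_truth(
    results: Sequence[CorrectionResult],
    truths: Sequence[SimTruth],
    reference: Dict[str, str],
    read_length: int,
) -> TruthScore:
    """Score correction results against simulator ground truth."""
    by_id = {t.read_id: t for t in truths}
    score = TruthScore()
    for res in results:
        truth = by_id.get(res.id)
        if truth is None:
            raise KeyError(f"no ground truth for read {res.id}")
        score.injected += len(truth.error_positions)
        if res.status == "discarded":
            score.reads_discarded += 1
            score.trimmed += len(truth.error_positions)
            continue
        true_seq = truth.true_sequence(reference, read_length)
        error_set = set(truth.error_positions)
        for pos in truth.error_positions:
            if pos < res.trim_start or pos >= res.trim_end:
                score.trimmed += 1
            elif res.corrected_sequence[pos - res.trim_start] == true_seq[pos]:
                score.corrected += 1
            else:
                score.remaining += 1
        score.false_substitutions += sum(
            1 for pos, _, _ in res.substitutions if pos not in error_set
        )
    return score


_TRUTH_FIELDS = [
    "read_id", "ref_id", "origin_start", "strand", "error_positions",
    "chimera", "ref_id2", "origin_start2", "strand2", "junction",
]


def write_truth(truths: Sequence[SimTruth], path) -> None:
    """Write ground truth as TSV, one row per read (chimeric reads carry a
    second origin block; error positions comma-separated)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRUTH_FIELDS)
        for t in truths:
            writer.writerow([
                t.read_id, t.ref_id, t.origin_start, t.strand,
                ",".join(map(str, t.error_positions)),
                int(t.chimera),
                t.ref_id2 or "", "" if t.origin_start2 is None else t.origin_start2,
                t.strand2 or "", "" if t.junction is None else t.junction,
            ])


def read_truth(path) -> List[SimTruth]:
    truths: List[SimTruth] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            truths.append(SimTruth(
                read_id=row["read_id"],
                ref_id=row["ref_id"],
                origin_start=int(row["origin_start"]),
                strand=row["strand"],
                error_positions=[int(x) for x in row["error_positions"].split(",") if x],
                chimera=row["chimera"] == "1",
                ref_id2=row["ref_id2"] or None,
                origin_start2=int(row["origin_start2"]) if row["origin_start2"] else None,
                strand2=row["strand2"] or None,
                junction=int(row["junction"]) if row["junction"] else None,
            ))
    return truths
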