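"""Reference-based evaluation of corrected read sets.

Four complementary views of correction quality, all computed against a
trusted reference:

* **False / missing k-mers** — a distinct canonical k-mer in the corrected
  reads but not the reference is *false*; a reference k-mer absent from the
  corrected reads is *missing*.  "False remain" is the false k-mers left
  after correction as a percentage of the false k-mers in the original
  reads; "true missing" is the missing k-mers as a percentage of the
  reference k-mers.  The score pi is their product — it is small only when
  a corrector removes wrong sequence without destroying real sequence.
* **Perfect reads** — reads with a full-length error-free match to the
  reference, as a percentage of the original reads (and of original bases).
* **Idealized contigs** — reference segments covered by full-length >=98%
  identity read placements chained by overlaps of >= O bases; their N50 and
  E-size bound the contiguity any assembler could achieve from the reads.
* **Chimeric reads** — reads with no full-length 98% match that split into
  two >=20-base pieces matching disjoint reference loci, per 10,000 reads.

Alignment here is substitution-only (Hamming) via exact-seed lookup, which
matches a corrector that makes substitution and trimming edits only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .corrector import ReadRecord
from .kmer_db import canonical, revcomp

__all__ = [
    "AlignmentParams",
    "Placement",
    "ReferenceIndex",
    "KmerEvalReport",
    "ContigStats",
    "PerfectReadStats",
    "kmer_set",
    "false_missing_kmers",
    "round_1sf",
    "align_read",
    "perfect_read_stats",
    "idealized_contigs",
    "n50",
    "e_size",
    "chimera_count",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment and chimera-detection parameters.

    min_identity     minimum fraction of matching bases for a valid
                     full-length placement (mismatch budget is
                     floor((1-identity) * length))
    min_overlap_o    minimum read overlap, in bases, to chain two placements
                     into one idealized contig
    chimera_min_piece  minimum length of each piece of a chimeric read
    seed_length      exact-match seed length for alignment candidate lookup
    """

    min_identity: float = 0.98
    min_overlap_o: int = 25
    chimera_min_piece: int = 20
    seed_length: int = 17

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_overlap_o < 1 or self.chimera_min_piece < 1:
            raise ValueError("overlap and chimera piece minimums must be >= 1")

    def max_mismatches(self, length: int) -> int:
        return math.floor((1 - self.min_identity) * length)


@dataclass(frozen=True)
class Placement:
    """A substitution-only full-length placement of a sequence.

    ``start``/``end`` delimit the covered reference interval (forward
    coordinates regardless of strand).
    """

    ref_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mismatches: int

    def overlaps(self, other: "Placement") -> bool:
        return (
            self.ref_id == other.ref_id
            and self.start < other.end
            and other.start < self.end
        )


class ReferenceIndex:
    """Exact seed index over the forward strand of a reference set.

    Reverse-strand placements are found by aligning the reverse complement
    of the query; all reported intervals are forward-strand coordinates.
    """

    def __init__(self, reference: Mapping[str, str], params: Optional[AlignmentParams] = None):
        self.params = params or AlignmentParams()
        self.reference = {rid: seq.upper() for rid, seq in reference.items()}
        s = self.params.seed_length
        self._seeds: Dict[str, List[Tuple[str, int]]] = {}
        for rid, seq in self.reference.items():
            for i in range(len(seq) - s + 1):
                w = seq[i : i + s]
                if _ACGT.issuperset(w):
                    self._seeds.setdefault(w, []).append((rid, i))

    # -- placement ---------------------------------------------------------

    def _candidate_offsets(self, seq: str) -> Set[Tuple[str, int]]:
        s = self.params.seed_length
        cands: Set[Tuple[str, int]] = set()
        for i in range(len(seq) - s + 1):
            for rid, off in self._seeds.get(seq[i : i + s], ()):
                start = off - i
                if start >= 0 and start + len(seq) <= len(self.reference[rid]):
                    cands.add((rid, start))
        return cands

    def placements(self, seq: str, max_mismatches: Optional[int] = None) -> List[Placement]:
        """All valid placements of ``seq`` (both strands), sorted by
        (mismatches, ref_id, start, forward-before-reverse)."""
        seq = seq.upper()
        if len(seq) < self.params.seed_length:
            return []
        if max_mismatches is None:
            max_mismatches = self.params.max_mismatches(len(seq))
        found: List[Placement] = []
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for rid, start in self._candidate_offsets(query):
                window = self.reference[rid][start : start + len(query)]
                mm = sum(a != b for a, b in zip(query, window))
                if mm <= max_mismatches:
                    found.append(Placement(rid, start, start + len(query), strand, mm))
        found.sort(key=lambda p: (p.mismatches, p.ref_id, p.start, p.strand == "-"))
        return found

    def best_placement(self, seq: str) -> Optional[Placement]:
        hits = self.placements(seq)
        return hits[0] if hits else None

    def is_exact_substring(self, seq: str) -> bool:
        """Full-length error-free match on either strand."""
        seq = seq.upper()
        if len(seq) >= self.params.seed_length:
            return bool(self.placements(seq, max_mismatches=0))
        return any(
            seq in ref or revcomp(seq) in ref for ref in self.reference.values()
        )


def align_read(
    read: str, reference: Mapping[str, str], params: Optional[AlignmentParams] = None,
    index: Optional[ReferenceIndex] = None,
) -> Optional[Placement]:
    """Best full-length substitution-only placement of a read, or None.

    A placement is valid when its mismatch count is within the identity
    budget; ties break to the fewest mismatches, then smallest reference id,
    offset, and forward strand first.
    """
    if index is None:
        index = ReferenceIndex(reference, params)
    return index.best_placement(read)


# -- false / missing k-mers -------------------------------------------------


def kmer_set(sequences: Sequence, k: int) -> Set[str]:
    """Distinct canonical k-mers over sequences (strings or ReadRecords);
    windows containing non-ACGT characters are skipped."""
    out: Set[str] = set()
    for item in sequences:
        seq = (item if isinstance(item, str) else item.sequence).upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if _ACGT.issuperset(w):
                out.add(canonical(w))
    return out


def round_1sf(x: float) -> float:
    """Round to one significant figure (0 stays 0)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


@dataclass
class KmerEvalReport:
    """False-remain / true-missing percentages and the pi score."""

    n_false_original: int
    n_false_corrected: int
    n_missing_corrected: int
    n_ref_kmers: int
    false_remain_pct: Optional[float]
    true_missing_pct: float
    pi_score: Optional[float]
    pi_score_1sf: Optional[float]


def false_missing_kmers(
    corrected: Sequence, original: Sequence, reference: Mapping[str, str], k: int = 31
) -> KmerEvalReport:
    """Distinct-k-mer set comparison of corrected reads against reference.

    A false k-mer occurring in many reads still counts once.  When the
    original reads contain no false k-mers the false-remain percentage (and
    hence pi) is undefined and reported as None.
    """
    ref = kmer_set(list(reference.values()), k)
    if not ref:
        raise ValueError("reference contains no k-mers at this k")
    orig = kmer_set(original, k)
    corr = kmer_set(corrected, k)
    false_orig = orig - ref
    false_corr = corr - ref
    missing = ref - corr
    true_missing = 100.0 * len(missing) / len(ref)
    if false_orig:
        false_remain = 100.0 * len(false_corr) / len(false_orig)
        pi = false_remain * true_missing
        return KmerEvalReport(
            len(false_orig), len(false_corr), len(missing), len(ref),
            false_remain, true_missing, pi, round_1sf(pi),
        )
    return KmerEvalReport(
        0, len(false_corr), len(missing), len(ref), None, true_missing, None, None
    )


# -- perfect reads ----------------------------------------------------------


@dataclass
class PerfectReadStats:
    """Perfect reads/bases as percentages of the original read set.

    ``retained_length_ratio`` = bases_pct / reads_pct: the mean length of a
    perfect read relative to the original read length (1.0 means no
    trimming of the reads that end up perfect).
    """

    n_perfect: int
    n_original_reads: int
    perfect_reads_pct: float
    perfect_bases_pct: float
    retained_length_ratio: Optional[float]


def perfect_read_stats(
    corrected: Sequence, original: Sequence, reference: Mapping[str, str],
    index: Optional[ReferenceIndex] = None,
) -> PerfectReadStats:
    """Fraction of original reads that are perfect after correction.

    A perfect read occurs as an exact substring of the reference (either
    strand) along its entire corrected length.  Percentages use the
    *original* read and base counts as denominators.
    """
    if not original:
        raise ValueError("original read set is empty")
    if index is None:
        index = ReferenceIndex(reference)
    n_orig = len(original)
    bases_orig = sum(len(r if isinstance(r, str) else r.sequence) for r in original)
    n_perfect = 0
    bases_perfect = 0
    for item in corrected:
        seq = item if isinstance(item, str) else item.sequence
        if seq and index.is_exact_substring(seq):
            n_perfect += 1
            bases_perfect += len(seq)
    reads_pct = 100.0 * n_perfect / n_orig
    bases_pct = 100.0 * bases_perfect / bases_orig
    ratio = (bases_pct / reads_pct) if reads_pct > 0 else None
    return PerfectReadStats(n_perfect, n_orig, reads_pct, bases_pct, ratio)


# -- idealized contigs ------------------------------------------------------


def n50(lengths: Sequence[int], genome_length: int) -> int:
    """Largest contig length L such that contigs of length >= L cover at
    least half the genome; 0 when no such length exists."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    total = 0
    for L in sorted(lengths, reverse=True):
        total += L
        if total >= 0.5 * genome_length:
            return L
    return 0


def e_size(lengths: Sequence[int], reference_length: int) -> float:
    """Expected contig length at a random reference base:
    sum(L_i^2) / reference length."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    return sum(L * L for L in lengths) / reference_length


@dataclass
class ContigStats:
    """Idealized contig lengths with N50 and E-size."""

    contig_lengths: List[int]
    n50: int
    e_size: float
    reference_length: int
    n_placed_reads: int = 0


def idealized_contigs(
    corrected: Sequence, reference: Mapping[str, str],
    params: Optional[AlignmentParams] = None, index: Optional[ReferenceIndex] = None,
) -> ContigStats:
    """Chain full-length >=min_identity read placements into idealized
    contigs (overlap >= min_overlap_o) and report N50 / E-size against the
    total reference length."""
    if index is None:
        index = ReferenceIndex(reference, params)
    p = index.params
    ref_len = sum(len(s) for s in index.reference.values())
    intervals: Dict[str, List[Tuple[int, int]]] = {}
    placed = 0
    for item in corrected:
        seq = item if isinstance(item, str) else item.sequence
        hit = index.best_placement(seq)
        if hit is not None:
            intervals.setdefault(hit.ref_id, []).append((hit.start, hit.end))
            placed += 1
    lengths: List[int] = []
    for ivs in intervals.values():
        ivs.sort()
        comp_start, comp_end = ivs[0]
        for start, end in ivs[1:]:
            # chain when this read overlaps the component by >= O bases
            if min(comp_end, end) - start >= p.min_overlap_o:
                comp_end = max(comp_end, end)
            else:
                lengths.append(comp_end - comp_start)
                comp_start, comp_end = start, end
        lengths.append(comp_end - comp_start)
    return ContigStats(
        contig_lengths=sorted(lengths, reverse=True),
        n50=n50(lengths, ref_len),
        e_size=e_size(lengths, ref_len),
        reference_length=ref_len,
        n_placed_reads=placed,
    )


# -- chimeric reads ---------------------------------------------------------


def is_chimeric(
    seq: str, index: ReferenceIndex
) -> bool:
    """A read is chimeric when no full-length placement meets the identity
    threshold, yet some split into two non-overlapping pieces (each >=
    chimera_min_piece bases) places both pieces at disjoint reference
    intervals at the identity threshold."""
    p = index.params
    seq = seq.upper()
    if len(seq) < 2 * p.chimera_min_piece:
        return False
    if index.best_placement(seq) is not None:
        return False
    for cut in range(p.chimera_min_piece, len(seq) - p.chimera_min_piece + 1):
        left = index.placements(seq[:cut])
        if not left:
            continue
        right = index.placements(seq[cut:])
        if not right:
            continue
        for a in left:
            for b in right:
                if not a.overlaps(b):
                    return True
    return False


def chimera_count(
    corrected: Sequence, reference: Mapping[str, str],
    params: Optional[AlignmentParams] = None, index: Optional[ReferenceIndex] = None,
) -> float:
    """Number of chimeric reads per 10,000 reads in the set."""
    if index is None:
        index = ReferenceIndex(reference, params)
    seqs = [(r if isinstance(r, str) else r.sequence) for r in corrected]
    if not seqs:
        return 0.0
    n_chim = sum(1 for s in seqs if is_chimeric(s, index))
    return 10_000.0 * n_chim / len(seqs)
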