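"""Anchor-based read correction with the four-case decision procedure.

A read is corrected by first locating an *anchor*: the first k-mer with
count >= 3, assumed error-free.  From the anchor the corrector walks toward
the 3' end one base at a time.  At each step the (k-1)-suffix ``m'`` of the
last accepted k-mer is extended by each base x; the candidate continuations
``m'x`` (reliable ones trumping the rest) are weighed against the current
base b and the local coverage estimate c (count of the last accepted k-mer):

Case 1 — unique continuation: a single candidate x exists; accept it,
         substituting x for b when they differ.
Case 2 — count threshold: the current base's continuation has count >= T,
         where T is chosen so the probability that c independent reads all
         show the same wrong base is below ``error_prob_bound``; keep b.
Case 3 — continuity of coverage: a unique candidate whose count is closest
         to c; accept it.
Case 4 — no change if b's continuation has non-zero count, otherwise trim
         the read at the current base.

At most M substitutions are allowed in any window of W bases; exceeding
that trims the read just prior to the first substitution of the window and
rolls those substitutions back.  After the forward pass the identical
procedure runs on the reverse complement of the working string (a backward
pass from the same anchor), whose trims map to the 5' end.  Reads with no
anchor, or shorter than ``min_output_length`` after trimming, are discarded.

Only substitutions are corrected — never insertions or deletions — so the
output is always a trimmed window of the input with some bases replaced.

The two baseline trimmers used for comparison are also provided:
:func:`trim20b` (drop the last 20 bases) and :func:`trim_qual5` (trim the
3' tail where quality drops to <= 5 for good).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

from scipy.stats import binom

from .kmer_db import KmerDatabases, KmerParams, continuation_candidates, revcomp

__all__ = [
    "ReadRecord",
    "CorrectionParams",
    "CorrectionResult",
    "Decision",
    "find_anchor",
    "choose_threshold",
    "evaluate_base",
    "correct_read",
    "trim20b",
    "trim_qual5",
]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, bases (may contain N), and per-base
    Phred qualities."""

    id: str
    sequence: str
    qualities: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualities", tuple(self.qualities))
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CorrectionParams:
    """Tunables of the correction procedure.

    max_subs_m / window_w
        no more than M substitutions are allowed in any window of W bases.
    error_prob_bound
        bound on the probability that the current base is wrong when Case 2
        accepts it (1e-6: "one in a million").
    per_base_error
        assumed per-base sequencing error rate for the Case 2 threshold
        model; a specific wrong base occurs with one third of this rate.
    min_output_length
        corrected reads shorter than this are discarded (default: k).
    """

    kmer_params: KmerParams = field(default_factory=KmerParams)
    max_subs_m: int = 3
    window_w: int = 10
    error_prob_bound: float = 1e-6
    per_base_error: float = 0.01
    min_output_length: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.max_subs_m < self.window_w:
            raise ValueError("require 1 <= max_subs_m < window_w")
        if not 0 < self.error_prob_bound < 1:
            raise ValueError("error_prob_bound must be in (0, 1)")
        if not 0 < self.per_base_error < 1:
            raise ValueError("per_base_error must be in (0, 1)")

    @property
    def min_len(self) -> int:
        return self.kmer_params.k if self.min_output_length is None else self.min_output_length


@dataclass
class CorrectionResult:
    """Outcome of correcting one read.

    ``corrected_sequence`` equals the original subsequence
    ``[trim_start, trim_end)`` with exactly the logged substitutions applied.
    Coordinates are 0-based half-open in the original read; substitutions are
    (position, original base, new base) triples.
    """

    id: str
    corrected_sequence: str
    trim_start: int
    trim_end: int
    substitutions: List[Tuple[int, str, str]]
    status: str  # "corrected" | "discarded"
    qualities: Tuple[int, ...] = ()


class Decision:
    """Outcome of evaluating one base: keep, substitute(x), or trim here."""

    __slots__ = ("action", "base")

    def __init__(self, action: str, base: Optional[str] = None):
        self.action = action  # "keep" | "substitute" | "trim"
        self.base = base

    def __eq__(self, other):
        return (
            isinstance(other, Decision)
            and self.action == other.action
            and self.base == other.base
        )

    def __repr__(self):
        return f"Decision({self.action!r}, {self.base!r})"


KEEP = Decision("keep")
TRIM = Decision("trim")


def find_anchor(read: ReadRecord, db: KmerDatabases, params: CorrectionParams) -> Optional[int]:
    """Smallest offset whose k-mer has count >= anchor_min_count, or None.

    The anchor k-mer is assumed valid: correction proceeds outward from it.
    Anchor counts come from the full database A; reliability is not required.
    """
    k = params.kmer_params.k
    seq = read.sequence.upper()
    need = params.kmer_params.anchor_min_count
    for p in range(len(seq) - k + 1):
        if db.count(seq[p : p + k]) >= need:
            return p
    return None


@lru_cache(maxsize=None)
def _threshold(c: int, p_specific: float, bound: float) -> int:
    # smallest t >= 2 with P(Binom(c, p_specific) >= t) < bound
    t = 2
    while binom.sf(t - 1, c, p_specific) >= bound:
        t += 1
    return t


def choose_threshold(local_coverage: int, params: CorrectionParams) -> int:
    """Case 2 count threshold T for a locus covered by ``local_coverage``
    reads.

    T is the smallest integer t >= 2 such that P(X >= t) < error_prob_bound
    for X ~ Binomial(local_coverage, per_base_error / 3): the chance that
    this many independent reads all show the same specific wrong base.
    Monotone non-decreasing in the coverage estimate.
    """
    if local_coverage < 0:
        raise ValueError("coverage must be >= 0")
    return _threshold(local_coverage, params.per_base_error / 3.0, params.error_prob_bound)


def evaluate_base(
    prev_kmer_count: int,
    candidates: Dict[str, int],
    b: str,
    T: int,
) -> Decision:
    """Apply the four cases, in order, to the base b.

    ``candidates`` maps bases to continuation counts (reliable-filtered, as
    produced by :func:`qcorrect.kmer_db.continuation_candidates`);
    ``prev_kmer_count`` is the local coverage estimate c.
    """
    # Case 1: unique continuation
    if len(candidates) == 1:
        (x,) = candidates
        return KEEP if x == b else Decision("substitute", x)
    # Case 2: count threshold
    if candidates.get(b, 0) >= T:
        return KEEP
    # Case 3: continuity of coverage — unique count closest to c
    if candidates:
        best = min(abs(c - prev_kmer_count) for c in candidates.values())
        closest = [x for x, c in candidates.items() if abs(c - prev_kmer_count) == best]
        if len(closest) == 1:
            x = closest[0]
            return KEEP if x == b else Decision("substitute", x)
    # Case 4: no change if b's continuation exists at all, else trim
    return KEEP if candidates.get(b, 0) > 0 else TRIM


def _walk(
    s: List[str],
    start: int,
    anchor_count: int,
    db: KmerDatabases,
    params: CorrectionParams,
) -> Tuple[int, List[Tuple[int, str]]]:
    """Walk forward through ``s`` from the base after the accepted k-mer
    ending at ``start``-1, correcting in place.

    Returns (trim position = exclusive end of the retained region, list of
    (position, new base) substitutions that survived the window rule).
    """
    k = params.kmer_params.k
    M, W = params.max_subs_m, params.window_w
    c = anchor_count
    subs: List[Tuple[int, str]] = []
    end = len(s)
    i = start
    while i < end:
        prefix = "".join(s[i - k + 1 : i])
        b = s[i]
        cands = continuation_candidates(prefix, db)
        decision = evaluate_base(c, cands, b, choose_threshold(c, params))
        if decision.action == "trim":
            return i, subs
        if decision.action == "substitute":
            s[i] = decision.base
            subs.append((i, decision.base))
            if len(subs) > M and subs[-1][0] - subs[-(M + 1)][0] <= W - 1:
                # window rule: > M substitutions within W bases — trim just
                # prior to the first change in the window and roll back
                cut = subs[-(M + 1)][0]
                return cut, [sub for sub in subs if sub[0] < cut]
        # accept the continuation k-mer; its count becomes the new c
        c = db.count("".join(s[i - k + 1 : i + 1]))
        i += 1
    return end, subs


def correct_read(read: ReadRecord, db: KmerDatabases, params: CorrectionParams) -> CorrectionResult:
    """Correct and trim a single read with the anchor + four-case procedure."""
    k = params.kmer_params.k
    n = len(read)
    original = read.sequence.upper()

    def discard() -> CorrectionResult:
        return CorrectionResult(read.id, "", 0, 0, [], "discarded")

    anchor = find_anchor(read, db, params)
    if anchor is None:
        return discard()
    anchor_count = db.count(original[anchor : anchor + k])

    # forward pass: anchor toward the 3' end
    s = list(original)
    fwd_end, fwd_subs = _walk(s, anchor + k, anchor_count, db, params)
    s = s[:fwd_end]

    # backward pass: identical walk on the reverse complement of the
    # post-forward working string, from the same anchor
    rc = list(revcomp("".join(s)))
    rc_anchor = len(s) - (anchor + k)  # rc offset of the anchor k-mer
    bwd_end, bwd_subs_rc = _walk(rc, rc_anchor + k, anchor_count, db, params)
    trim_start = len(s) - bwd_end  # rc keeps [0, bwd_end) -> original [len-bwd_end, len)
    trim_end = fwd_end

    if trim_end - trim_start < params.min_len:
        return discard()

    corrected = rc[:bwd_end][::-1]
    corrected = [b.translate(_COMP) for b in corrected]
    corrected_seq = "".join(corrected)

    subs: List[Tuple[int, str, str]] = []
    for pos, new in fwd_subs:
        if trim_start <= pos < trim_end:
            subs.append((pos, original[pos], new))
    for rc_pos, new_rc in bwd_subs_rc:
        pos = len(s) - 1 - rc_pos
        if trim_start <= pos < trim_end:
            subs.append((pos, original[pos], new_rc.translate(_COMP)))
    subs.sort()

    return CorrectionResult(
        id=read.id,
        corrected_sequence=corrected_seq,
        trim_start=trim_start,
        trim_end=trim_end,
        substitutions=subs,
        status="corrected",
        qualities=read.qualities[trim_start:trim_end],
    )


_COMP = str.maketrans("ACGTN", "TGCAN")


def _trim_result(read: ReadRecord, end: int, min_len: int = 1) -> CorrectionResult:
    if end < min_len:
        return CorrectionResult(read.id, "", 0, 0, [], "discarded")
    return CorrectionResult(
        id=read.id,
        corrected_sequence=read.sequence[:end],
        trim_start=0,
        trim_end=end,
        substitutions=[],
        status="corrected",
        qualities=read.qualities[:end],
    )


def trim20b(read: ReadRecord) -> CorrectionResult:
    """Baseline: trim 20 bases from the 3' end (discard reads <= 20 bp)."""
    return _trim_result(read, max(0, len(read) - 20))


def trim_qual5(read: ReadRecord) -> CorrectionResult:
    """Baseline: trim the 3' end at the first base where quality goes <= 5
    and never rises above 5 again."""
    end = len(read)
    while end > 0 and read.qualities[end - 1] <= 5:
        end -= 1
    return _trim_result(read, end)
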