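"""Canonical k-mer databases with quality-aware reliability marking.

Two databases are built from a read set: ``A`` holds every canonical k-mer
with its count (strand-merged occurrences across all reads), and ``R`` marks
the subset of *reliable* k-mers — those with at least one occurrence in which
every base has Phred quality >= q.  Error k-mers tend to be both rare and to
lack a fully high-quality occurrence, so the reliable subset lets the
corrector prefer trustworthy continuations while still falling back to the
full spectrum when no reliable continuation exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Set, TextIO

import numpy as np

__all__ = [
    "KmerParams",
    "KmerDatabases",
    "canonical",
    "revcomp",
    "count_kmers",
    "mark_reliable",
    "build_databases",
    "continuation_candidates",
    "write_database",
    "read_database",
]

_RC = str.maketrans("ACGTacgt", "TGCAtgca")
_ACGT = frozenset("ACGT")
BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT, case preserved)."""
    return seq.translate(_RC)[::-1]


def canonical(kmer: str) -> str:
    """Return the lexicographically smaller of a k-mer and its reverse
    complement.

    Raises ValueError for non-ACGT characters; callers counting reads should
    skip such windows instead (see :func:`count_kmers`).
    """
    if not _ACGT.issuperset(kmer):
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    rc = kmer.translate(_RC)[::-1]
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerParams:
    """Parameters of the k-mer databases.

    k
        k-mer length; odd so that no k-mer is its own reverse complement,
        which keeps canonical counting unambiguous.
    q
        Phred quality threshold: a k-mer occurrence is high-quality when all
        of its bases have quality >= q.
    anchor_min_count
        minimum count for a k-mer to serve as a correction anchor.
    """

    k: int = 31
    q: int = 5
    anchor_min_count: int = 3

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.k % 2 == 0:
            raise ValueError("k must be odd (no reverse-complement palindromes)")
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if self.anchor_min_count < 1:
            raise ValueError("anchor_min_count must be >= 1")


@dataclass
class KmerDatabases:
    """Counts of all canonical k-mers (A) and the reliable subset (R)."""

    k: int
    counts: Dict[str, int] = field(default_factory=dict)
    reliable: Set[str] = field(default_factory=set)

    def count(self, kmer: str) -> int:
        """Count of a k-mer (any orientation, windows with N count 0)."""
        if not _ACGT.issuperset(kmer):
            return 0
        return self.counts.get(canonical(kmer), 0)

    def validate(self) -> None:
        """Check structural invariants (R subset of A, canonical keys)."""
        for m in self.reliable:
            if m not in self.counts:
                raise AssertionError(f"reliable k-mer {m} not in counts")
        for m, c in self.counts.items():
            if c < 1:
                raise AssertionError(f"count of {m} is {c} < 1")
            if len(m) != self.k or canonical(m) != m:
                raise AssertionError(f"non-canonical key {m!r}")


def _iter_windows(seq: str, k: int) -> Iterable[tuple[int, str]]:
    """Yield (offset, window) for every ACGT-only k-window of ``seq``."""
    n = len(seq)
    for i in range(n - k + 1):
        w = seq[i : i + k]
        if _ACGT.issuperset(w):
            yield i, w


def count_kmers(reads: Sequence, params: KmerParams) -> KmerDatabases:
    """Count canonical k-mers over a read set (database A only).

    ``reads`` is any sequence of objects with a ``sequence`` attribute (or
    plain strings).  Windows containing non-ACGT characters are skipped;
    reads shorter than k contribute nothing.
    """
    k = params.k
    counts: Dict[str, int] = {}
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        for _, w in _iter_windows(seq.upper(), k):
            m = canonical(w)
            counts[m] = counts.get(m, 0) + 1
    return KmerDatabases(k=k, counts=counts)


def _high_quality_windows(qualities: Sequence[int], k: int, q: int) -> np.ndarray:
    """Boolean array: window i has all k base qualities >= q."""
    qual = np.asarray(qualities, dtype=np.int16)
    if len(qual) < k:
        return np.zeros(0, dtype=bool)
    ok = qual >= q
    # min over each k-window == all() over the window
    win = np.lib.stride_tricks.sliding_window_view(ok, k)
    return win.all(axis=1)


def mark_reliable(reads: Sequence, counts: Mapping[str, int], params: KmerParams) -> Set[str]:
    """Return the canonical k-mers with at least one all-high-quality
    occurrence (every base quality >= q) in some read window."""
    k, q = params.k, params.q
    reliable: Set[str] = set()
    for read in reads:
        seq = read.sequence.upper()
        hq = _high_quality_windows(read.qualities, k, q)
        for i, w in _iter_windows(seq, k):
            if hq[i]:
                m = canonical(w)
                if m in counts:
                    reliable.add(m)
    return reliable


def build_databases(reads: Sequence, params: KmerParams) -> KmerDatabases:
    """Single pass building both the count database and the reliable set."""
    k, q = params.k, params.q
    counts: Dict[str, int] = {}
    reliable: Set[str] = set()
    for read in reads:
        seq = read.sequence.upper()
        hq = _high_quality_windows(read.qualities, k, q)
        for i, w in _iter_windows(seq, k):
            m = canonical(w)
            counts[m] = counts.get(m, 0) + 1
            if hq[i]:
                reliable.add(m)
    return KmerDatabases(k=k, counts=counts, reliable=reliable)


def continuation_candidates(prefix: str, db: KmerDatabases) -> Dict[str, int]:
    """Candidate next bases for a (k-1)-mer prefix.

    For each base x, the continuation k-mer is prefix+x.  Reliable
    continuations trump unreliable ones: if any continuation is in R, only
    those are returned.  Counts always come from the full database A (a
    reliable k-mer's abundance is its total abundance).

    A prefix containing non-ACGT characters yields no candidates.
    """
    if len(prefix) != db.k - 1:
        raise ValueError(f"prefix must have length k-1={db.k - 1}")
    if not _ACGT.issuperset(prefix):
        return {}
    in_a: Dict[str, int] = {}
    in_r: Dict[str, int] = {}
    for x in BASES:
        m = canonical(prefix + x)
        c = db.counts.get(m, 0)
        if c > 0:
            in_a[x] = c
            if m in db.reliable:
                in_r[x] = c
    return in_r if in_r else in_a


def write_database(db: KmerDatabases, handle: TextIO) -> None:
    """Write the databases as sorted text: kmer <TAB> count <TAB> reliable."""
    for m in sorted(db.counts):
        handle.write(f"{m}\t{db.counts[m]}\t{1 if m in db.reliable else 0}\n")


def read_database(handle: TextIO, k: int | None = None) -> KmerDatabases:
    """Read a database written by :func:`write_database`."""
    counts: Dict[str, int] = {}
    reliable: Set[str] = set()
    for lineno, line in enumerate(handle, 1):
        line = line.strip()
        if not line:
            continue
        try:
            m, c, r = line.split("\t")
            counts[m] = int(c)
            if r == "1":
                reliable.add(m)
        except ValueError as exc:
            raise ValueError(f"malformed database line {lineno}: {line!r}") from exc
    if counts:
        klen = len(next(iter(counts)))
        if k is not None and k != klen:
            raise ValueError(f"database k={klen} does not match requested k={k}")
        k = klen
    elif k is None:
        raise ValueError("cannot infer k from an empty database")
    db = KmerDatabases(k=k, counts=counts, reliable=reliable)
    db.validate()
    return db
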