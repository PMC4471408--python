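"""Shared fixtures: deterministic toy corpora and a mid-size simulated run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from qcorrect.corrector import CorrectionParams, ReadRecord
from qcorrect.kmer_db import KmerParams, build_databases

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

HIGH_Q = 35


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_read(seq: str, rid: str = "r", qual: int = HIGH_Q) -> ReadRecord:
    return ReadRecord(rid, seq, (qual,) * len(seq))


def tiling_reads(reference: str, read_len: int, step: int, qual: int = HIGH_Q):
    """Error-free reads tiling a reference at a fixed step (forward strand)."""
    reads = []
    starts = list(range(0, len(reference) - read_len + 1, step))
    if starts[-1] != len(reference) - read_len:
        starts.append(len(reference) - read_len)
    for i, s in enumerate(starts):
        reads.append(make_read(reference[s : s + read_len], f"tile{i}", qual))
    return reads


@pytest.fixture(scope="session")
def toy_corpus():
    """60 bp reference, 20 clean 30 bp reads tiling it (k=15 corpus)."""
    rng = np.random.default_rng(42)
    ref = random_dna(rng, 60)
    reads = tiling_reads(ref, 30, 2)
    while len(reads) < 20:
        reads.append(make_read(ref[10:40], f"extra{len(reads)}"))
    params = CorrectionParams(kmer_params=KmerParams(k=15, q=5))
    db = build_databases(reads, params.kmer_params)
    return ref, reads, db, params


def assert_window_invariant(result, window_w: int, max_subs_m: int) -> None:
    """No window of W consecutive output bases holds more than M
    substitutions."""
    positions = sorted(p for p, _, _ in result.substitutions)
    for i in range(len(positions)):
        in_window = [p for p in positions if positions[i] <= p < positions[i] + window_w]
        assert len(in_window) <= max_subs_m, (
            f"{len(in_window)} substitutions within a {window_w}-base window "
            f"of read {result.id}"
        )
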