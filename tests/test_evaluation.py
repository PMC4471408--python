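"""k-mer comparison metrics, Hamming alignment, contig statistics, chimeras."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qcorrect.evaluation import (
    AlignmentParams,
    ReferenceIndex,
    align_read,
    chimera_count,
    e_size,
    false_missing_kmers,
    idealized_contigs,
    is_chimeric,
    kmer_set,
    n50,
    perfect_read_stats,
    round_1sf,
)
from qcorrect.kmer_db import revcomp

from conftest import random_dna


# -- false / missing k-mers -------------------------------------------------


def test_tiling_reads_have_no_false_kmers():
    rng = np.random.default_rng(5)
    ref = random_dna(rng, 200)
    reads = [ref[i : i + 50] for i in range(0, 151, 10)]
    rep = false_missing_kmers(reads, reads, {"ref": ref}, k=21)
    assert rep.n_false_corrected == 0
    assert rep.n_false_original == 0
    assert rep.false_remain_pct is None  # no false k-mers to remain
    assert rep.true_missing_pct == 0.0


def test_uncorrected_reads_leave_all_false_kmers():
    rng = np.random.default_rng(6)
    ref = random_dna(rng, 300)
    reads = [ref[i : i + 60] for i in range(0, 241, 20)]
    bad = reads[0][:30] + "T" + reads[0][31:]
    if bad == reads[0]:
        bad = reads[0][:30] + "G" + reads[0][31:]
    corrupted = [bad] + reads[1:]
    rep = false_missing_kmers(corrupted, corrupted, {"ref": ref}, k=21)
    assert rep.n_false_original > 0
    assert rep.false_remain_pct == 100.0
    # set sanity: false and missing sets are bounded by their universes
    assert rep.n_false_corrected <= len(kmer_set(corrupted, 21))
    assert rep.n_missing_corrected <= rep.n_ref_kmers


def test_distinct_kmer_counting_is_set_based():
    # a false k-mer present in multiple reads counts once
    ref = "A" * 50
    reads = ["ACGTACGTACG"] * 5
    rep = false_missing_kmers(reads, reads, {"ref": ref}, k=5)
    assert rep.n_false_original == len(kmer_set(["ACGTACGTACG"], 5))


@pytest.mark.parametrize(
    "x, expected", [(0.116, 0.1), (3.7, 4), (0.0191, 0.02), (37.0, 40), (0, 0)]
)
def test_round_to_one_significant_figure(x, expected):
    assert round_1sf(x) == pytest.approx(expected)


def test_pi_monotonicity():
    rng = np.random.default_rng(7)
    ref = random_dna(rng, 400)
    reads = [ref[i : i + 60] for i in range(0, 341, 15)]
    noisy = [r[:20] + "T" * 3 + r[23:] for r in reads[:4]] + reads
    cleaner = noisy[1:]  # drop one noisy read: fewer false k-mers
    rep_noisy = false_missing_kmers(noisy, noisy, {"ref": ref}, k=21)
    rep_clean = false_missing_kmers(cleaner, noisy, {"ref": ref}, k=21)
    assert rep_clean.n_false_corrected <= rep_noisy.n_false_corrected
    if rep_clean.true_missing_pct == rep_noisy.true_missing_pct:
        assert rep_clean.pi_score <= rep_noisy.pi_score


# -- alignment --------------------------------------------------------------


def exhaustive_best_placement(read, reference, params):
    """Oracle: Hamming-scan every offset of every reference, both strands."""
    best = None
    budget = params.max_mismatches(len(read))
    for strand, query in (("+", read), ("-", revcomp(read))):
        for rid in sorted(reference):
            ref = reference[rid]
            for off in range(len(ref) - len(query) + 1):
                mm = sum(a != b for a, b in zip(query, ref[off : off + len(query)]))
                if mm <= budget:
                    key = (mm, rid, off, strand == "-")
                    if best is None or key < best[0]:
                        best = (key, (rid, off, strand, mm))
    return None if best is None else best[1]


@pytest.fixture(scope="module")
def align_ref():
    rng = np.random.default_rng(8)
    return {"chr": random_dna(rng, 2000)}


class TestAlignRead:

    def test_exact_substring_places_with_zero_mismatches(self, align_ref):
        hit = align_read(align_ref["chr"][300:400], align_ref)
        assert (hit.start, hit.end, hit.mismatches, hit.strand) == (300, 400, 0, "+")

    def test_reverse_strand_placement(self, align_ref):
        hit = align_read(revcomp(align_ref["chr"][500:600]), align_ref)
        assert (hit.start, hit.strand) == (500, "-")

    def test_mismatch_budget_at_98_percent(self, align_ref):
        read = list(align_ref["chr"][700:800])
        for p in (10, 55):
            read[p] = next(b for b in "ACGT" if b != read[p])
        assert align_read("".join(read), align_ref).mismatches == 2  # 2 <= 2 valid
        read[90] = next(b for b in "ACGT" if b != read[90])
        assert align_read("".join(read), align_ref) is None  # 3 > floor(0.02*100)

    def test_read_shorter_than_seed(self, align_ref):
        assert align_read("ACGT", align_ref) is None

    def test_matches_exhaustive_hamming_scan(self, align_ref):
        rng = np.random.default_rng(9)
        params = AlignmentParams()
        index = ReferenceIndex(align_ref, params)
        for _ in range(40):
            start = int(rng.integers(0, 1900))
            read = list(align_ref["chr"][start : start + 100])
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, 100))
                read[p] = "ACGT"[int(rng.integers(4))]
            seq = "".join(read)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            hit = index.best_placement(seq)
            oracle = exhaustive_best_placement(seq, align_ref, params)
            if oracle is None:
                assert hit is None
            else:
                assert (hit.ref_id, hit.start, hit.strand, hit.mismatches) == oracle


# -- perfect reads ----------------------------------------------------------


class TestPerfectReads:
    def test_published_trimming_arithmetic(self):
        # reads% 90 and bases% 77 imply perfect reads retain 77/90 = 0.86
        # of their original length, i.e. 14% of their bases were trimmed
        assert 77 / 90 == pytest.approx(0.86, abs=0.005)

    def test_untrimmed_exact_reads_give_equal_percentages(self):
        rng = np.random.default_rng(10)
        align_ref = {"r": random_dna(rng, 500)}
        reads = [align_ref["r"][i : i + 80] for i in range(0, 401, 40)]
        stats = perfect_read_stats(reads, reads, align_ref)
        assert stats.perfect_reads_pct == 100.0
        assert stats.perfect_bases_pct == 100.0
        assert stats.retained_length_ratio == pytest.approx(1.0)

    def test_trimmed_read_percentages(self):
        rng = np.random.default_rng(12)
        align_ref = {"r": random_dna(rng, 500)}
        original = [align_ref["r"][0:100], align_ref["r"][200:300]]
        corrected = [align_ref["r"][0:50], "T" * 100]  # one perfect 50 bp read
        stats = perfect_read_stats(corrected, original, align_ref)
        assert stats.perfect_reads_pct == 50.0
        assert stats.perfect_bases_pct == 25.0

    def test_reverse_strand_reads_are_perfect(self):
        rng = np.random.default_rng(13)
        align_ref = {"r": random_dna(rng, 300)}
        stats = perfect_read_stats([revcomp(align_ref["r"][40:120])], ["A" * 80], align_ref)
        assert stats.n_perfect == 1

    def test_empty_original_set_rejected(self):
        with pytest.raises(ValueError):
            perfect_read_stats([], [], {"r": "ACGT" * 10})


# -- idealized contigs ------------------------------------------------------


@pytest.fixture(scope="module")
def contig_ref():
    rng = np.random.default_rng(14)
    return {"chr": random_dna(rng, 1000)}


class TestIdealizedContigs:

    def test_overlap_at_threshold_chains(self, contig_ref):
        reads = [contig_ref["chr"][0:100], contig_ref["chr"][75:175]]  # overlap 25
        stats = idealized_contigs(reads, contig_ref)
        assert stats.contig_lengths == [175]

    def test_overlap_below_threshold_splits(self, contig_ref):
        reads = [contig_ref["chr"][0:100], contig_ref["chr"][76:176]]  # overlap 24
        stats = idealized_contigs(reads, contig_ref)
        assert sorted(stats.contig_lengths) == [100, 100]

    def test_single_read_covering_reference(self):
        rng = np.random.default_rng(15)
        contig_ref = {"r": random_dna(rng, 400)}
        stats = idealized_contigs([contig_ref["r"]], contig_ref)
        assert stats.contig_lengths == [400]
        assert stats.e_size == 400.0
        assert stats.n50 == 400

    def test_order_independent(self, contig_ref):
        rng = np.random.default_rng(16)
        reads = [contig_ref["chr"][i : i + 80] for i in range(0, 800, 30)]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        a = idealized_contigs(reads, contig_ref)
        b = idealized_contigs(shuffled, contig_ref)
        assert a.contig_lengths == b.contig_lengths
        assert a.n50 == b.n50

    def test_unplaceable_reads_give_empty_stats(self, contig_ref):
        stats = idealized_contigs(["T" * 50 + "A" * 50], {"r": "C" * 500})
        assert stats.contig_lengths == []
        assert stats.n50 == 0
        assert stats.e_size == 0.0


def brute_force_n50(lengths, genome):
    best = 0
    for L in set(lengths):
        if sum(x for x in lengths if x >= L) >= 0.5 * genome:
            best = max(best, L)
    return best


@pytest.mark.parametrize(
    "lengths, genome, expected",
    [([80, 70, 50], 200, 70), ([200], 200, 200), ([10], 200, 0), ([], 200, 0)],
)
def test_n50_examples(lengths, genome, expected):
    assert n50(lengths, genome) == expected


@pytest.mark.parametrize(
    "lengths, ref_len, expected",
    [([100, 300], 500, 200.0), ([400], 400, 400.0), ([], 100, 0.0)],
)
def test_e_size_examples(lengths, ref_len, expected):
    assert e_size(lengths, ref_len) == pytest.approx(expected)


@given(
    st.lists(st.integers(1, 500), max_size=30),
    st.integers(1, 5000),
)
def test_n50_and_e_size_match_bruteforce(lengths, genome):
    assert n50(lengths, genome) == brute_force_n50(lengths, genome)
    assert e_size(lengths, genome) == pytest.approx(
        sum(x * x for x in lengths) / genome
    )


# -- chimeric reads ---------------------------------------------------------


@pytest.fixture(scope="module")
def chimera_ref():
    rng = np.random.default_rng(17)
    return {"chr": random_dna(rng, 2000)}


class TestChimeras:

    def test_spliced_read_is_chimeric(self, chimera_ref):
        read = chimera_ref["chr"][100:150] + chimera_ref["chr"][900:950]
        index = ReferenceIndex(chimera_ref)
        assert is_chimeric(read, index)
        assert chimera_count([read], chimera_ref) == 10_000.0

    def test_perfect_read_is_not_chimeric(self, chimera_ref):
        index = ReferenceIndex(chimera_ref)
        assert not is_chimeric(chimera_ref["chr"][300:400], index)

    def test_short_piece_disqualifies(self, chimera_ref):
        # junction read whose first piece is 19 bp: below the 20-base minimum
        seq = chimera_ref["chr"]
        # choose the second locus so the junction cannot slide: a 20-base
        # left piece (19 from locus A + 1 from locus B) must not match
        b = next(s for s in range(900, 1200) if seq[s] != seq[119])
        read = seq[100:119] + seq[b : b + 81]
        index = ReferenceIndex(chimera_ref)
        assert not is_chimeric(read, index)

    def test_overlapping_pieces_do_not_count(self, chimera_ref):
        # both halves from the same locus reconstruct a full-length match
        read = chimera_ref["chr"][100:200]
        index = ReferenceIndex(chimera_ref)
        assert not is_chimeric(read, index)

    def test_rate_per_10k(self, chimera_ref):
        chim = chimera_ref["chr"][100:150] + chimera_ref["chr"][900:950]
        clean = [chimera_ref["chr"][i : i + 100] for i in range(0, 1900, 200)]
        rate = chimera_count([chim] + clean, chimera_ref)
        assert rate == pytest.approx(10_000.0 / (1 + len(clean)))
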