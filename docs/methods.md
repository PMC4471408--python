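# Methods

## Correction model

`qcorrect` corrects substitution errors in short reads using the spectrum
of k-mers of the read set itself, without a reference.  Two databases are
built in one pass: **A**, the count of every canonical k-mer (a k-mer and
its reverse complement are one object; the canonical form is the
lexicographically smaller of the two), and **R**, the set of k-mers with at
least one occurrence whose bases all have quality ≥ q.  The model
assumptions are the usual ones for k-mer spectrum correctors: genuine
genomic k-mers recur roughly at coverage depth, error k-mers are rare, and
a k-mer seen at least once entirely in high-quality bases is very unlikely
to be an artifact.  Neither assumption is reliable alone — real data show
recurrent errors and errors under high quality scores — which is why the
decision procedure combines counts, reliability and local coverage rather
than thresholding on any single signal.

Correction of a read proceeds from its anchor (first k-mer of count ≥
`anchor_min_count`; no anchor → read discarded) forward to the 3' end, then
identically on the reverse complement of the partially corrected string
from the same anchor, so 3'-style trimming on the reverse complement maps
to 5' trimming.  The walk maintains a working string: each accepted base is
written back, so later k-mers reflect earlier substitutions.  The four
cases (unique continuation; count ≥ T; unique count closest to the
previous k-mer's count c; keep-if-nonzero else trim) are applied strictly
in order, and candidate continuations are restricted to reliable k-mers
whenever at least one continuation is reliable.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 31 | k-mer length, bases; odd, so canonical counting has no palindromes |
| `q` | 5 | Phred threshold for a high-quality k-mer occurrence |
| `anchor_min_count` | 3 | minimum count of the anchor k-mer |
| `max_subs_m` (M) | 3 | maximum substitutions per window |
| `window_w` (W) | 10 | window length, bases |
| `error_prob_bound` | 1e-6 | Case 2 accepts b only if the same-wrong-base probability is below this |
| `per_base_error` | 0.01 | assumed sequencing error rate in the Case 2 model |
| `min_output_length` | k | shorter corrected reads are discarded |

The Case 2 threshold T is the smallest integer t ≥ 2 with
P(X ≥ t) < `error_prob_bound` for X ~ Binomial(c, `per_base_error`/3): c
reads cover the locus, each showing one specific wrong base with a third of
the per-base error rate.  The local coverage c is estimated by the count of
the previously accepted k-mer.  This is the simplest model consistent with
a one-in-a-million guarantee; the exact schedule is exposed through the two
parameters, and T(c) is cached per coverage value.  At c = 50 the model
gives T = 5.

## Design choices where the design was open

* **R as a filter, not a second counter.**  Reliability is a property of a
  k-mer (has it ever been seen entirely in confident bases?), so R is a
  marked subset of A and candidate counts always come from A: a reliable
  k-mer's abundance is its total abundance.  The alternative — counting
  only high-quality occurrences in R — would make counts depend on the
  quality profile and break the local-coverage estimate.
* **Case 2 comparator is ≥ T** (non-strict): the probability guarantee is
  naturally stated as "count reaching T suffices", and T already carries a
  floor of 2.
* **Backward pass**: run on the reverse complement of the post-forward
  working string without re-anchoring; the anchor was already accepted as
  valid, and re-anchoring could move the trusted region onto uncorrected
  sequence.
* **Window rule rollback**: when a substitution brings a W-window to M+1
  substitutions, the read is trimmed just prior to the first substitution
  of that window and the rolled-back substitutions are dropped from the
  log (those positions are discarded anyway).  Each pass enforces the rule
  over its own substitutions; since the two passes are separated by the
  k untouched anchor bases and k ≥ W at the defaults, no output window can
  mix substitutions from both passes.
* **Anchors need not be reliable** — count ≥ 3 alone qualifies; the
  reliable set only arbitrates between competing continuations.
* **Non-ACGT bases** are excluded from the databases; any window containing
  one has count 0, so an N is either overwritten by a unique continuation
  (Case 1) or becomes a Case 4 trim point.
* **Discarded reads** are omitted from the output FASTQ and counted in the
  run summary; downstream assemblers expect only usable reads.
* **Databases are in-memory hashes**: the package targets desk-scale
  genomes (megabases); there is no disk-spill or concurrent counting.
* **Coordinates** are 0-based half-open everywhere; substitutions are
  reported in original-read coordinates and retain the original base
  quality in the output FASTQ (quality described the call position, not the
  call identity).

## Evaluation

All metrics compare distinct canonical k-mer sets or substitution-only
(Hamming) full-length placements.  Alignment uses an exact-seed index
(17-mers) over the forward strand; reverse-strand placements align the
reverse-complemented query.  A placement is valid when its mismatch count
is within floor((1 − identity) × length), identity 0.98 by default; ties
break to fewest mismatches, then smallest reference id, offset, and forward
strand.  Because any valid placement of a ≥ 50 bp read at 98 % identity
must contain an error-free 17-mer, seed lookup finds exactly the placements
an exhaustive Hamming scan would (verified against that oracle in the
tests).  Substitution-only identity is the appropriate stand-in here
because the corrector emits substitution and trimming edits only; an
affine-gap aligner would measure the same thing at far higher cost, and
indel-containing placements are declared out of scope rather than
approximated.

Idealized contigs chain placements whose reference intervals overlap by at
least O = 25 bases into connected components; the contig length is the
component's span.  N50 is the largest contig length L such that contigs of
length ≥ L total at least half the genome (0 when no length qualifies);
E-size is Σ Lᵢ² divided by the reference length.  π is reported raw and
rounded to one significant figure, matching how such scores are usually
printed.  Chimera detection scans every split point leaving both pieces ≥
20 bases and asks for valid placements of the two pieces at
non-overlapping reference intervals (any separation, strand or sequence —
the loosest reading of "disjoint places"); the whole read must first fail
to place full-length.

## Simulator

The simulator emulates the properties of the Illumina data this kind of
corrector targets: ~45× coverage in ~100 bp single-end reads, uniform
origins on both strands of an i.i.d. random reference (optionally with
planted exact repeats), a per-base substitution rate interpolated linearly
from 0.2 % at the 5' end to 3 % at the 3' end (qualities degrade toward the
3' end), and 0.1 % chimeric reads splicing two independent loci with both
pieces ≥ 20 bases.  Quality strings are the Phred score of each position's
error probability plus uniform integer jitter in ±3, clamped to [2, 40], so
some errors occur under high quality scores and quality alone cannot
identify them.  Linear interpolation and the jitter model are this
package's own inventions — real Illumina profiles are only qualitatively
like this — and all knobs are exposed.

What the simulator does **not** model bounds what passing tests show about
real data: no indels, no GC-dependent or otherwise non-uniform coverage,
no recurrent (systematic) errors at specific motifs, no paired-end
structure, and reference repeats only if explicitly planted.  On real data
the recurrent-error and repeat structure are exactly what makes correction
hard, so the recovery rates measured here (≈ 99 % of injected errors
removed at 45×) are an upper bound, not a field prediction.  The
evaluation-metric implementations, by contrast, are exact set/interval
computations and transfer as-is.

## Numerical and degenerate-input choices

* Binomial tails come from `scipy.stats.binom.sf`; the tests check the
  resulting thresholds against an independent log-space summation oracle.
* "False remain" is undefined when the original reads contain no false
  k-mers; it is reported as null rather than 0 or 100.
* N50 of an empty (or never-reaching-half) contig list is 0; E-size of an
  empty list is 0.
* Reads shorter than the seed length (17) cannot be placed and never count
  as perfect or chimeric; reads shorter than k contribute no k-mers and
  are discarded by the corrector (no anchor).
* Ties in Case 3 (two counts equidistant from c) deliberately fall through
  to Case 4 rather than picking arbitrarily.

## Problem sizes

The test suite and the reproduction script use a 100 kb reference at 45×
(45,000 reads) for the end-to-end recovery checks, 50 kb at 45× for the
clean-data identity check, and ≤ 5 kb references for oracle-equivalence
suites; these sizes give stable percentages (hundreds of thousands of
k-mers, ~70,000 injected errors) while keeping a full run in minutes on a
single CPU.
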