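# Methods

## The problem

Long-read sequencing (PacBio CLR, nanopore) delivers reads tens of
kilobases long but with per-base error rates around 10–15%, dominated by
insertions and deletions.  Short-read data from the same sample is cheap
and accurate (<1% error, substitution-dominated).  Hybrid correction uses
the short reads to repair the long ones before assembly.  `lrcorrect`
implements the FM-index formulation of this idea: instead of building a
de Bruijn graph at one fixed k with a fixed pruning threshold, it indexes
the short reads once in a multi-string Burrows–Wheeler Transform (BWT) with
an FM-index, which answers the frequency of *any* k-mer in O(k) rank
steps.  The single index therefore represents every de Bruijn graph of the
short-read set simultaneously, with pruning decided per query.

## Index layer

**Multi-string BWT.**  Every short read receives its own `$` terminator;
terminators sort before all bases, ties broken by read index, which fixes
one deterministic BWT per input ordering (k-mer counts do not depend on the
tie rule).  Construction sorts suffixes of the concatenated reads by
prefix doubling (Manber–Myers, numpy `lexsort`); the distinct terminator
ranks make suffix comparison stop at each read boundary, so the sort
converges in O(log(max read length)) rounds.  The alphabet is the six
symbols `$ A C G N T` (codes 0–5).  `N` is a real, countable symbol, but
traversal only ever proposes `A/C/G/T`, so corrections are unambiguous.
All input is uppercased on ingest.

**Serialization.**  The on-disk format is a headerless flat byte array:
each byte holds a symbol code in its low 3 bits and a base-32 run-length
digit in its high 5 bits; consecutive bytes with the same symbol extend the
run little-endian (`length += digit << 5j` for the j-th continuation byte).
Round-trips are bit-exact.  Compatibility with external tools' RLE files is
best effort only — the exact continuation convention in other
implementations is not documented, so this dialect is the package's own.

**FM-index.**  Two interchangeable backends answer `rank(c, p)`:

* *bitarray* (default): one packed 64-bit occupancy bit vector per symbol
  plus exclusive prefix popcounts per word — O(1) ranks, larger memory;
* *sampled*: occurrence checkpoints every `sample_rate` symbols (default
  128) plus a linear scan of the decoded BWT inside the block — slower,
  smaller.

Both are exercised by the same test oracles and must agree on every query.
The hot kernels (rank, backward search, per-window counting, the scoring
alignment) are numba-compiled; a pure-Python rank loop was ~1000x too slow
for the reference simulation profile.

**Strand convention.**  Every public k-mer frequency is the sum of the
forward and reverse-complement backward-search counts.  This is applied
unconditionally, so reverse-complement palindromes count double; because
the doubling is uniform across all k-mers of a read, the dynamic threshold
absorbs it and no special case is needed.

## Correction

Each pass over a read, at k-mer size k (first pass k=21, second pass K=59):

1. **Frequencies.**  All `len(read) − k + 1` window frequencies are
   computed by lock-step backward search.
2. **Dynamic threshold.**  `t = max(T, ceil(F·m))`, where `m` is the median
   of the window frequencies at or above the absolute floor `T` (default
   T=5, F=0.10).  Inclusive `>= T` membership is the default so that a read
   whose solid k-mers all sit exactly at T still gets `t = T`; a strict
   `> T` variant is available behind `CorrectionParams(strict_median=True)`.
   `ceil` keeps the threshold integral and conservative.
3. **Segmentation.**  Positions with frequency `>= t` are solid, strictly
   below are weak; maximal runs form alternating regions (0-based,
   half-open k-mer coordinates).
4. **Repair**, left to right, coordinates re-anchored by the cumulative
   length delta of earlier replacements (anchors themselves are never
   rewritten, since every replacement starts with its seed k-mer and ends
   with its target k-mer):
   * *two flanks*: the solid k-mer immediately adjacent on each side is
     seed and target; a depth-first bridge search connects them;
   * *one flank*: head/tail regions are repaired by depth-first extension
     from the single adjacent solid k-mer (head extension runs on the
     reverse complement);
   * *no flank*: an all-weak read is returned unchanged — there is no
     anchor to start from.
5. **Candidate selection.**  Candidates are compared with the original
   segment spanning seed start to target end; the smallest Levenshtein
   distance wins, ties broken by larger minimum interior k-mer frequency,
   then lexicographically (fully deterministic output).

The second pass repeats the procedure on the output of the first with the
longer K: merging of distinct genomic paths in a de Bruijn graph requires a
shared pattern of length ≥ k, so raising k strictly reduces ambiguity and
resolves repeat-induced "hairballs" once pass one has restored enough
solid K-mer anchors.  The branch budget scales with the pass, `L = B·k`
(default B=4).

### Traversal semantics

The original description names the branch limit and an "expected path
length" but fixes neither precisely; the package's own choices are:

* **Branch accounting**: every node expansion with ≥2 qualifying
  successors costs one unit of `L`; exceeding `L` aborts the whole
  traversal, returning complete paths found so far.
* **Length bounds**: for an original segment of E bases, paths must land in
  `[max(k, floor(0.5·E)), ceil(1.5·E) + k]` — wide enough for ~15% indel
  inflation in either direction.
* **Bridge termination**: a branch is recorded and stopped the first time
  its path ends with the target inside the bounds; reaching the maximum
  length without the target kills the branch.  If the forward search
  returns nothing, the search is retried from the reverse complement of
  the target towards the reverse complement of the seed (fan-out near the
  seed becomes fan-in from the other side) and results are
  reverse-complemented back.
* **Extension termination**: paths are recorded when they die or reach the
  maximum length, and kept if at least the minimum length.  The chosen
  extension candidate is then *trimmed* under free-end edit distance (the
  best-scoring candidate prefix for tails, suffix for heads, never shorter
  than the seed); ties prefer the length closest to the original segment.
  This guarantees an error-free segment is reproduced verbatim even when
  the graph continues past the read end.
* **Path cap**: at most 10 complete paths are retained per traversal
  (first found in deterministic A<C<G<T depth-first order), bounding the
  edit-distance work.

## Synthetic data

The generator emulates the hybrid setting the corrector targets, with
defaults fixed once:

| parameter | default | rationale |
|---|---|---|
| genome | 50 kb, uniform random | desk-scale stand-in for a microbial genome |
| repeats | one 500 bp element, two copies | longer than k=21 and any short read, shorter than a long read: ambiguous for pass one, resolvable by pass two |
| short reads | 100 bp, 50x, 0.5% substitutions | typical Illumina profile |
| long reads | 4 kb, 20x, 15% error at sub:ins:del = 1:5:4 | PacBio-CLR-like indel-dominated profile |

Reads are drawn uniformly from both strands; long reads carry a truth
record (origin interval, strand, CIGAR-like edit trace over `= X I D`)
enabling alignment-free scoring.  Features of real data deliberately *not*
modelled: non-uniform coverage (GC bias, chimeras, adapters), quality-value
structure, heterozygosity, and the coverage ramp correction at genome ends
is the only end effect present.  A green recovery test therefore
establishes that the algorithm removes the errors it models — not that
real-library artefacts are handled.

## Evaluation

Scoring follows the per-reference-locus convention: each read's original
and corrected sequences are globally aligned (unit costs, full DP with
deterministic traceback: diagonal, then template gap, then read gap) to
its known oriented origin template.  A template locus is *correct* when it
aligns to a single identical read base; mismatched or deleted loci are
incorrect; read insertions carry no locus.  Comparing before/after status
gives TP (fixed), FP (introduced), FN (missed), TN (untouched correct),
and

    sensitivity = TP/(TP+FN)   specificity = TN/(TN+FP)   gain = (TP−FP)/(TP+FN)

`gain` is the net fraction of input errors removed.  A zero-length
corrected read counts its whole origin interval as FN.  Because truth
intervals are known, no external aligner is involved and alignment
ambiguity is limited to equal-cost local rearrangements, which affect
before and after statuses alike.

## Numerical and degenerate-input choices

* Reads shorter than the pass k-mer size pass through unchanged.
* An empty read collection yields an empty BWT (`num_strings = 0`); empty
  reads and non-`ACGNT` characters are rejected at ingest with the read
  index named.
* `rank` positions are validated to `[0, N]`; backward search over an
  empty index counts zero.
* k-mers longer than every indexed read count zero rather than erroring.
* FASTQ input is accepted everywhere; output is FASTA only — corrected
  bases have no meaningful quality values.
* Per-read correction is independent and deterministic, so any worker
  count produces byte-identical output in input order.

## Known limitations

* Construction is in-memory (numpy suffix sort): fine for tens of
  megabases of short reads, not engineered for multi-gigabase libraries.
* No read trimming, splitting or filtering is performed — by design, whole
  reads in, whole reads out.
* The sampled FM-index backend trades substantial speed for memory and is
  practical mainly for verification and small runs.
* Scoring alignments are full-matrix DP (O(nm) per read), acceptable at
  the simulator's read lengths.
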