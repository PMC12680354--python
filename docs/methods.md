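# Methods

## Model and procedure

`lrquant` quantifies isoform expression from long reads without base-level
alignment. The unit of evidence is the transcript compatibility class
(TCC): the set of reference transcripts containing a k-mer (for index
construction) or compatible with a read (for counting). The pipeline is

reference FASTA → compacted T-DBG index → per-read TCC assignment →
TCC count vector → EM apportionment → abundance table (est_counts, TPM).

### T-DBG index

Nodes of the de Bruijn graph are canonical k-mers (lexicographic minimum of
a k-mer and its reverse complement; k is odd, so no k-mer is its own
reverse complement). Maximal non-branching runs whose k-mers share one TCC
are collapsed into unitigs, so each unitig references exactly one TCC;
compaction therefore splits at both branch points and TCC changes. Unitig
adjacency is the undirected, deduplicated set of (k−1)-overlap links
(self-loops, which arise from tandem-periodic sequence, count once).
`graph_stats` reports unitig/edge counts and the fraction of unitig bp in
the largest connected component; these quantities shrink as k grows past
repeat lengths, which is the structural rationale for the k = 63 default —
larger k raises the probability of unique mapping and of a non-empty
intersection, at the cost of requiring 63 consecutive error-free bases for
a k-mer hit.

K-mers containing N are not indexed and never count as hits. Transcripts
shorter than k contribute no k-mers but stay in the output table with zero
counts.

### Decision cascade

For a read, k-mer TCCs are collected via canonical lookup and classified:

1. any examined k-mer on the d-list → `dlist_veto` (the d-list k-mer is a
   certificate that the read may originate from non-transcriptome sequence,
   e.g. intron-containing pre-mRNA; the veto applies to the whole read);
2. no hits → `unmapped`; reads shorter than k are unmapped, not errors;
3. non-empty intersection of all hit TCCs → `intersection`;
4. else, if some hit k-mer has a singleton TCC → most frequent TCC among
   singleton-TCC k-mers (`unique_mode`); ties break to the smallest
   transcript ordinal;
5. else → most frequent TCC among all hit k-mers, counting any class seen
   at least once (`mode`); ties break to the class whose smallest ordinal
   is smallest, then lexicographically on the sorted ordinal vector.

The tie rules extend the "first occurring transcript" convention to a total
order so classification is deterministic. "Most frequent with threshold
one" is read as minimum multiplicity 1.

Contig skipping: when a k-mer lands in a unitig, only the first, middle
(floor midpoint) and last k-mers of the contig-consistent stretch are
examined; consistency means same unitig, same strand, offsets advancing
with read position. On agreement the stretch contributes those examined
k-mers and the scan jumps to the next contig; on disagreement the stretch
is scanned exhaustively. Whenever the cascade reaches the mode branches the
whole read is rescanned k-mer-by-k-mer, so mode counts are always those of
an exhaustive scan; this makes the skipping classifier equal the
brute-force classifier read-for-read (verified over random error-bearing
fixtures), with the one documented exception that a d-list k-mer hiding
strictly inside an accepted stretch goes unexamined.

### Effective lengths

l_e(t) = (Σ read lengths over mapped reads whose TCC contains t) / (number
of such reads) − k, over the first `cap` mapped reads (default 1,000,000 —
enough to touch every expressed transcript in a mammalian-scale run). A
read informs every member of its class, since pseudoalignment yields no
single assignment. Transcripts untouched by those reads fall back to
annotated length − k; everything is clamped to ≥ 1. The subtraction is k
(not k−1), matching the defining expression. With `length_norm=False`
(the default) all l_e = 1 and the pipeline reduces exactly to count
apportionment — preferable at high or non-uniform error rates, where
data-driven length correction hurts.

### EM

Update: α_t ← Σ_c n_c · (α_t/l_t) / Σ_{u∈c} α_u/l_u, which is EM for the
multinomial read-generation model with class likelihood Σ_{t∈c} θ_t/l_t;
the observed-data log-likelihood Σ_c n_c log Σ_{t∈c} α_t/l_t is recorded
every iteration and asserted non-decreasing in tests. Modes:

* `default`: all classes; α initialized to unique counts plus uniform
  shares of multi-mapping counts;
* `longread`: EM over classes with ≥ 2 members only, initialized uniformly;
  unique counts are added after convergence. This shields uniquely-mapping
  evidence from being reapportioned by the EM fixed point (compare the
  worked configuration {t0}:30, {t0,t1}:10 → (35, 5) long-read vs (40, 0)
  default).

Convergence: max relative change in α below `tol` (default 1e-8, relative
floor 1e-10 so vanishing transcripts converge), capped at 10,000
iterations. Both modes conserve total mapped reads to floating-point
accuracy. TPM_t = 1e6 · (α_t/l_t) / Σ_u α_u/l_u; an all-zero run yields an
all-zero table rather than NaN.

## Simulator

The generator emulates the study conditions used for error-robustness
analysis: full-length reads (each read is its source transcript's entire
sequence; a fragment mode emits uniform substrings ≥ min_len), strand
flipped with probability 0.5, expression either uniform (remainder reads to
the lowest ordinals) or multinomial-lognormal(μ=0, σ=1). Errors: event
count ~ Binomial(read length, error rate); each event independently typed
by the profile mix — ONT 38.5/38.5/23, PacBio 24.5/52.4/23.1
(deletion/substitution/insertion, %) — at a uniform position; substitutions
draw a different base uniformly, indels are single-base (indel length
distributions, homopolymer effects, quality strings, and length-dependent
error are deliberately out of scope). Every function is pure in
(inputs, seed).

What passing on this substrate does *not* show: real ONT/PacBio error is
positionally non-uniform and sequence-dependent, real transcriptomes have
far denser isoform overlap than planted shared blocks, and real reads are
frequently truncated. Results here characterize algorithmic correctness and
error-response, not real-data accuracy.

## Problem sizes in the test suite

Package-chosen desk scales: oracle equivalence over 100 random fixtures
(2–50 transcripts, fragment reads, error 0–10%, k ∈ {15, 21, 31});
exact recovery on 50 transcripts × 1,000 uniform error-free reads at k=63;
robustness trend on 200 transcripts × 4,000 lognormal reads per error rate
in {0, 1, 3, 10}% at k=63; simulator calibration at 10,000 × 1,000 bp reads
(3 binomial-SE acceptance bands).

## Numerical and design choices

* Canonical k-mer storage with per-hit orientation; reverse-strand reads
  are first-class (batch classification is invariant to reverse
  complementing every read).
* Serialization is versioned JSON; the k-mer map is rebuilt
  deterministically from unitig sequences on load, so save→load roundtrips
  compare equal field-wise and version or truncation problems raise.
* Index node iteration is sorted, so unitig decomposition (including the
  cut point of a pure cycle) and all downstream outputs are deterministic;
  repeated runs produce byte-identical TSV/JSON.
* Metrics: Lin's CCC with population (1/n) moments; identical constant
  vectors score 1 by convention, a constant estimate against varying truth
  scores 0. NRMSE divides by the population stdev of truth and rejects
  constant truth. MRD uses an ε-guard (1e-9) on zero denominators only when
  zero-expression transcripts are explicitly included. PET's detection
  threshold defaults to 0 (any positive estimate detects). Correlation-type
  metrics default to log2(x+1); the transform and unit are recorded in each
  report because agreement values are not comparable across transforms.
* U→T normalization on input so direct-RNA FASTA/FASTQ behaves like cDNA.

## Known limitations

* The index is held fully in memory as Python dictionaries; it targets
  fixture-to-small-transcriptome scales, not genome-wide annotation.
* The d-list veto checks examined k-mers (all k-mers whenever any stretch
  disagrees or the mode path triggers a rescan), not positionally masked
  sub-alignments.
* No bootstrap replicates, gene-level aggregation, or BAM-style output of
  pseudoalignments.
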