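# Methods

## Streaming model

Files are processed in chunks of `chunk_size` reads (default 10,000), so
memory scales with the chunk, not the file. Two pieces of state deliberately
persist across chunks: the duplicate filter's seen-set and the paired-end
pair bookkeeping. Because of this, outputs and summaries are invariant to
the chunk size — a property the test suite checks byte-for-byte at chunk
sizes 1, 7, 100 and 10,000, with every step enabled. Processing is
single-threaded by contract; chunks share no other state, which leaves room
for parallelism later.

Within a chunk, trimmers always run before removal filters (in their
declared order within each group), so the length and mean-quality filters
judge the read a downstream mapper would actually see.

For paired-end input the two mates are processed independently and a pair is
written only when both members survive. Inputs are required to be
rank-aligned; identifier stems (first whitespace token, trailing `/1`/`/2`
stripped — covering both pre- and post-Casava-1.8 headers) are verified at
every rank and a mismatch raises a synchronisation error rather than
guessing at a global re-pairing. Reads that survive their own filters but
lose their partner are accounted under the removal reason `pair`, so
`input_reads == output_reads + Σ removed` holds exactly for every run; this
conservation is asserted internally and property-tested over random
configurations.

## Quality encodings

Detection uses only the observed ASCII range of (at most) the first 10,000
reads, against the published admissible intervals: Sanger 33–73, Illumina
≥1.8 33–74, Solexa 59–104, Illumina 1.3+ 64–104, Illumina 1.5+ 66–104. The
decision is by the minimum character (< 59 → offset 33, then
Sanger/Illumina-1.8 split on whether the maximum exceeds 73; 59–63 → Solexa;
64–65 → Illumina 1.3+; ≥ 66 → Illumina 1.5+). A minimum below 33 fits no
dialect and raises. Range-based detection is inherently ambiguous for files
whose scores are uniformly high — a limitation shared by all offset
detectors, and the reason the round-trip tests pin the encoding explicitly.
Solexa scores are log-odds and are converted with
Q = round(10·log₁₀(10^(Qs/10) + 1)). Output is always Phred+33; the input
dialect is preserved only as run metadata.

## Adapter trimming

Two match classes are searched, both with mismatch budget
⌊error_rate · matched_length⌋:

* internal: the full adapter at every offset inside the read (Hamming
  distance; exhaustive enumeration);
* flank: an overlap of length k ≥ `min_overlap` anchored at the read end
  being trimmed toward (adapter prefix vs 3′ suffix for right-trimming,
  adapter suffix vs 5′ prefix for left-trimming). Only the longest
  admissible overlap is reported: shorter admissible overlaps are nested
  inside it and cannot change the trim boundary.

Right-trimming keeps `[0, s)` for the smallest match start s; left-trimming
keeps `[e, L)` for the largest match end e. N in the read never matches any
adapter base. With `allow_indels`, Levenshtein distance replaces Hamming
under the same budget; internal matches are then located with a semiglobal
dynamic program run from both read ends, so the outermost admissible match
boundary — the only quantity the keep-rule consumes — is exact even when a
closer-scoring match exists elsewhere. The per-overlap budget schedule
⌊rate·k⌋ and the inclusive thresholds are this package's concrete choices;
they follow common trimmer convention. Multiple adapters are applied in the
order given, each seeing the previous result.

The trimmer is validated against a brute-force oracle that enumerates every
offset and overlap literally and applies the keep-rule; 1,000 random
instances (plus dedicated indel-mode cases) must agree exactly.

## Filters

* N filter: count of N ≤ `max_n`.
* Complexity: Shannon entropy of overlapping dinucleotide frequencies,
  normalised by log₂16, keep when ≥ threshold (default 0.5). A homopolymer
  scores 0 and a two-letter repeat ≈ 0.25, both removed at the default;
  random sequence scores ≈ 1. N-containing windows are excluded; reads with
  no scorable window are kept (no evidence of low complexity).
* Duplicates: exact identity of the base string only — not identifiers,
  qualities, or reverse complements. A SHA-1 digest per distinct sequence
  bounds memory; collision risk is negligible at any realistic scale.
* Length and mean quality: inclusive thresholds; an empty read has no mean
  and is removed when the mean-quality filter is active.

## Simulator

The generator emulates adapter read-through: N = round(coverage ·
ref_len / (2 · read_length)) fragments with lengths drawn from
Normal(frag_mean, frag_sd), rounded and truncated to ≥ 1 bp (and to the
reference length). Defaults are 100 bp PE reads, 10X coverage,
Normal(200, 70) fragments, TruSeq adapters. Mate 1 reads the fragment's
forward strand; mate 2 the reverse complement. A fragment shorter than the
read length yields reads whose 3′ tail is the adapter prefix, padded with
random bases if the adapter is exhausted (the padding rule is this
package's choice). The truth table records each read's true length
min(fragment, read_length) and a contamination flag.

Noise is i.i.d. per-base substitution (default 0.5%) with a flat or
linearly decaying quality profile, drawn from a stream seeded separately
from the fragment layout so error rates can be varied on an identical
library. This is deliberately simpler than empirically trained
position-dependent error profiles: passing tests show correct mechanics and
sensible behaviour under uniform noise, not performance on a real
instrument's error structure. Indel errors, amplicon layouts and optical
duplicates are not modelled.

## Evaluation

Read-level classes: a contaminated read trimmed exactly (± the optional
`tolerance`, default 0) to its true length is TP; a clean untrimmed read is
TN; any over-trimming — including any trimming at all of a clean read, and
reads missing from the output entirely (scored as length 0) — is FP;
under-trimming is FN. The clean-but-trimmed → FP assignment is the one
genuinely open edge in the published class definitions and is fixed here as
over-trimming. Statistics with a zero denominator are reported as missing,
never as 0. Mate-averaged statistics are the arithmetic mean of the two
mate-wise values.

The proportion-based MCC is algebraically identical to the integer-count
contingency form; the suite verifies this numerically and checks
MCC ∈ [−1, 1] and its (TP↔TN, FP↔FN) symmetry over random tables.

### Why perfect recovery is not exactly 1

With noise-free reads and exact matching one might expect all five
statistics to reach 1.0. Two structural effects prevent this, at rates the
fragment-length model fixes: (a) a contaminated read whose adapter overhang
is shorter than `min_overlap` (default 5 bp) is undetectable — under
Normal(200, 70) fragments about 0.8% of fragments fall in the 96–99 bp
window, each producing two FN reads; (b) a clean read's genomic 3′ suffix
matches the adapter prefix at ≥ 5 bp with probability ≈ 4⁻⁵·(4/3) ≈ 0.13%,
producing occasional FPs. Lowering `min_overlap` trades (a) for a much
larger (b). The end-to-end suite therefore observes SEN ≈ 0.9 and
SPC ≈ 0.999 under exact matching at these defaults; the same ceiling
applies to any trimmer scored this way.

## Problem sizes and defaults

QC defaults: sample 100,000 reads, k = 8, top 20 (the k-mer and top-list
sizes are this package's defaults; diagnostics are computed on the sample,
including the duplicate table, which therefore estimates rather than counts
file-wide duplication). The reservoir sampler is single-pass and exact. The
test and acceptance workloads use 1,000 read pairs from a 20 kb random
reference and fixtures of 5,000–10,000 reads — large enough that every
statistic is exercised well away from small-sample noise while keeping the
whole suite to a few seconds.

## Known limitations

* No bzip2/zstd, FASTA input to the pipeline, or interleaved PE files.
* No 3′ quality trimming, windowed quality filters, or paired-overlap
  (R1/R2 consensus) adapter detection.
* Encoding detection cannot distinguish dialects whose ASCII ranges
  coincide on a given file (it then picks per the decision table).
* The HTML QC report is a static rendering of the JSON numbers, not an
  interactive viewer.
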