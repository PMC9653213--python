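# Methods

## Coordinate model

All internal coordinates are 0-based half-open genomic intervals; GTF
(1-based inclusive) and BED (already half-open) are converted at the file
boundary. Each transcript is represented by its full pre-mRNA span (TSS to
TES), and *transcript coordinates* run 5′→3′ along the unspliced span with
position 0 at the 5′ end. No splicing is applied anywhere in the pipeline:
intronic positions (branchpoints, splice sites) are addressable exactly like
exonic ones, which is the point of profiling pre-mRNA-binding proteins. A
spliced-coordinate mode is a deliberate non-goal.

Feature conventions, fixed once and used consistently:

* the **5′ss point** of an intron is its first intronic base in transcript
  orientation; the **3′ss point** is the first exonic base of the downstream
  exon;
* **TSS/TES** are the first and last base of the span;
* UTRs exist only when a CDS is annotated and are the exonic pieces outside
  the CDS hull;
* every occurrence of a feature class (each intron, each branchpoint) is an
  independent instance and contributes its own row to downstream matrices.
  All annotated transcripts on a whitelist are processed independently; no
  canonical-transcript selection is attempted, since site selection is a
  scientific decision the user should own.

## Diagnostic signals

Three per-nucleotide signals can be extracted from an indexed BAM, all
oriented 5′→3′ over the span:

* **coverage** — reads whose aligned reference bases (CIGAR M/=/X, plus D;
  not N) include the position;
* **truncation (CIT)** — one site per read, placed `offset` nt from the
  read's 5′-most aligned base in read orientation. The default
  `offset = −1` reflects reverse transcription stopping one base short of
  the crosslink, so the crosslink sits immediately 5′ of the read start;
  the offset is exposed because library chemistries differ.
* **mutation (CIM)** — mismatches (MD tag, or a reference FASTA when MD is
  absent), deletions (each deleted base counted) and insertions (counted on
  the base immediately 5′ of the insertion point in read orientation), in
  any combination.

Read filters default to conservative standards (drop unmapped, secondary,
supplementary, QC-fail and flagged duplicates; MAPQ ≥ 1) and, for paired
data, to counting read 2 only — the eCLIP convention in which read 2's 5′
end abuts the crosslink. Reads are counted toward every overlapping
transcript; since normalization is per transcript, multi-assignment is
harmless and avoids an arbitrary assignment rule. Pre-computed
strand-specific BigWig tracks can replace BAM extraction (values are read
over the span, missing intervals as 0), and any per-transcript signal can be
exported back to genome-orientation WIG/BigWig, summing transcripts that
overlap on the same strand.

## Normalization

Counts are converted to a density with a pseudocount `c` (default 1 count
per nucleotide): `p_i = (x_i + c) / (Σx + cL)`. The pseudocount guarantees
strictly positive densities — and thus defined logarithms — even for an
empty background, in which case `q` is uniform and RI reduces to enrichment
against a flat background. Per-nucleotide relative information is
`RI_i = p_i log2(p_i/q_i)` (bits by default; the base is configurable).
Signed values are kept: negative RI marks depletion relative to background,
and Σ RI_i is exactly the KL divergence D(p‖q) ≥ 0. A `--clip-negative`
display option floors values at 0 for heatmap parity, at the cost of that
decomposition.

Properties relied on (and tested): Gibbs' inequality with equality iff
p = q; invariance under joint scaling of both count tracks and the
pseudocount; permutation equivariance; sign(RI_i) = sign(p_i − q_i).

Transcripts enter normalization only if raw totals pass thresholds
(defaults: IP ≥ 1, SMInput ≥ 0 — permissive, and explicit knobs rather than
claims about any particular upstream pipeline). Exclusions are reported with
reasons.

## Windowing and aggregation

A window specification is (feature class, anchor, upstream, downstream),
default ±50 nt. Anchors: `point` for single-base features;
`five_prime_boundary` = the feature's 5′-most base; `three_prime_boundary` =
the first base *after* the feature (for an intron, the first downstream
exonic base — identical to the 3′ss point convention). Relative position 0
is the anchor base, upstream positions are negative, and windows are never
scaled by feature length. Cells outside the transcript span are masked and
excluded from aggregation denominators — never imputed as zero, which would
bias edge positions toward the pseudocount level. Aggregation is the
per-column mean or median over unmasked cells, reported together with the
per-column count of contributing windows. Both boundaries of an interval
feature can be profiled by running two window specs, one per anchor.

## Synthetic data generator

The simulator emulates the background premise of eCLIP — coverage tracks
expression — and its IP/SMInput contrast, at toy scale:

* a toy genome of disjoint multi-exon transcripts alternating strands
  (defaults: 3 exons of 80–150 nt, introns of 60–120 nt, random base
  composition), written as FASTA + GTF + a branchpoint BED (one point per
  intron, 25 nt upstream of each 3′ss);
* one expression level per transcript (uniform in [0.5, 2]), shared by both
  libraries; SMInput reads (30 nt, sense-strand, all-M) start uniformly over
  the span at `read_depth ×` expression;
* IP reads are a mixture: with probability `(f−1)/f` a read is a crosslink
  read at one of the planted sites (default: fold f = 10 at 30 nt upstream
  of every 3′ss), otherwise background. This parameterization makes f = 1
  collapse IP onto the SMInput generator exactly and makes planted signal
  monotone in f;
* a crosslink read is truncated (starts one base 3′ of the site, so the
  default extractor recovers the site exactly) with probability
  `truncation_rate` (default 1.0), else reads through the site and carries a
  transition mutation there with probability `mutation_rate` (default 0.1);
* MD/NM tags are written directly (trivial for all-M reads); BAMs are
  coordinate-sorted and indexed without external commands so output is
  deterministic given the seed. A paired-end mode writes the signal read as
  read 2 with a signal-free mate, to exercise mate selection.

What the simulator does **not** emulate: mappability and GC biases, PCR
duplication structure, spliced reads, overlapping genes, indel-type CIMs,
and crosslink-site sequence preference. Tests passing on this fixture
demonstrate the correctness of the bookkeeping (coordinates, strands,
normalization, anchoring) — not that any biological binding preference
would be recovered from real libraries.

## Numerical and design choices

* Problem sizes in the validation study: 50 transcripts × 100
  reads/library for enrichment recovery; 20 randomized alignment sets of
  ≤ 200 reads for oracle comparisons; 1000 random density pairs for the
  KL identities. These run in seconds and are statistically comfortable
  for the planted effect sizes.
* Density sums are checked to 1e-9; KL non-negativity to −1e-9 (pure
  float rounding).
* Ties in `argmax` of a profile resolve to the lowest position (numpy
  convention); irrelevant in practice for planted signals.
* Degenerate inputs: zero-count tracks are valid (densities become
  uniform); empty feature lists produce empty matrices which refuse
  aggregation; anchors outside the span yield fully-masked rows with a
  warning.
* Fixture BAM record order is made deterministic by sorting on
  (position, name, flag) before writing.

## Known limitations

* The plug-in estimate of `p log2(p/q)` from finite counts is biased
  slightly upward at every position (O(1/N), where N includes the
  pseudocount mass). With many window rows the *mean* profile's standard
  error shrinks while this bias does not, so a z-test of "mean RI = 0" at a
  null position will eventually reject even for pure background; the bias
  here (~4 × 10⁻⁴ bits/position at the default study size) is ~500× smaller
  than the planted peak (~0.5 bits) and is visible only to such tests, not
  in any plot. Interpret absolute RI levels near zero accordingly.
* Windows around features close to transcript ends lose cells to masking;
  `n_per_position` should always be inspected alongside the profile.
* Signals are computed on pre-mRNA coordinates; mature-mRNA metagenes
  (e.g. around stop codons on spliced transcripts) are out of scope.
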