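# Methods

## Overview

The package implements a desk-scale small RNA-seq profiling pipeline:
clean-read preprocessing, exhaustive perfect-match genome mapping,
priority-ordered annotation into small-RNA classes, and class-specific
quantification.  This note records the model behind each stage, the
parameters that matter, the numerical conventions, and what the bundled
simulator does and does not emulate.

## Preprocessing

Clean reads are raw reads that survive adapter trimming and four filters.
The 3′ adapter is located by a semi-global alignment: over all start
positions, the overlap between read suffix and adapter prefix is scored as
`matches − 3·mismatches`, a candidate is admissible when the overlap is at
least `min_overlap` (default 6 nt) and its mismatch fraction at most
`max_mismatch_rate` (default 0.1), and the best score wins with ties going
to the leftmost (most conservative) trim.  Everything from the match to the
read's 3′ end is removed.  A 5′ adapter, when configured, is matched as an
adapter-suffix/read-prefix overlap and either trimmed or treated as a
contaminant (`discard_adapter5`); it is off by default because standard
single-end small-RNA protocols read through the 3′ adapter only.

Filters, applied in order with a strict accounting ledger
(`raw = clean + contaminant + length + quality`): contaminant screen
(exact substring against an optional user-supplied set, off by default),
length outside [18, 40] nt (the lower bound is the "inadequate" read
cutoff; the upper bound is the gel size-selection window, even though the
sequencer delivers longer cycles), and quality (any ambiguous base, or mean
Phred below 20 — a conventional operationalisation, since "low-quality" has
no universal definition; both thresholds are config-exposed).

Identical clean reads are collapsed into tags `(sequence, count)`, ordered
by descending count then sequence.  Tags are the unit of all downstream
computation; the collapse is lossless by construction.

## Genome matching

Only perfectly matching reads are retained, so mapping is exact substring
search, implemented as a k-mer hash (k = 18, the shortest retained read)
over the forward genome with full-window verification.  Reverse-strand hits
are found by querying the reverse complement: a hit `(chrom, start, '−')`
means the genome forward-strand substring equals the reverse complement of
the tag.  All occurrences are reported — a hit-count cap would corrupt the
weighted quantification below.  A self-reverse-complementary tag present
once in the genome yields two hits (one per strand) at the same position;
the brute-force oracle used in tests follows the same convention.
Coordinates are 0-based half-open internally and converted only at the GFF3
boundary.  Positions containing N are never indexed and never match.

Mapping summaries report `total clean reads / mapped reads / percentage`
with the percentage computed by exact integer ratio and rounded half-up to
two decimals, matching how published summary tables print.

## Annotation hierarchy

Each mapped tag is assigned the highest-priority class that any of its hits
overlaps, in the fixed order
`miRNA > rRNA/snoRNA/tRNA/scRNA/snRNA > piRNA > endo-siRNA`; the structural
classes form one tier.  Annotation is by genomic interval overlap against
user-supplied tracks rather than sequence-database alignment: coordinate
tracks are deterministic, version-pinnable, and regenerable from
miRBase/Rfam/RepeatMasker coordinates.  An overlap counts when it covers at
least `min_overlap_frac` (default 0.8) of the tag length and satisfies the
strand rule: same-strand for miRNA and structural classes; for piRNA
clusters (single-strand annotations) the same-strand default can be
switched to strand-agnostic.  Ties within a tier are broken by largest
overlap then lexicographic locus id, making classification independent of
input order.  Tags claimed by no track are `unannotated` until the
endo-siRNA screen (below) has a chance to claim them.

## miRNA profiling

miRNA-classified tags are counted per mature miRNA: a tag contributes its
full count to each distinct mature interval its assigning hit overlaps at
the annotation fraction; hairpin-only overlaps are kept in a flagged bucket
rather than silently dropped.  Counts are normalized to RPM within each
sample.  The normalization denominator is deliberately configurable because
two readings are defensible: the default is the per-sample total of
miRNA-annotated reads (so RPM columns sum to 10⁶ exactly and the analysis is
self-contained within the miRNA class), with total genome-mapped reads as
the alternative.

Expression is called at RPM ≥ 1.  A signature miRNA of a focal sample must
be expressed there and show a fold change of at least `fold` (default 2)
against **each** other sample — a conjunction, not a comparison to the
mean, though `vs="mean"` is provided.  Fold changes are computed on the RPM
scale.  Zeros in a comparison sample would make every ratio infinite, so a
zero denominator is replaced by `epsilon` (default 0.5 RPM); the guard
touches only zero denominators, leaving exact finite boundary cases such as
10/5 = 2 untouched.

The log2 layer is `log2(RPM + pseudocount)` with pseudocount 0 by default
(the RPM ≥ 1 filter is expected to precede it; zeros map to NaN).  Sample
clustering uses pseudocount 1 so all features are finite, restricted to
miRNAs expressed in at least one sample, with distance `1 − Pearson r`
between samples and average linkage — the standard recipe behind expression
heat maps.  Tests assert cluster topology on constructed data, never merge
heights.

## piRNA profiling

piRNAs are repeat-derived and multi-map heavily, so read counting uses
weighted reads: each tag distributes `ω = count / n_hits` to every one of
its hits.  The weight is conserved exactly — summed over a tag's hits it
returns the count, and total weighted signal equals the piRNA read count —
and a uniquely mapping tag keeps its full count.

The genome-wide distribution sums ω per (chromosome, bin, strand), with
each hit binned by its strand-aware 5′ end (not midpoint).  Bin size
defaults to 1 kb on the toy genome; 100 kb is the sensible scale for a real
mammalian genome.  Profiles are additionally scaled to weighted-RPM over
the per-sample mapped-read total.  Samples whose weighted piRNA total falls
below a configurable fraction of the best sample are omitted from
distribution figures (mesenchymal-like libraries have almost no piRNA
signal and would render as empty panels).

Repeat-family enrichment between two samples compares, per family, the
weighted in-family vs out-of-family counts rounded to the nearest integer
in a 2×2 Fisher exact test, with Benjamini–Hochberg correction across
families.  The rounding is an explicit approximation (weights are
fractional); the exact test was chosen for robustness on small tables, and
no specific test is mandated by the method being reproduced.

## Endo-siRNA screen

Endo-siRNAs are not a track but a rule: a tag passes when (1) its length is
within [18, 23] nt, (2) it has at least one perfect genome match, and
(3) it is repeat-derived — at least one hit overlapped by a repeat interval
over ≥ `repeat_overlap_frac` (default 0.5) of the tag length.  Because the
annotation order places endo-siRNA last, tags already claimed by miRNA,
structural or piRNA tracks are excluded even when all three criteria hold.
Each criterion is recorded separately per tag, so the screen is auditable.
Expression-by-length profiles sum ω per length scaled to tag count per 10
million, with the per-sample genome-mapped read total as denominator — the
only per-sample total available at that stage.

## Trend summary

Along a user-declared developmental ordering (the orchestrator never
hard-codes one), each class's fraction of annotated reads receives a label
— increasing / declining / flat — from the sign of the Spearman correlation
with the order.  This is deliberately descriptive: with three to five
samples no significance statement is meaningful.

## The simulator

The simulator exists to make every stage falsifiable against known truth.
It builds a toy genome (default two chromosomes, 160 kb total) with:
miRNA hairpins (80 nt) containing one or two nested 22-nt matures;
structural RNA loci; single-strand piRNA clusters (1.5–3 kb), hosted inside
ERV1/2/3 repeat intervals with probability 0.7; standalone LINE/SINE
repeats that source endo-siRNA reads; and background regions.  All tracks
are placed disjointly with a 60 bp margin, and a build is rejected and
retried unless no 18-mer (canonical up to reverse complement) occurs in two
different track groups or in a track and the background — this k-mer
disjointness is what makes perfect-match classification of error-free reads
provably unambiguous, so recovery tests can demand 100% accuracy rather
than a tolerance.

Reads are drawn per library from a multinomial over classes, with per-class
read-length models shaped to the canonical library profiles: miRNA peaked
at 22–23 nt, piRNA at 27–30 nt, endo-siRNA at 21–22 nt, structural
fragments broad, and background including 15–17 nt inserts so the length
filter is exercised.  The five default cell-type mixtures encode the
qualitative contrasts the real libraries show — miRNA ≈ 60% of annotated
reads everywhere except the germ-cell library, where piRNA is modal; piRNA
abundance ordered GC > SSC > ESC > ST > MSC; endo-siRNA ordered
ESC > SSC > … > GC; miRNA declining and piRNA increasing along
ESC → SSC → GC.  No quantitative per-class percentages are published for
the original libraries, so the mixtures are fixed qualitative encodings,
not fits.  Mature-miRNA sampling weights follow two latent log-normal
programs (pluripotent/germline shared by ESC- and SSC-like profiles,
somatic shared by ST- and MSC-like) plus per-library noise, which is what
makes sample clustering reproduce the {ESC,SSC} vs {ST,MSC} grouping.

Each read is a subsequence of its source locus (piRNA reads from the
cluster's annotated strand only), mutated by independent per-base
substitutions at `error_rate` (no indels — under perfect-match mapping the
only consequence of an error is mapping loss, which mirrors the retention
rule), then the 3′ adapter is appended and the result truncated to the
50-cycle machine read length.  Qualities are constant high Phred; quality
failures are exercised with constructed fixtures rather than simulation.
Every read is logged in a truth table (class, locus, strand, insert length,
error count).  All randomness flows from explicit seeds in public
signatures; fixed inputs give byte-identical FASTQ/FASTA/GFF outputs.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: overlapping annotations (real genomes overlap
heavily; the disjoint design isolates hierarchy logic, which is instead
tested on hand-built overlapping fixtures), PCR duplicates, indels, quality
ramps, sequence-composition biases, and real repeat families (repeats here are
unique sequence labelled as families, so "repeat-derived" is a coordinate
property, not a homology one).

## Problem sizes and determinism

Recovery and conservation tests run on five 10,000-read libraries; the
end-to-end acceptance checks use five 50,000-read libraries at error rates
0 and 0.01, and the matcher oracle comparison uses 20 random genomes of
30–100 kb × 500 queries.  These sizes give every per-class analysis
thousands of reads while keeping the whole suite around a minute.  The
acceptance script uses 20,000-read libraries for the same reason.  All
simulations, tests and the acceptance script are seeded and deterministic;
the acceptance script derives every stream from its `--seed` argument.

## Known limitations

- No mismatch-tolerant mapping: biological variants and sequencing errors
  both cost mapped reads, indistinguishably.
- No de novo miRNA discovery, piRNA cluster calling, ping-pong or 1U/10A
  nucleotide-bias analysis.
- One library per cell type is assumed (no replicate-based differential
  statistics); the signature call is a thresholded fold change, not a test.
- The Fisher/BH enrichment on rounded weighted counts treats weights as
  counts; with heavy multi-mapping the effective sample size is
  overstated.
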