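# Methods

## Rationale

Alignment-derived QC metrics (mapping rate, PCR duplicate rate,
insert-size distribution, contamination content) normally require a
reference genome. The strategy implemented here removes that
requirement by assembling the raw reads into a quick draft — with no
parameter optimization, scaffolding or polishing — and using the
draft itself as the mapping target. The draft only has to satisfy one
property: contigs must typically be much longer than the library
insert, so that both mates of a pair land on the same contig and the
pair-level metrics are computable. Everything in the package is
designed around that observation.

## Trimming

Reads are processed 3'-first: adapter removal, then quality trimming,
then filtering. Adapter removal looks for the leftmost position where
an adapter's prefix overlaps the read suffix by at least 6 bases with
at most one mismatch per 10 overlapped bases; this is a deterministic
approximation of common adapter trimmers, not a reimplementation of
any one of them. Quality trimming removes the longest 3' suffix of
bases below Q30. A read is rejected if fewer than 35 bases survive or
the surviving mean quality is below 30 (defaults; all three are
`TrimPolicy` fields). A pair survives only if both mates survive;
single survivors are counted as orphans and dropped, because every
downstream metric is pair-based. Only Phred+33 FASTQ is accepted;
quality characters outside that range raise an error rather than
being silently misdecoded as Phred+64.

## Draft assembly

The assembler is a canonical-k-mer de Bruijn unitig builder
(default k = 31, minimum contig length 100, both values exposed).
Paired and mate-pair reads are treated as single-end and pooled.
Reads are split at N bases before k-mer extraction. k-mers are packed
two bits per base into 64-bit words (bounding k at 32; the parameter
type admits the usual odd sizes 15–31), counted together with their
reverse complements, and unitigs are the maximal paths in which every
internal node has a unique successor whose predecessor is also
unique.

### Error cleaning

With substitution errors, a raw unitig graph shatters: an error near
a read end creates a short dead-end side path (a tip), and an error
in the middle of a read creates a k-node side path that *rejoins* the
main path (a bubble side), because the k-mer just past the error is
again a true genome k-mer. At 8× coverage and a 10⁻³ error rate a
0.5 Mb genome would otherwise fragment into ~100 bp unitigs, which is
useless as a mapping target. Two conservative passes run when the
k-mer coverage cutoff is 1 (with a cutoff ≥ 2 the counting stage
already removes error k-mers and cleaning is skipped):

1. **Tip clipping** removes dead-end unitigs shorter than 2k bases
   whose mean k-mer count is error-like.
2. **Redundant weak branch removal** removes a unitig of at most 3k
   bases with error-like coverage only when every predecessor of its
   first k-mer retains another successor and every successor of its
   last k-mer retains another predecessor — i.e. when removal cannot
   create a new dead end. Candidates are processed weakest-first and
   the junction conditions are re-checked at removal time, so of two
   parallel branches the stronger always survives, and a genuine
   low-coverage *bridge* (a region covered by a single read) is never
   removed because its junctions have no alternative branch.

"Error-like" is coverage-relative: mean count ≤ max(2, 0.25 × the
strongest adjacent junction k-mer count). A fixed count-1 rule would
miss the count-2 error paths that appear at high coverage when two
reads happen to share a substitution at the same position.

Determinism: unitig seeds are visited in ascending packed-code order,
contigs are emitted as min(seq, revcomp(seq)) sorted lexicographically
and named `contig_<index>` in that order, so output is reproducible
across runs and platforms.

### Shape metrics

N50 follows the cumulative-half rule on descending contig lengths.
Chaff is the percentage of assembly bases in contigs of **at most**
300 bp. `% assembly size` = 100 × total bases / reference size and
can exceed 100 for redundant assemblies; it is reported only when a
reference size is supplied.

## Map-back

The mapper is seed-and-extend and ungapped: every sampled
`seed_len`-mer of the read (default 31) is looked up exactly in a
sorted-array index of contig k-mers, on both strands; each candidate
diagonal is extended to a full-read ungapped placement and accepted
when its mismatch count is at most `max_mismatch_frac` (default 0.04)
of the read length. The placement with fewest mismatches wins; ties
break on the lexicographic (contig, start, strand) triple and tied
reads carry a multi-mapping flag. Ungapped alignment is a deliberate
scope cut: the pair- and coverage-level QC metrics are insensitive to
rare short indels at desk scale, and the simulator emits substitution
errors only, keeping the validated surface honest.

Seed offsets are sampled every `seed_stride` bases (default 7, the
final window always included). Any placement with an error-free
stretch of 31 bases starting at a sampled offset is still found —
in particular every placement of an error-free read — and wherever
the strided and exhaustive searches both map a read they agree
exactly; stride 1 restores exhaustive seeding.

Contig edges are explicit. A best placement that runs past a contig
end is either soft-clipped and kept (`edge_policy="clip"`, the QC
default) or reported unmapped with the overhang recorded
(`edge_policy="unmapped"`). The second mode exists to reproduce the
behaviour of aligners that concatenate reference sequences and flag
junction-spanning reads as unmapped — the mechanism by which
fragmented assemblies depress both mapping rates and duplicate-rate
estimates. The `edge_effect_diagnostic` quantifies the fragmentation
penalty as the fraction of start positions admitting a full-length
alignment, Σ max(0, Lᵢ − readlen + 1) / Σ Lᵢ.

Alignments round-trip through SAM (soft clips in CIGAR, NM tags,
proper FLAG bits, 1-based POS) via pysam, so externally produced SAM
substitutes for the internal mapper anywhere alignments are consumed.
Internally all coordinates are 0-based half-open.

## Pair metrics

A pair is **proper** when both mates map to the same contig in the
expected orientation (FR for paired-end, RF for mate-pair) with an
outer-distance insert in (0, cap]; the insert uses unclipped
coordinates so edge-clipped alignments still measure the true span.

**Duplicate marking** re-implements coordinate-based pair semantics:
the key is both mates' (contig, 5' unclipped coordinate, strand) with
the mates canonically ordered, so a pair and its mate-swapped twin
share a key. Within a key group the retained pair has the highest
summed base quality (ties: smallest pair id, then input order);
`%duplicates = 2 × marked pairs / mapped reads`. Only both-mapped
pairs are eligible. Multi-mapped reads stay eligible by default (they
retain one primary placement), matching common aligner behaviour.

**Insert statistics** are computed on the core of the proper-pair
distribution: inserts within 10 MADs of the median. When the MAD is 0
(tight libraries at low depth) the window falls back to ±10% of the
median. The mean and sample SD (ddof = 1) come from the core; the
full histogram is kept for plotting, so short-insert or chimeric
artifacts remain visible even though they do not perturb the summary.
Both the MAD factor and the fallback are module constants rather than
magic numbers.

The mapping-rate denominator is reads entering mapping (post-trim);
trimming losses are reported separately, so the two stages remain
auditable.

## TAGC contamination screening

Each contig becomes a (GC%, mean coverage, taxon) point. GC excludes
ambiguous bases. Coverage is aligned (non-clipped) bases over contig
length and includes duplicate reads, since screening happens on raw
mapped reads before any deduplication. Taxa come from BLAST-style
tabular hits (outfmt-6 column order) plus a subject→taxon map: per
contig the best hit is the highest bitscore among hits with E-value
strictly below 1e-50 (ties: lowest E-value, then input order);
contigs without a qualifying hit are "no-hit" and drawn gray. The
similarity search itself is external by construction — the package
consumes its tabular output, and the simulator writes truth hit
tables in the same format so the whole path runs offline.

Quantification counts each read once via its primary alignment's
contig. In `all` mode percentages are relative to the total reads in
the library; in `subset` mode, ⌊fraction × n⌋ contigs are drawn
uniformly without replacement under a fixed seed and percentages are
relative to reads mapped to the subset — the two denominators the
screening protocol reports. Per-read (not per-pair) counting means a
pair split across two contigs contributes each mate to its own
contig's taxon. Cluster reading stays visual/taxon-driven; no 2-D
clustering algorithm is layered on top. Zero-coverage contigs are
drawn at a pseudo-floor of 0.01× on the log-scaled axis.

## Simulator

Genomes are i.i.d. base sequences with P(G) = P(C) = GC/200.
Fragments are drawn with Normal(insert mean, SD) lengths truncated to
[read length, genome length] and uniform starts; paired-end reads are
the fragment's first and last `read_len` bases in FR orientation,
mate-pair reads point outward (RF) with the outer span on the source
genome equal to the fragment length — circularization is emulated at
the orientation level, not mechanistically. PCR duplication copies a
fragment *before* error injection with probability `dup_prob`, so
duplicate copies differ only by their independent sequencing errors —
exactly what coordinate-based duplicate marking detects and what the
base-quality tie-break requires. Substitution errors hit each base
independently; positions are recorded in the truth object. The
quality model is a constant Q37 with an optional low-quality 3' tail —
enough to exercise the trimming rules, with no pretension to real
platform error profiles. Spiking partitions the pair count between
host and contaminant genomes so the configured read-count ratio holds
exactly among original fragments.

What the simulator deliberately does not model: indels, GC-dependent
coverage bias, optical duplicates, empirical quality profiles,
mate-pair chimeras/PE leakage. Passing recovery tests therefore show
that the estimators are correct under clean generative conditions,
not that they are robust to every artifact of real libraries; the
edge-effect experiment probes the one artifact the method is most
sensitive to (assembly fragmentation) explicitly.

## Benchmark designs and problem sizes

The validation designs in `refless_qc.benchmarks` scale the method's
original benchmark regime (multi-Mb genomes at 70×+) down to sizes a
single CPU handles in minutes, keeping the quantities being recovered
at their stated values:

* Insert recovery: 0.5 Mb genome, 20,000 pairs (8×), SD 20 bp, error
  rate 10⁻³, target means 180/300/600 bp; recovery tolerance 2%.
* Mate-pair: 1 Mb genome; the draft comes from a 60,000-pair PE
  library (12×) so the draft N50 comfortably exceeds the 2.5 kb
  outer span; 20,000 MP pairs, SD 300 bp; tolerance 2%.
* Duplicates: duplication probabilities 0–0.35 at 20,000 pairs,
  mapped to the source genome; tolerance 1 percentage point against
  the realized duplicate fraction.
* Contamination: two 0.5 Mb genomes (GC 40% vs 50%) mixed at exactly
  20:1. The total of 315,000 pairs gives the contaminant ~6×
  coverage — the same mechanism that gives a small contaminant genome
  high coverage inside a deep host library — so its contigs assemble
  and its reads map. Tolerances: contaminant read fraction within
  1 percentage point, host:contaminant ratio within 15%.

## Numerical and degenerate-input choices

* Empty assemblies, zero-read reports and sub-2-pair insert sets are
  warnings plus None/zero fields, never exceptions.
* N50 of an empty contig set is undefined (None).
* GC of an all-N contig is undefined (None) with a warning.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configuration yields
  byte-identical FASTQ, SAM and JSON artifacts.
* Tie-breaks (mapper placements, duplicate retention, annotation
  hits, contig naming) are all total orders, making every pipeline
  output order-independent and reproducible.

## Known limitations

* Ungapped mapping: indel-rich data will show depressed mapping rates.
* k ≤ 32 in the packed k-mer representation.
* The assembler targets QC drafts; it is not a general-purpose
  assembler (no scaffolding, no repeat resolution, single k).
* Order-level taxonomy is a flat map supplied by the user or the
  simulator; no taxonomy-tree traversal.
* Contamination quantification inherits the draft's completeness: a
  contaminant too shallow to assemble is invisible, which is a
  property of the screening strategy itself.
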