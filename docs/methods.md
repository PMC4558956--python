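# Methods

## The two-stage model

Gene-level RNA-seq quantification from alignments faces two distinct
ambiguities: a fragment may have several equally-good alignment loci
(multi-mapping, typically caused by gene families, pseudogenes and other
repeats), and a single locus may overlap several annotated genes (ambiguity).
Count-based quantifiers resolve neither: they discard such fragments, which
turns genuinely expressed family members into false negatives while leaving
no trace in the output.

`mmgkit` treats the discarded fragments as signal. Stage 1 is a conventional
unique-fragment counter; stage 2 observes that although a multi-mapped
fragment cannot be placed in one *gene*, it can be placed uniquely in one
*set of genes* — the union, over all its reported loci, of the genes each
locus overlaps. Because reads from a family consistently touch the same loci,
these sets repeat across fragments and samples, forming stable multi-map
groups (MMGs). Group-level counts are unique assignments, so they support the
same downstream statistics as gene-level counts. No relatedness of the genes
within a group is assumed; groups emerge from the data, not from annotation
(a biotype column, when present, is carried as metadata only).

## Stage-1 semantics

Overlap is always measured against a gene's exon union; intronic alignments
are `no_feature`. Per aligned base of a mate there is a set of covering
genes; the three modes combine those per-base sets:

* `union`: union over aligned bases;
* `intersection-strict`: intersection over all aligned bases, an uncovered
  base contributing the empty set (complete containment required);
* `intersection-nonempty`: intersection over the covered bases only.

For a pair, each mate's mode-level set is computed and the two sets are
unioned before the cardinality decision (1 → assigned, 0 → `no_feature`,
>1 → `ambiguous`). This per-mate-then-union rule is one of several defensible
pair treatments; it is fixed here for determinism and validated against
enumerated two-gene toys in the test suite. Multi-mapping is decided by the
`NH` tag when present, with the number of reported loci as fallback, and
always precedes the overlap decision. In the CIGAR, `M/=/X` and `D` consume
reference and participate in per-base sets; `N` skips reference; `I/S/H`
consume none. Counting is unstranded by default; `yes`/`reverse` protocols
restrict features to the strand implied by mate orientation.

Fates forwarded to stage 2: `alignment_not_unique` and `ambiguous` fragments
always carry their per-locus overlap sets; `no_feature` fragments are
forwarded only when at least one locus overlaps at least one gene (an
overhang under strict mode, for instance). A fragment whose loci touch no
gene at all stays discarded.

## Stage-2 rules

The group universe is compiled across all samples before filtering. The
filter keeps a group with ≥ `min_reads` fragments (default 100) in
≥ `min_samples` samples; `min_samples` has no silently-scaled default in the
pipeline — the caller states it (the reference configuration is 13 of 27
datasets). Both thresholds are inclusive (`≥`).

Collapse merges redundancy among large groups: visiting groups of size
≥ `collapse_min_size` (default 5) smallest-first (ties by group id), a group
that is a strict subset of any surviving group is merged into its smallest
superset (ties by group id), counts summed per sample; the scan restarts
until a fixed point. Groups below the size threshold are never merged away.
Merging only removes sets — it never creates a new superset relation for an
already-visited group — so single-merge-at-a-time and restart-scan orders
reach the same fixed point; the tests verify this against an independent
naive implementation on random instances, plus idempotence and per-sample
count conservation. Merged groups keep the superset's id; no lineage record
is retained.

Size-1 groups are legitimate (all loci overlapping one gene, or some loci
intergenic) and are reported like any other row; `group_sizes` lets callers
split them out for inclusion in single-gene analyses.

## Expression units

`FPKM = (Rc/T)/Rm` and its inverse `Rc = FPKM·Rm·T` are applied literally; no
effective-length correction is performed (for full-length simulated reads,
annotated and effective length coincide, and the correction is a documented
overestimation bias for short transcripts). `Rm` is the total number of
fragments in the sample; for perfect simulated reads mapped equals total, and
for real data the choice is the caller's (pass whichever library size is
appropriate). MMG expression is length-free FPM. The log transform used for
distance matrices is `log2(FPM + 1)`; base and pseudocount are parameters.

## The simulator and what it does (not) emulate

The generator emulates the conditions the method is designed around: a
transcriptome mixing unique genes with duplicated families, perfect 100-bp
paired-end reads at a 250-bp insert, and exhaustive reporting of equally-best
loci. Defaults: fixed depth 1000 pairs per gene (uniform design); the
targeted design draws depth uniformly on [100, 100 000]; transcript lengths
are drawn uniformly on [400, 1500] bp (the 400-bp floor is forced by the
insert size, the ceiling is a realistic median-scale mRNA length chosen once);
uniform base composition; single-exon contiguous embedding in one synthetic
chromosome with 100-bp intergenic filler, with an optional multi-exon/intron
layout for exercising spliced (`N`-containing) alignments. Family members are
copies of one ancestral sequence with i.i.d. per-base substitution at the
stated divergence; divergence 0 gives identical copies. Transcripts of
*different* families/genes are regenerated until they share no read-length
k-mer, so multi-mapping occurs exactly where the design requests it.

Fragment geometry: start uniform on `[0, L − insert]`; mate 1 is the first
`read_len` bases of the fragment, mate 2 the reverse complement of its last
`read_len` bases; all qualities Q40. One named RNG (NumPy PCG64) drives the
whole generator, so a seed fixes every output byte.

The truth aligner indexes every read-length k-mer of every transcript and
reports all exact-match loci, paired at the insert spacing and projected to
genome coordinates through the known layout (producing `M`/`N` CIGARs under
the intron layout); the lowest-coordinate locus is primary, `NH` is the locus
count. For perfect reads this equals exhaustive string search, which the
tests assert against a naive all-positions scan.

Deliberately not modelled: sequencing errors and quality models, GC and
positional bias, fragment-length dispersion, incomplete or wrong annotation,
and spliced alignment inference. Passing tests therefore demonstrate the
correctness of the counting, grouping and accounting logic under ideal input
— they bound from above, not estimate, performance on real libraries.

## Evaluation harness

Observed-vs-expected agreement uses Pearson correlation on raw FPKM; missing
genes count as zero, and zero variance yields NaN rather than an error.
Gross-error classification flags genes assigned < 100 fragments (under) or
> 1900 (over) by at least one method — strict inequalities, tied to the
uniform 1000-pair design; for variable-depth designs a ratio-based classifier
(observed/expected outside [0.1, 1.9] by default) replaces the absolute
thresholds. Matrix exports (problematic-gene × method counts; 1 − Pearson
correlation distance over rows or columns of a log-FPM matrix) are provided
for heatmap/ordination workflows; rendering is out of scope, as are
differential-expression statistics themselves — the package exports
edgeR-ready matrices.

## Numerical and design choices

* Coordinates are converted once at the I/O boundary (GTF 1-based inclusive →
  0-based half-open internally); interval queries are half-open throughout.
* The reference transcript of a gene is the one maximising summed exon
  length, ties to the lexicographically smallest transcript id; per-gene
  characteristic statistics (exon lengths, exon count, transcript length,
  %GC, overlapping-fragment count) are computed on that transcript.
* MMG identity is the sorted, `|`-joined gene-id string — deterministic and
  greppable.
* Problem sizes in the shipped tests and the acceptance script (200 genes at
  depth 1000; 1000-instance filter/collapse randomisations) were chosen as
  the smallest scales at which the studied effects are unambiguous.

## Known limitations

Pair handling approximates, but is not bug-for-bug identical to, any specific
release of existing count tools. Orphan mates are counted and processed
single-end rather than rejected. The truth aligner only finds loci inside
annotated transcripts (exact for its perfect-read contract; not a general
aligner). Aligner-specific artefacts — e.g. differing `no_feature` rates
between spliced aligners under strict intersection — originate upstream of
counting and are out of scope.
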