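# Methods

This note documents the models and procedures implemented in `mitotx`, the
choices made where the published analysis leaves the details open, and what
the synthetic benchmark does and does not demonstrate.

## Coordinates and inputs

All internal coordinates are 1-based and fully inclusive, following GFF3;
BED export converts to 0-based half-open at the boundary and nowhere else.
Strand is the transcript strand. Alignments are consumed as coordinate-sorted
SAM/BAM; unmapped, secondary and supplementary records are skipped, strand is
taken from flag 0x10 and the mismatch count from the NM tag. Alignments are
treated as ungapped blocks (one query base per covered reference position):
gapped records are accepted with a warning, their deleted positions count
toward depth but contribute no base call, and inserted bases are ignored.
Read trimming, quality filtering and mapping are upstream of this package;
multi-mapped reads are taken as the aligner placed them.

## Coverage, windows, and the expression threshold

Depth at a position is the number of reads covering it, per strand. Window
profiles tile each chromosome with windows starting at 1, 1+step, …; the
last window is truncated at the chromosome end and its mean uses the
truncated length (the alternative — discarding partial windows — silently
drops chromosome ends, which matters on a genome made of many small
chromosomes). CPM normalizes a window's mean depth by the library's total
mapped reads × 10⁻⁶; mapped reads, not raw reads, are the denominator so
that libraries with different enrichment efficiencies stay comparable.
Where a single profile is needed from two replicate libraries, per-library
mean depths and per-library CPMs are averaged window-wise (rather than
pooling reads first); the two conventions differ only by replicate
library-size weighting.

The expression threshold is descriptive, not inferential: the
`tail_fraction` (default 0.05) upper quantile of window mean depths, under a
nearest-rank definition (smallest window mean with at most that fraction of
windows above it). Region calling itself uses the configured depth floor
(default 100×) with *strict* inequality, matching the published ">100×"
reading; the quantile is computed and reported so the floor can be judged
against the genome-wide distribution.

## Expressed regions, enrichment, cross-mapping

Windows above the floor merge into maximal regions when they overlap or abut
(configurable gap, default 0); region depth is then re-measured over the
merged footprint from the per-base track. A region is flagged as annotated
when any gene/tRNA/rRNA/pseudogene lies within 2 kb of it. Enrichment
classification compares the region's window CPM between conditions:
`mito_enriched` requires every mito-replicate CPM to exceed every
total-cellular CPM *and* the pooled fold to reach 2.0 (both configurable);
`tc_enriched` is the mirror; anything else is `ambiguous`. The published
analysis says only "overrepresented" — the replicate-concordance-plus-fold
rule is this package's operationalization, and the classification is by
construction antisymmetric under swapping the two conditions.

TC-enriched regions on the mitochondrial reference are the signature of
cross-mapped transcripts from plastid or nuclear insertions, not of
mitochondrial transcription. Separately, a sequence-based flag marks regions
sharing at least one exact k-mer (default k = 50, either orientation) with
an annotated gene located elsewhere: depth there may be inflated by reads
from the intact gene. k = 50 is half a read length — long enough that chance
matches are effectively impossible at this genome size, short enough to
catch sub-read-length duplications.

RPKM for a gene counts reads overlapping the feature on its coding strand,
divided by feature length in kb and library size in millions.

## 3′ drop-offs

For each gene the report compares mean coding-strand depth over the 100 nt
downstream of the stop codon with the final 100 nt of CDS
(`ratio_after_stop`); a ratio < 0.1 is called a sharp 3′ drop-off, the
signature of a processed transcript end at or near the stop. The published
account gives no numeric cutoff; 0.1 is configurable. An internal scan over
the CDS takes, at each position, the ratio of the mean depth in the 100 nt
after to the 100 nt before, and flags a mid-CDS collapse when the minimum
falls below the same cutoff — the pattern expected when the annotated ORF is
longer than the actual transcribed unit. Zero-depth denominators yield NaN
ratios and never flag. CDS shorter than the window are evaluated over the
available length with a warning.

## ORF screen

ORFs are ATG-to-stop spans under the standard genetic code (plant
mitochondria use the standard code; start = ATG, stops = TAA/TAG/TGA, all
configurable), on both strands in all three frames, with the stop codon
included in the span — so the 201-nt minimum is 66 codons plus stop. The
default reports maximal ORFs (first ATG after the previous stop per frame);
an `all_starts` mode reports one ORF per in-frame ATG, since the tool used
in the original analysis does not document which convention produced its
count. ORFs without a terminal stop are not reported. The distance filter
keeps ORFs strictly more than 2 kb (edge-to-edge; overlap = 0) from any
annotated gene-like feature on the same chromosome. Ranking annotates each
ORF with coding-strand mean depth and returns the top ⌈n·0.05⌉, flagging
those strictly above the 100× floor; ties break by (depth desc, chromosome,
start) so repeated runs agree.

## Small-RNA screen

The read filter retains 17–25 nt, perfectly matched (NM = 0) reads not
overlapping the coding strand of an annotated protein/tRNA/rRNA gene;
antisense overlap is retained, and pseudogenes do not exclude. A *stack* is
a group of filtered reads sharing exact (chromosome, start, length, strand);
it becomes a candidate when its pooled mito-enriched count is ≥ 50 and at
most one other filtered read (either strand, any library) overlaps its
footprint by ≥ 1 nt. The published text gives "minimum depth of 50×" in one
place and ">50×" in another; ≥ over pooled mito replicates is implemented
and configurable. Candidate sequences are taken from the genome
(reverse-complemented for − strand), so they always match the length field.
Mito overrepresentation requires the candidate's CPM to be higher in both
mito libraries than in both total-cellular libraries. The small-RNA/mRNA
relationship is summarized as the Pearson correlation of CPM over matched
fine windows (50/25); fewer than three windows or a zero-variance profile
raises an explicit undefined-correlation error rather than returning a
number.

## Editing caller

The pileup accumulates base calls per position per transcript strand, each
call tagged when it lies within `trim_margin` nt of its read's 3′ sequencing
end (the right edge of a + read, the left edge of a − read). A site is
called when, on a single strand, depth ≥ 100 and the most frequent
non-reference base reaches a frequency of ≥ 0.20 ("minimum of 20 %" is read
inclusively). The frequency denominator is all base calls on that strand at
the position, not ref+alt only — simpler and monotone in the variant count.
Only the single most frequent non-reference base is considered per column.
When both strands pass at one position the deeper strand is reported; an
exact tie keeps + and sets an ambiguity flag. For unannotated positions this
majority-strand rule is also how the transcript strand is assigned.

Canonical typing: C→U on the transcript, i.e. genomic C→T for a + site and
G→A for a − site; everything else is non-canonical and, in plant
mitochondria, almost always artifactual. Category assignment uses precedence
CDS > pseudogene > intron > UTR > IGS on the site's strand. Coding sites are
typed synonymous/nonsynonymous by translating the codon with and without the
edit (multi-exon CDS resolved through the exon chain; stop-gain counts as
nonsynonymous). Intronic sites within 20 nt (inclusive) of an exon boundary
are dropped outright — read mapping across splice junctions is unreliable
there; introns may be annotated explicitly or implied by exon gaps. UTR
covers unannotated positions within 2 kb of a same-strand CDS; beyond that
is IGS.

The end-trim re-analysis recomputes each site's depth and frequency with
base calls within 5 nt of read 3′ ends masked; sites that no longer meet the
calling thresholds are flagged as artifacts. The original analysis re-ran
mapping and variant calling on re-trimmed reads; for ungapped alignments,
in-pileup masking is equivalent and far cheaper. This reproduces the
published failure mode — non-canonical calls supported by terminal
mismatches (consistent with a 1-bp adapter remnant) vanish, canonical sites
are untouched.

Identical large repeats make one biological site appear at two coordinates.
Deduplication takes an explicit table of identical repeat pairs (pairs of
repeat features sharing a parent id), maps positions in the second copy onto
the first, and collapses sites with the same base change at homologous
offsets; the summary reports per-category counts before and after collapse
and mean frequency over unique, non-artifact sites (representative = the
deeper copy). Calling itself never suppresses repeat columns — the repeat
table drives deduplication explicitly, which avoids the silent-dropout
behaviour some variant callers show in repeated regions. Reference-assembly
errors masquerading as editing are out of detection scope (they require
genomic-DNA evidence).

## Synthetic data generator

The generator is a desk-scale stand-in for a 7-Mb, 63-chromosome genome:
8 chromosomes of 20–60 kb, 10 protein-coding genes (one with a 300-nt
intron, one with a mid-CDS coverage collapse at 60 % of the CDS), a tRNA, an
rRNA, an expressed pseudogene, five intergenic transcripts at 350–800×
(one hosting a 729-nt ORF constructed to be the only ORF in its region, one
carrying a verbatim 390-nt gene-fragment duplication, two on otherwise
"empty" chromosomes), plastid and nuclear insertions expressed mainly in
total-cellular libraries (mito 150× / TC 1200×), and an identical ~2-kb
repeat pair whose reads are assigned to either copy with probability 0.5.
Mito-enriched transcript depth defaults to 500×; total-cellular libraries
carry 10 % of the mito-origin signal; background "spurious transcription" is
uniform at 10× combined across both strands, consistent with the observed
near-ubiquitous low-level transcription of these genomes.

Editing sites are realized by flipping the base on each covering read
independently with the planted frequency (planted frequencies avoid the
0.15–0.25 band so the 20 % cutoff is never a coin flip); read-end artifact
sites are clusters of reads sharing an exact 3′ terminus whose final base
mismatches with probability 0.9 — the geometry created by a 1-bp adapter
remnant at a processed transcript end. The small-RNA assay plants six
discrete stacks with per-library counts chosen to exercise the pooled-depth
rule, the overrepresentation flag and the neighbor filter, plus degradation
smears (400 reads per mito library per expressed transcript, 80 % sense)
and sparse background at 0.04×. Background small-RNA reads avoid planted
stack footprints (±30 nt): stacks model discrete processed RNAs at
otherwise quiet loci, and this keeps the stack benchmark a test of the
stacking filter rather than of background collision chance.

Reads are emitted pre-mapped (SAM), skipping FASTQ and alignment: mapping is
out of scope and emitting alignments keeps the planted truth exact. All
randomness flows from one seeded generator, so a given spec and seed produce
byte-identical output. The generator does **not** model base-calling errors,
quality scores, indels, coverage biases (GC, position), fragment-length
distributions, or genuinely multi-mapping reads beyond the single planted
repeat — so passing recovery tests demonstrate the correctness of the
screening logic under clean mapping, not robustness to alignment noise.

## Problem sizes and numerical choices

The default synthetic benchmark is ~0.33 Mb of genome and ~450k alignments
across eight libraries; generation takes a few seconds and the full pipeline
under a minute on one core — sizes chosen so the whole truth-recovery suite
runs comfortably at a desk. Depth vectors are exact integer counts (delta
encoding + cumulative sum); window means use cumulative sums, so they are
exact up to float64. Nearest-rank quantiles involve no interpolation.
Tie-breaks (ORF ranking, strand assignment) are documented above and
deterministic. Degenerate inputs: empty profiles raise; zero-variance
correlation raises; zero-depth drop-off denominators produce NaN and no
flag; CDS whose concatenated length is not a codon multiple fail validation
up front.

## Known limitations

* Enrichment classification with two replicates has no variance model; it is
  a deterministic rule, not a test, and "ambiguous" is a real output.
* The editing caller assumes substitution-only alignments; indel-containing
  reads contribute depth but no calls, which slightly deflates frequencies
  in gapped regions.
* UTR assignment is distance-based (2 kb), not evidence-based; true distal
  UTRs and close intergenic transcripts are indistinguishable by design.
* The cross-mapping flag is sequence-based and symmetric: it marks risk of
  cross-mapping, it does not apportion reads between copies.
* Small-RNA candidate calling pools mito replicates for the depth rule;
  whether the original analysis pooled or required per-replicate depth is
  not stated.
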