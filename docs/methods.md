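# Methods

`methsuite` analyses post-alignment bisulfite sequencing (BS-Seq) data —
whole-genome or reduced-representation — downstream of a bisulfite
aligner. Its inputs are per-cytosine methylation calls (BS-Seeker2 CGmap
dialect), coordinate-sorted SAM alignments, a reference genome (FASTA),
gene annotation (GFF3/GTF) and TFBS intervals (BED). This note records
the models, the parameters that matter, the numerical choices, and what
the bundled simulator does and does not emulate.

## Coordinates and context classification

All internal coordinates are 1-based inclusive (the CGmap convention);
BED input is converted on read and back on write. A cytosine's context is
determined by its two 3′ neighbours *on its own strand*: CG if the next
base pairs as G; CHG if the next is H (= A, C or T) and the following
pairs as G; CHH if both are H. For a Crick-strand cytosine (a G on the
Watson reference) the neighbours are the complemented bases to the left.
Sites whose needed neighbours run off the chromosome or include N are
unassignable and excluded from every analysis; real pipelines differ in
how they treat these few edge sites and excluding them is the
conservative choice.

## Coverage survival (COV)

The fraction of cytosine sites covered by at least *d* reads, per
context, is the empirical survival function of per-site depth. The
denominator is **all** reference cytosines of the context, both strands
(a Watson C and the Crick G of the same CG are two sites, matching the
per-strand CGmap rows); sites absent from the CGmap or with zero total
count sit at depth 0. This makes the curve genome-relative — "x% of sites
at ≥20×" describes the genome, not merely the covered subset — and is
why the FASTA is a required input. Contexts are re-derived from the
genome rather than trusted from the file so the covered and uncovered
tallies share one definition.

## Methylation profiling (MET)

The level of any site set is the **weighted** methylation level,
Σ(methylated reads)/Σ(total reads), not the mean of per-site fractions;
it is robust to low-depth sites and is what most methylome studies
report. Sites need `min_depth` covering reads to be retained (default 4,
a common floor for trusting a per-site fraction; a CLI flag). Empty sets
are undefined (NA), never 0 — an uncovered window is a gap in the track,
not an unmethylated region.

Five summaries:

1. **Global**: weighted level per context.
2. **Distribution**: retained-site fractions in ten level bins, left-closed
   with the last bin closed at 1.0 so a fully methylated site is counted.
3. **Elements**: the genome is partitioned into promoter (the 1,000 bp 5′
   of the TSS, strand-aware, clamped at chromosome ends), gene body
   (TSS–TTS), exon, intron (gene body minus exons; the two tile the body
   exactly) and IGN (intergenic non-coding: outside all gene bodies and
   promoters). Classes are deliberately not mutually exclusive — a base
   can be exon of one gene and promoter of another; a retained site
   contributes to every class containing it, plus a "genome" row that
   equals the global summary exactly.
4. **Chromosome track**: weighted level in non-overlapping windows
   (default 100 kb, enough to smooth site-to-site noise while resolving
   chromosome-arm structure such as pericentromeric hypermethylation).
5. **Gene table**: per-gene weighted levels of promoter / gene body /
   exon / intron per context, using each gene's own intervals; exon+intron
   count sums equal the gene-body sums per gene by construction, which the
   tests assert as an invariant.

## TFBS metaprofile (TXN)

Methylation around binding sites is summarised by pooling counts from
every retained cytosine within ±`flank` (default 1,500 bp) of each site's
anchor into `tile`-wide bins (default 30 bp, so 100 tiles). The anchor is
the left-of-centre base of the interval (⌊(start+end)/2⌋ — binding sites
vary in length, so profiles are centre-aligned). Minus-strand sites have
their offsets mirrored so profiles are in the factor's 5′→3′ frame;
strandless BED rows are treated as +. A cytosine near two sites
contributes to both (incidence pooling, standard metaplot practice). The
baseline is the identical computation pooled over *every* interval in the
BED — the "average of all factors" curve a specific factor is compared
against. The default context is CG (`--context` switches); no
significance test is attached to a dip, only the two curves.

## Bisulfite-aware SNP calling (SNP)

Bisulfite conversion destroys some genotype evidence: a T in a
Watson-converted (C→T) read may be a genuine T or a converted
unmethylated C, and an A in a Crick-converted (G→A) read likewise may be
a converted G. The pileup therefore keeps Watson- and Crick-derived
counts separate (the conversion strand comes from aligner tags, falling
back to the SAM reverse flag), and masking removes Watson-T and Crick-A
observations at every position before genotyping. Calls use only the
remaining informative depth:

* **homozygous** — top non-reference allele ≥ `hom_frac` (default 0.9) of
  informative depth;
* **heterozygous** — the two most frequent alleles each ≥
  `het_minor_frac` (default 0.2), jointly ≥ `hom_frac`, at least one
  non-reference;
* minimum informative depth 5; base quality ≥ 20 when qualities are
  present.

These thresholds are conservative majority-vote heuristics, all exposed
as flags; no genotype likelihood model is fitted. Because a reference C/G
position is only callable from the opposite strand's evidence,
heterozygous calls involving a C↔T or G↔A pair are intrinsically
suppressed — documented behaviour of strand-aware BS genotyping, not a
defect.

## Read-depth CNV calling (CNV)

Per-base depth from aligned reference footprints is averaged in fixed
bins (default 10 kb — coarse enough that WGBS-scale coverage gives stable
bin means, fine enough to localise segmental events), then divided by the
genome-wide median of non-zero bins. Median (not mean) and genome-wide
(not per-chromosome) normalisation keeps a whole-chromosome aneuploidy
visible as a chromosome-long shift. Segments are maximal runs of ≥
`min_run` (default 3) consecutive bins at or beyond a threshold. Gain
threshold 1.5 is the midpoint between normal (1×) and a single-copy
duplication (2×); the loss threshold is likewise the midpoint between
normal and a heterozygous deletion (0.5×), i.e. 0.75 — a threshold *at*
0.5 would turn every true het-deletion bin into a coin flip against its
own expectation and make contiguous runs undetectable. No GC correction
or HMM/CBS segmentation is applied; breakpoints are bin-resolution.

## Synthetic data generator

The simulator emulates the full input stack with planted, recoverable
truth: an i.i.d. genome at configurable GC (default 0.36, plant-like);
non-overlapping genes with exon/intron structure placed clear of
chromosome edges; TFBS in intergenic space; a methylome where every
classifiable cytosine draws depth ~ Poisson(`depth_mean`, default 10) and
methylated count ~ Binomial(depth, p); and error-free ungapped 75 bp
reads, conversion-strand assigned 50/50, with unmethylated cytosines
converted at rate `conversion` (default 0.99) on the read's own strand.

Site probabilities are point masses at the per-context targets (defaults
CG 0.8 / CHG 0.3 / CHH 0.1 — a strongly methylated genic CG landscape
against low CHH background), so weighted-level recovery is exact in
expectation; promoters can be overridden (e.g. CG 0.2) to plant
hypomethylation. TFBS dips default to a **V shape** — deepest
(`dip_level`, 0.1) at the anchor, ramping linearly to background at
±`dip_width` (90 bp): real protection footprints decay with distance, and
a graded dip makes "the profile minimum is central" a well-posed recovery
target, which a perfectly flat dip would not be (all fully-dipped tiles
would share one expectation and the argmin would be noise). A flat dip
remains available (`dip_shape="flat"`). SNPs are planted at A/T reference
positions (so conversion cannot mimic them), hom or het with a random
alternate allele; copy-number segments scale the local read-start rate.

Everything is drawn from one integer-seeded generator: identical config +
seed reproduces byte-identical FASTA/GFF/BED/CGmap/SAM output, and the
planted truth is serialised to JSON alongside.

What the simulator does **not** emulate: sequencing errors (a knob,
default 0, so SNP precision/recall isolates caller logic), PCR
duplicates, mapping ambiguity/bias, indels and CIGAR complexity (covered
by handcrafted fixtures in the tests), RRBS fragment selection, GC-biased
coverage, and spatially correlated methylation. Passing recovery tests
therefore demonstrates correctness of the analysis logic under clean
conditions, not robustness to real-library artifacts.

## Problem sizes and test design

Recovery scenarios are sized so the whole suite runs in about a minute:
200 kb genomes give >10,000 sites per context for level recovery (±0.01
at Poisson(10) depth), 300 kb with 20 genes or 40 TFBS for element and
dip recovery, 150 kb at 30× for 150 planted SNPs, 1 Mb at 20× for CNV
segments of 10 and 8 bins, and 20 independent 200 kb uniform-coverage
genomes for the segmentation false-positive check. Oracles are
independent re-implementations: a string-based context classifier checked
exhaustively over all 5-mers, an expanded-multiset survival function, a
per-read per-base pileup enumeration, and per-base depth arrays.

## Known limitations

* The CGmap reader fixes the 8-column BS-Seeker2 dialect; other callers'
  outputs need conversion.
* SAM is read as plain text (BAM/CRAM should be converted with
  `samtools view` first); pileups are held as per-chromosome arrays,
  appropriate for the genome sizes this suite targets rather than
  mammalian-scale whole genomes on minimal RAM.
* No differential-methylation statistics, no dip significance test, no
  indel calling, no sub-bin CNV breakpoints.
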