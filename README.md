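# methsuite

Post-alignment analysis of bisulfite sequencing (BS-Seq) data — both
whole-genome (WGBS) and reduced-representation (RRBS) — for researchers
profiling DNA methylation. Downstream of a bisulfite aligner, `methsuite`
takes per-cytosine methylation calls (BS-Seeker2 CGmap), coordinate-sorted
SAM alignments, a reference genome (FASTA), gene annotation (GFF3/GTF)
and transcription-factor binding sites (BED), and produces:

* **cov** — reverse cumulative coverage of cytosine sites per context
  (CG / CHG / CHH, H ∈ {A,C,T}), genome-relative: uncovered sites count
  at depth 0;
* **met** — methylation profiling at five scales: global levels, level
  distribution in 10% bins, genomic elements (promoter = 1 kb upstream of
  the TSS, gene body = TSS–TTS, exon, intron, intergenic non-coding),
  chromosome-wide windowed track, and a gene-centric table;
* **txn** — methylation metaprofile in 30 bp tiles within ±1,500 bp of
  TFBS centres, with an all-TFBS baseline for comparison;
* **snp** — bisulfite-aware SNP calling: conversion-confounded
  observations (Watson-read T, Crick-read A) are masked and genotypes are
  called from the informative depth only;
* **cnv** — read-depth copy-number calling: binned depth, genome-median
  normalisation, and maximal gain/loss runs;
* **simulate** — a seeded generator of all five input files with planted
  truth (methylation levels, promoter hypomethylation, TFBS dips, SNPs,
  CNV segments), used throughout the test suite.

Throughout, the methylation level of a site set is the *weighted* level

```
level(S) = Σ_{i∈S} mC_i / Σ_{i∈S} C_i
```

(methylated read count over total read count, pooled), and a cytosine's
context is defined by its two 3′ neighbours on its own strand. See
`docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

Simulate a 120 kb genome with 8 genes, 10 TFBS, promoter CG
hypomethylation (0.2 vs the 0.8 background), 18 SNPs and a 2× duplication,
then profile it:

```sh
cat > config.yaml <<EOF
chrom_lengths: {chr1: 120000}
n_genes: 8
n_tfbs: 10
n_hom_snps: 12
n_het_snps: 6
promoter_levels: {CG: 0.2}
cnv_segments: [[chr1, 80001, 110000, 2.0]]
EOF
methsuite simulate --config config.yaml --seed 7 --outdir sim
methsuite met --cgmap sim/methylome.cgmap --gff sim/genes.gff3 \
              --fasta sim/genome.fa --window-size 10000 --outdir met
methsuite snp --sam sim/reads.sam --fasta sim/genome.fa --outdir snp
methsuite cnv --sam sim/reads.sam --fasta sim/genome.fa \
              --bin-size 5000 --outdir cnv
```

`met/global.tsv` then contains the genome-wide weighted levels, close to
the planted CG 0.8 / CHG 0.3 / CHH 0.1 (CG is pulled down by the
hypomethylated promoters):

```
context  level     mc_sum  total_sum  n_sites
CG       0.754292  58217   77181      7665
CHG      0.300173  19076   63550      6292
CHH      0.0997322 28975   290528     28778
```

and the CG rows of `met/elements.tsv` recover the planted promoter
hypomethylation (0.195 vs 0.806 in gene bodies; exon and intron agree
with the gene body they tile):

```
element    context  mc_sum  total_sum  n_sites  level
promoter   CG       1079    5541       548      0.19473
gene_body  CG       11458   14208      1406     0.806447
exon       CG       6406    7913       776      0.809554
intron     CG       5052    6295       630      0.802542
IGN        CG       45680   57432      5711     0.795375
```

The SNP caller reports exactly the planted variants ("snp: 12 homozygous,
6 heterozygous calls"), e.g. the first homozygous row of
`snp/snp_hom.tsv`:

```
chrom  pos   ref  alleles  counts  fractions  depth
chr1   6011  A    T        7       1.000      7
```

and `cnv/cnv_segments.tsv` recovers the duplication with bin-exact
boundaries and a mean depth ratio near 2:

```
chrom  start  end     direction  mean_ratio  n_bins
chr1   80001  110000  gain       1.96241     6
```

Each subcommand also writes a matching figure (PNG) next to its tables.

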