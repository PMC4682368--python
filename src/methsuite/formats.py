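"""Readers, writers and reference-context classification.

Every analysis in the suite flows through a handful of external formats:
a reference genome (FASTA), per-cytosine methylation calls (BS-Seeker2
CGmap dialect), gene annotation (GFF3/GTF), transcription-factor binding
sites (BED) and bisulfite read alignments (SAM).  This module owns those
formats plus the CG/CHG/CHH context classifier that everything else
depends on.

Coordinate convention: 1-based inclusive everywhere (the CGmap
convention).  BED input is converted on read and converted back on write;
GFF coordinates are used as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
CONTEXTS = ("CG", "CHG", "CHH")
H_BASES = frozenset("ACT")

#: CIGAR operation alphabet: (consumes_query, consumes_reference)
CIGAR_CONSUMES = {
    "M": (True, True), "=": (True, True), "X": (True, True),
    "I": (True, False), "S": (True, False),
    "D": (False, True), "N": (False, True),
    "H": (False, False), "P": (False, False),
}
_CIGAR_OPS = "MIDNSHP=X"


class FormatError(ValueError):
    """Malformed input file."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: an uppercase nucleotide string over {A,C,G,T,N}."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CytosineRecord:
    """One reference cytosine with its methylation evidence.

    ``strand_base`` is ``C`` for a Watson-strand cytosine and ``G`` for a
    Crick-strand cytosine (the CGmap convention of reporting the base seen
    on the Watson strand).  ``level`` is ``None`` for uncovered sites.
    """

    chrom: str
    pos: int  # 1-based
    strand_base: str  # 'C' or 'G'
    context: str  # CG / CHG / CHH
    level: float | None
    mc_count: int
    total_count: int
    sub_context: str = ""


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand and exon structure.

    TSS is the strand-aware 5' end (``start`` on +, ``end`` on -); TTS the
    3' end.  Exons are 1-based inclusive, sorted, non-overlapping and lie
    within ``[start, end]``.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gene body minus exons, as sorted 1-based inclusive intervals."""
        out = []
        cursor = self.start
        for s, e in self.exons:
            if s > cursor:
                out.append((cursor, s - 1))
            cursor = max(cursor, e + 1)
        if cursor <= self.end:
            out.append((cursor, self.end))
        return tuple(out)


@dataclass(frozen=True)
class TFBSRecord:
    """One transcription-factor binding interval (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    name: str = "TFBS"
    strand: str = "."  # '+', '-' or '.' (unknown)

    @property
    def center(self) -> int:
        # left-of-center base for even-length intervals
        return (self.start + self.end) // 2


@dataclass
class Alignment:
    """A mapped bisulfite read, decoupled from the SAM parser.

    ``pos`` is the 1-based leftmost reference coordinate; ``cigar`` a list
    of (op, length) pairs; ``bs_strand`` is 'watson' (C->T converted
    library) or 'crick' (G->A converted), or None if undeterminable.
    """

    name: str
    chrom: str
    pos: int
    seq: str
    cigar: list[tuple[str, int]]
    bs_strand: str | None
    quals: list[int] | None = None

    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar if CIGAR_CONSUMES[op][1])

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_index_0based, reference_pos_1based) for every
        aligned base; deletions/skips advance the reference, insertions
        and soft clips advance the query, neither is yielded."""
        q, r = 0, self.pos
        for op, n in self.cigar:
            cq, cr = CIGAR_CONSUMES[op]
            if cq and cr:
                for k in range(n):
                    yield q + k, r + k
            if cq:
                q += n
            if cr:
                r += n

    def reference_blocks(self) -> list[tuple[int, int]]:
        """Maximal aligned (match) reference intervals, 1-based inclusive;
        deletion gaps split blocks and contribute no coverage."""
        blocks = []
        r = self.pos
        for op, n in self.cigar:
            cq, cr = CIGAR_CONSUMES[op]
            if cq and cr:
                if blocks and blocks[-1][1] == r - 1:
                    blocks[-1] = (blocks[-1][0], r + n - 1)
                else:
                    blocks.append((r, r + n - 1))
            if cr:
                r += n
        return [(s, e) for s, e in blocks]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Parse a FASTA file into a name -> GenomeSequence map.

    Sequences are uppercased.  Duplicate headers, sequence data before the
    first header, and empty files are errors (with line numbers where a
    line is at fault).
    """
    genome: dict[str, GenomeSequence] = {}
    name: str | None = None
    chunks: list[str] = []

    def flush():
        if name is not None:
            genome[name] = GenomeSequence(name, "".join(chunks).upper())

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                flush()
                if header in genome:
                    raise FormatError(
                        f"{path}: duplicate FASTA record {header!r} at line {lineno}")
                name, chunks = header, []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}")
                chunks.append(line)
        flush()
    if not genome:
        raise FormatError(f"{path}: empty FASTA file")
    return genome


def write_fasta(genome: Mapping[str, GenomeSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name].seq
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_context(genome: Mapping[str, GenomeSequence], chrom: str,
                     pos: int, strand_base: str) -> str | None:
    """Classify the cytosine at ``pos`` as CG, CHG or CHH.

    For a Watson cytosine (``strand_base='C'``) the two 3' neighbours are
    the bases to the right; for a Crick cytosine (``strand_base='G'``,
    i.e. a G on the Watson strand) they are the bases to the left, read on
    the reverse complement.  Returns None (not-assignable) when the needed
    neighbours run off the chromosome or include N.
    """
    seq = genome[chrom].seq
    i = pos - 1
    base = seq[i]
    if strand_base == "C":
        if base != "C":
            raise ValueError(
                f"{chrom}:{pos} reference base is {base}, expected C")
        n1 = seq[i + 1] if i + 1 < len(seq) else None
        n2 = seq[i + 2] if i + 2 < len(seq) else None
    elif strand_base == "G":
        if base != "G":
            raise ValueError(
                f"{chrom}:{pos} reference base is {base}, expected G")
        n1 = seq[i - 1].translate(COMPLEMENT) if i - 1 >= 0 else None
        n2 = seq[i - 2].translate(COMPLEMENT) if i - 2 >= 0 else None
    else:
        raise ValueError(f"strand_base must be 'C' or 'G', got {strand_base!r}")

    if n1 == "G":
        return "CG"
    if n1 is None or n1 not in H_BASES:
        return None
    if n2 == "G":
        return "CHG"
    if n2 is None or n2 not in H_BASES:
        return None
    return "CHH"


def sub_context(genome: Mapping[str, GenomeSequence], chrom: str, pos: int,
                strand_base: str) -> str:
    """Dinucleotide sub-context (C plus its immediate 3' neighbour on the
    cytosine's own strand), e.g. CG / CA / CT / CC; 'C-' at an edge."""
    seq = genome[chrom].seq
    i = pos - 1
    if strand_base == "C":
        n1 = seq[i + 1] if i + 1 < len(seq) else "-"
    else:
        n1 = seq[i - 1].translate(COMPLEMENT) if i - 1 >= 0 else "-"
    return "C" + n1


# ---------------------------------------------------------------------------
# CGmap
# ---------------------------------------------------------------------------

def read_cgmap(path: str | Path) -> Iterator[CytosineRecord]:
    """Stream CytosineRecords from a BS-Seeker2 CGmap file.

    Columns: chrom, strand base (C/G), 1-based position, context, dinucleotide
    sub-context, level, methylated count, total count.  Lines whose context
    is not CG/CHG/CHH (e.g. ``--``) are skipped; the skip count is logged.
    """
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise FormatError(
                    f"{path}: expected 8 tab-separated columns at line "
                    f"{lineno}, got {len(fields)}")
            chrom, strand_base, pos_s, context, sub, level_s, mc_s, tot_s = fields
            if context not in CONTEXTS:
                skipped += 1
                continue
            try:
                pos = int(pos_s)
                mc = int(mc_s)
                total = int(tot_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric field at line {lineno}: {exc}") from None
            level = None if total == 0 else float(level_s)
            yield CytosineRecord(chrom, pos, strand_base, context, level,
                                 mc, total, sub)
    if skipped:
        logger.info("read_cgmap(%s): skipped %d non-CG/CHG/CHH lines",
                    path, skipped)


def format_level(mc: int, total: int) -> str:
    return "na" if total == 0 else f"{mc / total:.4f}"


def write_cgmap(records: Iterable[CytosineRecord], path: str | Path) -> None:
    """Write records in the canonical 8-column dialect (level re-derived
    from the counts as %.4f, 'na' for uncovered sites)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join((
                r.chrom, r.strand_base, str(r.pos), r.context,
                r.sub_context or r.context[:2],
                format_level(r.mc_count, r.total_count),
                str(r.mc_count), str(r.total_count))) + "\n")


# ---------------------------------------------------------------------------
# gene annotation (GFF3 / GTF via gffutils)
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Load gene models (with exons) from a GFF3 or GTF file.

    Exons are linked to genes through any depth of Parent linkage (gene ->
    mRNA -> exon or gene -> exon).  Genes without exons get a single exon
    spanning the gene; exons leaking outside the gene span are clamped
    with a warning; genes of unknown strand are dropped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        if g.strand not in ("+", "-"):
            logger.warning("gene %s: unknown strand %r, dropped", g.id, g.strand)
            continue
        exons = []
        for ex in db.children(g.id, featuretype="exon"):
            s, e = ex.start, ex.end
            if s < g.start or e > g.end:
                logger.warning("exon %s-%s outside gene %s span, clamped",
                               s, e, g.id)
                s, e = max(s, g.start), min(e, g.end)
            if s <= e:
                exons.append((s, e))
        if not exons:
            exons = [(g.start, g.end)]
        exons.sort()
        merged: list[tuple[int, int]] = []
        for s, e in exons:  # overlapping exon rows (isoforms) are unioned
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        genes.append(GeneModel(g.id, g.seqid, g.strand, g.start, g.end,
                               tuple(merged)))
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels as minimal GFF3 (gene rows with exon children)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tmethsuite\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tmethsuite\texon\t{s}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{k};"
                         f"Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_tfbs_bed(path: str | Path) -> list[TFBSRecord]:
    """Read TFBS intervals from BED (>=3 columns), converting the 0-based
    half-open file coordinates to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(
                    f"{path}: BED needs >=3 columns at line {lineno}")
            try:
                start0, end0 = int(f[1]), int(f[2])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric BED coordinate at line {lineno}") from None
            if start0 >= end0:
                raise FormatError(
                    f"{path}: empty/inverted BED interval at line {lineno}")
            name = f[3] if len(f) > 3 and f[3] else "TFBS"
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append(TFBSRecord(f[0], start0 + 1, end0, name, strand))
    return out


def write_tfbs_bed(records: Iterable[TFBSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\t0\t"
                     f"{r.strand}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def bisulfite_strand(read: pysam.AlignedSegment) -> str | None:
    """Determine the bisulfite conversion strand of a read.

    Prefers the aligner tag (Bismark/BS-Seeker2 style ``XG:Z:CT``/``GA``,
    or ``XO:Z:+...``/``-...``); falls back to the SAM reverse flag.
    """
    if read.has_tag("XG"):
        v = read.get_tag("XG")
        if v in ("CT", "GA"):
            return "watson" if v == "CT" else "crick"
    if read.has_tag("XO"):
        v = str(read.get_tag("XO"))
        if v.startswith(("+", "-")):
            return "watson" if v.startswith("+") else "crick"
    if read.flag is not None:
        return "crick" if read.is_reverse else "watson"
    return None


def read_alignments(path: str | Path, require_sorted: bool = False
                    ) -> Iterator[Alignment]:
    """Stream mapped reads from a SAM file as Alignment objects.

    Unmapped reads and reads without sequence are skipped; reads whose
    bisulfite strand cannot be determined are skipped with a counted
    warning.  With ``require_sorted`` an out-of-order record raises,
    instructing the caller to coordinate-sort the file first.
    """
    n_unstranded = 0
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.query_sequence is None:
                continue
            chrom = read.reference_name
            pos = read.reference_start + 1
            if require_sorted:
                if last is not None and chrom != last[0]:
                    if chrom in seen_chroms:
                        raise FormatError(
                            f"{path} is not coordinate-sorted (chromosome "
                            f"{chrom} recurs); sort it, e.g. `samtools sort`")
                    seen_chroms.add(last[0])
                elif last is not None and pos < last[1]:
                    raise FormatError(
                        f"{path} is not coordinate-sorted at {chrom}:{pos}; "
                        "sort it, e.g. `samtools sort`")
                last = (chrom, pos)
            strand = bisulfite_strand(read)
            if strand is None:
                n_unstranded += 1
                continue
            cigar = read.cigartuples or [(0, len(read.query_sequence))]
            quals = list(read.query_qualities) if read.query_qualities is not None else None
            yield Alignment(
                name=read.query_name, chrom=chrom, pos=pos,
                seq=read.query_sequence,
                cigar=[(_CIGAR_OPS[op], n) for op, n in cigar],
                bs_strand=strand, quals=quals)
    if n_unstranded:
        logger.warning("read_alignments(%s): %d reads without determinable "
                       "bisulfite strand skipped", path, n_unstranded)
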