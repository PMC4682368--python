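"""Synthetic bisulfite-sequencing data with planted ground truth.

Generates the five inputs the analysis modules consume — reference genome
(FASTA), per-cytosine methylation calls (CGmap), gene annotation (GFF3),
TFBS intervals (BED) and converted-read alignments (SAM) — from a single
seeded configuration, together with a TruthSet recording every planted
quantity (per-context weighted levels, promoter hypomethylation, TFBS
dips, SNPs, copy-number segments) so recovery can be asserted exactly.

The generator is deterministic: identical config + seed reproduces
byte-identical output files.  Reads are error-free by default and
ungapped (read-length M CIGARs); CIGAR complexity is exercised by
handcrafted fixtures in the tests, not here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pysam

from .formats import (Alignment, CONTEXTS, CytosineRecord, GeneModel,
                      GenomeSequence, TFBSRecord, classify_context,
                      format_level, sub_context, write_fasta,
                      write_gene_annotation, write_tfbs_bed)

_BASE_ORDER = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G, _T, _A = (ord(x) for x in "CGTA")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions the
    recovery tests assert against.

    ``levels`` are the planted per-context weighted methylation levels;
    ``depth_mean`` the Poisson mean of per-site CGmap depth;
    ``aln_depth_mean`` the target read depth of the alignment simulation;
    ``conversion`` the bisulfite conversion rate of unmethylated C.
    ``cnv_segments`` entries are (chrom, start, end, copy_ratio).
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 200_000})
    gc: float = 0.36
    levels: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.3, "CHH": 0.1})
    depth_mean: float = 10.0
    # gene geometry
    n_genes: int = 20
    gene_length: tuple[int, int] = (2_000, 4_000)
    exons_per_gene: tuple[int, int] = (2, 4)
    promoter_len: int = 1_000
    promoter_levels: dict[str, float] | None = None
    # TFBS geometry
    n_tfbs: int = 0
    tfbs_length: int = 10
    factors: tuple[str, ...] = ("TFA",)
    dip_width: int = 90
    dip_level: float = 0.1
    dip_shape: str = "graded"  # 'graded' (V-shaped) or 'flat'
    # alignments
    read_length: int = 75
    aln_depth_mean: float = 30.0
    conversion: float = 0.99
    error_rate: float = 0.0
    n_hom_snps: int = 0
    n_het_snps: int = 0
    cnv_segments: tuple[tuple[str, int, int, float], ...] = ()


@dataclass
class TruthSet:
    """Planted quantities, serialised beside the generated files."""

    levels: dict[str, float]
    promoter_levels: dict[str, float] | None = None
    dip: dict | None = None
    snps: list[dict] = field(default_factory=list)
    cnv_segments: list[list] = field(default_factory=list)
    realized_levels: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# genome, genes, TFBS
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[dict[str, GenomeSequence], list[GeneModel],
                               list[TFBSRecord]]:
    """Random i.i.d. genome at the configured GC, non-overlapping genes
    with exon/intron structure placed clear of chromosome edges, and TFBS
    intervals in intergenic space."""
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2,
                  (1 - config.gc) / 2])
    genome: dict[str, GenomeSequence] = {}
    for chrom, L in config.chrom_lengths.items():
        seq = rng.choice(_BASE_ORDER, size=L, p=p).tobytes().decode("ascii")
        genome[chrom] = GenomeSequence(chrom, seq)

    genes = _place_genes(config, rng)
    tfbs = _place_tfbs(config, rng, genes)
    return genome, genes, tfbs


def _place_genes(config: SimulationConfig, rng: np.random.Generator
                 ) -> list[GeneModel]:
    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return genes
    margin = config.promoter_len + 500
    total_len = sum(config.chrom_lengths.values())
    gid = 0
    for chrom, L in config.chrom_lengths.items():
        n_here = max(0, round(config.n_genes * L / total_len))
        if gid + n_here > config.n_genes or chrom == list(config.chrom_lengths)[-1]:
            n_here = config.n_genes - gid
        if n_here == 0:
            continue
        usable = L - 2 * margin
        slot = usable // n_here
        if slot < config.gene_length[1] + config.promoter_len + 200:
            raise ValueError(
                f"cannot fit {n_here} genes of length up to "
                f"{config.gene_length[1]} on {chrom} (length {L})")
        for k in range(n_here):
            slot_start = margin + k * slot
            glen = int(rng.integers(config.gene_length[0],
                                    config.gene_length[1] + 1))
            wiggle = slot - glen - config.promoter_len - 100
            start = slot_start + config.promoter_len + int(rng.integers(0, wiggle + 1))
            end = start + glen - 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gid + 1:03d}", chrom, strand,
                                   start, end,
                                   _make_exons(rng, start, end, config)))
            gid += 1
    return genes


def _make_exons(rng: np.random.Generator, start: int, end: int,
                config: SimulationConfig) -> tuple[tuple[int, int], ...]:
    k = int(rng.integers(config.exons_per_gene[0],
                         config.exons_per_gene[1] + 1))
    if k == 1 or end - start < 4 * k:
        return ((start, end),)
    # 2(k-1) distinct internal breakpoints -> k exons with introns between
    cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * (k - 1),
                              replace=False))
    bounds = [start, *cuts.tolist(), end]
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        s = bounds[i] if i == 0 else bounds[i] + 1
        exons.append((s, bounds[i + 1]))
    return tuple(exons)


def _place_tfbs(config: SimulationConfig, rng: np.random.Generator,
                genes: list[GeneModel]) -> list[TFBSRecord]:
    if config.n_tfbs == 0:
        return []
    # intergenic complement of gene bodies and promoters, with a buffer
    # wide enough that dips stay intergenic
    buffer = config.promoter_len + config.dip_width + 10
    blocked: dict[str, list[tuple[int, int]]] = {
        c: [] for c in config.chrom_lengths}
    for g in genes:
        blocked[g.chrom].append((g.start - buffer, g.end + buffer))
    free: list[tuple[str, int, int]] = []
    edge = config.dip_width + 10
    for chrom, L in config.chrom_lengths.items():
        cursor = 1 + edge
        for s, e in sorted(blocked[chrom]):
            if s - 1 >= cursor + config.tfbs_length:
                free.append((chrom, cursor, s - 1))
            cursor = max(cursor, e + 1)
        if L - edge >= cursor + config.tfbs_length:
            free.append((chrom, cursor, L - edge))
    widths = np.array([e - s + 1 - config.tfbs_length for _, s, e in free],
                      dtype=float)
    if len(free) == 0 or widths.sum() <= 0:
        raise ValueError("no intergenic space left to place TFBS intervals")
    out = []
    for i in range(config.n_tfbs):
        j = int(rng.choice(len(free), p=widths / widths.sum()))
        chrom, s, e = free[j]
        start = int(rng.integers(s, e - config.tfbs_length + 2))
        out.append(TFBSRecord(chrom, start, start + config.tfbs_length - 1,
                              config.factors[i % len(config.factors)],
                              "+" if rng.random() < 0.5 else "-"))
    out.sort(key=lambda t: (t.chrom, t.start))
    return out


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _cytosine_table(genome: Mapping[str, GenomeSequence], chrom: str
                    ) -> list[tuple[int, str, str, str]]:
    """(pos, strand_base, context, sub_context) for every classifiable
    cytosine of one chromosome, both strands, in position order."""
    rows = []
    seq = genome[chrom].seq
    for i, base in enumerate(seq):
        if base in "CG":
            ctx = classify_context(genome, chrom, i + 1, base)
            if ctx is not None:
                rows.append((i + 1, base, ctx,
                             sub_context(genome, chrom, i + 1, base)))
    return rows


def _site_probability(config: SimulationConfig, pos: int, ctx: str,
                      promoter_mask: np.ndarray | None,
                      dip_frac: np.ndarray | None) -> float:
    p = config.levels[ctx]
    if (config.promoter_levels and promoter_mask is not None
            and promoter_mask[pos] and ctx in config.promoter_levels):
        p = config.promoter_levels[ctx]
    if dip_frac is not None and not np.isnan(dip_frac[pos]):
        f = dip_frac[pos]  # 0 at the anchor, 1 at the dip edge
        if config.dip_shape == "flat":
            p = config.dip_level
        else:
            p = config.dip_level + (p - config.dip_level) * f
    return p


def _modifier_arrays(config: SimulationConfig, genes: list[GeneModel],
                     tfbs: list[TFBSRecord]
                     ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    promoter_mask = {c: np.zeros(L + 1, dtype=bool)
                     for c, L in config.chrom_lengths.items()}
    for g in genes:
        L = config.chrom_lengths[g.chrom]
        if g.strand == "+":
            s, e = g.start - config.promoter_len, g.start - 1
        else:
            s, e = g.end + 1, g.end + config.promoter_len
        s, e = max(s, 1), min(e, L)
        if s <= e:
            promoter_mask[g.chrom][s:e + 1] = True
    dip_frac = {c: np.full(L + 1, np.nan)
                for c, L in config.chrom_lengths.items()}
    w = config.dip_width
    for t in tfbs:
        L = config.chrom_lengths[t.chrom]
        c = t.center
        lo, hi = max(1, c - w), min(L, c + w)
        offs = np.abs(np.arange(lo, hi + 1) - c) / w
        cur = dip_frac[t.chrom][lo:hi + 1]
        dip_frac[t.chrom][lo:hi + 1] = np.fmin(cur, offs)
    return promoter_mask, dip_frac


def simulate_methylome(config: SimulationConfig,
                       genome: Mapping[str, GenomeSequence],
                       genes: list[GeneModel], tfbs: list[TFBSRecord],
                       rng: np.random.Generator
                       ) -> tuple[list[CytosineRecord], TruthSet]:
    """Draw a methylome over every classifiable cytosine (both strands).

    Each site gets a methylation probability from its context's planted
    level, overridden inside promoters (``promoter_levels``) and TFBS dips
    (``dip_level``/``dip_shape``); depth ~ Poisson(depth_mean) and the
    methylated count ~ Binomial(depth, p).  Depth-0 sites are emitted with
    total_count 0.
    """
    promoter_mask, dip_frac = _modifier_arrays(config, genes, tfbs)
    records: list[CytosineRecord] = []
    mc_sum = dict.fromkeys(CONTEXTS, 0)
    tot_sum = dict.fromkeys(CONTEXTS, 0)
    for chrom in config.chrom_lengths:
        table = _cytosine_table(genome, chrom)
        probs = np.array([
            _site_probability(config, pos, ctx, promoter_mask[chrom],
                              dip_frac[chrom])
            for pos, _, ctx, _ in table])
        depth = rng.poisson(config.depth_mean, size=len(table))
        mc = rng.binomial(depth, probs)
        for (pos, base, ctx, sub), d, m in zip(table, depth, mc):
            level = None if d == 0 else m / d
            records.append(CytosineRecord(chrom, pos, base, ctx, level,
                                          int(m), int(d), sub))
            mc_sum[ctx] += int(m)
            tot_sum[ctx] += int(d)
    truth = TruthSet(
        levels=dict(config.levels),
        promoter_levels=dict(config.promoter_levels)
        if config.promoter_levels else None,
        dip={"width": config.dip_width, "level": config.dip_level,
             "shape": config.dip_shape} if tfbs else None,
        realized_levels={ctx: mc_sum[ctx] / tot_sum[ctx]
                         for ctx in CONTEXTS if tot_sum[ctx] > 0})
    return records, truth


# ---------------------------------------------------------------------------
# SNPs, CNVs and converted reads
# ---------------------------------------------------------------------------

def plant_snps(config: SimulationConfig,
               genome: Mapping[str, GenomeSequence],
               rng: np.random.Generator) -> list[dict]:
    """Choose hom/het SNP positions at non-cytosine (A/T) reference bases,
    outside zero-copy regions, with a random alternate allele."""
    n_total = config.n_hom_snps + config.n_het_snps
    if n_total == 0:
        return []
    candidates: list[tuple[str, int]] = []
    for chrom, gs in genome.items():
        arr = np.frombuffer(gs.seq.encode(), dtype=np.uint8)
        ok = (arr == _A) | (arr == _T)
        for s, e, ratio in [(s, e, r) for c, s, e, r in config.cnv_segments
                            if c == chrom]:
            if ratio == 0:
                ok[s - 1:e] = False
        # keep SNPs a read-length clear of chromosome ends
        ok[:config.read_length] = False
        ok[-config.read_length:] = False
        candidates.extend((chrom, int(i) + 1) for i in np.nonzero(ok)[0])
    if len(candidates) < n_total:
        raise ValueError("not enough A/T positions to plant the requested SNPs")
    picks = rng.choice(len(candidates), size=n_total, replace=False)
    snps = []
    for k, idx in enumerate(sorted(picks.tolist())):
        chrom, pos = candidates[idx]
        ref = genome[chrom].seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snps.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                     "genotype": "hom" if k < config.n_hom_snps else "het"})
    # interleave hom/het assignment independent of genomic order
    kinds = ["hom"] * config.n_hom_snps + ["het"] * config.n_het_snps
    rng.shuffle(kinds)
    for s, kind in zip(snps, kinds):
        s["genotype"] = kind
    return snps


def _copy_ratio_weights(config: SimulationConfig, chrom: str, L: int
                        ) -> np.ndarray:
    w = np.ones(max(L - config.read_length + 1, 1))
    for c, s, e, ratio in config.cnv_segments:
        if c == chrom:
            if ratio < 0:
                raise ValueError("copy ratio must be >= 0")
            w[max(s - 1, 0):min(e, len(w))] = ratio
    return w


def simulate_alignments(config: SimulationConfig,
                        genome: Mapping[str, GenomeSequence],
                        snps: list[dict], rng: np.random.Generator
                        ) -> tuple[list[Alignment], TruthSet]:
    """Uniform error-free reads with planted SNP alleles and copy-number
    scaled depth, bisulfite-converted on a 50/50 Watson/Crick draw.

    Unmethylated cytosines on the read's conversion strand convert with
    probability ``conversion`` (C->T on Watson reads, G->A on Crick
    reads); per-site methylation probabilities come from the planted
    context levels.  Returned alignments are coordinate-sorted, ungapped
    (``<read_length>M``), and tagged with their conversion strand.
    """
    for s in snps:
        for c, cs, ce, ratio in config.cnv_segments:
            if ratio == 0 and s["chrom"] == c and cs <= s["pos"] <= ce:
                raise ValueError(
                    f"SNP at {c}:{s['pos']} lies inside a zero-copy deletion")
    rl = config.read_length
    alignments: list[Alignment] = []
    for chrom, L in config.chrom_lengths.items():
        weights = _copy_ratio_weights(config, chrom, L)
        n_reads = int(round(config.aln_depth_mean * weights.sum() / rl))
        if n_reads == 0:
            continue
        seq = np.frombuffer(genome[chrom].seq.encode(), dtype=np.uint8)
        # per-site methylation probability, Watson Cs and Crick Cs (ref G)
        p_meth = np.full(L, config.levels.get("CHH", 0.1))
        for i in np.nonzero((seq == _C) | (seq == _G))[0]:
            ctx = classify_context(genome, chrom, int(i) + 1, chr(seq[i]))
            if ctx is not None:
                p_meth[i] = config.levels[ctx]
        starts = np.sort(rng.choice(len(weights), size=n_reads,
                                    p=weights / weights.sum()))
        watson = rng.random(n_reads) < 0.5
        frags = [seq[s:s + rl].copy() for s in starts]
        # plant SNP alleles: hom reads always carry alt, het reads 50/50
        for s in (x for x in snps if x["chrom"] == chrom):
            lo = np.searchsorted(starts, s["pos"] - rl, side="left")
            hi = np.searchsorted(starts, s["pos"] - 1, side="right")
            alt = ord(s["alt"])
            for ridx in range(lo, hi):
                off = s["pos"] - 1 - starts[ridx]
                if s["genotype"] == "hom" or rng.random() < 0.5:
                    frags[ridx][off] = alt
        for ridx, (start, frag) in enumerate(zip(starts, frags)):
            if watson[ridx]:
                cpos = np.nonzero(frag == _C)[0]
                conv_to = _T
            else:
                cpos = np.nonzero(frag == _G)[0]
                conv_to = _A
            if cpos.size:
                meth = rng.random(cpos.size) < p_meth[start + cpos]
                conv = rng.random(cpos.size) < config.conversion
                frag[cpos[~meth & conv]] = conv_to
            if config.error_rate > 0:
                err = np.nonzero(rng.random(rl) < config.error_rate)[0]
                for e in err:
                    frag[e] = rng.choice(_BASE_ORDER[_BASE_ORDER != frag[e]])
            alignments.append(Alignment(
                name="", chrom=chrom, pos=int(start) + 1,
                seq=frag.tobytes().decode("ascii"),
                cigar=[("M", rl)],
                bs_strand="watson" if watson[ridx] else "crick"))
    for i, aln in enumerate(alignments):
        aln.name = f"read{i + 1:07d}"
    truth = TruthSet(levels=dict(config.levels), snps=list(snps),
                     cnv_segments=[list(s) for s in config.cnv_segments])
    return alignments, truth


def write_sam(alignments: list[Alignment],
              chrom_lengths: Mapping[str, int], path: str | Path) -> None:
    """Write coordinate-sorted alignments as plain SAM with XG conversion
    tags (CT = Watson, GA = Crick)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": L} for c, L in chrom_lengths.items()]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aln in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = aln.name
            a.query_sequence = aln.seq
            a.flag = 0
            a.reference_name = aln.chrom
            a.reference_start = aln.pos - 1
            a.mapping_quality = 40
            a.cigarstring = "".join(f"{n}{op}" for op, n in aln.cigar)
            a.query_qualities = pysam.qualitystring_to_array(
                "I" * len(aln.seq))
            a.set_tag("XG", "CT" if aln.bs_strand == "watson" else "GA")
            out.write(a)


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

def write_cgmap_records(records: list[CytosineRecord], path: str | Path
                        ) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join((
                r.chrom, r.strand_base, str(r.pos), r.context, r.sub_context,
                format_level(r.mc_count, r.total_count),
                str(r.mc_count), str(r.total_count))) + "\n")


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate and write the full synthetic dataset; returns the paths
    plus the in-memory objects (genome, genes, tfbs, records, alignments,
    truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, genes, tfbs = simulate_genome(config, rng)
    records, met_truth = simulate_methylome(config, genome, genes, tfbs, rng)
    snps = plant_snps(config, genome, rng)
    alignments, aln_truth = simulate_alignments(config, genome, snps, rng)
    truth = TruthSet(levels=met_truth.levels,
                     promoter_levels=met_truth.promoter_levels,
                     dip=met_truth.dip, snps=aln_truth.snps,
                     cnv_segments=aln_truth.cnv_segments,
                     realized_levels=met_truth.realized_levels)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff": outdir / "genes.gff3",
        "bed": outdir / "tfbs.bed",
        "cgmap": outdir / "methylome.cgmap",
        "sam": outdir / "reads.sam",
        "truth": outdir / "truth.json",
    }
    write_fasta(genome, paths["fasta"])
    write_gene_annotation(genes, paths["gff"])
    write_tfbs_bed(tfbs, paths["bed"])
    write_cgmap_records(records, paths["cgmap"])
    write_sam(alignments, config.chrom_lengths, paths["sam"])
    truth.to_json(paths["truth"])
    return {"paths": {k: str(v) for k, v in paths.items()},
            "genome": genome, "genes": genes, "tfbs": tfbs,
            "records": records, "alignments": alignments, "truth": truth}
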