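"""Context-resolved methylation profiling.

Five related summaries of a per-cytosine methylation call set:

* global weighted methylation level per context (CG / CHG / CHH);
* distribution of per-site methylation levels in ten 10% bins;
* weighted level per genomic element class (promoter, gene body, exon,
  intron, intergenic non-coding region);
* a chromosome-wide track of weighted levels in non-overlapping windows;
* a gene-centric table of promoter / gene-body / exon / intron levels.

Throughout, the *weighted* methylation level of a set of sites is
sum(methylated reads) / sum(covering reads), not the mean of per-site
fractions; a site must be covered by at least ``min_depth`` reads to be
retained.  Sets with no retained sites have an undefined level (NaN),
never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import CONTEXTS, CytosineRecord, GeneModel

ELEMENT_CLASSES = ("promoter", "gene_body", "exon", "intron", "IGN")
_CTX_CODE = {c: i for i, c in enumerate(CONTEXTS)}


@dataclass(frozen=True)
class MethylationSummary:
    context: str
    scope: str
    level: float  # NaN when total_sum == 0
    mc_sum: int
    total_sum: int
    n_sites: int


def records_frame(records: Iterable[CytosineRecord] | pd.DataFrame
                  ) -> pd.DataFrame:
    """Materialise cytosine records into the columnar frame the profiling
    functions operate on (passes DataFrames through unchanged)."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = [(r.chrom, r.pos, r.context, r.mc_count, r.total_count)
            for r in records if r.context in _CTX_CODE]
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "mc", "total"])


def _retained(frame: pd.DataFrame, min_depth: int) -> pd.DataFrame:
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return frame[frame["total"] >= min_depth]


def _summary(context: str, scope: str, mc: int, total: int, n: int
             ) -> MethylationSummary:
    level = mc / total if total > 0 else float("nan")
    return MethylationSummary(context, scope, level, int(mc), int(total), int(n))


def global_methylation(records, min_depth: int = 4
                       ) -> dict[str, MethylationSummary]:
    """Genome-wide weighted methylation level per context."""
    kept = _retained(records_frame(records), min_depth)
    out = {}
    for ctx in CONTEXTS:
        sub = kept[kept["context"] == ctx]
        out[ctx] = _summary(ctx, "global", sub["mc"].sum(), sub["total"].sum(),
                            len(sub))
    return out


def level_distribution(records, min_depth: int = 4, n_bins: int = 10
                       ) -> dict[str, np.ndarray]:
    """Fraction of retained sites per methylation-level bin and context.

    Bins are left-closed ([0,0.1), [0.1,0.2), ...) with the last bin
    closed at 1.0; per context the fractions sum to 1.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    kept = _retained(records_frame(records), min_depth)
    out = {}
    for ctx in CONTEXTS:
        sub = kept[kept["context"] == ctx]
        if len(sub) == 0:
            out[ctx] = np.full(n_bins, np.nan)
            continue
        levels = sub["mc"].to_numpy() / sub["total"].to_numpy()
        idx = np.minimum((levels * n_bins).astype(int), n_bins - 1)
        out[ctx] = np.bincount(idx, minlength=n_bins) / len(sub)
    return out


# ---------------------------------------------------------------------------
# genomic elements
# ---------------------------------------------------------------------------

@dataclass
class ElementAnnotation:
    """Genome partition into element classes.

    ``masks[cls][chrom]`` is a boolean membership array indexed by 1-based
    position (index 0 unused).  ``gene_regions[gene_id][region]`` holds the
    per-gene interval lists used by the gene-centric table.  Element
    classes are not mutually exclusive (a base can be exon of one gene and
    promoter of another); IGN is everything outside all gene bodies and
    promoters.
    """

    chrom_lengths: dict[str, int]
    masks: dict[str, dict[str, np.ndarray]]
    gene_regions: dict[str, dict[str, list[tuple[int, int]]]]
    genes: list[GeneModel]


def promoter_interval(gene: GeneModel, chrom_length: int,
                      promoter_len: int = 1000) -> tuple[int, int] | None:
    """The ``promoter_len`` bases 5' of the TSS, strand-aware, clamped to
    the chromosome; None if the gene starts at the very end."""
    if gene.strand == "+":
        s, e = gene.tss - promoter_len, gene.tss - 1
    else:
        s, e = gene.tss + 1, gene.tss + promoter_len
    s, e = max(s, 1), min(e, chrom_length)
    return (s, e) if s <= e else None


def build_elements(genes: Sequence[GeneModel],
                   chrom_lengths: Mapping[str, int],
                   promoter_len: int = 1000) -> ElementAnnotation:
    """Derive promoter / gene-body / exon / intron / IGN annotation from
    gene models.  Exon and intron tile each gene body exactly."""
    masks = {cls: {c: np.zeros(l + 1, dtype=bool)
                   for c, l in chrom_lengths.items()}
             for cls in ELEMENT_CLASSES}
    gene_regions: dict[str, dict[str, list[tuple[int, int]]]] = {}

    def mark(cls: str, chrom: str, s: int, e: int):
        masks[cls][chrom][s:e + 1] = True

    for g in genes:
        if g.chrom not in chrom_lengths:
            continue
        L = chrom_lengths[g.chrom]
        prom = promoter_interval(g, L, promoter_len)
        regions = {
            "promoter": [prom] if prom else [],
            "gene_body": [(g.start, g.end)],
            "exon": list(g.exons),
            "intron": list(g.introns),
        }
        gene_regions[g.gene_id] = regions
        for cls, ivals in regions.items():
            for s, e in ivals:
                mark(cls, g.chrom, max(s, 1), min(e, L))

    for chrom in chrom_lengths:
        ign = ~(masks["gene_body"][chrom] | masks["promoter"][chrom])
        ign[0] = False
        masks["IGN"][chrom] = ign
    return ElementAnnotation(dict(chrom_lengths), masks, gene_regions,
                             list(genes))


def element_methylation(records, elements: ElementAnnotation,
                        min_depth: int = 4) -> pd.DataFrame:
    """Weighted level per (element class x context), plus a "genome" row
    over all retained sites.

    A retained cytosine contributes its counts to every class whose
    intervals contain it; a site can be gene_body and exon at once.
    """
    kept = _retained(records_frame(records), min_depth)
    rows = []
    for ctx in CONTEXTS:
        sub = kept[kept["context"] == ctx]
        rows.append(("genome", ctx, sub["mc"].sum(), sub["total"].sum(),
                     len(sub)))
        sums = {cls: [0, 0, 0] for cls in ELEMENT_CLASSES}
        for chrom, grp in sub.groupby("chrom", sort=True):
            if chrom not in elements.chrom_lengths:
                continue
            pos = grp["pos"].to_numpy()
            mc = grp["mc"].to_numpy()
            tot = grp["total"].to_numpy()
            for cls in ELEMENT_CLASSES:
                inmask = elements.masks[cls][chrom][pos]
                sums[cls][0] += int(mc[inmask].sum())
                sums[cls][1] += int(tot[inmask].sum())
                sums[cls][2] += int(inmask.sum())
        for cls in ELEMENT_CLASSES:
            rows.append((cls, ctx, *sums[cls]))
    df = pd.DataFrame(rows, columns=["element", "context", "mc_sum",
                                     "total_sum", "n_sites"])
    df["level"] = np.where(df["total_sum"] > 0,
                           df["mc_sum"] / df["total_sum"].replace(0, 1),
                           np.nan)
    return df


def chromosome_track(records, chrom_lengths: Mapping[str, int],
                     window_size: int = 100_000, min_depth: int = 4
                     ) -> pd.DataFrame:
    """Weighted level per non-overlapping window ([1,w], [w+1,2w], ...) and
    context; windows with no retained sites are NaN (a plotting gap)."""
    if window_size < 1000:
        raise ValueError("window_size must be >= 1000")
    kept = _retained(records_frame(records), min_depth)
    rows = []
    for chrom in chrom_lengths:
        L = chrom_lengths[chrom]
        n_win = (L + window_size - 1) // window_size
        sub = kept[kept["chrom"] == chrom]
        widx = (sub["pos"].to_numpy() - 1) // window_size
        ctxc = sub["context"].map(_CTX_CODE).to_numpy(dtype=int)
        mc = sub["mc"].to_numpy()
        tot = sub["total"].to_numpy()
        for w in range(n_win):
            row = {"chrom": chrom, "win_start": w * window_size + 1,
                   "win_end": min((w + 1) * window_size, L)}
            inwin = widx == w
            for ctx, code in _CTX_CODE.items():
                sel = inwin & (ctxc == code)
                t = tot[sel].sum()
                row[f"level_{ctx}"] = mc[sel].sum() / t if t > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


GENE_TABLE_REGIONS = ("promoter", "gene_body", "exon", "intron")


def gene_region_sums(records, elements: ElementAnnotation,
                     min_depth: int = 4) -> pd.DataFrame:
    """Per-gene, per-region, per-context (mc_sum, total_sum, n_sites),
    using each gene's own intervals."""
    kept = _retained(records_frame(records), min_depth)
    by_chrom: dict[str, tuple[np.ndarray, ...]] = {}
    for chrom, grp in kept.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        by_chrom[chrom] = (grp["pos"].to_numpy(),
                           grp["context"].map(_CTX_CODE).to_numpy(dtype=int),
                           grp["mc"].to_numpy(), grp["total"].to_numpy())
    rows = []
    for g in elements.genes:
        data = by_chrom.get(g.chrom)
        regions = elements.gene_regions.get(g.gene_id, {})
        for region in GENE_TABLE_REGIONS:
            sums = {ctx: [0, 0, 0] for ctx in CONTEXTS}
            if data is not None:
                pos, ctxc, mc, tot = data
                for s, e in regions.get(region, []):
                    lo = np.searchsorted(pos, s, side="left")
                    hi = np.searchsorted(pos, e, side="right")
                    for ctx, code in _CTX_CODE.items():
                        sel = ctxc[lo:hi] == code
                        sums[ctx][0] += int(mc[lo:hi][sel].sum())
                        sums[ctx][1] += int(tot[lo:hi][sel].sum())
                        sums[ctx][2] += int(sel.sum())
            for ctx in CONTEXTS:
                rows.append((g.gene_id, region, ctx, *sums[ctx]))
    return pd.DataFrame(rows, columns=["gene_id", "region", "context",
                                       "mc_sum", "total_sum", "n_sites"])


def gene_table(records, elements: ElementAnnotation,
               min_depth: int = 4) -> pd.DataFrame:
    """Gene-centric methylation table: one row per gene, one column per
    region x context weighted level; uncovered cells are NaN (rendered NA
    on output)."""
    sums = gene_region_sums(records, elements, min_depth)
    sums["level"] = np.where(sums["total_sum"] > 0,
                             sums["mc_sum"] / sums["total_sum"].replace(0, 1),
                             np.nan)
    wide = sums.pivot_table(index="gene_id", columns=["region", "context"],
                            values="level", dropna=False)
    wide.columns = [f"{region}_{ctx}" for region, ctx in wide.columns]
    order = [f"{r}_{c}" for r in GENE_TABLE_REGIONS for c in CONTEXTS]
    wide = wide.reindex(columns=order)
    gene_ids = [g.gene_id for g in elements.genes]
    return wide.reindex(gene_ids)
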