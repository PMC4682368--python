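"""Bisulfite-aware SNP calling from strand-split pileups.

Bisulfite conversion turns unmethylated C into T on the read's own
strand, so some base observations carry no genotype information: a T seen
in a Watson-converted (C->T) read could be a genuine T or a converted C,
and an A in a Crick-converted (G->A) read could be a genuine A or a
converted G.  Those observations are masked before genotyping; calls are
made from the remaining "informative" depth.  A consequence worth
knowing: at reference C/G positions only the opposite strand's evidence
is usable, so heterozygous calls involving a C<->T or G<->A pair are
intrinsically suppressed — documented behaviour, not a bug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .formats import Alignment, GenomeSequence

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_T, _A = _BASE_IDX["T"], _BASE_IDX["A"]


@dataclass
class PileupColumn:
    """Per-position, per-bisulfite-strand base counts."""

    chrom: str
    pos: int  # 1-based
    ref: str
    watson: np.ndarray  # counts of A,C,G,T from Watson-converted reads
    crick: np.ndarray   # counts of A,C,G,T from Crick-converted reads
    informative: np.ndarray | None = None

    @property
    def depth(self) -> int:
        return int(self.watson.sum() + self.crick.sum())

    @property
    def informative_depth(self) -> int:
        return 0 if self.informative is None else int(self.informative.sum())


@dataclass(frozen=True)
class SNPCall:
    chrom: str
    pos: int
    ref: str
    kind: str  # 'hom' or 'het'
    alleles: tuple[str, ...]  # one allele for hom, two for het
    counts: tuple[int, ...]
    fractions: tuple[float, ...]  # over informative depth
    informative_depth: int


def build_pileup(alignments: Iterable[Alignment],
                 genome: Mapping[str, GenomeSequence],
                 min_baseq: int = 20) -> Iterator[PileupColumn]:
    """CIGAR-aware pileup over coordinate-sorted alignments.

    Soft clips and insertions contribute nothing; deletions contribute
    nothing at the deleted positions.  Base observations below
    ``min_baseq`` are dropped when qualities are present; reads without a
    determinable bisulfite strand never reach here (the SAM reader skips
    them).  Columns are yielded in order for covered positions only.
    """
    counts: dict[str, np.ndarray] = {}
    chrom_order: list[str] = []
    n_reads = 0
    for aln in alignments:
        if aln.chrom not in genome:
            raise ValueError(f"alignment chromosome {aln.chrom!r} absent "
                             "from the reference genome")
        if aln.chrom not in counts:
            counts[aln.chrom] = np.zeros(
                (2, 4, genome[aln.chrom].length + 1), dtype=np.int32)
            chrom_order.append(aln.chrom)
        strand_idx = 0 if aln.bs_strand == "watson" else 1
        arr = counts[aln.chrom]
        for qpos, rpos in aln.aligned_pairs():
            if aln.quals is not None and aln.quals[qpos] < min_baseq:
                continue
            b = _BASE_IDX.get(aln.seq[qpos])
            if b is not None and rpos <= genome[aln.chrom].length:
                arr[strand_idx, b, rpos] += 1
        n_reads += 1
    logger.info("build_pileup: %d reads piled over %d chromosome(s)",
                n_reads, len(counts))
    for chrom in chrom_order:
        arr = counts[chrom]
        covered = np.nonzero(arr.sum(axis=(0, 1)))[0]
        seq = genome[chrom].seq
        for pos in covered:
            yield PileupColumn(chrom, int(pos), seq[pos - 1],
                               arr[0, :, pos].copy(), arr[1, :, pos].copy())


def mask_confounded(column: PileupColumn) -> PileupColumn:
    """Fill ``informative`` counts: drop conversion-ambiguous observations.

    T from Watson-converted reads (indistinguishable from converted
    unmethylated C) and A from Crick-converted reads (likewise from
    converted G) are removed at every position; everything else is kept.
    """
    informative = column.watson + column.crick
    informative[_T] -= column.watson[_T]
    informative[_A] -= column.crick[_A]
    column.informative = informative
    return column


def call_snps(pileup: Iterable[PileupColumn], min_depth: int = 5,
              hom_frac: float = 0.9, het_minor_frac: float = 0.2
              ) -> list[SNPCall]:
    """Genotype pileup columns into homozygous / heterozygous SNP calls.

    Per column with informative depth >= ``min_depth``: homozygous when
    the top non-reference allele reaches ``hom_frac`` of the informative
    depth; heterozygous when the two most frequent alleles each reach
    ``het_minor_frac``, jointly reach ``hom_frac``, and at least one is
    non-reference.  Columns supporting the reference are silent.
    """
    if not (0 < hom_frac <= 1 and 0 < het_minor_frac <= 1):
        raise ValueError("allele-fraction thresholds must be in (0, 1]")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    calls: list[SNPCall] = []
    for col in pileup:
        if col.informative is None:
            mask_confounded(col)
        depth = col.informative_depth
        if depth < min_depth or col.ref not in _BASE_IDX:
            continue
        inf = col.informative
        frac = inf / depth
        ref_idx = _BASE_IDX[col.ref]
        order = np.argsort(inf, kind="stable")[::-1]
        top_nonref = next(i for i in order if i != ref_idx)
        if frac[top_nonref] >= hom_frac:
            calls.append(SNPCall(
                col.chrom, col.pos, col.ref, "hom",
                (BASES[top_nonref],), (int(inf[top_nonref]),),
                (float(frac[top_nonref]),), depth))
            continue
        a, b = int(order[0]), int(order[1])
        if (frac[a] >= het_minor_frac and frac[b] >= het_minor_frac
                and frac[a] + frac[b] >= hom_frac
                and (a != ref_idx or b != ref_idx)):
            calls.append(SNPCall(
                col.chrom, col.pos, col.ref, "het",
                (BASES[a], BASES[b]), (int(inf[a]), int(inf[b])),
                (float(frac[a]), float(frac[b])), depth))
    return calls
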