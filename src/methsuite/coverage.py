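"""Coverage diagnostics: reverse cumulative depth distribution per context.

Sites with high read depth give accurate methylation estimates, so the
fraction of the genome's cytosines covered to at least a given depth is
the basic quality readout for a bisulfite library.  The denominator is
ALL reference cytosines of a context, on both strands — sites absent from
the methylation calls count at depth 0 — which is why the reference
genome is a required input.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .formats import CONTEXTS, CytosineRecord, GenomeSequence, classify_context

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageDistribution:
    """Empirical survival function of per-site depth for one context."""

    context: str
    depths: np.ndarray  # ascending integer grid starting at 0
    frac_at_least: np.ndarray  # P(depth >= d) per grid point
    n_sites: int


def reference_cytosine_counts(genome: Mapping[str, GenomeSequence]
                              ) -> dict[str, int]:
    """Count reference cytosines per context, both strands (a Watson C and
    a Crick G are separate sites).  Edge/N-adjacent sites are excluded."""
    counts = dict.fromkeys(CONTEXTS, 0)
    for chrom, gs in genome.items():
        for i, base in enumerate(gs.seq):
            if base in "CG":
                ctx = classify_context(genome, chrom, i + 1, base)
                if ctx is not None:
                    counts[ctx] += 1
    return counts


def coverage_histogram(records: Iterable[CytosineRecord],
                       genome: Mapping[str, GenomeSequence]
                       ) -> dict[str, Counter]:
    """Per-context depth -> site-count histograms over ALL reference
    cytosines; uncovered sites are counted at depth 0.

    Contexts are re-derived from the genome (not taken from the file) so
    the covered and uncovered tallies share one definition; records whose
    reference base is not the stated cytosine are skipped with a warning.
    """
    n_ref = reference_cytosine_counts(genome)
    hists = {ctx: Counter() for ctx in CONTEXTS}
    n_bad = 0
    for r in records:
        if r.chrom not in genome:
            n_bad += 1
            continue
        base = genome[r.chrom].seq[r.pos - 1]
        if base != r.strand_base or base not in "CG":
            n_bad += 1
            continue
        ctx = classify_context(genome, r.chrom, r.pos, r.strand_base)
        if ctx is None:
            continue
        hists[ctx][r.total_count] += 1
    if n_bad:
        logger.warning("coverage_histogram: %d records whose reference base "
                       "is not the stated cytosine were skipped", n_bad)
    for ctx in CONTEXTS:
        covered = sum(hists[ctx].values())
        hists[ctx][0] += n_ref[ctx] - covered
    return hists


def reverse_cumulative(hist: Mapping[int, int], context: str = ""
                       ) -> CoverageDistribution:
    """Survival function of a depth histogram: frac_at_least[d] is the
    fraction of sites with depth >= d, on the grid 0..max depth."""
    total = sum(hist.values())
    if total <= 0:
        raise ValueError("empty histogram: no sites to summarise")
    max_depth = max(hist)
    counts = np.zeros(max_depth + 1, dtype=np.int64)
    for d, c in hist.items():
        counts[d] = c
    # survival: sum of counts at depth >= d
    at_least = counts[::-1].cumsum()[::-1]
    return CoverageDistribution(
        context=context,
        depths=np.arange(max_depth + 1),
        frac_at_least=at_least / total,
        n_sites=total,
    )
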