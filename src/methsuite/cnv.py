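"""Read-depth copy-number analysis.

Bisulfite sequencing is DNA sequencing, so read depth is a usable proxy
for copy number: duplications show as sustained depth amplification and
deletions as depletion.  Depth is averaged in fixed genomic bins,
normalised by the genome-wide median bin depth (median, not mean, so a
whole-chromosome aneuploidy still shows as a chromosome-long shift), and
maximal runs of consecutive bins beyond gain/loss thresholds are reported
as segments.  No GC correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .formats import Alignment


@dataclass
class DepthBins:
    chrom: str
    bin_size: int
    starts: np.ndarray       # 1-based bin starts
    ends: np.ndarray         # 1-based inclusive bin ends (last may be partial)
    raw: np.ndarray          # mean per-base depth per bin
    ratio: np.ndarray | None = None  # raw / genome-wide median (normalize())


@dataclass(frozen=True)
class CNVSegment:
    chrom: str
    start: int  # 1-based, bin-aligned
    end: int
    direction: str  # 'gain' or 'loss'
    mean_ratio: float
    n_bins: int


def bin_depth(alignments: Iterable[Alignment],
              chrom_lengths: Mapping[str, int],
              bin_size: int = 10_000) -> list[DepthBins]:
    """Mean per-base depth in consecutive bins, from aligned reference
    footprints (CIGAR match blocks; clips, insertions and deletion gaps
    contribute nothing).  The trailing partial bin is averaged over its
    true width."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    # difference arrays -> cumulative sum gives per-base depth
    diffs = {c: np.zeros(l + 2, dtype=np.int64)
             for c, l in chrom_lengths.items()}
    for aln in alignments:
        if aln.chrom not in diffs:
            raise ValueError(f"alignment chromosome {aln.chrom!r} absent "
                             "from the reference genome")
        d = diffs[aln.chrom]
        L = chrom_lengths[aln.chrom]
        for s, e in aln.reference_blocks():
            s, e = max(s, 1), min(e, L)
            if s <= e:
                d[s] += 1
                d[e + 1] -= 1
    out = []
    for chrom, L in chrom_lengths.items():
        depth = diffs[chrom].cumsum()[1:L + 1].astype(float)
        n_bins = (L + bin_size - 1) // bin_size
        starts = np.arange(n_bins, dtype=np.int64) * bin_size + 1
        ends = np.minimum(starts + bin_size - 1, L)
        sums = np.add.reduceat(depth, (starts - 1))
        raw = sums / (ends - starts + 1)
        out.append(DepthBins(chrom, bin_size, starts, ends, raw))
    return out


def normalize(bins: list[DepthBins]) -> list[DepthBins]:
    """Attach ratios: raw depth / genome-wide median bin depth (zero-depth
    bins excluded from the median)."""
    raw_all = np.concatenate([b.raw for b in bins])
    nonzero = raw_all[raw_all > 0]
    if nonzero.size == 0:
        raise ValueError("all bins have zero depth; nothing to normalise")
    med = float(np.median(nonzero))
    for b in bins:
        b.ratio = b.raw / med
    return bins


def segment(bins: list[DepthBins], gain_thresh: float = 1.5,
            loss_thresh: float = 0.75, min_run: int = 3) -> list[CNVSegment]:
    """Maximal runs of >= ``min_run`` consecutive bins all at or beyond a
    threshold (>= gain_thresh for gains, <= loss_thresh for losses)."""
    if not (0 < loss_thresh < 1 < gain_thresh):
        raise ValueError("need 0 < loss_thresh < 1 < gain_thresh")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    segments: list[CNVSegment] = []
    for b in bins:
        if b.ratio is None:
            raise ValueError("bins are not normalised; call normalize() first")
        for direction, state in (("gain", b.ratio >= gain_thresh),
                                 ("loss", b.ratio <= loss_thresh)):
            i, n = 0, len(state)
            while i < n:
                if not state[i]:
                    i += 1
                    continue
                j = i
                while j < n and state[j]:
                    j += 1
                if j - i >= min_run:
                    segments.append(CNVSegment(
                        b.chrom, int(b.starts[i]), int(b.ends[j - 1]),
                        direction, float(b.ratio[i:j].mean()), j - i))
                i = j
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def bins_frame(bins: list[DepthBins]) -> pd.DataFrame:
    rows = []
    for b in bins:
        ratio = b.ratio if b.ratio is not None else np.full(len(b.raw), np.nan)
        for s, e, r, q in zip(b.starts, b.ends, b.raw, ratio):
            rows.append((b.chrom, int(s), int(e), float(r), float(q)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "raw_depth",
                                       "ratio"])


def segments_frame(segments: list[CNVSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.start, s.end, s.direction, s.mean_ratio, s.n_bins)
         for s in segments],
        columns=["chrom", "start", "end", "direction", "mean_ratio", "n_bins"])
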