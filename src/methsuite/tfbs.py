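"""Methylation metaprofiles around transcription-factor binding sites.

DNA methylation inside a binding footprint can block protein binding, so
the signature of an active factor is a local dip in methylation centred
on its sites.  The profile pools methylated / total read counts from
every retained cytosine within ``flank`` bases of each site's centre into
fixed-width tiles, and reports the weighted level per tile alongside a
baseline computed identically over *all* intervals in the BED (the
"average of all TFBSs" curve a specific factor is compared against).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import CONTEXTS, TFBSRecord
from .methylation import records_frame


@dataclass(frozen=True)
class TFBSProfile:
    factor: str
    context: str
    offsets: np.ndarray        # tile centres, symmetric about 0
    level: np.ndarray          # weighted level per tile (NaN where empty)
    n_sites: np.ndarray        # cytosine incidences per tile
    mc_sum: np.ndarray
    total_sum: np.ndarray
    baseline_level: np.ndarray  # pooled profile over every BED interval
    n_tfbs: int


def orient_offset(offset: int, strand: str) -> int:
    """Mirror genomic offsets for minus-strand sites so profiles are in
    the factor's own 5'->3' frame; unknown strand is treated as +."""
    return -offset if strand == "-" else offset


def _pooled(frame: pd.DataFrame, sites: list[TFBSRecord], flank: int,
            tile: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_tiles = 2 * flank // tile
    mc = np.zeros(n_tiles, dtype=np.int64)
    tot = np.zeros(n_tiles, dtype=np.int64)
    n = np.zeros(n_tiles, dtype=np.int64)
    by_chrom = {chrom: grp.sort_values("pos") for chrom, grp
                in frame.groupby("chrom", sort=True)}
    for t in sites:
        grp = by_chrom.get(t.chrom)
        if grp is None:
            continue
        anchor = t.center
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, anchor - flank, side="left")
        hi = np.searchsorted(pos, anchor + flank, side="right")
        if lo == hi:
            continue
        off = pos[lo:hi] - anchor
        if t.strand == "-":
            off = -off
        idx = np.minimum((off + flank) // tile, n_tiles - 1).astype(int)
        np.add.at(mc, idx, grp["mc"].to_numpy()[lo:hi])
        np.add.at(tot, idx, grp["total"].to_numpy()[lo:hi])
        np.add.at(n, idx, 1)
    return mc, tot, n


def tfbs_profile(records, tfbs: list[TFBSRecord], factor: str = "ALL",
                 flank: int = 1500, tile: int = 30, min_depth: int = 4,
                 context: str = "CG") -> TFBSProfile:
    """Pooled methylation metaprofile for one factor (or ALL).

    Each site's anchor is the left-of-centre base of its interval; a
    retained cytosine within ``flank`` bases of an anchor contributes its
    counts to the tile containing its (strand-oriented) offset, for every
    site it is near.  Tile level is sum(mc)/sum(total) pooled over all the
    factor's sites; the baseline is the same computation over every
    interval in the BED.
    """
    if flank % tile != 0:
        raise ValueError(f"flank ({flank}) must be divisible by tile ({tile})")
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}")
    if factor in ("ALL", None):
        chosen = list(tfbs)
    else:
        chosen = [t for t in tfbs if t.name == factor]
    if not chosen:
        names = sorted({t.name for t in tfbs})
        raise ValueError(f"no TFBS named {factor!r}; available: {names}")

    frame = records_frame(records)
    frame = frame[(frame["total"] >= min_depth) & (frame["context"] == context)]

    mc, tot, n = _pooled(frame, chosen, flank, tile)
    base_mc, base_tot, _ = _pooled(frame, list(tfbs), flank, tile)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(tot > 0, mc / np.maximum(tot, 1), np.nan)
        baseline = np.where(base_tot > 0, base_mc / np.maximum(base_tot, 1),
                            np.nan)
    n_tiles = 2 * flank // tile
    offsets = -flank + tile // 2 + tile * np.arange(n_tiles)
    return TFBSProfile(factor=factor if factor else "ALL", context=context,
                       offsets=offsets, level=level, n_sites=n,
                       mc_sum=mc, total_sum=tot, baseline_level=baseline,
                       n_tfbs=len(chosen))


def profile_frame(profile: TFBSProfile) -> pd.DataFrame:
    """Tabular rendering: offset, level, n_sites, baseline_level."""
    return pd.DataFrame({
        "offset": profile.offsets,
        "level": profile.level,
        "n_sites": profile.n_sites,
        "baseline_level": profile.baseline_level,
    })
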