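"""Chromatin-heterogeneity background estimation.

The background probability of a non-specific contact landing in bin j is
p_bg_j = N_bg_j / N_bg, where N_bg_j counts background signal in the bin.
For all-to-all experiments the background is pooled trans contacts of mRNAs
(their cis contacts are dominated by distance decay, their trans contacts by
chromatin accessibility and amplification bias); for one-to-all experiments
it is a user-supplied input track at fine (default 1 kb) resolution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .binning import BinGrid
from .io import FineTrack, GeneRecord

logger = logging.getLogger(__name__)


def build_ata_background(
    contacts: pd.DataFrame,
    annotation: dict[str, GeneRecord],
    mrna_names: list[str],
    chromsizes: dict[str, int],
    fine_binsize: int = 1000,
) -> FineTrack:
    """Pool trans contacts of the listed mRNAs into a fine uniform track.

    For each mRNA only contacts on chromosomes other than its own source
    chromosome are counted, so distance-decay structure around the mRNA genes
    never leaks into the heterogeneity estimate.
    """
    missing = [n for n in mrna_names if n not in annotation]
    if missing:
        raise ValueError(
            f"mRNA names absent from annotation: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    track = FineTrack(fine_binsize, dict(chromsizes))
    total = 0
    by_rna = contacts.groupby("rna_name", sort=False, observed=True)
    for name in mrna_names:
        if name not in by_rna.groups:
            continue
        sub = by_rna.get_group(name)
        source_chrom = annotation[name].chrom
        sub = sub[sub["chrom"] != source_chrom]
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
        for chrom in pd.unique(sub["chrom"].to_numpy()):
            if chrom not in chromsizes:
                continue
            m = mids[(sub["chrom"] == chrom).to_numpy()]
            nb = len(track.values[chrom])
            track.values[chrom] += np.bincount(m // fine_binsize, minlength=nb)
            total += len(m)
    if total == 0:
        raise ValueError(
            "no mRNA trans contacts pooled; provide a custom background track"
        )
    return track


def select_mrnas(annotation: dict[str, GeneRecord]) -> list[str]:
    """Default mRNA set for the ATA background: protein-coding genes."""
    return [g.name for g in annotation.values() if g.biotype == "protein_coding"]


def rebin_background(bg: FineTrack, grid: BinGrid) -> np.ndarray:
    """Aggregate the fine track onto a per-RNA grid by fractional overlap.

    Uses the cumulative fine signal: a grid bin's count is C(end) - C(start)
    with linear interpolation inside fine bins, so partial overlaps split
    values proportionally and totals are preserved.
    """
    table = grid.table
    out = np.zeros(len(table))
    w = bg.binsize
    for chrom in pd.unique(table["chrom"].to_numpy()):
        rows = np.nonzero((table["chrom"] == chrom).to_numpy())[0]
        if chrom not in bg.values:
            logger.warning("chromosome %s absent from background track", chrom)
            continue
        vals = bg.values[chrom]
        length = bg.chromsizes[chrom]
        cum = np.concatenate([[0.0], np.cumsum(vals)])

        def cum_at(x: np.ndarray) -> np.ndarray:
            idx = np.minimum(x // w, len(vals) - 1).astype(np.int64)
            # the last fine bin may be truncated at the chromosome end;
            # interpolate over its actual extent so totals are preserved
            extent = np.minimum((idx + 1) * w, length) - idx * w
            frac = np.clip((x - idx * w) / extent, 0.0, 1.0)
            return cum[idx] + vals[idx] * frac

        starts = table["start"].to_numpy()[rows]
        ends = table["end"].to_numpy()[rows]
        out[rows] = cum_at(ends) - cum_at(starts)
    return out


def uniform_background(grid: BinGrid) -> np.ndarray:
    """Width-proportional background counts (the --no-background mode)."""
    return grid.widths.astype(float)


def bg_probabilities(
    rebinned: np.ndarray,
    testable: np.ndarray,
    widths: np.ndarray | None = None,
    min_nonzero_fine: float | None = None,
    fine_binsize: int | None = None,
) -> np.ndarray:
    """Convert rebinned background counts to probabilities over testable bins.

    Zero-count testable bins are imputed a width-proportional pseudo-count
    equal to (minimum nonzero fine-bin count) * (bin width / fine width)
    before normalization, so the scaling estimate f = (O/N)/p_bg is defined
    everywhere; without an imputation basis the smallest nonzero rebinned
    count is used. Non-testable bins get probability 0. The testable
    probabilities sum to 1.
    """
    rebinned = np.asarray(rebinned, float)
    testable = np.asarray(testable, bool)
    if rebinned[testable].sum() <= 0:
        raise ValueError("background is zero on all testable bins")
    p = rebinned.copy()
    zero = testable & (p <= 0)
    if zero.any():
        if min_nonzero_fine and fine_binsize and widths is not None:
            p[zero] = min_nonzero_fine * np.asarray(widths, float)[zero] / fine_binsize
        else:
            p[zero] = p[testable & (p > 0)].min()
    p[~testable] = 0.0
    p /= p[testable].sum()
    return p
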