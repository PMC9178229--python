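"""Windowed transposable-element landscapes anchored on syntenic genes.

TE density is compared between species on a common coordinate frame by
anchoring on genes that are collinear and syntenic (involved in no event):
a TE is attributed to a 500 kb window when it lies within 50 kb of any
syntenic gene whose midpoint falls in the window, and each TE is counted
at most once per window.  Per-family z-scores across windows flag local
family expansions; rank correlation of window counts relates TE density
to event density.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import FeatureRecord, GeneRecord

logger = logging.getLogger(__name__)

__all__ = [
    "tile_windows",
    "windowed_unique_te_counts",
    "family_zscores",
    "fold_enrichment",
    "density_correlation",
]


def tile_windows(chrom_lengths: Mapping[str, int], window: int) -> pd.DataFrame:
    """Non-overlapping tiles of ``window`` bp covering each chromosome."""
    rows = []
    for chrom, L in chrom_lengths.items():
        for start in range(0, int(L), window):
            rows.append({"chrom": chrom, "win_start": start, "win_end": min(start + window, int(L))})
    return pd.DataFrame(rows)


def windowed_unique_te_counts(
    syntenic_genes: Sequence[GeneRecord],
    tes: Sequence[FeatureRecord],
    chrom_lengths: Mapping[str, int],
    te_window: int = 500_000,
    flank: int = 50_000,
    by_family: bool = False,
) -> pd.DataFrame:
    """Count unique TEs near syntenic genes per tiling window.

    A TE belongs to a window when its interval intersects the +/- ``flank``
    neighbourhood of at least one syntenic gene whose midpoint lies in the
    window; a TE reachable from several genes in the same window is counted
    once.  Windows without syntenic genes count zero.  With ``by_family``,
    one column of counts per TE family (feature label) is returned.
    """
    windows = tile_windows(chrom_lengths, te_window)
    te_by_chrom: dict[str, list[FeatureRecord]] = {}
    for te in tes:
        te_by_chrom.setdefault(te.chrom, []).append(te)
    for c in te_by_chrom:
        te_by_chrom[c].sort(key=lambda t: (t.start, t.end))
    gene_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in syntenic_genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)

    families = sorted({te.label or "TE" for te in tes})
    count_rows = []
    for w in windows.itertuples(index=False):
        genes = [
            g
            for g in gene_by_chrom.get(w.chrom, [])
            if w.win_start <= g.midpoint < w.win_end
        ]
        fam_counts = {f: 0 for f in families}
        total = 0
        if genes:
            # union of flanked gene neighbourhoods in this window
            ivals = sorted((g.start - flank, g.end + flank) for g in genes)
            merged = [list(ivals[0])]
            for s, e in ivals[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            chrom_tes = te_by_chrom.get(w.chrom, [])
            starts = np.array([t.start for t in chrom_tes])
            ends = np.array([t.end for t in chrom_tes])
            hit = np.zeros(len(chrom_tes), dtype=bool)
            for s, e in merged:
                hit |= (ends > s) & (starts < e)
            # zero-length TEs at an interval edge
            if len(chrom_tes):
                degenerate = starts == ends
                if degenerate.any():
                    for s, e in merged:
                        hit |= degenerate & (starts >= s) & (starts < e)
            for te, h in zip(chrom_tes, hit):
                if h:
                    fam_counts[te.label or "TE"] += 1
                    total += 1
        row = {"chrom": w.chrom, "win_start": w.win_start, "win_end": w.win_end}
        if by_family:
            row.update(fam_counts)
        row["count"] = total
        count_rows.append(row)
    return pd.DataFrame(count_rows)


def family_zscores(
    family_window_counts: pd.DataFrame,
    min_mean: float = 1.0,
) -> pd.DataFrame:
    """Per-(family, window) z-scores of TE counts across the whole genome.

    Families with a genome-wide mean below ``min_mean`` copies per window
    are excluded, as are families with zero count variance (logged).
    z = (count - mean) / sd with mean and sd taken across all windows.
    """
    meta_cols = [c for c in ("chrom", "win_start", "win_end", "count") if c in family_window_counts.columns]
    fam_cols = [c for c in family_window_counts.columns if c not in meta_cols]
    out = family_window_counts[meta_cols].copy()
    kept = []
    for fam in fam_cols:
        x = family_window_counts[fam].astype(float)
        mean, sd = x.mean(), x.std(ddof=0)
        if mean < min_mean:
            logger.info("family %s excluded: mean %.3f per window < %.3f", fam, mean, min_mean)
            continue
        if sd == 0:
            logger.info("family %s excluded: zero variance across windows", fam)
            continue
        out[fam] = (x - mean) / sd
        kept.append(fam)
    if not kept:
        logger.warning("no TE families survived the mean-density filter")
    return out


def fold_enrichment(window_count: float, genome_mean: float) -> float:
    """Fold enrichment of a window count over the genome-wide mean."""
    if genome_mean <= 0:
        raise ValueError("genome-wide mean must be positive")
    return window_count / genome_mean


def density_correlation(
    mgee_window_counts: Sequence[float], te_window_counts: Sequence[float]
) -> tuple[float, float]:
    """Kendall rank correlation (tau-b, tie-corrected) between window counts."""
    x = np.asarray(mgee_window_counts, dtype=float)
    y = np.asarray(te_window_counts, dtype=float)
    if x.size != y.size:
        raise ValueError("count vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 windows")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)
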