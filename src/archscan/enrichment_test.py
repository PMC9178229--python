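"""Permutation enrichment machinery for events around genomic regions.

For a region of interest and a half-width x, the observed statistic is the
number of (collapsed) events lying within the region body or strictly
closer than x bp to either edge.  The null distribution redraws all events
of the same type genome-wide from a positional null model; the empirical
P-value is the proportion of null replicates whose count equals or exceeds
the observation.  Across an island set, a window size is called enriched
when the number of islands with P below alpha exceeds the 95th percentile
of the corresponding binomial null; across islands, Benjamini-Hochberg
FDR gives per-island q-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import FeatureRecord, MgeeEvent, PipelineParams
from .positional_null import NullModel

logger = logging.getLogger(__name__)

__all__ = [
    "count_events_near",
    "empirical_enrichment_p",
    "EnrichStats",
    "islandset_exceedance",
    "ExceedanceResult",
    "bh_fdr",
    "run_enrichment_scan",
]


def _window(region: FeatureRecord, x: int) -> tuple[float, float]:
    return region.start - x, region.end + x


def count_events_near(
    events: Sequence[MgeeEvent], region: FeatureRecord, x: int
) -> int:
    """Count events within the region body or strictly within x bp of it.

    An event at exactly x bp from an edge is not counted (the distance must
    be strictly less than x).
    """
    lo, hi = _window(region, x)
    return sum(
        1 for e in events if e.chrom == region.chrom and lo < e.pos < hi
    )


@dataclass
class EnrichStats:
    observed: int
    p_emp: float
    n_perm: int
    null_mean: float
    null_sd: float
    n_exceed: int


def empirical_enrichment_p(
    observed: int,
    n_events_of_type: int,
    region: FeatureRecord,
    x: int,
    null_model: NullModel,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    chunk: int = 4_000_000,
) -> EnrichStats:
    """Empirical P that the observed window count arises under the null.

    Each replicate redraws all ``n_events_of_type`` event positions
    genome-wide from the null model and counts how many fall in the window;
    ``p_emp`` is the proportion of replicates that equal or exceed the
    observation (so an observation of zero always gives P = 1).

    Since events land on chromosomes independently, the redraw factorizes
    exactly: each replicate's number of events on the region's chromosome
    is binomial in that chromosome's weight, and only those positions are
    simulated (from the model's positional sampler for that chromosome).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is very small; empirical P is coarse")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        region_chrom_idx = null_model.chroms.index(region.chrom)
    except ValueError:
        raise ValueError(f"region chromosome {region.chrom!r} unknown to null model")
    lo, hi = _window(region, x)
    n = n_events_of_type
    w_focal = float(null_model.chrom_weights[region_chrom_idx])
    sampler = null_model.samplers[region.chrom]
    n_exceed = 0
    total = 0.0
    total_sq = 0.0
    done = 0
    mean_focal = max(n * w_focal, 1.0)
    per_chunk = max(1, int(chunk / mean_focal))
    while done < n_perm:
        m = min(per_chunk, n_perm - done)
        k_focal = rng.binomial(n, w_focal, size=m) if n > 0 else np.zeros(m, dtype=int)
        n_pos = int(k_focal.sum())
        pos = sampler.sample(n_pos, rng) if n_pos else np.empty(0)
        in_win = np.concatenate([[0], np.cumsum((pos > lo) & (pos < hi))])
        bounds = np.concatenate([[0], np.cumsum(k_focal)])
        counts = in_win[bounds[1:]] - in_win[bounds[:-1]]
        n_exceed += int((counts >= observed).sum())
        total += counts.sum()
        total_sq += (counts.astype(float) ** 2).sum()
        done += m
    mean = total / n_perm
    var = max(total_sq / n_perm - mean * mean, 0.0)
    return EnrichStats(
        observed=observed,
        p_emp=n_exceed / n_perm,
        n_perm=n_perm,
        null_mean=mean,
        null_sd=float(np.sqrt(var)),
        n_exceed=n_exceed,
    )


@dataclass
class ExceedanceResult:
    n_islands: int
    n_significant: int
    threshold: int
    is_enriched: bool
    alpha: float


def islandset_exceedance(
    p_values: Sequence[float], alpha: float = 0.05
) -> ExceedanceResult:
    """Binomial exceedance across an island set at one window size.

    With a 5% null expectation per island, the set is enriched when the
    number of islands with P < alpha strictly exceeds the 95th percentile
    of Binomial(n_islands, alpha), i.e. the smallest k whose CDF reaches
    0.95.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty island set")
    n = p.size
    n_sig = int((p < alpha).sum())
    threshold = int(stats.binom.ppf(0.95, n, alpha))
    # ppf returns min{k : CDF(k) >= 0.95} for discrete distributions
    return ExceedanceResult(
        n_islands=n,
        n_significant=n_sig,
        threshold=threshold,
        is_enriched=n_sig > threshold,
        alpha=alpha,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment_scan(
    events_by_type: Mapping[str, Sequence[MgeeEvent]],
    regions: Sequence[FeatureRecord],
    window_sizes: Sequence[int],
    null_models: Mapping[str, NullModel],
    params: PipelineParams | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full type x region x window-size enrichment scan.

    Regions may be genomic islands, candidate genes, or (point) breakpoints.
    Per window size, q-values are BH-adjusted across all regions tested and
    the island-set exceedance summary is recorded.  Deterministic for a
    given seed: each (type, region, window) cell consumes an independent
    spawned random stream.
    """
    params = params or PipelineParams()
    if seed is None:
        seed = params.seed
    root = np.random.SeedSequence(seed)
    rows = []
    exceed_rows = []
    types = sorted(events_by_type)
    streams = {}
    children = root.spawn(len(types) * len(regions) * len(window_sizes))
    k = 0
    for t in types:
        for region in regions:
            for x in window_sizes:
                streams[(t, region.feature_id, x)] = children[k]
                k += 1

    for t in types:
        events = list(events_by_type[t])
        model = null_models[t]
        n = len(events)
        for x in window_sizes:
            pvals = []
            for region in regions:
                observed = count_events_near(events, region, x)
                rng = np.random.default_rng(streams[(t, region.feature_id, x)])
                st = empirical_enrichment_p(
                    observed, n, region, x, model, n_perm=params.n_perm, seed=rng
                )
                pvals.append(st.p_emp)
                rows.append(
                    {
                        "mgee_type": t,
                        "region_id": region.feature_id,
                        "window_bp": x,
                        "observed": observed,
                        "p_emp": st.p_emp,
                        "null_mean": st.null_mean,
                        "null_sd": st.null_sd,
                        "n_perm": st.n_perm,
                        "model_kind": model.kind,
                    }
                )
            qvals = bh_fdr(pvals)
            for (row, q) in zip(rows[-len(regions):], qvals):
                row["q"] = q
            exc = islandset_exceedance(pvals, alpha=params.alpha)
            exceed_rows.append(
                {
                    "mgee_type": t,
                    "window_bp": x,
                    "n_islands": exc.n_islands,
                    "n_significant": exc.n_significant,
                    "threshold": exc.threshold,
                    "is_enriched": exc.is_enriched,
                    "alpha": exc.alpha,
                }
            )
    results = pd.DataFrame(rows)
    exceedance = pd.DataFrame(exceed_rows)
    return results, exceedance
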