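"""Differential-expression overlap statistics and event-rate arithmetic.

Genes involved in each event type are compared against the background
differential-expression (DE) rate of genes in no event, by one-sided exact
binomial test; duplication groups count as a single unit that is DE if any
member is.  Event rates per million years divide event counts by the
relevant divergence time.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, Set

import pandas as pd
from scipy import stats

from .types import DUP, MgeeEvent

__all__ = ["de_enrichment_test", "fold_change", "rate_per_myr"]


def fold_change(proportion: float, background_proportion: float) -> float:
    """Ratio of a type's DE proportion to the background DE proportion."""
    if background_proportion <= 0:
        raise ValueError("background proportion must be positive")
    return proportion / background_proportion


def de_enrichment_test(
    events: Sequence[MgeeEvent],
    de_genes: Set[str] | Iterable[str],
    background_genes: Set[str] | Iterable[str],
    id_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-type DE overlap against the non-event background.

    ``background_genes`` are genes involved in no event; the background DE
    proportion p0 is their DE fraction.  For LSGs and rearrangements the
    unit is the gene; for duplications the unit is the group, counted DE if
    any member is DE.  Each type gets a one-sided exact binomial upper-tail
    P for k DE units of n at rate p0, and the fold enrichment over p0.
    ``id_map`` optionally translates DE-list identifiers onto the
    annotation's gene ids before matching.
    """
    de = set(de_genes)
    if id_map:
        de = {id_map.get(g, g) for g in de}
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene set")
    n_bg = len(background)
    k_bg = len(background & de)
    p0 = k_bg / n_bg

    rows = [
        {
            "mgee_type": "background",
            "n": n_bg,
            "k": k_bg,
            "proportion": p0,
            "binomial_p": float("nan"),
            "fold": 1.0,
        }
    ]
    by_type: dict[str, list[MgeeEvent]] = {}
    for e in events:
        by_type.setdefault(e.mgee_type, []).append(e)
    for t in sorted(by_type):
        evs = by_type[t]
        if t == DUP:
            n = len(evs)
            k = sum(1 for e in evs if any(g in de for g in e.gene_ids))
        else:
            units = [g for e in evs for g in e.gene_ids]
            n = len(units)
            k = sum(1 for g in units if g in de)
        prop = k / n if n else 0.0
        if n and p0 > 0:
            p = float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
        elif k == 0:
            p = 1.0
        else:
            p = 0.0
        rows.append(
            {
                "mgee_type": t,
                "n": n,
                "k": k,
                "proportion": prop,
                "binomial_p": p,
                "fold": fold_change(prop, p0) if p0 > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def rate_per_myr(n_events: int, divergence_myr: float) -> float:
    """Long-term event rate per million years over a divergence time."""
    if divergence_myr <= 0:
        raise ValueError("divergence time must be positive")
    return n_events / divergence_myr
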