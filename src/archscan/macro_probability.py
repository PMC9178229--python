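"""Probability that a focal set of chromosomes is among the rearranged draws.

Observing macro-rearrangements on exactly the chromosomes that carry the
largest islands of local adaptation invites a simple question: if k of the
n chromosomes had been hit at random, how often would the focal set be
fully contained?  The equal-probability case has a closed form; when the
chance of rearrangement is taken proportional to chromosome length the
probability is estimated by Monte Carlo over sequential weighted draws
without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt
from typing import Sequence

import numpy as np

__all__ = ["DrawSpec", "exact_draw_probability", "weighted_draw_probability", "WeightedEstimate"]


@dataclass
class DrawSpec:
    """Specification for a chromosome-draw probability calculation."""

    n_chrom: int
    n_draws: int
    focal: frozenset
    weights: tuple[float, ...] | None = None
    n_mc: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_draws <= self.n_chrom):
            raise ValueError("need 0 < n_draws <= n_chrom")
        if self.weights is not None:
            if len(self.weights) != self.n_chrom:
                raise ValueError("weights length must equal n_chrom")
            if any(w < 0 for w in self.weights):
                raise ValueError("weights must be non-negative")


def exact_draw_probability(
    n_chrom: int, n_draws: int, n_focal: int
) -> float:
    """P(all focal chromosomes drawn) for equally likely draws without replacement.

    P = C(n_chrom - f, n_draws - f) / C(n_chrom, n_draws); zero when the
    focal set is larger than the number of draws.
    """
    if n_chrom < 1 or not (0 < n_draws <= n_chrom) or n_focal < 0:
        raise ValueError("need n_chrom >= 1, 0 < n_draws <= n_chrom, n_focal >= 0")
    if n_focal > n_draws:
        return 0.0
    return comb(n_chrom - n_focal, n_draws - n_focal) / comb(n_chrom, n_draws)


@dataclass
class WeightedEstimate:
    p: float
    se: float
    n_mc: int


def weighted_draw_probability(
    weights: Sequence[float],
    focal: Sequence[int],
    n_draws: int,
    n_mc: int = 100_000,
    seed: int = 0,
) -> WeightedEstimate:
    """Monte-Carlo P(focal set fully drawn) under length-weighted draws.

    Each replicate makes ``n_draws`` sequential draws without replacement,
    selection probability proportional to the remaining weights.  This
    sequential scheme is sampled in bulk via the Gumbel-perturbed-key
    equivalence: ranking chromosomes by log(w) plus independent standard
    Gumbel noise and taking the top ``n_draws`` reproduces the sequential
    draw distribution exactly.  Returns the hit fraction and its binomial
    standard error.
    """
    w = np.asarray(weights, dtype=float)
    focal_idx = np.asarray(sorted(set(focal)), dtype=int)
    if w.ndim != 1 or len(w) < 1:
        raise ValueError("weights must be a non-empty vector")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    if not (0 < n_draws <= len(w)):
        raise ValueError("need 0 < n_draws <= number of chromosomes")
    if focal_idx.size and (focal_idx.min() < 0 or focal_idx.max() >= len(w)):
        raise ValueError("focal indices out of range")
    if focal_idx.size > n_draws:
        return WeightedEstimate(0.0, 0.0, n_mc)
    if np.any(w[focal_idx] == 0):
        return WeightedEstimate(0.0, 0.0, n_mc)

    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(w), -np.inf)
    hits = 0
    chunk = max(1, int(2e7) // len(w))
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        keys = logw[None, :] + rng.gumbel(size=(m, len(w)))
        # focal contained in the top-n_draws iff the n_draws-th largest key
        # does not exceed any focal key
        kth = np.partition(keys, len(w) - n_draws, axis=1)[:, len(w) - n_draws]
        hits += int(np.all(keys[:, focal_idx] >= kth[:, None], axis=1).sum())
        done += m
    p = hits / n_mc
    return WeightedEstimate(p=p, se=sqrt(p * (1.0 - p) / n_mc), n_mc=n_mc)
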