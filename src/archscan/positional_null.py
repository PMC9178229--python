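"""Positional null-density models for event occurrence along chromosomes.

The permutation enrichment test needs a null that redraws event positions
genome-wide.  A replicate first draws a chromosome with probability
proportional to its gene count, then a position within it from one of four
density assumptions:

``flat``
    uniform along the chromosome;
``gene_density``
    proportional to the local gene density (histogram of gene midpoints);
``single_adj``
    a boundary-corrected kernel density fitted to observed event positions
    after *reflected rescaling* (each chromosome folded at its midpoint so
    relative positions live on [0, 0.5]), shared across chromosomes;
``double_adj``
    the same fitted density applied independently to each side of an
    ancestral macro-rearrangement breakpoint, each segment rescaled to its
    own length and weighted by its gene count.

The boundary correction reflects kernel mass at both edges of the bounded
support (Epanechnikov kernel), so the density integrates to one on [0, 0.5].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .types import Genome

logger = logging.getLogger(__name__)

__all__ = [
    "reflect_rescale",
    "fit_boundary_density",
    "BoundaryDensity",
    "NullModel",
    "build_null_model",
    "sample_positions",
]

NULL_KINDS = ("flat", "gene_density", "single_adj", "double_adj")

REFLECT_SUPPORT = 0.5  # upper edge of the folded relative-position support


def reflect_rescale(positions, chrom_length: float) -> np.ndarray:
    """Fold positions at the chromosome midpoint: r = min(p/L, 1 - p/L).

    Both chromosome ends map to 0 and the centre to 0.5, pooling the two
    arms for density estimation.
    """
    p = np.asarray(positions, dtype=float)
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    if np.any(p < 0) or np.any(p > chrom_length):
        raise ValueError("position outside chromosome [0, L]")
    rel = p / chrom_length
    return np.minimum(rel, 1.0 - rel)


class BoundaryDensity:
    """A density on [0, U] evaluated on a fixed grid, sampleable by inverse CDF."""

    def __init__(self, grid: np.ndarray, pdf: np.ndarray):
        if np.any(pdf < 0):
            raise ValueError("density must be non-negative")
        self.grid = grid
        area = np.trapezoid(pdf, grid)
        if area <= 0:
            raise ValueError("degenerate density (zero mass)")
        self.pdf = pdf / area
        # cumulative trapezoid for inverse-CDF sampling
        widths = np.diff(grid)
        seg = 0.5 * (self.pdf[:-1] + self.pdf[1:]) * widths
        cdf = np.concatenate([[0.0], np.cumsum(seg)])
        self.cdf = cdf / cdf[-1]

    @property
    def support(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    def __call__(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.grid, self.pdf)

    def integral(self) -> float:
        return float(np.trapezoid(self.pdf, self.grid))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        return np.interp(u, self.cdf, self.grid)


def _uniform_density(support: float = REFLECT_SUPPORT, grid_size: int = 2001) -> BoundaryDensity:
    grid = np.linspace(0.0, support, grid_size)
    return BoundaryDensity(grid, np.full(grid_size, 1.0 / support))


def fit_boundary_density(
    values,
    bandwidth: float = 0.15,
    support: float = REFLECT_SUPPORT,
    grid_size: int = 2001,
) -> BoundaryDensity:
    """Boundary-corrected Epanechnikov KDE on the closed support [0, support].

    Kernel mass escaping past either edge is reflected back, so the fitted
    density integrates to one.  Fewer than 10 values fall back to a flat
    density (logged), since a kernel fit to so few points is not meaningful.
    """
    x = np.asarray(values, dtype=float)
    if x.size and (x.min() < 0 or x.max() > support):
        raise ValueError(f"values outside support [0, {support}]")
    if x.size < 10:
        logger.warning(
            "fit_boundary_density: only %d values; falling back to flat density", x.size
        )
        return _uniform_density(support, grid_size)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    grid = np.linspace(0.0, support, grid_size)

    def epan(u: np.ndarray) -> np.ndarray:
        out = 1.0 - u * u
        out[np.abs(u) > 1.0] = 0.0
        return 0.75 * out

    # reflection at 0 (x -> -x) and at the far edge (x -> 2*support - x)
    g = grid[:, None]
    pdf = (
        epan((g - x[None, :]) / bandwidth)
        + epan((g + x[None, :]) / bandwidth)
        + epan((g - (2.0 * support - x[None, :])) / bandwidth)
    ).sum(axis=1) / (x.size * bandwidth)
    return BoundaryDensity(grid, pdf)


# ---------------------------------------------------------------------------
# Per-chromosome samplers
# ---------------------------------------------------------------------------


class _UniformSampler:
    def __init__(self, length: float):
        self.length = length

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.random(n) * self.length


class _HistogramSampler:
    """Sample from a histogram of gene midpoints (gene-density model)."""

    def __init__(self, edges: np.ndarray, counts: np.ndarray):
        if counts.sum() <= 0:
            # no genes: degenerate to uniform over span
            counts = np.ones_like(counts, dtype=float)
        self.edges = edges
        self.probs = counts / counts.sum()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        bins = rng.choice(len(self.probs), size=n, p=self.probs)
        left = self.edges[bins]
        width = self.edges[bins + 1] - left
        return left + rng.random(n) * width


class _ReflectedSampler:
    """Draw a folded relative position, then unfold with a fair coin."""

    def __init__(self, density: BoundaryDensity, length: float):
        self.density = density
        self.length = length

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = self.density.sample(n, rng)
        flip = rng.random(n) < 0.5
        rel = np.where(flip, 1.0 - r, r)
        return np.clip(rel * self.length, 0.0, np.nextafter(self.length, 0.0))


class _SegmentedSampler:
    """One reflected density per breakpoint-delimited segment (double-adj)."""

    def __init__(self, segments: list[tuple[float, float, float]], density: BoundaryDensity):
        # segments: (start, end, weight)
        starts = np.array([s for s, _, _ in segments])
        ends = np.array([e for _, e, _ in segments])
        weights = np.array([w for _, _, w in segments], dtype=float)
        if weights.sum() <= 0:
            weights = ends - starts
        self.starts, self.ends = starts, ends
        self.weights = weights / weights.sum()
        self.inner = [
            _ReflectedSampler(density, e - s) for s, e in zip(starts, ends)
        ]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        seg = rng.choice(len(self.inner), size=n, p=self.weights)
        out = np.empty(n)
        for i, sampler in enumerate(self.inner):
            mask = seg == i
            k = int(mask.sum())
            if k:
                out[mask] = self.starts[i] + sampler.sample(k, rng)
        return out


@dataclass
class NullModel:
    """A fully specified positional null: chromosome weights plus per-chromosome samplers."""

    kind: str
    chroms: list[str]
    chrom_lengths: dict[str, float]
    chrom_weights: np.ndarray
    samplers: dict[str, object]
    bandwidth: float = 0.15
    breakpoints: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.chrom_weights, dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("chromosome weights must sum to 1")
        self.chrom_weights = w

    def sample_arrays(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw n positions; returns (chromosome index array, bp position array)."""
        cumw = np.cumsum(self.chrom_weights)
        cumw[-1] = 1.0
        u = rng.random(n)
        idx = np.searchsorted(cumw, u, side="right")
        if all(isinstance(s, _UniformSampler) for s in self.samplers.values()):
            # inversion shortcut: the offset of u within its chromosome's
            # weight bin is itself uniform, so it can serve as the position
            lengths = np.array([self.samplers[c].length for c in self.chroms])
            lo = np.concatenate([[0.0], cumw[:-1]])
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = (u - lo[idx]) / self.chrom_weights[idx]
            return idx, np.clip(frac, 0.0, 1.0 - 1e-12) * lengths[idx]
        pos = np.empty(n)
        for i, chrom in enumerate(self.chroms):
            mask = idx == i
            k = int(mask.sum())
            if k:
                pos[mask] = self.samplers[chrom].sample(k, rng)
        return idx, pos

    def density_frame(self, n_grid: int = 201):
        """Per-chromosome density on a relative-position grid, for inspection."""
        import pandas as pd

        rows = []
        for chrom in self.chroms:
            L = self.chrom_lengths[chrom]
            grid = np.linspace(0, L, n_grid, endpoint=False)
            # estimate density by sampling-free evaluation where possible
            sampler = self.samplers[chrom]
            if isinstance(sampler, _UniformSampler):
                dens = np.full(n_grid, 1.0 / L)
            elif isinstance(sampler, _ReflectedSampler):
                rel = np.minimum(grid / L, 1 - grid / L)
                dens = sampler.density(rel) / L
            elif isinstance(sampler, _SegmentedSampler):
                dens = np.zeros(n_grid)
                for (s, e, w), inner in zip(
                    zip(sampler.starts, sampler.ends, sampler.weights), sampler.inner
                ):
                    seglen = e - s
                    in_seg = (grid >= s) & (grid < e)
                    rel = np.minimum((grid[in_seg] - s) / seglen, 1 - (grid[in_seg] - s) / seglen)
                    dens[in_seg] = w * inner.density(rel) / seglen
            else:  # histogram
                edges, probs = sampler.edges, sampler.probs
                widths = np.diff(edges)
                bin_idx = np.clip(np.searchsorted(edges, grid, side="right") - 1, 0, len(probs) - 1)
                dens = probs[bin_idx] / widths[bin_idx]
            for g, d in zip(grid, dens):
                rows.append({"chrom": chrom, "pos": g, "density": d})
        return pd.DataFrame(rows)


def build_null_model(
    kind: str,
    genome: Genome,
    events_for_fit: Sequence[tuple[str, float]] | None = None,
    breakpoints: Mapping[str, float] | None = None,
    bandwidth: float = 0.15,
    exclude_chroms: Sequence[str] = (),
    gene_density_bin: int = 500_000,
) -> NullModel:
    """Construct one of the four positional null models.

    ``events_for_fit`` is a sequence of (chrom, position) pairs of observed
    events of the type being modelled; only events on chromosomes *not* in
    ``exclude_chroms`` (the macro-rearranged ones) contribute to the fitted
    density, matching the idea that the adjusted models describe the
    baseline positional preference of events on architecturally conserved
    chromosomes.  ``breakpoints`` (chromosome -> bp) is required for
    ``double_adj``; chromosomes without a listed breakpoint fall back to the
    single, whole-chromosome fitted density.
    """
    if kind not in NULL_KINDS:
        raise ValueError(f"unknown null model kind {kind!r}; expected one of {NULL_KINDS}")

    by_chrom = genome.genes_by_chrom()
    chroms = [c for c in genome.chrom_lengths]
    counts = np.array([len(by_chrom[c]) for c in chroms], dtype=float)
    for c, n in zip(chroms, counts):
        if n == 0:
            logger.warning("chromosome %s has no genes; weight 0 under gene-count weighting", c)
    if counts.sum() == 0:
        raise ValueError("genome has no genes; cannot weight chromosomes")
    weights = counts / counts.sum()
    lengths = {c: float(genome.chrom_lengths[c]) for c in chroms}

    samplers: dict[str, object] = {}
    bps: dict[str, float] = dict(breakpoints or {})

    if kind == "flat":
        for c in chroms:
            samplers[c] = _UniformSampler(lengths[c])
    elif kind == "gene_density":
        for c in chroms:
            L = lengths[c]
            edges = np.arange(0.0, L + gene_density_bin, gene_density_bin)
            edges[-1] = max(edges[-1], L)
            mids = np.array([g.midpoint for g in by_chrom[c]])
            hist, _ = np.histogram(mids, bins=edges)
            samplers[c] = _HistogramSampler(edges, hist.astype(float))
    else:
        fit_events = [
            (c, p) for c, p in (events_for_fit or []) if c not in set(exclude_chroms)
        ]
        folded = np.concatenate(
            [
                reflect_rescale([p], lengths[c])
                for c, p in fit_events
                if c in lengths
            ]
        ) if fit_events else np.array([])
        density = fit_boundary_density(folded, bandwidth=bandwidth)
        if kind == "single_adj":
            for c in chroms:
                samplers[c] = _ReflectedSampler(density, lengths[c])
        else:  # double_adj
            if not bps:
                raise ValueError("double_adj model requires breakpoints")
            for c in chroms:
                if c in bps:
                    bp = float(bps[c])
                    if not (0 < bp < lengths[c]):
                        raise ValueError(f"breakpoint {bp} outside chromosome {c}")
                    seg_counts = [
                        sum(1 for g in by_chrom[c] if g.midpoint < bp),
                        sum(1 for g in by_chrom[c] if g.midpoint >= bp),
                    ]
                    segments = [
                        (0.0, bp, float(seg_counts[0])),
                        (bp, lengths[c], float(seg_counts[1])),
                    ]
                    samplers[c] = _SegmentedSampler(segments, density)
                else:
                    samplers[c] = _ReflectedSampler(density, lengths[c])

    return NullModel(
        kind=kind,
        chroms=chroms,
        chrom_lengths=lengths,
        chrom_weights=weights,
        samplers=samplers,
        bandwidth=bandwidth,
        breakpoints=bps,
    )


def sample_positions(
    model: NullModel, n: int, seed: int | np.random.Generator
) -> list[tuple[str, float]]:
    """Draw n (chromosome, bp) positions from a null model, deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx, pos = model.sample_arrays(n, rng)
    return [(model.chroms[i], float(p)) for i, p in zip(idx, pos)]
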