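"""Core domain containers shared across the pipeline.

All coordinates are 0-based half-open internally. GFF3 input (1-based
inclusive) is converted on read and restored on write; BED input is passed
through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "GeneRecord",
    "FeatureRecord",
    "MgeeEvent",
    "Genome",
    "PipelineParams",
    "LSG",
    "REARR",
    "DUP",
]

# MGEE type tags
LSG = "LSG"
REARR = "REARR"
DUP = "DUP"

MGEE_TYPES = (LSG, REARR, DUP)


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its interval, exon structure and representative midpoint.

    The midpoint is the average of CDS midpoints (falling back to exon
    midpoints, then to the interval midpoint).  Downstream positional
    statistics use the midpoint only; the ``extent`` property provides the
    midpoint +/- 1 bp interval used when a non-degenerate extent is needed
    for ordering genes without overlap.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    exons: tuple[tuple[int, int], ...] = ()
    midpoint: float = -1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{s}, {e}) outside gene interval"
                )
        if self.midpoint < 0:
            object.__setattr__(self, "midpoint", _interval_midpoint(self.start, self.end))
        if not (self.start <= self.midpoint < self.end):
            raise ValueError(
                f"gene {self.gene_id}: midpoint {self.midpoint} outside [{self.start}, {self.end})"
            )

    @property
    def extent(self) -> tuple[float, float]:
        """Midpoint +/- 1 bp, a minimal non-overlapping positional extent."""
        return (self.midpoint - 1.0, self.midpoint + 1.0)


def _interval_midpoint(start: int, end: int) -> float:
    return (start + end) / 2.0


@dataclass(frozen=True)
class FeatureRecord:
    """A generic located feature: genomic island, breakpoint, TE or candidate gene.

    ``kind == "breakpoint"`` denotes a point feature (start == end).
    ``label`` carries the island-set name (e.g. "PNW"/"global") or the TE
    class/family (e.g. "LTR.ERV1").
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    kind: str = "island"
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.feature_id}: start {self.start} > end {self.end}"
            )
        if self.kind == "breakpoint" and self.start != self.end:
            raise ValueError(
                f"breakpoint {self.feature_id} must be a point feature (start == end)"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class MgeeEvent:
    """A classified micro genome-evolution event.

    One of three types: a lineage-specific gene (LSG), an interchromosomal
    micro-rearrangement of one or more adjacent genes (REARR), or a
    within-chromosome duplication group (DUP).
    """

    event_id: str
    mgee_type: str
    gene_ids: tuple[str, ...]
    chrom: str
    pos: float
    lineage: str = "stickleback"  # {stickleback, tubesnout, ambiguous}
    confidence: str = "n/a"  # {permissive, stringent, n/a}

    def __post_init__(self) -> None:
        if self.mgee_type not in MGEE_TYPES:
            raise ValueError(f"unknown MGEE type {self.mgee_type!r}")
        if len(self.gene_ids) < 1:
            raise ValueError(f"event {self.event_id}: needs at least one gene")
        if self.mgee_type == LSG and self.confidence not in ("permissive", "stringent"):
            raise ValueError(
                f"LSG event {self.event_id}: confidence must be permissive or stringent"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class Genome:
    """A set of gene records plus chromosome lengths."""

    genes: list[GeneRecord]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for g in self.genes:
            length = self.chrom_lengths.get(g.chrom)
            if length is None:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > length:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chrom} ({length} bp)"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def genes_by_chrom(self) -> dict[str, list[GeneRecord]]:
        """Genes grouped by chromosome, sorted by midpoint."""
        out: dict[str, list[GeneRecord]] = {c: [] for c in self.chrom_lengths}
        for g in self.genes:
            out[g.chrom].append(g)
        for c in out:
            out[c].sort(key=lambda g: (g.midpoint, g.gene_id))
        return out

    def gene_index(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}


#: Default seven window half-widths x spanning 100 kb to 3 Mb.
DEFAULT_WINDOW_SIZES = (
    100_000,
    250_000,
    500_000,
    1_000_000,
    1_500_000,
    2_000_000,
    3_000_000,
)


@dataclass
class PipelineParams:
    """Every numeric threshold used by the pipeline, with field-standard defaults.

    Units: lengths/distances in base pairs, identities in percent, fractions
    in [0, 1]; ``kde_bandwidth`` is on the rescaled [0, 0.5] relative-position
    support.
    """

    min_match_len: int = 100  # homolog hits must exceed this length
    min_identity: float = 75.0  # ... at more than this percent identity
    te_seq_frac: float = 0.50  # gene dropped if > this fraction hits TEs ...
    te_seq_identity: float = 75.0  # ... at > this nucleotide identity
    te_exon_frac: float = 0.10  # gene dropped if > this exon fraction overlaps TEs
    lsg_evalue: float = 0.001  # e-value used by the upstream homology searches
    lsg_permissive_cov: float = 0.90  # region-hit coverage above which an LSG is excluded
    dup_collapse_dist: int = 1_000_000  # adjacent duplicate copies closer than this merge
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    flank_te: int = 50_000  # TE attribution flank around syntenic genes
    te_window: int = 500_000  # TE landscape window (also gene-density bin width)
    te_min_mean: float = 1.0  # families below this mean copies/window are dropped
    kde_bandwidth: float = 0.15  # boundary-kernel bandwidth on [0, 0.5]
    n_perm: int = 10_000  # permutation replicates per enrichment test
    n_mc_draws: int = 100_000  # Monte-Carlo draws for weighted chromosome sampling
    alpha: float = 0.05
    q_thresh: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "min_match_len": self.min_match_len,
            "min_identity": self.min_identity,
            "te_seq_frac": self.te_seq_frac,
            "te_seq_identity": self.te_seq_identity,
            "te_exon_frac": self.te_exon_frac,
            "lsg_evalue": self.lsg_evalue,
            "lsg_permissive_cov": self.lsg_permissive_cov,
            "dup_collapse_dist": self.dup_collapse_dist,
            "flank_te": self.flank_te,
            "te_window": self.te_window,
            "te_min_mean": self.te_min_mean,
            "kde_bandwidth": self.kde_bandwidth,
            "n_perm": self.n_perm,
            "n_mc_draws": self.n_mc_draws,
            "alpha": self.alpha,
            "q_thresh": self.q_thresh,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        ws = tuple(self.window_sizes)
        if list(ws) != sorted(set(ws)):
            raise ValueError("window_sizes must be strictly increasing")
        if ws[0] < 100_000 or ws[-1] > 3_000_000:
            raise ValueError("window_sizes must lie within [100 kb, 3 Mb]")

    def with_updates(self, **kwargs) -> "PipelineParams":
        return replace(self, **kwargs)
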