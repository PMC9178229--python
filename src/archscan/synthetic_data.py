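"""Synthetic multi-species comparative-genomics data with planted truth.

The generator emulates the tabular shape of a real study — a focal
("stickleback") gene annotation, best-hit homolog tables against three
related species (an outgroup "tubesnout", a far outgroup "seabass" and a
sister stickleback "pungitius"), genomic-island BED tracks, a TE
annotation, and a differential-expression gene list — while planting a
known set of micro genome-evolution events so that every downstream stage
can be validated against ground truth.

Planted structure:

* lineage-specific genes lose their outgroup hits but keep a pungitius hit;
* rearranged genes move their (up to five) outgroup hits onto a
  non-homologous chromosome, with the far outgroup either corroborating the
  move (stickleback-lineage signal) or siding with the focal genome
  (tubesnout-lineage decoys, plantable via a rate);
* duplication groups map many-to-one onto a single-copy locus in both
  outgroups;
* all remaining genes are one-to-one collinear.

Event positions can be biased toward chromosome ends (an "end-elevated"
density, a mixture of a uniform and a symmetric triangular density peaked
at both ends) and multiplied by a controllable enrichment factor inside
island regions.  TE tracks are generated with a target rank correlation to
event density via a Gaussian copula, with one optional extreme
single-family hotspot window, and DE labels are planted at a background
rate multiplied up for duplication groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DUP, LSG, REARR, FeatureRecord, GeneRecord, Genome, MgeeEvent
from .te_landscape import tile_windows

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "generate_genome",
    "plant_mgees",
    "generate_te_landscape",
    "generate_de_labels",
]

SPECIES = ("tubesnout", "seabass", "pungitius")
_PREFIX = {"tubesnout": "tub", "seabass": "seb", "pungitius": "pun"}


@dataclass
class SyntheticTruth:
    """Ground truth for a planted dataset."""

    planted_events: list[MgeeEvent]
    gene_assignment: dict[str, str]  # gene_id -> MGEE type (planted genes only)
    enrichment_factor: float
    density_shape: str
    seed: int

    def events_of_type(self, mgee_type: str) -> list[MgeeEvent]:
        return [e for e in self.planted_events if e.mgee_type == mgee_type]

    def event_positions(self) -> list[tuple[str, float]]:
        return [(e.chrom, e.pos) for e in self.planted_events]


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(
    n_chrom: int,
    genes_per_chrom: int,
    chrom_lengths: int | Sequence[int],
    seed: int = 0,
    min_gene_len: int = 1_000,
    max_gene_len: int = 4_000,
) -> Genome:
    """Generate non-overlapping genes on ``n_chrom`` chromosomes.

    Each chromosome is divided into equal slots, one gene per slot with
    jittered position, guaranteeing non-overlap; genes carry 1-3 exons.
    Deterministic for a given seed.
    """
    if n_chrom < 1 or genes_per_chrom < 1:
        raise ValueError("need n_chrom >= 1 and genes_per_chrom >= 1")
    if isinstance(chrom_lengths, (int, np.integer)):
        lengths = [int(chrom_lengths)] * n_chrom
    else:
        lengths = [int(L) for L in chrom_lengths]
        if len(lengths) != n_chrom:
            raise ValueError("chrom_lengths must match n_chrom")
    if any(L <= 0 for L in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    chrom_len_map: dict[str, int] = {}
    for ci, L in enumerate(lengths, start=1):
        chrom = f"chr{ci:02d}"
        chrom_len_map[chrom] = L
        slot = L // genes_per_chrom
        if slot <= min_gene_len + 2:
            raise ValueError(
                f"{genes_per_chrom} genes of >= {min_gene_len} bp cannot fit on a "
                f"{L} bp chromosome"
            )
        for gi in range(genes_per_chrom):
            lo = gi * slot
            glen = int(rng.integers(min_gene_len, min(max_gene_len, slot - 2) + 1))
            start = int(lo + rng.integers(0, slot - glen))
            end = start + glen
            n_exon = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exon - 2, replace=False)) if n_exon > 1 else np.array([], dtype=int)
            bounds = np.concatenate([[0], cuts, [glen]])
            exons = tuple(
                (start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
                for k in range(n_exon)
            )
            exons = tuple((s, e) for s, e in exons if e > s) or ((start, end),)
            mids = [(s + e) / 2.0 for s, e in exons]
            genes.append(
                GeneRecord(
                    gene_id=f"g{ci:02d}_{gi + 1:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=exons,
                    midpoint=float(np.mean(mids)),
                )
            )
    return Genome(genes=genes, chrom_lengths=chrom_len_map)


# ---------------------------------------------------------------------------
# MGEE planting
# ---------------------------------------------------------------------------

def _end_elevated_density(u: np.ndarray, end_weight: float) -> np.ndarray:
    """Mixture density on [0, 1]: uniform plus a triangular peak at both ends.

    The triangular component 2 * (1 - 2 * min(u, 1-u)) integrates to one and
    vanishes at the centre, so the mixture has mean one and biases events
    toward chromosome ends without changing the overall rate.
    """
    m = np.minimum(u, 1.0 - u)
    return (1.0 - end_weight) + end_weight * 2.0 * (1.0 - 2.0 * m)


def _target_chrom(species: str, chrom: str) -> str:
    return _PREFIX[species] + chrom.removeprefix("chr")


def _syntenic_hit(rng, gene: GeneRecord, species: str, rank: int = 1) -> dict:
    return {
        "query_id": gene.gene_id,
        "species": species,
        "chrom": _target_chrom(species, gene.chrom),
        "start": gene.start,
        "end": gene.end,
        "pct_identity": float(np.round(rng.uniform(80.0, 99.0), 2)),
        "match_len": gene.end - gene.start,
        "rank": rank,
        "region_hit_coverage": 0.0,
        "nr_hit": False,
    }


def plant_mgees(
    genome: Genome,
    rates: Mapping[str, float],
    density_shape: str = "uniform",
    island_regions: Sequence[FeatureRecord] = (),
    enrichment_factor: float = 1.0,
    seed: int = 0,
    end_weight: float = 0.6,
    lsg_stringent_frac: float = 0.25,
    rearr_multi_prob: float = 0.2,
    tubesnout_lineage_frac: float = 0.0,
    dup_tandem_prob: float = 0.8,
    exact_counts: Mapping[str, int] | None = None,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Plant LSG/rearrangement/duplication events and emit homolog maps.

    ``rates`` maps event type to the per-gene planting probability; inside
    island regions the probability is multiplied by ``enrichment_factor``.
    ``density_shape`` is "uniform" or "end-elevated" (events biased toward
    chromosome ends with mixture weight ``end_weight``).  A fraction
    ``tubesnout_lineage_frac`` of rearrangements is planted with the
    far-outgroup signal pointing at the focal genome, i.e. as moves on the
    tubesnout lineage that the classifier must exclude.

    ``exact_counts`` optionally fixes the number of planted events per type:
    seed genes are then drawn without replacement with probability
    proportional to the island/density multipliers (so the same enrichment
    structure holds at a fixed event count), and ``rates`` is ignored for
    those types.
    """
    for t in rates:
        if t not in (LSG, REARR, DUP):
            raise ValueError(f"unknown event type {t!r}")
        if not (0.0 <= rates[t] <= 1.0):
            raise ValueError(f"rate for {t} must be in [0, 1]")
    if enrichment_factor < 1.0:
        raise ValueError("enrichment_factor must be >= 1")
    if density_shape not in ("uniform", "end-elevated"):
        raise ValueError("density_shape must be 'uniform' or 'end-elevated'")
    for isl in island_regions:
        L = genome.chrom_lengths.get(isl.chrom)
        if L is None or isl.end > L or isl.start < 0:
            raise ValueError(f"island {isl.feature_id} outside the genome")

    rng = np.random.default_rng(seed)
    by_chrom = genome.genes_by_chrom()
    n_chrom = len(genome.chrom_lengths)
    chrom_names = list(genome.chrom_lengths)

    def in_island(g: GeneRecord) -> bool:
        return any(
            isl.chrom == g.chrom and isl.start <= g.midpoint < isl.end
            for isl in island_regions
        )

    assignment: dict[str, str] = {}
    groups: list[tuple[str, list[GeneRecord]]] = []  # (type, member genes)
    rearr_lineage: dict[str, str] = {}  # first member gene id -> lineage

    exact_counts = dict(exact_counts or {})
    pre_selected: dict[str, str] = {}
    if exact_counts:
        pool: list[GeneRecord] = [g for chrom in chrom_names for g in by_chrom[chrom]]
        w = np.empty(len(pool))
        for j, g in enumerate(pool):
            u = g.midpoint / genome.chrom_lengths[g.chrom]
            dens = (
                _end_elevated_density(np.array([u]), end_weight)[0]
                if density_shape == "end-elevated"
                else 1.0
            )
            w[j] = (enrichment_factor if in_island(g) else 1.0) * dens
        taken = np.zeros(len(pool), dtype=bool)
        for t in (LSG, REARR, DUP):
            k = int(exact_counts.get(t, 0))
            if k == 0:
                continue
            if k > int((~taken).sum()):
                raise ValueError(f"cannot plant {k} {t} events: not enough free genes")
            keys = np.log(w) + rng.gumbel(size=len(pool))
            keys[taken] = -np.inf
            top = np.argsort(keys)[::-1][:k]
            taken[top] = True
            for j in top:
                pre_selected[pool[j].gene_id] = t

    for chrom in chrom_names:
        ordered = by_chrom[chrom]
        L = genome.chrom_lengths[chrom]
        i = 0
        while i < len(ordered):
            g = ordered[i]
            if g.gene_id in assignment:
                i += 1
                continue
            u = g.midpoint / L
            dens = (
                _end_elevated_density(np.array([u]), end_weight)[0]
                if density_shape == "end-elevated"
                else 1.0
            )
            mult = enrichment_factor if in_island(g) else 1.0
            chosen = pre_selected.get(g.gene_id)
            if chosen is None:
                for t in (LSG, REARR, DUP):
                    if t in exact_counts:
                        continue
                    p = min(rates.get(t, 0.0) * mult * dens, 0.95)
                    if p > 0 and rng.random() < p:
                        chosen = t
                        break
            if chosen is None:
                i += 1
                continue
            members = [g]
            assignment[g.gene_id] = chosen
            if chosen == REARR:
                while (
                    rng.random() < rearr_multi_prob
                    and i + len(members) < len(ordered)
                    and ordered[i + len(members)].gene_id not in assignment
                    and ordered[i + len(members)].gene_id not in pre_selected
                    and len(members) < 3
                ):
                    nxt = ordered[i + len(members)]
                    members.append(nxt)
                    assignment[nxt.gene_id] = REARR
                rearr_lineage[g.gene_id] = (
                    "tubesnout" if rng.random() < tubesnout_lineage_frac else "stickleback"
                )
            elif chosen == DUP:
                partner = None
                if (
                    rng.random() < dup_tandem_prob
                    and i + 1 < len(ordered)
                    and ordered[i + 1].gene_id not in assignment
                    and ordered[i + 1].gene_id not in pre_selected
                ):
                    partner = ordered[i + 1]
                else:
                    free = [
                        h for h in ordered
                        if h.gene_id not in assignment and h.gene_id not in pre_selected
                    ]
                    if free:
                        partner = free[int(rng.integers(0, len(free)))]
                if partner is None:
                    # no partner available: cannot plant a duplication here
                    del assignment[g.gene_id]
                    i += 1
                    continue
                members.append(partner)
                assignment[partner.gene_id] = DUP
            groups.append((chosen, members))
            i += 1

    # --- emit homolog tables -------------------------------------------------
    rows: list[dict] = []
    truth_events: list[MgeeEvent] = []
    counters = {LSG: 0, REARR: 0, DUP: 0}

    planted_ids = set(assignment)
    for chrom in chrom_names:
        for g in by_chrom[chrom]:
            if g.gene_id in planted_ids:
                continue
            for sp in SPECIES:
                rows.append(_syntenic_hit(rng, g, sp))

    for t, members in groups:
        counters[t] += 1
        first = members[0]
        chrom = first.chrom
        ci = chrom_names.index(chrom)
        if t == LSG:
            g = first
            stringent = rng.random() < lsg_stringent_frac
            hit = _syntenic_hit(rng, g, "pungitius")
            hit["region_hit_coverage"] = (
                0.0 if stringent else float(np.round(rng.uniform(0.05, 0.90), 3))
            )
            rows.append(hit)
            truth_events.append(
                MgeeEvent(
                    event_id=f"true_lsg_{counters[t]:04d}",
                    mgee_type=LSG,
                    gene_ids=(g.gene_id,),
                    chrom=chrom,
                    pos=g.midpoint,
                    lineage="stickleback",
                    confidence="stringent" if stringent else "permissive",
                )
            )
        elif t == REARR:
            lineage = rearr_lineage[first.gene_id]
            other_ci = int(rng.integers(0, n_chrom - 1))
            if other_ci >= ci:
                other_ci += 1
            other_chrom = chrom_names[other_ci]
            other_L = genome.chrom_lengths[other_chrom]
            for g in members:
                glen = g.end - g.start
                n_hits = int(rng.integers(1, 4))
                start0 = int(rng.integers(0, max(other_L - glen, 1)))
                for r in range(1, n_hits + 1):
                    s = start0 if r == 1 else int(rng.integers(0, max(other_L - glen, 1)))
                    rows.append(
                        {
                            "query_id": g.gene_id,
                            "species": "tubesnout",
                            "chrom": _target_chrom("tubesnout", other_chrom),
                            "start": s,
                            "end": s + glen,
                            "pct_identity": float(np.round(rng.uniform(78.0, 95.0), 2)),
                            "match_len": glen,
                            "rank": r,
                            "region_hit_coverage": 0.0,
                            "nr_hit": False,
                        }
                    )
                seb_chrom = other_chrom if lineage == "stickleback" else chrom
                seb = _syntenic_hit(rng, g, "seabass")
                seb["chrom"] = _target_chrom("seabass", seb_chrom)
                if lineage == "stickleback":
                    seb["start"], seb["end"] = start0, start0 + glen
                rows.append(seb)
                rows.append(_syntenic_hit(rng, g, "pungitius"))
            truth_events.append(
                MgeeEvent(
                    event_id=f"true_rearr_{counters[t]:04d}",
                    mgee_type=REARR,
                    gene_ids=tuple(g.gene_id for g in members),
                    chrom=chrom,
                    pos=float(np.mean([g.midpoint for g in members])),
                    lineage=lineage,
                )
            )
        else:  # DUP
            anchor = members[0]
            for sp in ("tubesnout", "seabass"):
                target_chrom = _target_chrom(sp, chrom)
                for g in members:
                    rows.append(
                        {
                            "query_id": g.gene_id,
                            "species": sp,
                            "chrom": target_chrom,
                            "start": anchor.start,
                            "end": anchor.end,
                            "pct_identity": float(np.round(rng.uniform(80.0, 99.0), 2)),
                            "match_len": anchor.end - anchor.start,
                            "rank": 1,
                            "region_hit_coverage": 0.0,
                            "nr_hit": False,
                        }
                    )
            for g in members:
                rows.append(_syntenic_hit(rng, g, "pungitius"))
            members_sorted = sorted(members, key=lambda g: g.midpoint)
            truth_events.append(
                MgeeEvent(
                    event_id=f"true_dup_{counters[t]:04d}",
                    mgee_type=DUP,
                    gene_ids=tuple(g.gene_id for g in members_sorted),
                    chrom=chrom,
                    pos=float(np.mean([g.midpoint for g in members_sorted])),
                    lineage="stickleback",
                )
            )

    df = pd.DataFrame(
        rows,
        columns=[
            "query_id", "species", "chrom", "start", "end",
            "pct_identity", "match_len", "rank", "region_hit_coverage", "nr_hit",
        ],
    )
    maps = {
        sp: df.loc[df["species"] == sp].reset_index(drop=True) for sp in SPECIES
    }
    truth = SyntheticTruth(
        planted_events=truth_events,
        gene_assignment=assignment,
        enrichment_factor=enrichment_factor,
        density_shape=density_shape,
        seed=seed,
    )
    return maps, truth


# ---------------------------------------------------------------------------
# TE landscape
# ---------------------------------------------------------------------------

def generate_te_landscape(
    genome: Genome,
    event_positions: Sequence[tuple[str, float]] = (),
    base_density: float = 20.0,
    corr_with_events: float = 0.0,
    hotspot: tuple[str, float] | None = None,
    families: Sequence[str] = ("LTR.ERV1", "DNA.hAT", "LINE.L2", "LTR.Gypsy"),
    family_weights: Sequence[float] | None = None,
    te_window: int = 500_000,
    anchor_genes: Sequence[GeneRecord] | None = None,
    flank: int = 50_000,
    seed: int = 0,
) -> tuple[list[FeatureRecord], pd.DataFrame]:
    """Generate a TE annotation whose window counts track event density.

    Per-window total TE counts follow a Gaussian copula against the
    planted event counts, targeting Kendall correlation
    ``corr_with_events``; counts are split across ``families`` at fixed
    proportions.  ``hotspot = (family, fold)`` forces one window (the one
    with the most planted events, ties broken by position) to carry
    ``fold`` times the genome-wide mean count of that family.  TEs are
    placed inside the flanked neighbourhoods of ``anchor_genes`` (default:
    all genes) so the gene-anchored windowed analysis recovers the planted
    counts.  Returns the TE features and the intended per-window count
    table (total and per family).
    """
    if not (-1.0 < corr_with_events < 1.0):
        raise ValueError("corr_with_events must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    windows = tile_windows(genome.chrom_lengths, te_window)
    W = len(windows)
    ev_counts = np.zeros(W)
    win_index = {
        (w.chrom, w.win_start): i for i, w in enumerate(windows.itertuples(index=False))
    }
    for chrom, pos in event_positions:
        key = (chrom, int(pos // te_window) * te_window)
        if key in win_index:
            ev_counts[win_index[key]] += 1

    # Gaussian copula: rank-transform event counts (jittered to break ties),
    # correlate a latent normal, and map through the Poisson quantile.
    rho = float(np.sin(np.pi * corr_with_events / 2.0))
    jitter = ev_counts + rng.uniform(0, 1e-6, W)
    z_e = stats.norm.ppf((stats.rankdata(jitter) - 0.5) / W)
    eps = rng.standard_normal(W)
    latent = rho * z_e + np.sqrt(max(1.0 - rho * rho, 0.0)) * eps
    u = stats.norm.cdf(latent)
    totals = stats.poisson.ppf(np.clip(u, 1e-12, 1 - 1e-12), base_density).astype(int)

    fams = list(families)
    wts = np.asarray(
        family_weights if family_weights is not None else np.ones(len(fams)), dtype=float
    )
    wts = wts / wts.sum()
    fam_counts = np.zeros((W, len(fams)), dtype=int)
    for i in range(W):
        if totals[i] > 0:
            fam_counts[i] = rng.multinomial(totals[i], wts)

    if hotspot is not None:
        fam, fold = hotspot
        if fam not in fams:
            raise ValueError(f"hotspot family {fam!r} not among families")
        fi = fams.index(fam)
        hot_w = int(np.argmax(ev_counts)) if ev_counts.max() > 0 else W // 2
        fam_mean = base_density * wts[fi]
        fam_counts[hot_w, fi] = int(round(fold * fam_mean))
        totals = fam_counts.sum(axis=1)

    anchors = list(anchor_genes) if anchor_genes is not None else list(genome.genes)
    anchors_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in anchors:
        anchors_by_chrom.setdefault(g.chrom, []).append(g)

    tes: list[FeatureRecord] = []
    te_id = 0
    for i, w in enumerate(windows.itertuples(index=False)):
        n_te = int(totals[i])
        if n_te == 0:
            continue
        # candidate placement intervals: gene neighbourhoods clipped to window
        ivals: list[tuple[int, int]] = []
        for g in anchors_by_chrom.get(w.chrom, []):
            if w.win_start <= g.midpoint < w.win_end:
                s = max(g.start - flank + 1, w.win_start)
                e = min(g.end + flank - 1, w.win_end)
                if e > s:
                    ivals.append((s, e))
        if not ivals:
            ivals = [(w.win_start, w.win_end)]
        lens = np.array([e - s for s, e in ivals], dtype=float)
        probs = lens / lens.sum()
        fam_of_te = np.repeat(np.arange(len(fams)), fam_counts[i])
        which = rng.choice(len(ivals), size=n_te, p=probs)
        for k in range(n_te):
            s0, e0 = ivals[which[k]]
            tlen = int(rng.integers(200, 2000))
            start = int(rng.integers(s0, max(e0 - tlen, s0) + 1))
            end = min(start + tlen, int(w.win_end))
            te_id += 1
            tes.append(
                FeatureRecord(
                    feature_id=f"te_{te_id:06d}",
                    chrom=w.chrom,
                    start=start,
                    end=max(end, start + 1),
                    kind="te",
                    label=fams[fam_of_te[k]],
                )
            )

    counts = windows.copy()
    counts["count"] = totals
    for fi, fam in enumerate(fams):
        counts[fam] = fam_counts[:, fi]
    return tes, counts


# ---------------------------------------------------------------------------
# Differential-expression labels
# ---------------------------------------------------------------------------

def generate_de_labels(
    genome: Genome,
    truth: SyntheticTruth | None,
    background_rate: float = 0.013,
    dup_multiplier: float = 10.0,
    rearr_multiplier: float = 1.0,
    lsg_multiplier: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant DE labels: background rate everywhere, boosted for event genes.

    Duplication groups are labelled as a unit (one member flagged when the
    group draws DE), matching how the overlap test counts them.  Returns a
    (gene_id, de_flag) table covering every gene.
    """
    if not (0.0 <= background_rate <= 1.0):
        raise ValueError("background_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    flags: dict[str, bool] = {g.gene_id: False for g in genome.genes}
    assignment = truth.gene_assignment if truth else {}
    multipliers = {LSG: lsg_multiplier, REARR: rearr_multiplier, DUP: dup_multiplier}

    dup_groups = truth.events_of_type(DUP) if truth else []
    dup_members = {g for e in dup_groups for g in e.gene_ids}
    for e in dup_groups:
        if rng.random() < min(background_rate * dup_multiplier, 1.0):
            pick = e.gene_ids[int(rng.integers(0, len(e.gene_ids)))]
            flags[pick] = True
    for g in genome.genes:
        if g.gene_id in dup_members:
            continue
        t = assignment.get(g.gene_id)
        rate = background_rate * (multipliers.get(t, 1.0) if t else 1.0)
        if rng.random() < min(rate, 1.0):
            flags[g.gene_id] = True
    return pd.DataFrame(
        {"gene_id": [g.gene_id for g in genome.genes],
         "de_flag": [flags[g.gene_id] for g in genome.genes]}
    )
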