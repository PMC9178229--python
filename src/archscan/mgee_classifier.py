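"""Rule-based calling of micro genome-evolution events from homolog maps.

Three classes of event are called from cross-species best-hit tables:

* **LSG** — a gene shared by the two stickleback genomes (threespine and
  *Pungitius*) with no homolog detectable in either outgroup (tubesnout,
  seabass) and no hit in the wider bony-fish protein database.  A follow-up
  search of the flanking-ortholog-bounded outgroup region tiers the calls:
  no region hit at all gives a *stringent* call, a partial hit (coverage
  <= 90%) a *permissive* call, and higher coverage excludes the gene.
* **REARR** — one or more adjacent genes whose outgroup homologs all lie on
  a chromosome non-homologous to their own, implying interchromosomal
  movement.  A three-taxon parsimony step assigns the lineage: both
  outgroups agreeing on the discordant location places the move on the
  stickleback lineage; seabass agreeing with stickleback places it on the
  tubesnout lineage (excluded); anything else is ambiguous (kept, flagged).
* **DUP** — two or more genes on one stickleback chromosome whose best hits
  collapse onto a single-copy outgroup locus, confirmed independently
  against the second outgroup (otherwise a deletion in the first outgroup
  is the more parsimonious explanation).

Chromosome homology itself is operationalised from the maps: a target
chromosome is homologous to a query chromosome when it receives at least a
support fraction (default 5%) of that query chromosome's one-to-one rank-1
hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import DUP, LSG, REARR, GeneRecord, MgeeEvent, PipelineParams

logger = logging.getLogger(__name__)

__all__ = [
    "filter_te_like_genes",
    "HomologyTable",
    "build_chromosome_homology",
    "call_micro_rearrangements",
    "call_lsgs",
    "call_duplications",
    "collapse_events",
    "MacroCall",
    "detect_macro_candidates",
]


# ---------------------------------------------------------------------------
# TE mis-annotation filtering
# ---------------------------------------------------------------------------

def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap_bp(ival: tuple[int, int], merged: list[tuple[int, int]]) -> int:
    s, e = ival
    total = 0
    for ms, me in merged:
        if me <= s:
            continue
        if ms >= e:
            break
        total += min(e, me) - max(s, ms)
    return total


def filter_te_like_genes(
    genes: Sequence[GeneRecord],
    te_blast_summaries: pd.DataFrame | None,
    te_annotations: Sequence = (),
    params: PipelineParams | None = None,
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Drop genes that are likely mis-annotated transposable elements.

    Two independent rules, both with strict thresholds:

    1. sequence rule — more than 50% of the gene's sequence hits TEs at more
       than 75% nucleotide identity (``te_blast_summaries`` columns:
       gene_id, te_hit_frac, te_hit_identity);
    2. exon-overlap rule — more than 10% of the gene's exon sequence
       overlaps TE annotations.

    Returns the retained genes plus a report naming the rule that removed
    each dropped gene.  A gene without exons is treated as a single exon
    spanning the whole gene (logged).
    """
    params = params or PipelineParams()
    summaries: dict[str, tuple[float, float]] = {}
    if te_blast_summaries is not None and len(te_blast_summaries):
        for row in te_blast_summaries.itertuples(index=False):
            summaries[str(row.gene_id)] = (
                float(row.te_hit_frac),
                float(row.te_hit_identity),
            )

    te_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for te in te_annotations:
        te_by_chrom.setdefault(te.chrom, []).append((te.start, te.end))
    te_by_chrom = {c: _merge_intervals(iv) for c, iv in te_by_chrom.items()}

    retained: list[GeneRecord] = []
    removals: list[dict] = []
    for gene in genes:
        frac, ident = summaries.get(gene.gene_id, (0.0, 0.0))
        if frac > params.te_seq_frac and ident > params.te_seq_identity:
            removals.append(
                {"gene_id": gene.gene_id, "rule": "te_sequence",
                 "value": frac, "threshold": params.te_seq_frac}
            )
            continue
        exons = list(gene.exons)
        if not exons:
            logger.info("gene %s has no exons; using full gene interval", gene.gene_id)
            exons = [(gene.start, gene.end)]
        merged = te_by_chrom.get(gene.chrom, [])
        exon_bp = sum(e - s for s, e in exons)
        ovl_bp = sum(_overlap_bp(iv, merged) for iv in exons)
        ovl_frac = ovl_bp / exon_bp if exon_bp else 0.0
        if ovl_frac > params.te_exon_frac:
            removals.append(
                {"gene_id": gene.gene_id, "rule": "te_exon_overlap",
                 "value": ovl_frac, "threshold": params.te_exon_frac}
            )
            continue
        retained.append(gene)
    report = pd.DataFrame(removals, columns=["gene_id", "rule", "value", "threshold"])
    return retained, report


# ---------------------------------------------------------------------------
# Chromosome homology
# ---------------------------------------------------------------------------

@dataclass
class HomologyTable:
    """Homologous target chromosomes per query chromosome, with hit support."""

    species: str
    min_support_frac: float
    homologs: dict[str, set[str]]
    support: dict[str, dict[str, int]]

    def homologous(self, query_chrom: str) -> set[str]:
        return self.homologs.get(query_chrom, set())


def _rank1(hits: pd.DataFrame) -> pd.DataFrame:
    return hits.loc[hits["rank"] == 1]


def _cluster_target_loci(rank1: pd.DataFrame) -> pd.Series:
    """Assign a target-locus id to each rank-1 hit by interval overlap.

    Hits on the same target chromosome whose intervals overlap are taken to
    point at the same target gene; this turns best-hit coordinates into a
    discrete many-to-one structure without needing target gene ids.
    """
    locus = pd.Series(index=rank1.index, dtype=object)
    for chrom, grp in rank1.groupby("chrom", sort=True):
        g = grp.sort_values(["start", "end"])
        current_end = -1
        cluster = -1
        for idx, row in zip(g.index, g.itertuples(index=False)):
            if row.start >= current_end:
                cluster += 1
                current_end = row.end
            else:
                current_end = max(current_end, row.end)
            locus.loc[idx] = f"{chrom}:{cluster}"
    return locus


def build_chromosome_homology(
    homolog_map: pd.DataFrame,
    species: str,
    genes: Sequence[GeneRecord],
    min_support_frac: float = 0.05,
) -> HomologyTable:
    """Identify homologous target chromosome(s) for each query chromosome.

    Only one-to-one rank-1 hits vote (queries whose best hit shares a target
    locus with another query are excluded, since duplicated loci carry no
    clean synteny signal).  A target chromosome is listed when it receives
    at least ``min_support_frac`` of a query chromosome's voting hits.
    """
    gene_chrom = {g.gene_id: g.chrom for g in genes}
    hits = homolog_map.loc[homolog_map["species"] == species]
    r1 = _rank1(hits)
    if len(r1) == 0:
        logger.warning("no rank-1 hits for species %s", species)
        return HomologyTable(species, min_support_frac, {}, {})
    locus = _cluster_target_loci(r1)
    locus_sizes = locus.value_counts()
    one_to_one = r1.loc[locus.map(locus_sizes).eq(1).values]

    support: dict[str, dict[str, int]] = {}
    for row in one_to_one.itertuples(index=False):
        qchrom = gene_chrom.get(row.query_id)
        if qchrom is None:
            continue
        support.setdefault(qchrom, {}).setdefault(row.chrom, 0)
        support[qchrom][row.chrom] += 1

    homologs: dict[str, set[str]] = {}
    for qchrom, counts in support.items():
        total = sum(counts.values())
        homologs[qchrom] = {
            t for t, n in counts.items() if total and n / total >= min_support_frac
        }
    for g in genes:
        if g.chrom not in homologs:
            homologs.setdefault(g.chrom, set())
    for qchrom, hset in homologs.items():
        if not hset:
            logger.warning(
                "query chromosome %s: no homologous %s chromosome identified",
                qchrom, species,
            )
    return HomologyTable(species, min_support_frac, homologs, support)


# ---------------------------------------------------------------------------
# Case B: micro-rearrangements
# ---------------------------------------------------------------------------

def _chrom_concordance(
    tables: Mapping[str, HomologyTable]
) -> set[tuple[str, str]]:
    """Pairs (tubesnout chrom, seabass chrom) homologous to a common query chromosome."""
    pairs: set[tuple[str, str]] = set()
    tub, seb = tables["tubesnout"], tables["seabass"]
    for qchrom in set(tub.homologs) | set(seb.homologs):
        for t in tub.homologous(qchrom):
            for s in seb.homologous(qchrom):
                pairs.add((t, s))
    return pairs


def call_micro_rearrangements(
    genes: Sequence[GeneRecord],
    maps: Mapping[str, pd.DataFrame],
    homology_tables: Mapping[str, HomologyTable],
    params: PipelineParams | None = None,
    max_rank: int = 5,
) -> list[MgeeEvent]:
    """Call putative interchromosomal micro-rearrangements.

    A gene is a candidate when none of its (up to ``max_rank``) tubesnout
    hits fall on a chromosome homologous to its own.  Lineage is assigned by
    outgroup parsimony on the best-hit chromosomes; tubesnout-lineage cases
    are excluded, ambiguous ones kept and flagged.  Genes whose
    flanking-ortholog-bounded tubesnout region produced a homology hit
    (region_hit_coverage > 0) are excluded as likely detection failures
    rather than true moves.  Consecutive candidate genes merge into a single
    multi-gene event.
    """
    params = params or PipelineParams()
    gene_ids = {g.gene_id for g in genes}
    tub_hits = maps["tubesnout"]
    unknown = set(tub_hits["query_id"]) - gene_ids
    if unknown:
        raise ValueError(f"homolog map queries absent from annotation: {sorted(unknown)[:5]}")
    seb_hits = maps.get("seabass")
    tub_table = homology_tables["tubesnout"]
    seb_table = homology_tables.get("seabass")
    concordant = (
        _chrom_concordance({"tubesnout": tub_table, "seabass": seb_table})
        if seb_table is not None
        else set()
    )

    tub_by_query = dict(tuple(tub_hits.groupby("query_id", sort=False)))
    seb_best: dict[str, str] = {}
    if seb_hits is not None:
        b = _rank1(seb_hits)
        seb_best = dict(zip(b["query_id"], b["chrom"]))

    candidates: dict[str, str] = {}  # gene_id -> lineage
    for gene in genes:
        rows = tub_by_query.get(gene.gene_id)
        if rows is None:
            continue  # no tubesnout homolog at all: case A territory
        rows = rows.loc[rows["rank"] <= max_rank]
        if len(rows) == 0:
            continue
        homologs = tub_table.homologous(gene.chrom)
        if any(c in homologs for c in rows["chrom"]):
            continue  # at least one syntenic mapping: not rearranged
        if float(rows["region_hit_coverage"].max()) > 0:
            continue  # homology detectable in the syntenic region: excluded
        tub_best = rows.loc[rows["rank"].idxmin(), "chrom"]
        lineage = "ambiguous"
        seb_chrom = seb_best.get(gene.gene_id)
        if seb_chrom is not None and seb_table is not None:
            if seb_chrom in seb_table.homologous(gene.chrom):
                lineage = "tubesnout"  # seabass agrees with stickleback
            elif (tub_best, seb_chrom) in concordant:
                lineage = "stickleback"  # outgroups agree with each other
        if lineage == "tubesnout":
            continue  # occurred on the tubesnout lineage: excluded
        candidates[gene.gene_id] = lineage

    # merge consecutive candidate genes (gene-order adjacency) into events
    events: list[MgeeEvent] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.midpoint, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)
    counter = 0
    for chrom, ordered in sorted(by_chrom.items()):
        run: list[GeneRecord] = []
        for g in ordered + [None]:
            if g is not None and g.gene_id in candidates:
                run.append(g)
                continue
            if run:
                counter += 1
                lineages = {candidates[m.gene_id] for m in run}
                lineage = "stickleback" if lineages == {"stickleback"} else "ambiguous"
                pos = float(np.mean([m.midpoint for m in run]))
                events.append(
                    MgeeEvent(
                        event_id=f"rearr_{counter:04d}",
                        mgee_type=REARR,
                        gene_ids=tuple(m.gene_id for m in run),
                        chrom=chrom,
                        pos=pos,
                        lineage=lineage,
                    )
                )
                run = []
    return events


# ---------------------------------------------------------------------------
# Case A: lineage-specific genes
# ---------------------------------------------------------------------------

def call_lsgs(
    genes: Sequence[GeneRecord],
    maps: Mapping[str, pd.DataFrame],
    params: PipelineParams | None = None,
) -> list[MgeeEvent]:
    """Call lineage-specific genes, tiered by confidence.

    A gene qualifies when it has no retained hit in tubesnout or seabass, at
    least one hit in *Pungitius* (establishing that the gene is shared by
    both stickleback genomes and so predates their split), and no hit in the
    bony-fish protein database (nr_hit).  The flanking-region search
    coverage then tiers the call: zero/absent coverage is *stringent*,
    coverage at or below 90% is *permissive* only, and higher coverage
    excludes the gene.  The stringent set is by construction a subset of the
    permissive set.
    """
    params = params or PipelineParams()
    if "pungitius" not in maps:
        raise ValueError("a pungitius map is required to establish stickleback-clade LSGs")
    tub_queries = set(maps["tubesnout"]["query_id"]) if "tubesnout" in maps else set()
    seb_queries = set(maps["seabass"]["query_id"]) if "seabass" in maps else set()
    pun = maps["pungitius"]
    pun_by_query = dict(tuple(pun.groupby("query_id", sort=False)))

    events: list[MgeeEvent] = []
    counter = 0
    for gene in sorted(genes, key=lambda g: (g.chrom, g.midpoint, g.gene_id)):
        if gene.gene_id in tub_queries or gene.gene_id in seb_queries:
            continue
        rows = pun_by_query.get(gene.gene_id)
        if rows is None:
            continue  # not shared with Pungitius: cannot call as clade LSG
        if bool(rows["nr_hit"].any()):
            continue  # detectable in the wider protein database
        coverage = float(rows["region_hit_coverage"].max())
        if coverage > params.lsg_permissive_cov:
            continue  # likely a missed homolog, excluded entirely
        confidence = "stringent" if coverage <= 0 else "permissive"
        counter += 1
        events.append(
            MgeeEvent(
                event_id=f"lsg_{counter:04d}",
                mgee_type=LSG,
                gene_ids=(gene.gene_id,),
                chrom=gene.chrom,
                pos=gene.midpoint,
                lineage="stickleback",
                confidence=confidence,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Case C: duplications
# ---------------------------------------------------------------------------

def call_duplications(
    genes: Sequence[GeneRecord],
    maps: Mapping[str, pd.DataFrame],
    params: PipelineParams | None = None,
) -> list[MgeeEvent]:
    """Call within-chromosome duplication groups.

    A group is two or more genes on the same stickleback chromosome whose
    rank-1 hits collapse onto one single-copy tubesnout locus.  The group is
    retained only when the same many-to-one pattern holds against seabass;
    otherwise a deletion in tubesnout is the more parsimonious explanation.
    Genes on different chromosomes sharing a target are not duplications
    (they surface as rearrangement candidates instead).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    tub_r1 = _rank1(maps["tubesnout"])
    seb_r1 = _rank1(maps["seabass"]) if "seabass" in maps else pd.DataFrame(columns=maps["tubesnout"].columns)

    tub_locus = _cluster_target_loci(tub_r1)
    seb_locus = _cluster_target_loci(seb_r1) if len(seb_r1) else pd.Series(dtype=object)
    seb_locus_by_query = dict(zip(seb_r1["query_id"], seb_locus)) if len(seb_r1) else {}

    events: list[MgeeEvent] = []
    counter = 0
    groups: dict[str, list[str]] = {}
    for idx, row in zip(tub_r1.index, tub_r1.itertuples(index=False)):
        groups.setdefault(tub_locus.loc[idx], []).append(row.query_id)

    for locus_id in sorted(groups):
        queries = [q for q in groups[locus_id] if q in gene_by_id]
        if len(queries) < 2:
            continue
        by_chrom: dict[str, list[str]] = {}
        for q in queries:
            by_chrom.setdefault(gene_by_id[q].chrom, []).append(q)
        for chrom in sorted(by_chrom):
            members = by_chrom[chrom]
            if len(members) < 2:
                continue
            seb_loci = {seb_locus_by_query.get(q) for q in members}
            if len(seb_loci) != 1 or None in seb_loci:
                continue  # not many-to-one against seabass: removed
            members = sorted(members, key=lambda q: gene_by_id[q].midpoint)
            counter += 1
            pos = float(np.mean([gene_by_id[q].midpoint for q in members]))
            events.append(
                MgeeEvent(
                    event_id=f"dup_{counter:04d}",
                    mgee_type=DUP,
                    gene_ids=tuple(members),
                    chrom=chrom,
                    pos=pos,
                    lineage="stickleback",
                )
            )
    return events


# ---------------------------------------------------------------------------
# Event collapsing
# ---------------------------------------------------------------------------

def collapse_events(
    events: Sequence[MgeeEvent],
    dup_collapse_dist: int = 1_000_000,
    genes: Sequence[GeneRecord] | None = None,
) -> list[MgeeEvent]:
    """Collapse events for counting: one event per rearrangement, and
    duplicate copies closer than ``dup_collapse_dist`` chained into one.

    Multi-gene rearrangements are already single events.  For duplication
    groups, consecutive copies separated by at least the collapse distance
    split the group into separate events; within a chain the event position
    is the midpoint of the merged span.  Idempotent, and no gene appears in
    two events of the same type afterwards.
    """
    gene_pos = {g.gene_id: g.midpoint for g in genes} if genes else {}
    out: list[MgeeEvent] = []
    seen_by_type: dict[str, set[str]] = {}
    counter: dict[str, int] = {}

    def _emit(ev: MgeeEvent) -> None:
        seen = seen_by_type.setdefault(ev.mgee_type, set())
        kept = tuple(g for g in ev.gene_ids if g not in seen)
        if not kept:
            return
        seen.update(kept)
        out.append(ev if kept == ev.gene_ids else
                   MgeeEvent(ev.event_id, ev.mgee_type, kept, ev.chrom, ev.pos,
                             ev.lineage, ev.confidence))

    for ev in sorted(events, key=lambda e: (e.mgee_type, e.chrom, e.pos, e.event_id)):
        if ev.mgee_type != DUP or ev.n_genes < 2:
            _emit(ev)
            continue
        positions = [gene_pos.get(g) for g in ev.gene_ids]
        if any(p is None for p in positions):
            # without gene coordinates, treat the group as one event
            _emit(ev)
            continue
        order = np.argsort(positions)
        chains: list[list[int]] = [[int(order[0])]]
        for i in order[1:]:
            prev = chains[-1][-1]
            if positions[int(i)] - positions[prev] < dup_collapse_dist:
                chains[-1].append(int(i))
            else:
                chains.append([int(i)])
        for k, chain in enumerate(chains):
            members = tuple(ev.gene_ids[i] for i in chain)
            span = [positions[i] for i in chain]
            pos = (min(span) + max(span)) / 2.0
            eid = ev.event_id if len(chains) == 1 else f"{ev.event_id}.{k + 1}"
            _emit(MgeeEvent(eid, DUP, members, ev.chrom, pos, ev.lineage, ev.confidence))
    return out


# ---------------------------------------------------------------------------
# Macro-rearrangement candidates
# ---------------------------------------------------------------------------

@dataclass
class MacroCall:
    """Per-chromosome macro-architecture classification from synteny runs."""

    chrom: str
    classification: str  # {conserved, fusion_or_translocation, complex, unknown}
    runs: list[tuple[str, int, int]] = field(default_factory=list)  # (target, first, last gene index)
    breakpoints: list[float] = field(default_factory=list)  # bp, between-run midpoints


def detect_macro_candidates(
    genes: Sequence[GeneRecord],
    homolog_map: pd.DataFrame,
    species: str = "tubesnout",
    min_block_genes: int = 5,
    min_run_frac: float = 0.20,
) -> dict[str, MacroCall]:
    """Flag candidate chromosome-scale rearrangements from gene-order runs.

    Each query chromosome's gene order is segmented into maximal runs of
    rank-1 hits to one target chromosome (runs shorter than
    ``min_block_genes`` are ignored as noise).  One qualifying run is a
    conserved chromosome; two runs from two targets each covering at least
    ``min_run_frac`` of mapped genes flag a fusion/translocation candidate,
    with the inferred breakpoint midway between the boundary genes; three or
    more qualifying runs flag a complex history.  A chromosome with no
    mapped genes is classified "unknown".
    """
    hits = homolog_map.loc[homolog_map["species"] == species]
    r1 = _rank1(hits)
    best = dict(zip(r1["query_id"], r1["chrom"]))

    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.midpoint, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)

    calls: dict[str, MacroCall] = {}
    for chrom, ordered in sorted(by_chrom.items()):
        mapped = [(i, g, best[g.gene_id]) for i, g in enumerate(ordered) if g.gene_id in best]
        if not mapped:
            calls[chrom] = MacroCall(chrom, "unknown")
            continue
        # maximal runs of identical target chromosome along gene order
        runs: list[tuple[str, int, int]] = []  # (target, first mapped idx, last mapped idx)
        for j, (i, g, t) in enumerate(mapped):
            if runs and runs[-1][0] == t:
                runs[-1] = (t, runs[-1][1], j)
            else:
                runs.append((t, j, j))
        big = [r for r in runs if r[2] - r[1] + 1 >= min_block_genes]
        # merge adjacent same-target runs that became adjacent after dropping noise
        merged: list[tuple[str, int, int]] = []
        for r in big:
            if merged and merged[-1][0] == r[0]:
                merged[-1] = (r[0], merged[-1][1], r[2])
            else:
                merged.append(r)
        n_mapped = len(mapped)
        qualifying = [
            r for r in merged if (r[2] - r[1] + 1) / n_mapped >= min_run_frac
        ]
        breakpoints = []
        for a, b in zip(merged[:-1], merged[1:]):
            left_gene = mapped[a[2]][1]
            right_gene = mapped[b[1]][1]
            breakpoints.append((left_gene.midpoint + right_gene.midpoint) / 2.0)
        run_view = [
            (t, mapped[f][0], mapped[l][0]) for t, f, l in merged
        ]
        if len(merged) <= 1:
            classification = "conserved"
        elif len(merged) == 2 and len({r[0] for r in merged}) == 2 and len(qualifying) == 2:
            classification = "fusion_or_translocation"
        elif len(merged) >= 3:
            classification = "complex"
        else:
            classification = "conserved"
        calls[chrom] = MacroCall(chrom, classification, run_view, breakpoints)
    return calls
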