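import numpy as np
import pandas as pd
import pytest

from archscan.mgee_classifier import (
    MacroCall,
    build_chromosome_homology,
    call_duplications,
    call_lsgs,
    call_micro_rearrangements,
    collapse_events,
    detect_macro_candidates,
    filter_te_like_genes,
)
from archscan.types import DUP, LSG, REARR, FeatureRecord, GeneRecord, MgeeEvent


def mk_gene(gene_id, chrom, start, end, exons=None):
    return GeneRecord(
        gene_id=gene_id, chrom=chrom, start=start, end=end,
        exons=tuple(exons) if exons else ((start, end),),
    )


def mk_hits(rows):
    cols = ["query_id", "species", "chrom", "start", "end",
            "pct_identity", "match_len", "rank", "region_hit_coverage", "nr_hit"]
    out = []
    for r in rows:
        base = {"pct_identity": 90.0, "rank": 1, "region_hit_coverage": 0.0,
                "nr_hit": False}
        base.update(r)
        base.setdefault("match_len", base["end"] - base["start"])
        out.append(base)
    return pd.DataFrame(out, columns=cols)


# ---------------------------------------------------------------------------
# TE mis-annotation filters
# ---------------------------------------------------------------------------

class TestTeFilters:
    def test_sequence_rule_removes_te_like_gene(self):
        gene = mk_gene("g1", "chr1", 0, 1000)
        summaries = pd.DataFrame(
            [{"gene_id": "g1", "te_hit_frac": 0.6, "te_hit_identity": 80.0}]
        )
        kept, report = filter_te_like_genes([gene], summaries)
        assert kept == [] and report.iloc[0]["rule"] == "te_sequence"

    def test_sequence_rule_thresholds_are_strict(self):
        gene = mk_gene("g1", "chr1", 0, 1000)
        # exactly 50% coverage / exactly 75% identity: retained
        summaries = pd.DataFrame(
            [{"gene_id": "g1", "te_hit_frac": 0.5, "te_hit_identity": 75.0}]
        )
        kept, _ = filter_te_like_genes([gene], summaries)
        assert kept == [gene]

    def test_exon_overlap_boundary_is_strict(self):
        # 9.9% of exon sequence overlapping TEs: retained
        gene = mk_gene("g1", "chr1", 0, 1000)
        tes = [FeatureRecord("te1", "chr1", 0, 99, kind="te")]
        kept, _ = filter_te_like_genes([gene], None, tes)
        assert kept == [gene]
        # 10.1%: removed
        tes = [FeatureRecord("te1", "chr1", 0, 101, kind="te")]
        kept, report = filter_te_like_genes([gene], None, tes)
        assert kept == [] and report.iloc[0]["rule"] == "te_exon_overlap"

    def test_planted_violations_removed_from_cohort(self):
        genes = [mk_gene(f"g{i}", "chr1", i * 10_000, i * 10_000 + 1000) for i in range(10)]
        summaries = pd.DataFrame(
            [{"gene_id": "g3", "te_hit_frac": 0.9, "te_hit_identity": 90.0}]
        )
        tes = [FeatureRecord("te1", "chr1", 70_000, 70_500, kind="te")]  # half of g7
        kept, report = filter_te_like_genes(genes, summaries, tes)
        assert len(kept) == 8
        assert set(report["gene_id"]) == {"g3", "g7"}


# ---------------------------------------------------------------------------
# Chromosome homology
# ---------------------------------------------------------------------------

def _homology_fixture(n_major, n_minor):
    genes, rows = [], []
    for i in range(n_major + n_minor):
        g = mk_gene(f"g{i}", "chrA", i * 1000, i * 1000 + 500)
        genes.append(g)
        target = "t1" if i < n_major else "t2"
        rows.append({"query_id": g.gene_id, "species": "tubesnout",
                     "chrom": target, "start": i * 1000, "end": i * 1000 + 500})
    return genes, mk_hits(rows)


class TestChromosomeHomology:
    def test_unanimous_mapping(self):
        genes, hits = _homology_fixture(20, 0)
        table = build_chromosome_homology(hits, "tubesnout", genes)
        assert table.homologous("chrA") == {"t1"}

    def test_split_above_support_threshold_lists_both(self):
        genes, hits = _homology_fixture(90, 10)
        table = build_chromosome_homology(hits, "tubesnout", genes)
        assert table.homologous("chrA") == {"t1", "t2"}

    def test_split_below_support_threshold_lists_majority_only(self):
        genes, hits = _homology_fixture(97, 3)
        table = build_chromosome_homology(hits, "tubesnout", genes)
        assert table.homologous("chrA") == {"t1"}

    def test_chromosome_without_hits_gets_empty_set(self):
        genes, hits = _homology_fixture(10, 0)
        genes.append(mk_gene("lonely", "chrB", 0, 500))
        table = build_chromosome_homology(hits, "tubesnout", genes)
        assert table.homologous("chrB") == set()


# ---------------------------------------------------------------------------
# Micro-rearrangements
# ---------------------------------------------------------------------------

def _rearr_fixture(move=("g5",), seabass_agrees_with="tubesnout",
                   region_cov=0.0):
    """chrA <-> t1/s1 background plus chrB <-> t9/s9; genes in ``move`` get
    all tubesnout hits on t9."""
    genes, rows = [], []
    for i in range(40):
        g = mk_gene(f"g{i}", "chrA", i * 10_000, i * 10_000 + 1000)
        genes.append(g)
    for i in range(20):
        g = mk_gene(f"h{i}", "chrB", i * 10_000, i * 10_000 + 1000)
        genes.append(g)
    for g in genes:
        tchrom = "t1" if g.chrom == "chrA" else "t9"
        schrom = "s1" if g.chrom == "chrA" else "s9"
        if g.gene_id in move:
            rows.append({"query_id": g.gene_id, "species": "tubesnout",
                         "chrom": "t9", "start": 500_000, "end": 501_000,
                         "region_hit_coverage": region_cov})
            s = "s9" if seabass_agrees_with == "tubesnout" else "s1"
            rows.append({"query_id": g.gene_id, "species": "seabass",
                         "chrom": s, "start": 500_000, "end": 501_000})
        else:
            rows.append({"query_id": g.gene_id, "species": "tubesnout",
                         "chrom": tchrom, "start": g.start, "end": g.end})
            rows.append({"query_id": g.gene_id, "species": "seabass",
                         "chrom": schrom, "start": g.start, "end": g.end})
    hits = mk_hits(rows)
    maps = {sp: hits.loc[hits["species"] == sp].reset_index(drop=True)
            for sp in ("tubesnout", "seabass")}
    tables = {sp: build_chromosome_homology(maps[sp], sp, genes)
              for sp in ("tubesnout", "seabass")}
    return genes, maps, tables


class TestMicroRearrangements:
    def test_syntenic_gene_not_called(self):
        genes, maps, tables = _rearr_fixture(move=())
        assert call_micro_rearrangements(genes, maps, tables) == []

    def test_outgroup_concordance_gives_stickleback_lineage(self):
        genes, maps, tables = _rearr_fixture(move=("g5",))
        (ev,) = call_micro_rearrangements(genes, maps, tables)
        assert ev.mgee_type == REARR
        assert ev.gene_ids == ("g5",) and ev.lineage == "stickleback"

    def test_adjacent_candidates_merge_into_one_event(self):
        genes, maps, tables = _rearr_fixture(move=("g5", "g6"))
        (ev,) = call_micro_rearrangements(genes, maps, tables)
        assert ev.n_genes == 2 and ev.gene_ids == ("g5", "g6")

    def test_tubesnout_lineage_case_excluded(self):
        genes, maps, tables = _rearr_fixture(move=("g5",), seabass_agrees_with="stickleback")
        assert call_micro_rearrangements(genes, maps, tables) == []

    def test_region_homology_hit_excludes_candidate(self):
        genes, maps, tables = _rearr_fixture(move=("g5",), region_cov=0.4)
        assert call_micro_rearrangements(genes, maps, tables) == []

    def test_unknown_query_gene_rejected(self):
        genes, maps, tables = _rearr_fixture()
        with pytest.raises(ValueError, match="absent"):
            call_micro_rearrangements(genes[:5], maps, tables)


# ---------------------------------------------------------------------------
# LSGs
# ---------------------------------------------------------------------------

def _lsg_fixture(region_cov=0.0, nr_hit=False, with_pungitius=True):
    genes = [mk_gene(f"g{i}", "chrA", i * 10_000, i * 10_000 + 1000) for i in range(10)]
    rows = []
    for g in genes[1:]:
        for sp in ("tubesnout", "seabass", "pungitius"):
            rows.append({"query_id": g.gene_id, "species": sp,
                         "chrom": sp[:1] + "1", "start": g.start, "end": g.end})
    # g0: the LSG candidate, pungitius-only
    if with_pungitius:
        rows.append({"query_id": "g0", "species": "pungitius", "chrom": "p1",
                     "start": 0, "end": 1000,
                     "region_hit_coverage": region_cov, "nr_hit": nr_hit})
    hits = mk_hits(rows)
    maps = {sp: hits.loc[hits["species"] == sp].reset_index(drop=True)
            for sp in ("tubesnout", "seabass", "pungitius")}
    return genes, maps


class TestLsgs:
    def test_clean_candidate_is_stringent(self):
        genes, maps = _lsg_fixture()
        (ev,) = call_lsgs(genes, maps)
        assert ev.mgee_type == LSG and ev.confidence == "stringent"
        assert ev.gene_ids == ("g0",)

    def test_partial_region_hit_is_permissive_only(self):
        genes, maps = _lsg_fixture(region_cov=0.5)
        (ev,) = call_lsgs(genes, maps)
        assert ev.confidence == "permissive"

    def test_high_region_coverage_excluded(self):
        genes, maps = _lsg_fixture(region_cov=0.95)
        assert call_lsgs(genes, maps) == []

    def test_nr_database_hit_excluded(self):
        genes, maps = _lsg_fixture(nr_hit=True)
        assert call_lsgs(genes, maps) == []

    def test_gene_absent_from_pungitius_not_called(self):
        genes, maps = _lsg_fixture(with_pungitius=False)
        assert call_lsgs(genes, maps) == []

    def test_missing_pungitius_map_is_an_error(self):
        genes, maps = _lsg_fixture()
        del maps["pungitius"]
        with pytest.raises(ValueError, match="pungitius"):
            call_lsgs(genes, maps)

    def test_stringent_subset_of_permissive(self, small_genome, planted):
        maps, _ = planted
        events = call_lsgs(small_genome.genes, maps)
        stringent = {e.gene_ids for e in events if e.confidence == "stringent"}
        permissive = {e.gene_ids for e in events}  # both tiers are retained calls
        assert stringent <= permissive and len(stringent) < len(permissive)


# ---------------------------------------------------------------------------
# Duplications
# ---------------------------------------------------------------------------

def _dup_fixture(same_chrom=True, seabass_many_to_one=True):
    genes = [mk_gene(f"g{i}", "chrA", i * 10_000, i * 10_000 + 1000) for i in range(10)]
    if not same_chrom:
        genes[5] = mk_gene("g5", "chrB", 50_000, 51_000)
    rows = []
    for g in genes:
        if g.gene_id in ("g4", "g5"):
            rows.append({"query_id": g.gene_id, "species": "tubesnout",
                         "chrom": "t1", "start": 40_000, "end": 41_000})
            if seabass_many_to_one:
                rows.append({"query_id": g.gene_id, "species": "seabass",
                             "chrom": "s1", "start": 40_000, "end": 41_000})
            else:
                rows.append({"query_id": g.gene_id, "species": "seabass",
                             "chrom": "s1", "start": g.start + 1_000_000,
                             "end": g.end + 1_000_000})
        else:
            rows.append({"query_id": g.gene_id, "species": "tubesnout",
                         "chrom": "t1", "start": g.start, "end": g.end})
            rows.append({"query_id": g.gene_id, "species": "seabass",
                         "chrom": "s1", "start": g.start, "end": g.end})
    hits = mk_hits(rows)
    maps = {sp: hits.loc[hits["species"] == sp].reset_index(drop=True)
            for sp in ("tubesnout", "seabass")}
    return genes, maps


class TestDuplications:
    def test_shared_single_copy_target_gives_group(self):
        genes, maps = _dup_fixture()
        (ev,) = call_duplications(genes, maps)
        assert ev.mgee_type == DUP and set(ev.gene_ids) == {"g4", "g5"}

    def test_seabass_one_to_one_removes_group(self):
        genes, maps = _dup_fixture(seabass_many_to_one=False)
        assert call_duplications(genes, maps) == []

    def test_cross_chromosome_sharing_is_not_a_duplication(self):
        genes, maps = _dup_fixture(same_chrom=False)
        assert call_duplications(genes, maps) == []


# ---------------------------------------------------------------------------
# Collapsing
# ---------------------------------------------------------------------------

class TestCollapse:
    def _dup_event(self, positions):
        genes = [mk_gene(f"g{i}", "chr1", int(p), int(p) + 1000)
                 for i, p in enumerate(positions)]
        ev = MgeeEvent("dup_1", DUP, tuple(g.gene_id for g in genes), "chr1",
                       float(np.mean([g.midpoint for g in genes])))
        return ev, genes

    def test_copies_within_collapse_distance_stay_one_event(self):
        ev, genes = self._dup_event([200_000, 900_000])
        out = collapse_events([ev], 1_000_000, genes)
        assert len(out) == 1 and out[0].n_genes == 2

    def test_distant_copies_split_into_two_events(self):
        ev, genes = self._dup_event([200_000, 1_500_000])
        out = collapse_events([ev], 1_000_000, genes)
        assert len(out) == 2 and all(e.n_genes == 1 for e in out)

    def test_collapse_is_idempotent(self):
        ev, genes = self._dup_event([200_000, 900_000, 2_500_000])
        once = collapse_events([ev], 1_000_000, genes)
        twice = collapse_events(once, 1_000_000, genes)
        assert [(e.gene_ids, e.pos) for e in twice] == [(e.gene_ids, e.pos) for e in once]

    def test_no_gene_in_two_events_of_same_type(self):
        ev1 = MgeeEvent("a", REARR, ("g1", "g2"), "chr1", 100.0)
        ev2 = MgeeEvent("b", REARR, ("g2", "g3"), "chr1", 200.0)
        out = collapse_events([ev1, ev2])
        all_genes = [g for e in out for g in e.gene_ids]
        assert len(all_genes) == len(set(all_genes))


# ---------------------------------------------------------------------------
# Macro candidates
# ---------------------------------------------------------------------------

def _macro_fixture(segments):
    """segments: list of (target_chrom, n_genes); genes laid consecutively."""
    genes, rows = [], []
    i = 0
    for target, n in segments:
        for _ in range(n):
            g = mk_gene(f"g{i}", "chrF", i * 100_000, i * 100_000 + 1000)
            genes.append(g)
            rows.append({"query_id": g.gene_id, "species": "tubesnout",
                         "chrom": target, "start": i * 1000, "end": i * 1000 + 500})
            i += 1
    return genes, mk_hits(rows)


class TestMacroCandidates:
    def test_collinear_chromosome_is_conserved(self):
        genes, hits = _macro_fixture([("t1", 60)])
        calls = detect_macro_candidates(genes, hits)
        assert calls["chrF"].classification == "conserved"

    def test_fused_chromosome_flagged_with_breakpoint(self):
        genes, hits = _macro_fixture([("t2", 50), ("t7", 70)])
        calls = detect_macro_candidates(genes, hits)
        call = calls["chrF"]
        assert call.classification == "fusion_or_translocation"
        # breakpoint between gene 49 and gene 50 (one intergenic interval)
        left = genes[49].midpoint
        right = genes[50].midpoint
        assert left < call.breakpoints[0] < right

    def test_three_interleaved_targets_are_complex(self):
        genes, hits = _macro_fixture([("t1", 30), ("t5", 20), ("t9", 25)])
        calls = detect_macro_candidates(genes, hits)
        assert calls["chrF"].classification == "complex"

    def test_unmapped_chromosome_is_unknown(self):
        genes, hits = _macro_fixture([("t1", 10)])
        genes.append(mk_gene("h0", "chrU", 0, 1000))
        calls = detect_macro_candidates(genes, hits)
        assert calls["chrU"].classification == "unknown"

    def test_small_noise_runs_ignored(self):
        genes, hits = _macro_fixture([("t1", 30), ("t9", 2), ("t1", 30)])
        calls = detect_macro_candidates(genes, hits, min_block_genes=5)
        assert calls["chrF"].classification == "conserved"


# ---------------------------------------------------------------------------
# Recovery of planted truth
# ---------------------------------------------------------------------------

class TestPlantedRecovery:
    def test_recall_and_precision_on_unambiguous_planting(self, small_genome, planted):
        maps, truth = planted
        tables = {sp: build_chromosome_homology(maps[sp], sp, small_genome.genes)
                  for sp in ("tubesnout", "seabass")}
        called = {
            LSG: call_lsgs(small_genome.genes, maps),
            REARR: call_micro_rearrangements(small_genome.genes, maps, tables),
            DUP: call_duplications(small_genome.genes, maps),
        }
        for t, events in called.items():
            truth_sets = {frozenset(e.gene_ids) for e in truth.events_of_type(t)}
            called_sets = {frozenset(e.gene_ids) for e in events}
            tp = len(truth_sets & called_sets)
            assert tp / len(called_sets) >= 0.95, f"{t} precision"
            assert tp / len(truth_sets) >= 0.95, f"{t} recall"

    def test_planted_tubesnout_lineage_decoys_are_excluded(self, small_genome):
        from archscan.synthetic_data import plant_mgees

        maps, truth = plant_mgees(
            small_genome, rates={REARR: 0.04}, seed=5, tubesnout_lineage_frac=1.0,
        )
        tables = {sp: build_chromosome_homology(maps[sp], sp, small_genome.genes)
                  for sp in ("tubesnout", "seabass")}
        events = call_micro_rearrangements(small_genome.genes, maps, tables)
        assert truth.planted_events  # decoys were planted
        assert events == []  # ... and all excluded as tubesnout-lineage
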