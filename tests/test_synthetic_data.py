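import numpy as np
import pandas as pd
import pytest
from scipy import stats

from archscan.synthetic_data import (
    generate_de_labels,
    generate_genome,
    generate_te_landscape,
    plant_mgees,
)
from archscan.te_landscape import density_correlation, family_zscores
from archscan.types import DUP, LSG, REARR, FeatureRecord


class TestGenerateGenome:
    def test_gene_counts_and_non_overlap(self):
        g = generate_genome(1, 10, 1_000_000, seed=0)
        assert len(g.genes) == 10
        ordered = sorted(g.genes, key=lambda x: x.start)
        assert all(a.end <= b.start for a, b in zip(ordered, ordered[1:]))

    def test_same_seed_reproduces_distinct_seed_differs(self):
        a = generate_genome(2, 50, 5_000_000, seed=3)
        b = generate_genome(2, 50, 5_000_000, seed=3)
        c = generate_genome(2, 50, 5_000_000, seed=4)
        assert [(g.gene_id, g.start, g.end, g.exons) for g in a.genes] == [
            (g.gene_id, g.start, g.end, g.exons) for g in b.genes
        ]
        assert [(g.start, g.end) for g in a.genes] != [(g.start, g.end) for g in c.genes]

    def test_genes_that_cannot_fit_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            generate_genome(1, 1000, 100_000, seed=0)

    def test_count_conserved_across_serialization(self, tmp_path):
        from archscan import io_tables

        g = generate_genome(2, 30, 3_000_000, seed=1)
        path = tmp_path / "g.gff3"
        io_tables.write_gene_annotation(g.genes, path)
        assert len(io_tables.read_gene_annotation(path)) == 60


class TestPlantMgees:
    def test_zero_rates_give_empty_truth_and_full_synteny(self, small_genome):
        maps, truth = plant_mgees(small_genome, rates={}, seed=0)
        assert truth.planted_events == []
        for sp, df in maps.items():
            assert len(df) == len(small_genome.genes)
            assert (df["rank"] == 1).all()
            # one-to-one: every query maps to a distinct target interval
            assert not df.duplicated(subset=["chrom", "start", "end"]).any()

    def test_bookkeeping_matches_emitted_truth(self, planted):
        maps, truth = planted
        genes_in_events = {g for e in truth.planted_events for g in e.gene_ids}
        assert genes_in_events == set(truth.gene_assignment)
        # no planted LSG/REARR gene keeps an outgroup syntenic presence
        lsg_genes = {g for e in truth.events_of_type(LSG) for g in e.gene_ids}
        assert not lsg_genes & set(maps["tubesnout"]["query_id"])
        assert not lsg_genes & set(maps["seabass"]["query_id"])
        assert lsg_genes <= set(maps["pungitius"]["query_id"])

    def test_determinism_per_seed(self, small_genome):
        r = {LSG: 0.02, REARR: 0.02, DUP: 0.02}
        maps1, t1 = plant_mgees(small_genome, rates=r, seed=9)
        maps2, t2 = plant_mgees(small_genome, rates=r, seed=9)
        for sp in maps1:
            pd.testing.assert_frame_equal(maps1[sp], maps2[sp])
        assert [e.gene_ids for e in t1.planted_events] == [
            e.gene_ids for e in t2.planted_events
        ]

    def test_island_outside_genome_rejected(self, small_genome):
        bad = FeatureRecord("isl", "chr01", 0, 99_000_000)
        with pytest.raises(ValueError, match="outside"):
            plant_mgees(small_genome, rates={}, island_regions=[bad],
                        enrichment_factor=2.0)

    def test_neutral_enrichment_factor_keeps_island_fraction_at_share(self):
        genome = generate_genome(2, 1000, 50_000_000, seed=21)
        # islands cover 20% of the genome
        islands = [FeatureRecord(f"i{c}", f"chr{c:02d}", 10_000_000, 20_000_000)
                   for c in (1, 2)]
        _, truth = plant_mgees(genome, rates={REARR: 0.08}, seed=22,
                               island_regions=islands, enrichment_factor=1.0,
                               rearr_multi_prob=0.0)
        genes = {g.gene_id: g for g in genome.genes}
        n = len(truth.planted_events)
        in_isl = sum(
            1 for e in truth.planted_events
            if any(i.chrom == e.chrom and i.start <= e.pos < i.end for i in islands)
        )
        # binomial 99.7% band around the 20% genome share
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(in_isl / n - 0.2) < 3 * se + 0.02

    def test_exact_counts_plant_requested_numbers(self, small_genome):
        maps, truth = plant_mgees(
            small_genome, rates={}, seed=3,
            exact_counts={REARR: 50}, rearr_multi_prob=0.0,
        )
        assert len(truth.events_of_type(REARR)) == 50

    def test_enrichment_factor_concentrates_events_in_islands(self):
        genome = generate_genome(2, 1000, 50_000_000, seed=30)
        islands = [FeatureRecord(f"i{c}", f"chr{c:02d}", 10_000_000, 20_000_000)
                   for c in (1, 2)]
        _, truth = plant_mgees(genome, rates={}, seed=31,
                               island_regions=islands, enrichment_factor=5.0,
                               exact_counts={REARR: 200}, rearr_multi_prob=0.0)
        in_isl = sum(
            1 for e in truth.planted_events
            if any(i.chrom == e.chrom and i.start <= e.pos < i.end for i in islands)
        )
        # expected island fraction 0.2*5/(0.8 + 0.2*5) = 0.556
        frac = in_isl / 200
        assert abs(frac - 5 / 9) < 3 * np.sqrt(5 / 9 * 4 / 9 / 200) + 0.02

    def test_end_elevated_density_shifts_events_to_chromosome_ends(self):
        genome = generate_genome(2, 1000, 50_000_000, seed=40)
        _, t_uni = plant_mgees(genome, rates={}, seed=41, exact_counts={REARR: 300},
                               density_shape="uniform", rearr_multi_prob=0.0)
        _, t_end = plant_mgees(genome, rates={}, seed=41, exact_counts={REARR: 300},
                               density_shape="end-elevated", rearr_multi_prob=0.0)

        def mean_folded(truth):
            return np.mean([
                min(e.pos / 50_000_000, 1 - e.pos / 50_000_000)
                for e in truth.planted_events
            ])

        assert mean_folded(t_end) < mean_folded(t_uni) - 0.02


class TestTeLandscape:
    def _events(self, genome, n=150, seed=1):
        rng = np.random.default_rng(seed)
        chroms = list(genome.chrom_lengths)
        return [
            (c, float(rng.uniform(0, genome.chrom_lengths[c])))
            for i in range(n)
            for c in [chroms[i % len(chroms)]]
        ]

    def test_zero_target_correlation(self):
        genome = generate_genome(2, 500, 25_000_000, seed=50)  # 100 windows
        ev = self._events(genome)
        tes, counts = generate_te_landscape(genome, ev, base_density=20.0,
                                            corr_with_events=0.0, seed=51)
        ev_counts = np.zeros(len(counts))
        keys = {(c, s): i for i, (c, s) in enumerate(zip(counts["chrom"], counts["win_start"]))}
        for c, p in ev:
            ev_counts[keys[(c, int(p // 500_000) * 500_000)]] += 1
        tau, _ = density_correlation(ev_counts, counts["count"])
        assert abs(tau) < 0.1

    def test_target_correlation_recovered_within_tolerance(self):
        genome = generate_genome(2, 1000, 50_000_000, seed=52)  # 200 windows
        ev = self._events(genome, n=600, seed=53)
        _, counts = generate_te_landscape(genome, ev, base_density=25.0,
                                          corr_with_events=0.45, seed=54)
        ev_counts = np.zeros(len(counts))
        keys = {(c, s): i for i, (c, s) in enumerate(zip(counts["chrom"], counts["win_start"]))}
        for c, p in ev:
            ev_counts[keys[(c, int(p // 500_000) * 500_000)]] += 1
        tau, _ = density_correlation(ev_counts, counts["count"])
        assert abs(tau - 0.45) < 0.1

    def test_te_feature_count_matches_intended_counts(self):
        genome = generate_genome(1, 200, 10_000_000, seed=55)
        tes, counts = generate_te_landscape(genome, self._events(genome, 50),
                                            base_density=10.0, seed=56)
        assert len(tes) == counts["count"].sum()

    def test_hotspot_window_attains_max_family_zscore(self):
        genome = generate_genome(2, 500, 25_000_000, seed=57)
        ev = self._events(genome, 200, seed=58)
        tes, counts = generate_te_landscape(
            genome, ev, base_density=20.0, corr_with_events=0.2,
            hotspot=("LTR.ERV1", 40.0), seed=59,
        )
        z = family_zscores(counts, min_mean=1.0)
        peak = z["LTR.ERV1"].idxmax()
        # with W windows the hotspot's own leverage caps z near sqrt(W-1);
        # it must still tower over every other window
        assert z["LTR.ERV1"].max() > 5
        # the forced window carries the family maximum of the intended counts
        assert counts["LTR.ERV1"].idxmax() == peak


class TestDeLabels:
    def test_neutral_multiplier_keeps_rates_equal(self):
        genome = generate_genome(2, 1000, 50_000_000, seed=60)
        _, truth = plant_mgees(genome, rates={DUP: 0.05}, seed=61)
        k_dup = k_bg = n_dup = n_bg = 0
        for s in range(10):
            de = generate_de_labels(genome, truth, background_rate=0.05,
                                    dup_multiplier=1.0, seed=100 + s)
            flags = dict(zip(de["gene_id"], de["de_flag"]))
            dup_genes = {g for e in truth.events_of_type(DUP) for g in e.gene_ids}
            groups = truth.events_of_type(DUP)
            n_dup += len(groups)
            k_dup += sum(1 for e in groups if any(flags[g] for g in e.gene_ids))
            bg = [g.gene_id for g in genome.genes if g.gene_id not in dup_genes]
            n_bg += len(bg)
            k_bg += sum(1 for g in bg if flags[g])
        p_dup, p_bg = k_dup / n_dup, k_bg / n_bg
        se = np.sqrt(0.05 * 0.95 * (1 / n_dup + 1 / n_bg))
        assert abs(p_dup - p_bg) < 3 * se

    def test_tenfold_multiplier_recovers_fold_between_7_and_13(self):
        genome = generate_genome(2, 1500, 60_000_000, seed=70)
        _, truth = plant_mgees(genome, rates={DUP: 0.05}, seed=71)
        k_dup = n_dup = k_bg = n_bg = 0
        for s in range(25):
            de = generate_de_labels(genome, truth, background_rate=0.013,
                                    dup_multiplier=10.0, seed=200 + s)
            flags = dict(zip(de["gene_id"], de["de_flag"]))
            groups = truth.events_of_type(DUP)
            dup_genes = {g for e in groups for g in e.gene_ids}
            n_dup += len(groups)
            k_dup += sum(1 for e in groups if any(flags[g] for g in e.gene_ids))
            bg = [g.gene_id for g in genome.genes if g.gene_id not in dup_genes]
            n_bg += len(bg)
            k_bg += sum(1 for g in bg if flags[g])
        fold = (k_dup / n_dup) / (k_bg / n_bg)
        assert 7.0 < fold < 13.0

    def test_empty_truth_gives_background_only(self):
        genome = generate_genome(1, 200, 10_000_000, seed=80)
        de = generate_de_labels(genome, None, background_rate=0.0, seed=81)
        assert not de["de_flag"].any()
        assert len(de) == 200
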