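"""End-to-end orchestration: simulate -> classify -> enrich -> TE scan -> DE test.

A single structured config (YAML mapping) names all inputs, null-model
kinds, seeds and the output directory; every stochastic step consumes an
explicit seed derived from the config seed, so a rerun with the same config
produces byte-identical result tables.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io_tables, synthetic_data
from .de_overlap import de_enrichment_test
from .enrichment_test import run_enrichment_scan
from .mgee_classifier import (
    build_chromosome_homology,
    call_duplications,
    call_lsgs,
    call_micro_rearrangements,
    collapse_events,
    detect_macro_candidates,
)
from .positional_null import build_null_model
from .te_landscape import family_zscores, windowed_unique_te_counts
from .types import DUP, LSG, REARR, FeatureRecord, Genome, PipelineParams

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """A self-contained synthetic demo configuration."""
    return {
        "seed": 0,
        "params": {"n_perm": 1000},
        "simulate": {
            "n_chrom": 4,
            "genes_per_chrom": 300,
            "chrom_length": 15_000_000,
            "rates": {"LSG": 0.04, "REARR": 0.04, "DUP": 0.04},
            "density_shape": "end-elevated",
            "enrichment_factor": 6.0,
            "n_islands_per_chrom": 6,
            "island_length": 500_000,
            "island_gap": 50_000,
            "te_base_density": 20.0,
            "te_corr": 0.3,
            "te_hotspot": ["LTR.ERV1", 40.0],
            "de_background_rate": 0.013,
            "de_dup_multiplier": 10.0,
        },
        "null_model": {"kind": "single_adj", "breakpoints": {}},
        "window_sizes": [100_000, 250_000, 500_000, 1_000_000, 1_500_000, 2_000_000, 3_000_000],
    }


def _build_params(config: Mapping) -> PipelineParams:
    overrides = dict(config.get("params", {}))
    if "window_sizes" in config:
        overrides["window_sizes"] = tuple(config["window_sizes"])
    if "seed" in config:
        overrides["seed"] = int(config["seed"])
    return PipelineParams(**overrides)


def _simulate(config: Mapping, params: PipelineParams, outdir: Path, log) -> dict:
    sim = config["simulate"]
    seed = params.seed
    genome = synthetic_data.generate_genome(
        n_chrom=sim["n_chrom"],
        genes_per_chrom=sim["genes_per_chrom"],
        chrom_lengths=sim["chrom_length"],
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    islands = []
    ilen = sim["island_length"]
    gap = sim.get("island_gap", 100_000)
    for chrom, L in genome.chrom_lengths.items():
        n_isl = sim.get("n_islands_per_chrom", 0)
        if not n_isl:
            continue
        # islands cluster, as differentiation islands do on real focal
        # chromosomes: one contiguous run of islands per chromosome
        span = n_isl * ilen + (n_isl - 1) * gap
        if span > L:
            raise ValueError(f"island cluster ({span} bp) does not fit on {chrom}")
        anchor = int(rng.integers(0, L - span))
        for k in range(n_isl):
            s = anchor + k * (ilen + gap)
            islands.append(
                FeatureRecord(
                    feature_id=f"isl_{chrom}_{k + 1}",
                    chrom=chrom,
                    start=s,
                    end=s + ilen,
                    kind="island",
                    label="PNW",
                )
            )
    islands.sort(key=lambda f: (f.chrom, f.start))
    maps, truth = synthetic_data.plant_mgees(
        genome,
        rates=sim["rates"],
        density_shape=sim.get("density_shape", "uniform"),
        island_regions=islands,
        enrichment_factor=sim.get("enrichment_factor", 1.0),
        seed=seed + 2,
    )
    hotspot = sim.get("te_hotspot")
    tes, te_counts = synthetic_data.generate_te_landscape(
        genome,
        event_positions=truth.event_positions(),
        base_density=sim.get("te_base_density", 20.0),
        corr_with_events=sim.get("te_corr", 0.0),
        hotspot=tuple(hotspot) if hotspot else None,
        te_window=params.te_window,
        flank=params.flank_te,
        seed=seed + 3,
    )
    de = synthetic_data.generate_de_labels(
        genome,
        truth,
        background_rate=sim.get("de_background_rate", 0.013),
        dup_multiplier=sim.get("de_dup_multiplier", 10.0),
        seed=seed + 4,
    )

    io_tables.write_gene_annotation(genome.genes, outdir / "genes.gff3")
    with open(outdir / "chrom_lengths.tsv", "w") as fh:
        fh.write("chrom\tlength\n")
        for c, L in genome.chrom_lengths.items():
            fh.write(f"{c}\t{L}\n")
    io_tables.write_features(islands, outdir / "islands.bed")
    io_tables.write_features(tes, outdir / "tes.bed")
    pd.concat(maps.values()).to_csv(outdir / "homolog_map.tsv", sep="\t", index=False)
    de.to_csv(outdir / "de_labels.tsv", sep="\t", index=False)
    io_tables.write_events_table(truth.planted_events, outdir / "truth_events.tsv")
    log(f"simulated {len(genome.genes)} genes, {len(truth.planted_events)} planted events, "
        f"{len(tes)} TEs, {len(islands)} islands")
    return {
        "genome": genome,
        "islands": islands,
        "maps": maps,
        "truth": truth,
        "tes": tes,
        "de": de,
    }


def run_pipeline(config: Mapping, outdir: str | os.PathLike) -> dict:
    """Execute the full synthetic pipeline described by ``config``.

    Writes every result table plus ``run_log.txt`` (parameters, seeds,
    ISO-timestamped stage lines) into ``outdir``.  Result tables are
    byte-identical across reruns with the same config; only the log
    carries timestamps.  Fails fast before any computation when the config
    is inconsistent (e.g. a double-adj null without breakpoints).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = _build_params(config)
    nm_conf = dict(config.get("null_model", {"kind": "flat"}))
    kind = nm_conf.get("kind", "flat")
    breakpoints = {str(k): float(v) for k, v in (nm_conf.get("breakpoints") or {}).items()}
    if kind == "double_adj" and not breakpoints:
        raise ValueError("double_adj null model requires breakpoints in config")
    if "simulate" not in config:
        raise ValueError("config must include a 'simulate' section")

    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp}  {msg}")
        logger.info(msg)

    log(f"params: {asdict(params)}")
    log(f"null model: kind={kind} breakpoints={breakpoints}")

    data = _simulate(config, params, outdir, log)
    genome: Genome = data["genome"]
    maps = data["maps"]

    # --- classification ------------------------------------------------------
    tables = {
        sp: build_chromosome_homology(maps[sp], sp, genome.genes)
        for sp in ("tubesnout", "seabass")
    }
    rearr = call_micro_rearrangements(genome.genes, maps, tables, params)
    lsgs = call_lsgs(genome.genes, maps, params)
    dups = call_duplications(genome.genes, maps, params)
    events = collapse_events(
        rearr + lsgs + dups, params.dup_collapse_dist, genome.genes
    )
    io_tables.write_events_table(events, outdir / "events.tsv")
    macro = detect_macro_candidates(genome.genes, maps["tubesnout"])
    pd.DataFrame(
        [
            {"chrom": c, "classification": m.classification,
             "n_runs": len(m.runs),
             "breakpoints": ",".join(f"{b:.0f}" for b in m.breakpoints)}
            for c, m in sorted(macro.items())
        ]
    ).to_csv(outdir / "macro_calls.tsv", sep="\t", index=False)
    by_type = {t: [e for e in events if e.mgee_type == t] for t in (LSG, REARR, DUP)}
    log(f"classified events: " + ", ".join(f"{t}={len(v)}" for t, v in by_type.items()))

    # --- enrichment ----------------------------------------------------------
    null_models = {}
    for t, evs in by_type.items():
        null_models[t] = build_null_model(
            kind,
            genome,
            events_for_fit=[(e.chrom, e.pos) for e in evs],
            breakpoints=breakpoints or None,
            bandwidth=params.kde_bandwidth,
            gene_density_bin=params.te_window,
        )
    results, exceedance = run_enrichment_scan(
        by_type, data["islands"], params.window_sizes, null_models, params,
        seed=params.seed + 10,
    )
    results.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    exceedance.to_csv(outdir / "exceedance.tsv", sep="\t", index=False)
    log(f"enrichment scan: {len(results)} cells, "
        f"{int(exceedance['is_enriched'].sum())} enriched (type, window) combinations")

    # --- TE landscape --------------------------------------------------------
    event_gene_ids = {g for e in events for g in e.gene_ids}
    syntenic = [g for g in genome.genes if g.gene_id not in event_gene_ids]
    te_counts = windowed_unique_te_counts(
        syntenic, data["tes"], genome.chrom_lengths,
        te_window=params.te_window, flank=params.flank_te, by_family=True,
    )
    te_counts.to_csv(outdir / "te_window_counts.tsv", sep="\t", index=False)
    zscores = family_zscores(te_counts, min_mean=params.te_min_mean)
    zscores.to_csv(outdir / "te_family_zscores.tsv", sep="\t", index=False)
    log(f"TE scan: {len(te_counts)} windows")

    # --- DE overlap ----------------------------------------------------------
    de_flags = set(data["de"].loc[data["de"]["de_flag"], "gene_id"])
    background = {g.gene_id for g in genome.genes} - event_gene_ids
    de_table = de_enrichment_test(events, de_flags, background)
    de_table.to_csv(outdir / "de_overlap.tsv", sep="\t", index=False)
    log("DE overlap test written")

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "params": params,
        "events": events,
        "results": results,
        "exceedance": exceedance,
        "te_counts": te_counts,
        "te_zscores": zscores,
        "de_table": de_table,
        "macro": macro,
        "truth": data["truth"],
    }
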