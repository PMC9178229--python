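"""Readers and writers for the pipeline's standard tabular formats.

GFF3 gene annotations are read through :mod:`gffutils`; BED and TSV tables
through :mod:`pandas`.  All readers are deterministic and order-stable, and
every interval is held internally as 0-based half-open.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .types import FeatureRecord, GeneRecord, MgeeEvent, PipelineParams

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_annotation",
    "write_gene_annotation",
    "read_features",
    "write_features",
    "read_homolog_map",
    "write_homolog_map",
    "write_events_table",
    "read_events_table",
]

HOMOLOG_COLUMNS = [
    "query_id",
    "species",
    "chrom",
    "start",
    "end",
    "pct_identity",
    "match_len",
    "rank",
    "region_hit_coverage",
    "nr_hit",
]

EVENT_COLUMNS = [
    "event_id",
    "mgee_type",
    "chrom",
    "pos",
    "n_genes",
    "gene_ids",
    "lineage",
    "confidence",
]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _validate_gff3_lines(path: str | os.PathLike) -> int:
    """Cheap structural validation so errors can name the offending line.

    Also rejects duplicated gene IDs (before gffutils would silently rename
    them).  Returns the number of feature lines seen.
    """
    n_features = 0
    gene_ivals: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: bad interval {start}..{end}"
                )
            n_features += 1
            if fields[2] == "gene":
                gid = next(
                    (kv[3:] for kv in fields[8].split(";") if kv.startswith("ID=")), None
                )
                if gid is not None and gid in gene_ivals:
                    raise ValueError(f"{path}: duplicate gene_id {gid!r} (line {lineno})")
                if gid is not None:
                    gene_ivals[gid] = (fields[0], start, end)
    return n_features


def read_gene_annotation(path: str | os.PathLike) -> list[GeneRecord]:
    """Read a GFF3 gene annotation into :class:`GeneRecord` objects.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    0-based half-open.  Each gene's representative midpoint is the average
    of its CDS midpoints (the midpoint +/- 1 bp extent is exposed on the
    record); genes without CDS features fall back to exon midpoints, then to
    the interval midpoint.
    """
    if _validate_gff3_lines(path) == 0:
        return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    records: list[GeneRecord] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = gene.id
        start0, end0 = gene.start - 1, gene.end
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        exons = list(db.children(gene, featuretype="exon", order_by="start"))
        exon_ivals = tuple((f.start - 1, f.end) for f in exons)
        for basis in (cds, exons):
            if basis:
                mids = [((f.start - 1) + f.end) / 2.0 for f in basis]
                midpoint = sum(mids) / len(mids)
                break
        else:
            midpoint = (start0 + end0) / 2.0
        records.append(
            GeneRecord(
                gene_id=gene_id,
                chrom=gene.seqid,
                start=start0,
                end=end0,
                strand=gene.strand or ".",
                exons=exon_ivals,
                midpoint=midpoint,
            )
        )
    return records


def write_gene_annotation(genes: Iterable[GeneRecord], path: str | os.PathLike) -> None:
    """Write gene records back to GFF3 (restoring 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tarchscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tarchscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_features(path: str | os.PathLike, kind: str = "island") -> list[FeatureRecord]:
    """Read a BED3/BED4 file as :class:`FeatureRecord` objects of one kind.

    BED's native 0-based half-open coordinates are preserved.  The optional
    name column becomes the feature label; features are numbered in file
    order when unnamed.
    """
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: BED line {lineno}: expected at least 3 fields"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start > end:
                raise ValueError(
                    f"{path}: BED line {lineno}: start {start} > end {end}"
                )
            label = fields[3] if len(fields) > 3 else ""
            feature_id = f"{kind}_{len(records) + 1:04d}" if not label else label
            records.append(
                FeatureRecord(
                    feature_id=feature_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    kind=kind,
                    label=label,
                )
            )
    return records


def write_features(features: Iterable[FeatureRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.label or f.feature_id}\n")


# ---------------------------------------------------------------------------
# Homolog-hit tables
# ---------------------------------------------------------------------------

def read_homolog_map(
    path: str | os.PathLike,
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Read a homolog-hit TSV, applying the match-length/identity filters.

    Hits with ``match_len`` not exceeding ``min_match_len`` (100 bp) or
    ``pct_identity`` not exceeding ``min_identity`` (75%) are dropped; the
    drop count is logged.  A duplicated (query_id, species, rank) triple is
    an error.
    """
    params = params or PipelineParams()
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "species": str, "chrom": str})
    missing = {"query_id", "species", "chrom", "start", "end", "pct_identity", "match_len", "rank"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing homolog columns: {sorted(missing)}")
    if "region_hit_coverage" not in df.columns:
        df["region_hit_coverage"] = 0.0
    if "nr_hit" not in df.columns:
        df["nr_hit"] = False
    df["region_hit_coverage"] = df["region_hit_coverage"].fillna(0.0)
    df["nr_hit"] = df["nr_hit"].fillna(False).astype(bool)

    dup = df.duplicated(subset=["query_id", "species", "rank"], keep=False)
    if dup.any():
        first = df.loc[dup, ["query_id", "species", "rank"]].iloc[0]
        raise ValueError(
            f"{path}: duplicate hit rank for query={first.query_id!r} "
            f"species={first.species!r} rank={first['rank']}"
        )
    if (df["pct_identity"].lt(0) | df["pct_identity"].gt(100)).any():
        raise ValueError(f"{path}: pct_identity outside [0, 100]")

    keep = (df["match_len"] > params.min_match_len) & (
        df["pct_identity"] > params.min_identity
    )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d/%d hits below >%d bp / >%.0f%% identity thresholds",
            path, n_dropped, len(df), params.min_match_len, params.min_identity,
        )
    return df.loc[keep].reset_index(drop=True)


def write_homolog_map(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=[c for c in HOMOLOG_COLUMNS if c in df.columns])


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def events_to_frame(events: Iterable[MgeeEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_id": e.event_id,
            "mgee_type": e.mgee_type,
            "chrom": e.chrom,
            "pos": e.pos,
            "n_genes": e.n_genes,
            "gene_ids": ",".join(e.gene_ids),
            "lineage": e.lineage,
            "confidence": e.confidence,
        }
        for e in events
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df.sort_values(["chrom", "pos", "event_id"], kind="mergesort").reset_index(drop=True)


def write_events_table(events: Iterable[MgeeEvent], path: str | os.PathLike) -> None:
    """Write events to TSV in deterministic (chrom, pos, event_id) order."""
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events_table(path: str | os.PathLike) -> list[MgeeEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "chrom": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MgeeEvent(
                event_id=row.event_id,
                mgee_type=row.mgee_type,
                gene_ids=tuple(str(row.gene_ids).split(",")),
                chrom=row.chrom,
                pos=float(row.pos),
                lineage=row.lineage,
                confidence=row.confidence,
            )
        )
    return out
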