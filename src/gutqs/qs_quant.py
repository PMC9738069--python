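"""Quorum-sensing gene quantification from BLAST tabular hits.

Consumes outfmt-6-style tabular alignments (tblastn of protein queries
vs per-sample assemblies for presence/absence; blastn of nucleotide
queries vs raw metagenome (MGX) and metatranscriptome (MTX) reads for
quantification), applies per-gene e-value / percent-identity cut-offs,
and derives:

* relative abundance = distinct gene reads / total reads in the sample,
* expression ratio   = (MTX gene reads / MTX total) / MGX relative
  abundance, undefined (sample excluded) when the gene has no MGX reads.

The default gene catalogue covers the luxR-family receptor queries
used for gut Bacteroides (four B. fragilis luxR paralogues, one
B. dorei luxR) and the orphan Enterobacteriaceae receptor sdiA.
Identity floors are strict (> 80% for luxR1 B. fragilis, > 97% for
luxR1 B. dorei, none for luxR2-4 B. fragilis, which are unique to
B. fragilis); e-value cut-offs are < 1e-30 for read searches and
< 1e-20 for assembly searches, also strict. Reads with several HSPs
count once (deduplicated by read id).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
_NUMERIC = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}

__all__ = [
    "GeneQuery",
    "BlastHitTable",
    "DEFAULT_CATALOGUE",
    "parse_blast_tab",
    "filter_hits",
    "count_gene_reads",
    "relative_abundance",
    "expression_ratio",
    "derive_gene_metrics",
    "presence_scan",
]


@dataclass(frozen=True)
class GeneQuery:
    gene_id: str
    accession: str
    evalue_max: float
    min_pident: float | None = None
    search_mode: str = "nucleotide-vs-reads"  # or "protein-vs-assembly"

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.min_pident is not None and not 0 <= self.min_pident <= 100:
            raise ValueError("min_pident must be in [0, 100]")


DEFAULT_CATALOGUE: list[GeneQuery] = [
    GeneQuery("luxR1_Bfragilis", "BF9343_2602", 1e-30, min_pident=80.0),
    GeneQuery("luxR2_Bfragilis", "BF9343_2858", 1e-30),
    GeneQuery("luxR3_Bfragilis", "BF9343_3797", 1e-30),
    GeneQuery("luxR4_Bfragilis", "BF9343_4003", 1e-30),
    GeneQuery("luxR1_Bdorei", "NZ_LR699004.1:3959839-3960450", 1e-30, min_pident=97.0),
    GeneQuery("sdiA_Ecoli", "sdiA", 1e-20, search_mode="protein-vs-assembly"),
]


@dataclass
class BlastHitTable:
    rows: pd.DataFrame  # outfmt-6 columns
    sample_id: str = ""
    sequencing_type: str = "MGX"  # MGX | MTX | assembly

    def __len__(self) -> int:
        return len(self.rows)


def _empty_rows() -> pd.DataFrame:
    data: dict[str, pd.Series] = {
        "qseqid": pd.Series(dtype=str),
        "sseqid": pd.Series(dtype=str),
    }
    for c in OUTFMT6_COLUMNS[2:]:
        data[c] = pd.Series(dtype=_NUMERIC[c])
    return pd.DataFrame(data)


def parse_blast_tab(
    source: str | io.TextIOBase,
    sample_id: str = "",
    sequencing_type: str = "MGX",
) -> BlastHitTable:
    """Parse an outfmt-6 tabular file (12 standard columns).

    Extra trailing columns are ignored with a warning; fewer than 12
    columns or non-numeric numeric fields raise with the line number.
    """
    buf = open(source) if isinstance(source, str) else source
    records: list[list] = []
    warned_extra = False
    try:
        for lineno, line in enumerate(buf, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
            if len(fields) > 12 and not warned_extra:
                logger.warning("line %d: ignoring %d extra columns", lineno, len(fields) - 12)
                warned_extra = True
            rec = fields[:2]
            for col, raw in zip(OUTFMT6_COLUMNS[2:], fields[2:12]):
                try:
                    rec.append(_NUMERIC[col](raw))
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: non-numeric value {raw!r} in column {col}"
                    ) from None
            records.append(rec)
    finally:
        if isinstance(source, str):
            buf.close()
    rows = pd.DataFrame(records, columns=OUTFMT6_COLUMNS) if records else _empty_rows()
    return BlastHitTable(rows, sample_id=sample_id, sequencing_type=sequencing_type)


def filter_hits(table: BlastHitTable, query: GeneQuery) -> BlastHitTable:
    """Apply the query's cut-offs: evalue < evalue_max and, when an
    identity floor is set, pident > min_pident (both strict)."""
    rows = table.rows
    keep = rows["evalue"] < query.evalue_max
    if query.min_pident is not None:
        keep &= rows["pident"] > query.min_pident
    return replace(table, rows=rows[keep].reset_index(drop=True))


def count_gene_reads(filtered: BlastHitTable) -> int:
    """Distinct read ids among the filtered hits (HSPs deduplicated)."""
    return int(filtered.rows["sseqid"].nunique())


def relative_abundance(hit_reads: int, total_reads: int) -> float:
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if hit_reads < 0:
        raise ValueError("hit_reads must be >= 0")
    return hit_reads / total_reads


def expression_ratio(
    mtx_hits: int, mtx_total: int, mgx_rel_abundance: float
) -> float | None:
    """MTX relative abundance over MGX relative abundance.

    Returns None (sample excluded) when the gene has no metagenome
    reads (mgx_rel_abundance == 0).
    """
    if mtx_total <= 0:
        raise ValueError("mtx_total must be > 0")
    if mgx_rel_abundance == 0:
        return None
    return (mtx_hits / mtx_total) / mgx_rel_abundance


def derive_gene_metrics(hit_table: pd.DataFrame) -> pd.DataFrame:
    """Add rel_abundance / expression / excluded columns to a per
    (sample, gene) table with mgx_hit_reads, mgx_total_reads,
    mtx_hit_reads, mtx_total_reads columns."""
    out = hit_table.copy()
    out["rel_abundance"] = [
        relative_abundance(int(h), int(t))
        for h, t in zip(out["mgx_hit_reads"], out["mgx_total_reads"])
    ]
    expr, excluded = [], []
    for _, row in out.iterrows():
        e = expression_ratio(
            int(row["mtx_hit_reads"]), int(row["mtx_total_reads"]), row["rel_abundance"]
        )
        expr.append(np.nan if e is None else e)
        excluded.append(e is None)
    out["expression"] = expr
    out["excluded"] = excluded
    return out


def quantify_from_hits(
    hits: Mapping[tuple[str, str], BlastHitTable],
    queries: Sequence[GeneQuery],
    totals: Mapping[tuple[str, str], int],
) -> pd.DataFrame:
    """Per-(sample, gene) metrics from raw read-search hit tables.

    ``hits`` maps (sample_id, sequencing_type) to the sample's hit table
    (rows for every gene, qseqid = gene id); ``totals`` maps the same
    keys to total read counts.
    """
    samples = sorted({k[0] for k in hits})
    records = []
    for sid in samples:
        for q in queries:
            if q.search_mode != "nucleotide-vs-reads":
                continue
            rec = {"sample_id": sid, "gene_id": q.gene_id}
            for st, prefix in (("MGX", "mgx"), ("MTX", "mtx")):
                table = hits.get((sid, st))
                if table is None:
                    rec[f"{prefix}_hit_reads"] = 0
                    rec[f"{prefix}_total_reads"] = totals.get((sid, st), 0)
                    continue
                sub = replace(table, rows=table.rows[table.rows["qseqid"] == q.gene_id])
                rec[f"{prefix}_hit_reads"] = count_gene_reads(filter_hits(sub, q))
                rec[f"{prefix}_total_reads"] = totals[(sid, st)]
            records.append(rec)
    return derive_gene_metrics(pd.DataFrame(records))


def presence_scan(
    assembly_hits: Mapping[str, BlastHitTable],
    queries: Sequence[GeneQuery],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence/absence of genes in per-sample assembly searches.

    A gene is present in a sample when at least one hit survives the
    query's cut-offs. Returns (per-sample presence table with best
    pident, per-gene summary with hit-sample counts and the mean of
    best pidents across positive samples).
    """
    per_sample = []
    for sid, table in sorted(assembly_hits.items()):
        for q in queries:
            sub = replace(table, rows=table.rows[table.rows["qseqid"] == q.gene_id])
            surv = filter_hits(sub, q).rows
            per_sample.append(
                {
                    "sample_id": sid,
                    "gene_id": q.gene_id,
                    "present": len(surv) > 0,
                    "best_pident": float(surv["pident"].max()) if len(surv) else np.nan,
                }
            )
    presence = pd.DataFrame(per_sample)
    summaries = []
    for q in queries:
        sub = presence[presence["gene_id"] == q.gene_id]
        pos = sub[sub["present"]]
        summaries.append(
            {
                "gene_id": q.gene_id,
                "n_samples_present": int(sub["present"].sum()),
                "mean_best_pident": float(pos["best_pident"].mean()) if len(pos) else np.nan,
            }
        )
    return presence, pd.DataFrame(summaries)
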