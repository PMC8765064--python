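"""Screening of trace-gas metabolism marker genes from homology-search hits.

Metagenomic reads searched against reference protein databases for ten
marker genes of atmospheric trace-gas oxidation — CoxL (CO dehydrogenase),
MmoX and PmoA (soluble/particulate methane monooxygenase), and seven
[NiFe]-hydrogenase groups (H2 oxidation) — yield tabular hits (BLAST
outfmt-6 dialect).  Hits pass quality control at >= 80% query coverage,
E-value <= 1e-10, and percent identity >= 50 for the [NiFe]-hydrogenase
genes or >= 60 for all others (inclusive thresholds), keeping one best hit
per read.  Surviving hits per gene are expressed as a proportion of each
sample's total quality-filtered reads and contrasted between elevation
groups with two-sided Mann-Whitney tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import PipelineConfig
from .gradient_stats import mann_whitney_u, zscore_table

__all__ = [
    "GENE_CLASSES",
    "HIT_COLUMNS",
    "read_hit_table",
    "filter_marker_hits",
    "gene_proportions",
    "compare_gene_abundances",
]

#: The ten trace-gas metabolic marker genes tracked by the screen.
GENE_CLASSES = (
    "CoxL",
    "MmoX",
    "PmoA",
    "NiFe_1c",
    "NiFe_1d",
    "NiFe_1f",
    "NiFe_1h",
    "NiFe_1l",
    "NiFe_2a",
    "NiFe_3",
)

#: In-memory hit-record columns used by the filtering and counting steps.
HIT_COLUMNS = (
    "read_id",
    "sample_id",
    "gene_class",
    "pct_identity",
    "pct_query_coverage",
    "evalue",
    "bitscore",
)

_OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_hit_table(
    path: str | Path,
    gene_map: dict[str, str] | pd.Series,
    sample_id: str | None = None,
    query_lengths: dict[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Parse BLAST outfmt-6 hits into the internal hit-record table.

    ``gene_map`` maps subject IDs (sseqid) to one of the ten gene classes.
    Query coverage is taken from a 13th column named ``qcovs`` when present;
    otherwise it is computed as 100*(qend-qstart+1)/query_length from
    ``query_lengths``.  The sample comes from a ``sample`` column when
    present, else from the ``sample_id`` argument.
    """
    first = pd.read_csv(path, sep="\t", nrows=0)
    has_header = "qseqid" in first.columns
    if has_header:
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        names = list(_OUTFMT6_COLUMNS)[: df.shape[1]]
        df.columns = names + list(df.columns[len(names):])
    gene_map = pd.Series(gene_map)
    unknown = set(df["sseqid"]) - set(gene_map.index)
    if unknown:
        raise ValueError(f"subject IDs without a gene-class mapping: "
                         f"{sorted(unknown)[:5]}")
    out = pd.DataFrame({
        "read_id": df["qseqid"].astype(str),
        "gene_class": df["sseqid"].map(gene_map).astype(str),
        "pct_identity": df["pident"].astype(float),
        "evalue": df["evalue"].astype(float),
        "bitscore": df["bitscore"].astype(float),
    })
    if "qcovs" in df.columns:
        out["pct_query_coverage"] = df["qcovs"].astype(float)
    else:
        if query_lengths is None:
            raise ValueError("need query_lengths (or a qcovs column) to "
                             "compute query coverage")
        lengths = pd.Series(query_lengths)
        qlen = df["qseqid"].map(lengths)
        if qlen.isna().any():
            missing = df["qseqid"][qlen.isna()].iloc[0]
            raise ValueError(f"no query length for read {missing!r}")
        aln = (df["qend"] - df["qstart"]).abs() + 1
        out["pct_query_coverage"] = 100.0 * aln / qlen
    if "sample" in df.columns:
        out["sample_id"] = df["sample"].astype(str)
    elif sample_id is not None:
        out["sample_id"] = sample_id
    else:
        raise ValueError("hits carry no 'sample' column; pass sample_id")
    return out[list(HIT_COLUMNS)]


def filter_marker_hits(
    hits: pd.DataFrame, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Apply QC thresholds (inclusive) and keep one best hit per read.

    Keep iff coverage >= hit_qcov_min, evalue <= hit_evalue_max, and
    identity >= 50 ([NiFe]-hydrogenase classes) / 60 (others).  Best hit per
    (sample, read): highest bitscore, then lowest E-value, then input order.
    """
    cfg = cfg or PipelineConfig()
    unknown = set(hits["gene_class"]) - set(GENE_CLASSES)
    if unknown:
        raise ValueError(f"unknown gene class label(s): {sorted(unknown)}")
    is_nife = hits["gene_class"].str.startswith("NiFe")
    identity_min = np.where(is_nife, cfg.hit_identity_min_nife,
                            cfg.hit_identity_min_other)
    keep = (
        (hits["pct_query_coverage"] >= cfg.hit_qcov_min)
        & (hits["evalue"] <= cfg.hit_evalue_max)
        & (hits["pct_identity"] >= identity_min)
    )
    passed = hits.loc[keep]
    # stable sort preserves input order as the final tie-break
    dedup = (
        passed.sort_values(["bitscore", "evalue"], ascending=[False, True],
                           kind="mergesort")
        .drop_duplicates(subset=["sample_id", "read_id"], keep="first")
        .sort_index()
    )
    return dedup.reset_index(drop=True)


def gene_proportions(
    filtered: pd.DataFrame, total_reads: pd.Series
) -> pd.DataFrame:
    """Surviving hits per (sample, gene) divided by the sample's total
    quality-filtered reads; genes with no hits get 0."""
    total_reads = pd.Series(total_reads, dtype=float)
    samples_with_hits = set(filtered["sample_id"])
    missing = samples_with_hits - set(total_reads.index)
    if missing:
        raise ValueError(f"samples with hits but no read total: "
                         f"{sorted(missing)[:5]}")
    if (total_reads <= 0).any():
        bad = total_reads.index[total_reads <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive total reads")
    counts = (
        filtered.groupby(["sample_id", "gene_class"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=total_reads.index, columns=list(GENE_CLASSES),
                 fill_value=0)
        .fillna(0)
        .rename_axis(index=None, columns=None)
    )
    return counts.div(total_reads, axis=0)


def compare_gene_abundances(
    props: pd.DataFrame, groups: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided Mann-Whitney contrast of each gene between elevation groups.

    Returns (tests, zscores): per-gene U, p, and direction (the sign of
    median_high - median_low, reported as 'high'/'low'/'equal'), plus the
    per-gene Z-score profile across samples.
    """
    labels = groups.reindex(props.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"samples without a group label: {missing[:5]}")
    high = props.loc[labels == "high"]
    low = props.loc[labels == "low"]
    if len(high) < 3 or len(low) < 3:
        raise ValueError("need >= 3 samples per elevation group")
    rows = []
    for gene in props.columns:
        u, p = mann_whitney_u(high[gene], low[gene], alternative="two-sided")
        diff = float(high[gene].median() - low[gene].median())
        direction = "high" if diff > 0 else ("low" if diff < 0 else "equal")
        rows.append((gene, u, p, direction))
    tests = pd.DataFrame(rows, columns=["gene_class", "U", "p", "direction"])
    tests = tests.set_index("gene_class")
    z = zscore_table(props)
    return tests, z
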