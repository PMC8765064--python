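"""Core tables, configuration, and TSV readers/writers shared by all stages.

The pipeline operates on three tabular inputs: a sample x ASV abundance table
(integer counts straight off the sequencer, or proportions), a per-sample
metadata table carrying elevation plus geochemical concentrations, and a
sample x KEGG-ortholog abundance table.  All are plain TSV with a header row
and the sample/feature ID in the first column; missing metadata values are
written with a configurable NA token (default ``"NA"``) and kept missing
rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "TaxonomyMap",
    "PipelineConfig",
    "CONCENTRATION_VARS",
    "ANALYSIS_VARS",
    "TAXONOMIC_RANKS",
    "read_asv_table",
    "read_ko_table",
    "read_metadata",
    "read_taxonomy",
    "write_table",
    "write_metadata",
    "log_transform_concentrations",
    "split_elevation_groups",
]

#: Geochemical concentration variables carried in sample metadata.  All are
#: mg/kg soil except perchlorate and chlorate (ug/kg).
CONCENTRATION_VARS = (
    "nitrate",
    "chloride",
    "total_cations",
    "total_anions",
    "total_salt",
    "perchlorate",
    "chlorate",
    "nh3",
    "sio2",
)

#: The ten environmental variables used by the gradient statistics:
#: elevation (m above sea level) plus the nine concentrations.
ANALYSIS_VARS = ("elevation",) + CONCENTRATION_VARS

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class AsvTable:
    """Sample x feature abundance matrix.

    ``data`` is indexed by sample ID with feature (ASV or KO) IDs as columns.
    ``kind`` is ``"counts"`` (non-negative integers) or ``"relative"``
    (each non-empty row sums to 1).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate feature ID: {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("abundance table must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if self.kind == "relative":
            # proportions of total sample reads: a full composition sums to 1,
            # a column subset (e.g. after prevalence filtering) to less
            sums = values.sum(axis=1)
            bad = sums > 1.0 + 1e-9
            if bad.any():
                raise ValueError(
                    f"relative table row {self.data.index[np.argmax(bad)]!r} "
                    f"sums to {sums[np.argmax(bad)]:.6g} > 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, samples: Iterable[str] | None = None,
               features: Iterable[str] | None = None) -> "AsvTable":
        data = self.data
        if samples is not None:
            data = data.loc[list(samples)]
        if features is not None:
            data = data[list(features)]
        return replace(self, data=data)


@dataclass
class TaxonomyMap:
    """ASV ID -> rank labels (domain..genus); any rank may be unassigned (NaN)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in TAXONOMIC_RANKS if r not in self.data.columns]
        if missing:
            raise ValueError(f"taxonomy table lacks rank columns: {missing}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate ASV ID in taxonomy: {dup!r}")

    def rank(self, rank: str) -> pd.Series:
        return self.data[rank]


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with study defaults.

    Defaults encode the filtering and acceptance rules of the analysis:
    ASVs with fewer than 10 total reads are dropped, samples need 1,000
    reads, the network keeps ASVs seen in >=10 samples and Spearman edges
    >0.75, forests use 100 trees / mtry 3, niche models are accepted at
    >10% variance explained with a >=5% (p<0.05) permutation importance,
    elevation groups split at 800 m, functional enrichment at |log2FC|>1
    with pathways flagged at >=5 enriched genes, and homology hits pass at
    >=80% query coverage, E<=1e-10 and >=50% ([NiFe]-hydrogenase) or >=60%
    (other genes) identity.
    """

    min_asv_reads: int = 10
    min_sample_reads: int = 1000
    min_prevalence: int = 10
    rarefaction_depth: int = 2000
    rho_edge_min: float = 0.75
    n_trees: int = 100
    mtry: int = 3
    n_importance_perm: int = 100
    min_var_explained_pct: float = 10.0
    min_inc_mse_pct: float = 5.0
    importance_alpha: float = 0.05
    elevation_split_m: float = 800.0
    log2fc_cutoff: float = 1.0
    pathway_min_genes: int = 5
    hit_qcov_min: float = 80.0
    hit_identity_min_nife: float = 50.0
    hit_identity_min_other: float = 60.0
    hit_evalue_max: float = 1e-10
    ko_rarefaction_depth: int = 5_203_694
    na_token: str = "NA"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_asv_reads", "min_sample_reads", "min_prevalence",
            "rarefaction_depth", "rho_edge_min", "n_trees", "mtry",
            "min_var_explained_pct", "min_inc_mse_pct", "importance_alpha",
            "elevation_split_m", "log2fc_cutoff", "pathway_min_genes",
            "hit_qcov_min", "hit_identity_min_nife", "hit_identity_min_other",
            "hit_evalue_max", "ko_rarefaction_depth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.mtry > len(ANALYSIS_VARS):
            raise ValueError(
                f"mtry={self.mtry} exceeds the {len(ANALYSIS_VARS)} environment variables"
            )


def _read_numeric_tsv(path: str | Path, na_token: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    df.index.name = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column {dup!r}")
    out = {}
    for col in df.columns:
        raw = df[col]
        vals = raw.where(raw != na_token, other=np.nan)
        try:
            out[col] = pd.to_numeric(vals)
        except (ValueError, TypeError):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna() & vals.notna()]
            raise ValueError(
                f"{path}: non-numeric cell {bad.iloc[0]!r} at row {bad.index[0]!r}, "
                f"column {col!r}"
            ) from None
    return pd.DataFrame(out, index=df.index)


def read_asv_table(path: str | Path, kind: str = "counts",
                   na_token: str = "NA") -> AsvTable:
    """Read a sample x ASV abundance TSV (samples in rows, header row of ASV IDs)."""
    df = _read_numeric_tsv(path, na_token)
    if df.isna().any().any():
        raise ValueError(f"{path}: abundance tables may not contain {na_token!r}")
    if kind == "counts":
        vals = df.to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"{path}: counts table contains non-integer values")
        df = df.astype(np.int64)
    return AsvTable(df, kind=kind)


def read_ko_table(path: str | Path, na_token: str = "NA") -> AsvTable:
    """Read a sample x KEGG-ortholog abundance TSV; returned kind is 'counts'
    for integer tables and 'relative' is never inferred (normalized KO tables
    are real-valued counts-per-genome, kept as kind='counts' semantics)."""
    df = _read_numeric_tsv(path, na_token)
    if df.isna().any().any():
        raise ValueError(f"{path}: abundance tables may not contain {na_token!r}")
    return AsvTable(df, kind="counts")


def read_metadata(path: str | Path, na_token: str = "NA") -> pd.DataFrame:
    """Read per-sample metadata: elevation + geochemistry (+ optional feature).

    Missing concentrations stay missing (NaN), never 0.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index.name = None
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    out = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        if col == "feature":
            out[col] = raw[col].where(raw[col] != na_token, other=np.nan)
            continue
        vals = raw[col].where(raw[col] != na_token, other=np.nan)
        try:
            out[col] = pd.to_numeric(vals)
        except (ValueError, TypeError):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna() & vals.notna()]
            raise ValueError(
                f"{path}: non-numeric cell {bad.iloc[0]!r} at sample "
                f"{bad.index[0]!r}, column {col!r}"
            ) from None
    _validate_metadata(out)
    return out


def _validate_metadata(meta: pd.DataFrame) -> None:
    if "elevation" in meta.columns:
        elev = meta["elevation"].dropna()
        if (elev < 0).any():
            raise ValueError(f"negative elevation for sample "
                             f"{elev.index[elev < 0][0]!r}")
    for col in CONCENTRATION_VARS:
        if col in meta.columns:
            vals = meta[col].dropna()
            if (vals < 0).any():
                raise ValueError(
                    f"negative concentration {col!r} for sample "
                    f"{vals.index[vals < 0][0]!r}"
                )


def read_taxonomy(path: str | Path, na_token: str = "NA") -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index.name = None
    df = df.where(df != na_token, other=np.nan)
    df = df.where(df != "", other=np.nan)
    return TaxonomyMap(df)


def write_table(table: AsvTable | pd.DataFrame, path: str | Path,
                na_token: str = "NA") -> None:
    """Write an abundance table or plain DataFrame as TSV (ID in first column)."""
    df = table.data if isinstance(table, AsvTable) else table
    df.to_csv(path, sep="\t", na_rep=na_token, index_label="sample_id")


def write_metadata(meta: pd.DataFrame, path: str | Path, na_token: str = "NA") -> None:
    meta.to_csv(path, sep="\t", na_rep=na_token, index_label="sample_id")


def log_transform_concentrations(meta: pd.DataFrame) -> pd.DataFrame:
    """log10-transform every concentration column, leaving elevation untouched.

    Each concentration c becomes log10(c + delta) where delta is half the
    smallest positive value of that variable (a scale-aware pseudocount, so
    zeros stay finite).  Missing entries stay missing.  A variable with no
    positive values has no defined delta and raises.
    """
    out = meta.copy()
    for col in CONCENTRATION_VARS:
        if col not in meta.columns:
            continue
        vals = meta[col]
        positive = vals[vals > 0]
        if positive.empty:
            raise ValueError(f"variable {col!r} has no positive values; "
                             "log transform undefined")
        delta = positive.min() / 2.0
        out[col] = np.log10(vals + delta)
    return out


def split_elevation_groups(meta: pd.DataFrame,
                           split_m: float = 800.0) -> pd.Series:
    """Label samples 'high' (elevation > split) or 'low' (< split).

    A sample exactly at the split goes to 'high' with a warning; the study
    design guarantees a gap around the split so the case is degenerate.
    """
    if "elevation" not in meta.columns:
        raise ValueError("metadata lacks an 'elevation' column")
    elev = meta["elevation"]
    if elev.isna().any():
        missing = list(elev.index[elev.isna()])
        raise ValueError(f"samples missing elevation: {missing}")
    at_split = elev == split_m
    if at_split.any():
        warnings.warn(
            f"samples exactly at the {split_m} m split assigned to 'high': "
            f"{list(elev.index[at_split])}",
            UserWarning,
            stacklevel=2,
        )
    labels = pd.Series(np.where(elev >= split_m, "high", "low"),
                       index=meta.index, name="group")
    return labels
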