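"""ASV-table filtering, rarefied richness, and Bray-Curtis dissimilarity.

Filtering applies three rules in a fixed, auditable order: (1) remove
non-target ASVs (chloroplast/mitochondrial/eukaryotic sequences and ASVs
without a phylum assignment), (2) remove ASVs with too few total reads,
(3) remove samples with too few remaining reads.  Richness is the number of
distinct ASVs observed in a fixed-depth subsample drawn without replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .data_model import AsvTable, PipelineConfig, TaxonomyMap

__all__ = [
    "FilterReport",
    "filter_asv_table",
    "prevalence_filter",
    "to_relative_abundance",
    "rarefied_richness",
    "bray_curtis",
]

# rank values flagging non-prokaryotic-target ASVs, matched case-insensitively
NONTARGET_LABELS = ("chloroplast", "mitochondria", "eukaryota")


@dataclass
class FilterReport:
    """Per-step removal counts from :func:`filter_asv_table`."""

    n_asvs_nontarget: int
    n_asvs_low_reads: int
    n_samples_low_reads: int

    def as_dict(self) -> dict[str, int]:
        return {
            "asvs_removed_nontarget_taxonomy": self.n_asvs_nontarget,
            "asvs_removed_low_total_reads": self.n_asvs_low_reads,
            "samples_removed_low_total_reads": self.n_samples_low_reads,
        }


def _is_nontarget(tax: TaxonomyMap, asv_ids: pd.Index) -> pd.Series:
    sub = tax.data.reindex(asv_ids)
    flagged = pd.Series(False, index=asv_ids)
    for rank in sub.columns:
        labels = sub[rank].astype("string").str.lower()
        for bad in NONTARGET_LABELS:
            flagged |= labels.str.contains(bad, regex=False).fillna(False)
    # no phylum assignment (absent from taxonomy, NaN, or empty string)
    phylum = sub["phylum"].astype("string").str.strip()
    flagged |= phylum.isna() | (phylum == "")
    return flagged


def filter_asv_table(
    table: AsvTable, tax: TaxonomyMap, cfg: PipelineConfig | None = None
) -> tuple[AsvTable, FilterReport]:
    """Apply the three community filters in order; returns table + report.

    Order: non-target taxonomy -> ASV total-read minimum -> sample
    total-read minimum.  Raises if nothing survives.
    """
    cfg = cfg or PipelineConfig()
    if table.kind != "counts":
        raise ValueError("filtering operates on a counts table")
    data = table.data

    nontarget = _is_nontarget(tax, data.columns)
    data = data.loc[:, ~nontarget.to_numpy()]

    low_asv = data.sum(axis=0) < cfg.min_asv_reads
    data = data.loc[:, ~low_asv.to_numpy()]

    low_sample = data.sum(axis=1) < cfg.min_sample_reads
    data = data.loc[~low_sample.to_numpy()]

    if data.shape[0] == 0 or data.shape[1] == 0:
        raise ValueError("no samples/ASVs survive filtering")

    report = FilterReport(
        n_asvs_nontarget=int(nontarget.sum()),
        n_asvs_low_reads=int(low_asv.sum()),
        n_samples_low_reads=int(low_sample.sum()),
    )
    return replace(table, data=data), report


def prevalence_filter(table: AsvTable, min_samples: int = 10) -> AsvTable:
    """Keep ASVs with non-zero abundance in at least ``min_samples`` samples."""
    prevalence = (table.data > 0).sum(axis=0)
    keep = prevalence >= min_samples
    if not keep.any():
        warnings.warn("prevalence filter removed every ASV", UserWarning,
                      stacklevel=2)
    return replace(table, data=table.data.loc[:, keep.to_numpy()])


def to_relative_abundance(table: AsvTable) -> AsvTable:
    """Convert counts to per-sample proportions (each row sums to 1)."""
    sums = table.data.sum(axis=1)
    if (sums == 0).any():
        zero = sums.index[sums == 0][0]
        raise ValueError(f"sample {zero!r} has zero total reads")
    data = table.data.div(sums, axis=0)
    return AsvTable(data, kind="relative")


def rarefied_richness(
    table: AsvTable, depth: int = 2000, seed: int = 0
) -> tuple[pd.Series, list[str]]:
    """Distinct ASVs per sample in a seeded ``depth``-read subsample.

    Reads are drawn without replacement (multivariate hypergeometric).
    Samples with fewer than ``depth`` total reads are scored at full depth
    and returned in the flagged list.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if table.kind != "counts":
        raise ValueError("rarefied richness requires a counts table")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy().astype(np.int64)
    richness = np.empty(counts.shape[0], dtype=np.int64)
    flagged: list[str] = []
    for i, row in enumerate(counts):
        total = int(row.sum())
        if total <= depth:
            richness[i] = int((row > 0).sum())
            if total < depth:
                flagged.append(table.data.index[i])
        else:
            draw = rng.multivariate_hypergeometric(row, depth)
            richness[i] = int((draw > 0).sum())
    return pd.Series(richness, index=table.data.index, name="richness"), flagged


def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y)."""
    values = table.data.to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).any():
        zero = table.data.index[values.sum(axis=1) == 0][0]
        raise ValueError(f"sample {zero!r} is all-zero; Bray-Curtis undefined")
    dm = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(dm, ids=list(table.data.index))
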