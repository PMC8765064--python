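"""KEGG-ortholog table processing and differential functional-gene analysis.

Samples are rarefied to a common number of annotated reads, normalized so
abundances are expressed per genome equivalent (each sample divided by the
median abundance of a set of universal single-copy genes), and then
contrasted between the high- and low-elevation groups: a gene with
log2(mean_low / mean_high) below -1 is at least twice as abundant at high
elevation ("high_enriched"), above +1 at low elevation ("low_enriched").
A pathway becomes a pathway of interest when enough of its member genes
(default 5) are high-enriched; a gene belonging to several pathways counts
in each of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import AsvTable

__all__ = [
    "PathwayMap",
    "read_pathway_map",
    "rarefy_ko_table",
    "single_copy_normalize",
    "ko_richness",
    "log2_fold_change",
    "classify_enriched",
    "pathways_of_interest",
]


@dataclass
class PathwayMap:
    """pathway_id -> (display name, member KO IDs); KOs may repeat across pathways."""

    names: dict[str, str]
    members: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("pathway map is empty")
        for pid, kos in self.members.items():
            if not kos:
                raise ValueError(f"pathway {pid!r} has no member KOs")


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Read a KO->pathway TSV with columns pathway_id, pathway_name, ko_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway_id", "pathway_name", "ko_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"pathway map needs columns {sorted(required)}")
    names = dict(df.drop_duplicates("pathway_id")[["pathway_id", "pathway_name"]]
                 .itertuples(index=False, name=None))
    members = {
        pid: frozenset(group["ko_id"])
        for pid, group in df.groupby("pathway_id")
    }
    return PathwayMap(names=names, members=members)


def rarefy_ko_table(ko: AsvTable, depth: int, seed: int = 0) -> AsvTable:
    """Subsample every sample to exactly ``depth`` annotated reads (seeded,
    without replacement).  Errors if any sample is below the depth."""
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    counts = ko.data.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("KO rarefaction requires integer counts")
    counts = counts.astype(np.int64)
    totals = counts.sum(axis=1)
    short = totals < depth
    if short.any():
        sample = ko.data.index[short][0]
        raise ValueError(
            f"sample {sample!r} has {totals[short][0]} annotated reads, "
            f"fewer than the rarefaction depth {depth}"
        )
    rng = np.random.default_rng(seed)
    # draw in sorted-KO order so the result is invariant to column order
    order = np.argsort(np.asarray(ko.data.columns, dtype=object))
    unorder = np.argsort(order)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        if totals[i] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row[order], depth)[unorder]
    return AsvTable(pd.DataFrame(out, index=ko.data.index, columns=ko.data.columns),
                    kind="counts")


def single_copy_normalize(ko: AsvTable, uscg_ids: list[str]) -> AsvTable:
    """Scale each sample by the median abundance of its universal single-copy
    genes, so abundances read as copies per genome equivalent (median USiCG
    abundance becomes exactly 1 in every sample)."""
    present = [k for k in uscg_ids if k in ko.data.columns]
    if len(present) < 5:
        raise ValueError(
            f"only {len(present)} universal single-copy genes present; need >= 5"
        )
    med = ko.data[present].median(axis=1)
    if (med == 0).any():
        sample = med.index[med == 0][0]
        raise ValueError(f"sample {sample!r} has median single-copy abundance 0")
    return AsvTable(ko.data.div(med, axis=0), kind="counts")


def ko_richness(ko: AsvTable) -> pd.Series:
    """Number of distinct KOs with abundance > 0 per sample."""
    return (ko.data > 0).sum(axis=1).rename("ko_richness")


def log2_fold_change(
    ko: AsvTable, groups: pd.Series, eps_mode: str = "half_min"
) -> pd.Series:
    """Per-KO log2(mean_low / mean_high) across the elevation groups.

    With ``eps_mode='half_min'`` both means get a pseudocount of half the
    smallest positive table value, keeping zero means finite; 'none' raises
    on a zero mean.  Orientation: fc < -1 means at least twice as abundant
    at HIGH elevation.
    """
    labels = groups.reindex(ko.data.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"samples without a group label: {missing[:5]}")
    high = ko.data.loc[labels == "high"]
    low = ko.data.loc[labels == "low"]
    if high.empty or low.empty:
        raise ValueError("both elevation groups must be non-empty")
    mu_high = high.mean(axis=0)
    mu_low = low.mean(axis=0)
    if eps_mode == "half_min":
        positive = ko.data.to_numpy()
        positive = positive[positive > 0]
        if positive.size == 0:
            raise ValueError("table has no positive values")
        eps = float(positive.min()) / 2.0
    elif eps_mode == "none":
        if (mu_high == 0).any() or (mu_low == 0).any():
            raise ValueError("zero group mean; use eps_mode='half_min'")
        eps = 0.0
    else:
        raise ValueError(f"unknown eps_mode {eps_mode!r}")
    fc = np.log2((mu_low + eps) / (mu_high + eps))
    return fc.rename("log2fc")


def classify_enriched(fc: pd.Series, cutoff: float = 1.0) -> pd.DataFrame:
    """Classify each KO from its fold change (strict boundaries).

    fc < -cutoff -> 'high_enriched'; fc > +cutoff -> 'low_enriched';
    otherwise 'neither'.
    """
    cls = pd.Series("neither", index=fc.index, name="class")
    cls[fc < -cutoff] = "high_enriched"
    cls[fc > cutoff] = "low_enriched"
    return pd.DataFrame({"log2fc": fc, "class": cls})


def pathways_of_interest(
    cls: pd.DataFrame,
    pmap: PathwayMap,
    min_genes: int = 5,
    blocklist: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Pathways with at least ``min_genes`` high-enriched member KOs.

    A KO shared by several pathways counts toward each; pathways on the
    ``blocklist`` (e.g. exclusively eukaryotic categories) are skipped.
    Returns a table sorted by enriched-gene count, descending.
    """
    high = set(cls.index[cls["class"] == "high_enriched"])
    rows = []
    for pid, members in pmap.members.items():
        if pid in blocklist:
            continue
        n_enriched = len(high & members)
        if n_enriched >= min_genes:
            rows.append((pid, pmap.names.get(pid, pid), n_enriched, len(members)))
    out = pd.DataFrame(rows, columns=["pathway_id", "pathway_name",
                                      "n_high_enriched", "n_members"])
    return out.sort_values(
        ["n_high_enriched", "pathway_id"], ascending=[False, True]
    ).reset_index(drop=True)
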