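"""Differential functional-gene (KEGG ortholog) analysis.

Simulates KO count tables for 27 metagenomes (15 high-, 12 low-elevation)
with a planted set of 40 genes four-fold enriched at high elevation, then
runs the functional chain: rarefy to a common annotated-read depth,
normalize to universal single-copy genes (so abundances read as copies per
genome equivalent), compare KO richness between groups, classify genes by
log2 fold change, and flag pathways of interest.
"""

import pandas as pd

from cryograd import (
    PathwayMap,
    classify_enriched,
    ko_richness,
    log2_fold_change,
    mann_whitney_u,
    pathways_of_interest,
    rarefy_ko_table,
    simulate_ko_table,
    single_copy_normalize,
)

samples = [f"M{i + 1:02d}" for i in range(27)]
groups = pd.Series(["high"] * 15 + ["low"] * 12, index=samples, name="group")
table, truth = simulate_ko_table(groups, seed=11, fold=4.0)

depth = int(table.data.sum(axis=1).min())
rarefied = rarefy_ko_table(table, depth, seed=11)
norm = single_copy_normalize(rarefied, truth.uscg_ids)
print(f"Rarefied every sample to {depth:,} annotated reads; normalized to "
      f"{len(truth.uscg_ids)} single-copy genes")

rich = ko_richness(table)
u, p = mann_whitney_u(rich[groups == "high"], rich[groups == "low"])
print(f"\nKO richness: high median {rich[groups == 'high'].median():.0f} vs "
      f"low median {rich[groups == 'low'].median():.0f} "
      f"(Mann-Whitney U = {u:.0f}, p = {p:.2g})")
print("  -> milder low-elevation soils carry more distinct functional genes")

fc = log2_fold_change(norm, groups)
cls = classify_enriched(fc)
n_high = (cls["class"] == "high_enriched").sum()
n_low = (cls["class"] == "low_enriched").sum()
recall = (cls.loc[truth.enriched_ko_ids, "class"] == "high_enriched").mean()
print(f"\nlog2FC classification: {n_high} KOs >2x more abundant at high "
      f"elevation, {n_low} at low elevation")
print(f"Planted high-elevation set recovered: {100 * recall:.0f}% "
      f"({len(truth.enriched_ko_ids)} genes planted at 4-fold)")

background = [k for k in table.asv_ids if k not in truth.enriched_ko_ids][:20]
pmap = PathwayMap(
    names={"pw_planted": "planted trace-gas-like pathway",
           "pw_bg": "unenriched background pathway"},
    members={"pw_planted": frozenset(truth.enriched_ko_ids[:10]),
             "pw_bg": frozenset(background)},
)
flagged = pathways_of_interest(cls, pmap, min_genes=5)
print(f"\nPathways of interest (>= 5 high-enriched member genes):")
print(flagged.to_string(index=False))
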