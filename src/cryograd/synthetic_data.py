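"""Synthetic elevational-gradient fixtures with planted ground truth.

Emulates the structure of a polar soil survey: samples spread along a
100-2,200 m elevation gradient; geochemical variables (salts, oxyanions)
positively correlated with elevation; a sparse community of thousands of
ASVs in which planted modules share a smooth response (logistic or
Gaussian) to one driver variable; KO tables with an elevation-enriched gene
set on top of a stable single-copy-gene baseline; and homology-hit tables
whose records deliberately straddle every QC threshold.  Every generator is
deterministic given its seed, and each returns the planted truth alongside
the data so recovery can be scored without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .data_model import CONCENTRATION_VARS, AsvTable, TaxonomyMap
from .trace_gas import GENE_CLASSES

__all__ = [
    "SimConfig",
    "ModuleSpec",
    "SyntheticTruth",
    "KoTruth",
    "HitTruth",
    "simulate_environment",
    "simulate_community",
    "simulate_taxonomy",
    "simulate_ko_table",
    "simulate_hit_table",
    "adjusted_rand_index",
    "H2_OXIDATION_GENES",
]

#: Uptake [NiFe]-hydrogenase marker genes (H2 oxidation); group 3 enzymes are
#: bidirectional/cofactor-coupled and not part of this set.
H2_OXIDATION_GENES = ("NiFe_1c", "NiFe_1d", "NiFe_1f", "NiFe_1h",
                      "NiFe_1l", "NiFe_2a")

# plausible magnitudes for each geochemical variable (same units as the
# metadata contract: mg/kg, perchlorate/chlorate in ug/kg)
_VAR_SCALE = {
    "nitrate": 500.0,
    "chloride": 800.0,
    "total_cations": 1500.0,
    "total_anions": 1800.0,
    "total_salt": 5700.0,
    "perchlorate": 60.0,
    "chlorate": 70.0,
    "nh3": 10.0,
    "sio2": 30.0,
}

# most variables track elevation strongly; NH3, SiO2 and chloride only weakly
_DEFAULT_ELEV_R = {v: 0.7 for v in CONCENTRATION_VARS}
_DEFAULT_ELEV_R.update({"nh3": 0.2, "sio2": 0.2, "chloride": 0.2})


@dataclass
class ModuleSpec:
    """Planted niche response of one co-occurring module."""

    size: int
    driver: str = "elevation"
    shape: str = "logistic_up"  # logistic_up | logistic_down | gaussian
    center: float = 0.0  # in driver standard-deviation units
    width: float = 0.5
    effect_size: float = 8.0

    def response(self, v_std: np.ndarray) -> np.ndarray:
        """Niche suitability g(v) in [0, 1] on the standardized driver."""
        if self.shape == "logistic_up":
            return 1.0 / (1.0 + np.exp(-(v_std - self.center) / self.width))
        if self.shape == "logistic_down":
            return 1.0 / (1.0 + np.exp((v_std - self.center) / self.width))
        if self.shape == "gaussian":
            return np.exp(-((v_std - self.center) ** 2) / (2 * self.width**2))
        raise ValueError(f"unknown response shape {self.shape!r}")

    def factor(self, v_std: np.ndarray) -> np.ndarray:
        """Multiplicative abundance response f(v) = exp(effect_size*(g(v)-1)).

        f equals 1 at the niche optimum and exp(-effect_size) in fully
        unsuitable samples, so effect_size is the log dynamic range of the
        planted niche (specialists vanish off-niche for effect_size >~ 8).
        """
        return np.exp(self.effect_size * (self.response(v_std) - 1.0))


@dataclass
class SimConfig:
    """Study conditions for the synthetic gradient survey."""

    n_samples: int = 150
    elevation_range: tuple[float, float] = (100.0, 2200.0)
    env_elev_correlation: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ELEV_R))
    n_background_asvs: int = 1000
    modules: list[ModuleSpec] = field(default_factory=lambda: [
        ModuleSpec(size=10, shape="logistic_up", center=0.5, width=0.3),
        ModuleSpec(size=10, shape="logistic_down", center=-0.5, width=0.3),
        ModuleSpec(size=10, shape="gaussian", center=0.0, width=0.35),
        ModuleSpec(size=10, shape="logistic_up", driver="nh3"),
        ModuleSpec(size=10, shape="logistic_up", driver="sio2"),
    ])
    background_occupancy: tuple[float, float] = (0.05, 0.6)
    depth_lognormal: tuple[float, float] = (np.log(30_000.0), 0.4)
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        lo, hi = self.elevation_range
        if not lo < hi:
            raise ValueError("elevation_range must be (min, max) with min < max")
        for m in self.modules:
            if m.size < 2:
                raise ValueError("module sizes must be >= 2")
            if m.effect_size < 0:
                raise ValueError("effect_size must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted community structure: memberships, drivers, niche parameters."""

    modules: dict[str, ModuleSpec]
    members: dict[str, list[str]]
    expected_module_abundance: pd.DataFrame  # samples x modules, latent scale

    def partition(self) -> dict[str, list[str]]:
        return dict(self.members)


@dataclass
class KoTruth:
    enriched_ko_ids: list[str]
    uscg_ids: list[str]
    fold: float
    low_only_ko_ids: list[str]


@dataclass
class HitTruth:
    survivor_mask: pd.Series  # aligned to the hit table index
    expected_counts: pd.DataFrame  # sample x gene surviving-hit counts


def _rng(seed: int, stream: int) -> np.random.Generator:
    # counter-based sub-streams: stages are independently reproducible
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_environment(cfg: SimConfig, seed: int = 0) -> pd.DataFrame:
    """Sample metadata with elevations uniform over the range and each
    geochemical variable linearly tied to elevation at its target Pearson r
    (Gaussian noise, clipped at 0)."""
    for var, r in cfg.env_elev_correlation.items():
        if abs(r) > 0.99:
            raise ValueError(f"target correlation {r} for {var!r} exceeds the "
                             "0.99 cap")
    rng = _rng(seed, 0)
    lo, hi = cfg.elevation_range
    elevation = rng.uniform(lo, hi, size=cfg.n_samples)
    z_elev = (elevation - elevation.mean()) / elevation.std()
    meta = pd.DataFrame(
        {"elevation": elevation},
        index=[f"S{i + 1:03d}" for i in range(cfg.n_samples)],
    )
    for var in CONCENTRATION_VARS:
        r = cfg.env_elev_correlation.get(var, 0.7)
        noise = rng.standard_normal(cfg.n_samples)
        # orthogonalize the noise against elevation in-sample so the
        # realized (not just population) correlation hits the target
        noise = noise - np.polyval(np.polyfit(z_elev, noise, 1), z_elev)
        noise /= noise.std()
        latent = r * z_elev + np.sqrt(max(0.0, 1.0 - r**2)) * noise
        scale = _VAR_SCALE[var]
        # location 4 sd above zero keeps clipping (and the r distortion
        # it would cause) negligible
        meta[var] = np.clip(scale + (scale / 4.0) * latent, 0.0, None)
    meta["feature"] = [f"F{1 + i % 10}" for i in range(cfg.n_samples)]
    return meta


def simulate_community(
    meta: pd.DataFrame, cfg: SimConfig, seed: int = 0
) -> tuple[AsvTable, SyntheticTruth]:
    """Sparse ASV counts with planted co-occurring modules.

    A member ASV j of module m has latent expected abundance
    ``scale_j * f_m(v_s) * exp(noise)`` where f_m is the module's
    multiplicative niche response on its standardized driver (1 at the
    optimum, exp(-effect_size) off-niche); member scales are drawn from the
    same lognormal as the background so that with effect_size = 0 members
    are statistically indistinguishable from background ASVs.  Background
    ASVs get gradient-independent sparse lognormal abundances.  Counts are
    multinomial at a lognormal per-sample depth.
    """
    rng = _rng(seed, 1)
    n = len(meta)
    n_module_asvs = sum(m.size for m in cfg.modules)
    asv_ids = [f"ASV{i + 1:05d}" for i in range(n_module_asvs + cfg.n_background_asvs)]

    latent = np.zeros((n, len(asv_ids)))
    members: dict[str, list[str]] = {}
    specs: dict[str, ModuleSpec] = {}
    expected_mod = {}
    col = 0
    for k, spec in enumerate(cfg.modules):
        if spec.driver not in meta.columns:
            raise ValueError(f"driver {spec.driver!r} not in metadata")
        module_id = f"true_{k + 1:02d}"
        v = meta[spec.driver].to_numpy(dtype=float)
        v_std = (v - v.mean()) / v.std()
        f = spec.factor(v_std)
        ids = asv_ids[col: col + spec.size]
        members[module_id] = ids
        specs[module_id] = spec
        scales = rng.lognormal(mean=1.0, sigma=1.0, size=spec.size)
        noise = rng.standard_normal((n, spec.size)) * cfg.noise_sd
        block = scales[None, :] * f[:, None] * np.exp(noise)
        latent[:, col: col + spec.size] = block
        expected_mod[module_id] = block.mean(axis=1)
        col += spec.size

    if cfg.n_background_asvs:
        occ_lo, occ_hi = cfg.background_occupancy
        occupancy = rng.uniform(occ_lo, occ_hi, size=cfg.n_background_asvs)
        present = rng.random((n, cfg.n_background_asvs)) < occupancy[None, :]
        bg_scale = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_background_asvs)
        bg_noise = rng.standard_normal((n, cfg.n_background_asvs)) * cfg.noise_sd
        latent[:, col:] = present * bg_scale[None, :] * np.exp(bg_noise)

    rowsum = latent.sum(axis=1)
    if (rowsum == 0).any():
        raise ValueError("a sample has zero expected abundance; increase "
                         "occupancy or module count")
    probs = latent / rowsum[:, None]
    mu, sigma = cfg.depth_lognormal
    depths = np.maximum(1, rng.lognormal(mu, sigma, size=n)).astype(np.int64)
    counts = np.vstack([
        rng.multinomial(depths[i], probs[i]) for i in range(n)
    ])
    table = AsvTable(
        pd.DataFrame(counts, index=meta.index, columns=asv_ids), kind="counts"
    )
    truth = SyntheticTruth(
        modules=specs,
        members=members,
        expected_module_abundance=pd.DataFrame(expected_mod, index=meta.index),
    )
    return table, truth


_PHYLA = ("Actinobacteria", "Acidobacteria", "Bacteroidetes", "Proteobacteria",
          "Chloroflexi", "Verrucomicrobia", "Gemmatimonadetes", "Cyanobacteria",
          "Planctomycetes", "Deinococcus-Thermus")


def simulate_taxonomy(
    asv_ids: list[str],
    seed: int = 0,
    n_chloroplast: int = 0,
    n_mitochondria: int = 0,
    n_eukaryote: int = 0,
    n_unassigned_phylum: int = 0,
) -> TaxonomyMap:
    """Random prokaryotic rank labels, with optional planted non-target ASVs
    (assigned from the start of ``asv_ids``) for exercising the filters."""
    rng = _rng(seed, 2)
    n = len(asv_ids)
    n_special = n_chloroplast + n_mitochondria + n_eukaryote + n_unassigned_phylum
    if n_special > n:
        raise ValueError("more special ASVs requested than IDs provided")
    rows = []
    for i, asv in enumerate(asv_ids):
        if i < n_chloroplast:
            rows.append(("Bacteria", "Cyanobacteria", "Chloroplast",
                         np.nan, np.nan, np.nan))
        elif i < n_chloroplast + n_mitochondria:
            rows.append(("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                         "Rickettsiales", "Mitochondria", np.nan))
        elif i < n_chloroplast + n_mitochondria + n_eukaryote:
            rows.append(("Eukaryota", "Ascomycota", np.nan, np.nan, np.nan, np.nan))
        elif i < n_special:
            rows.append(("Bacteria", np.nan, np.nan, np.nan, np.nan, np.nan))
        else:
            phylum = _PHYLA[int(rng.integers(0, len(_PHYLA)))]
            rows.append(("Bacteria", phylum, f"{phylum}_class",
                         f"{phylum}_order", f"{phylum}_family", np.nan))
    df = pd.DataFrame(
        rows,
        index=asv_ids,
        columns=["domain", "phylum", "class", "order", "family", "genus"],
    )
    return TaxonomyMap(df)


def simulate_ko_table(
    groups: pd.Series,
    seed: int = 0,
    n_kos: int = 400,
    n_enriched: int = 40,
    n_uscg: int = 10,
    n_low_only: int = 60,
    fold: float = 4.0,
    reads_per_copy: float = 2000.0,
) -> tuple[AsvTable, KoTruth]:
    """KO counts with a planted high-elevation-enriched gene set.

    Baseline per-KO abundances are lognormal; the planted enriched set is
    multiplied by ``fold`` in high-elevation samples; a further
    ``n_low_only`` genes occur only in low-elevation samples (at low
    abundance), reproducing the higher functional-gene richness of milder
    soils; universal single-copy genes are held at expected copy number 1.
    Counts are Poisson at ``reads_per_copy`` reads per unit abundance.
    """
    if fold <= 0:
        raise ValueError("fold factor must be positive")
    rng = _rng(seed, 3)
    samples = list(groups.index)
    high = (groups == "high").to_numpy()
    n_base = n_kos - n_uscg - n_low_only
    if n_base <= n_enriched:
        raise ValueError("n_kos too small for the requested planted sets")
    uscg_ids = [f"K{15000 + i:05d}" for i in range(n_uscg)]
    other_ids = [f"K{i + 1:05d}" for i in range(n_base)]
    low_only_ids = [f"K{16000 + i:05d}" for i in range(n_low_only)]
    enriched = list(rng.choice(other_ids, size=n_enriched, replace=False))
    base = rng.lognormal(mean=-1.0, sigma=1.0, size=n_base)
    expected = np.tile(base, (len(samples), 1))
    enriched_idx = [other_ids.index(k) for k in enriched]
    expected[np.ix_(high, enriched_idx)] *= fold
    low_only = np.tile(
        rng.lognormal(mean=-5.0, sigma=0.5, size=n_low_only),
        (len(samples), 1),
    )
    low_only[high, :] = 0.0
    uscg_expected = np.ones((len(samples), n_uscg))
    lam = np.hstack([expected, low_only, uscg_expected]) * reads_per_copy
    counts = rng.poisson(lam)
    data = pd.DataFrame(counts, index=samples,
                        columns=other_ids + low_only_ids + uscg_ids)
    return (
        AsvTable(data, kind="counts"),
        KoTruth(enriched_ko_ids=sorted(enriched), uscg_ids=uscg_ids,
                fold=fold, low_only_ko_ids=low_only_ids),
    )


def _default_hit_groups() -> pd.Series:
    # 15 high- and 12 low-elevation metagenomes, like a typical deep-sequenced subset
    labels = ["high"] * 15 + ["low"] * 12
    return pd.Series(labels, index=[f"M{i + 1:02d}" for i in range(27)],
                     name="group")


def simulate_hit_table(
    groups: pd.Series | None = None,
    seed: int = 0,
    base_hits: float = 20.0,
    h2_fold: float = 5.0,
    total_reads: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.Series, HitTruth]:
    """Homology-hit fixtures straddling every QC threshold, plus planted
    group-differential surviving counts.

    For every gene class the table carries probe hits just below and above
    each threshold (identity 49/51 or 59/61, coverage 79/81, E-value
    1e-9/1e-11) and exactly at the boundary (kept, thresholds inclusive).
    Surviving-hit counts per (sample, gene) are Poisson at ``base_hits``,
    multiplied by ``h2_fold`` for the H2-oxidation genes in high-elevation
    samples.  The truth records which rows must survive filtering and the
    per-cell surviving counts.
    """
    groups = _default_hit_groups() if groups is None else groups
    rng = _rng(seed, 4)
    samples = list(groups.index)
    high = groups == "high"

    rows: list[tuple] = []
    survive: list[bool] = []

    def add(sample, gene, ident, cov, evalue, keep, read):
        rows.append((read, sample, gene, ident, cov, evalue,
                     float(200.0 + rng.random())))
        survive.append(keep)

    probe_read = 0
    for gi, gene in enumerate(GENE_CLASSES):
        ident_min = 50.0 if gene.startswith("NiFe") else 60.0
        sample = samples[gi % len(samples)]
        probes = [
            (ident_min - 1.0, 90.0, 1e-20, False),  # identity below
            (ident_min + 1.0, 90.0, 1e-20, True),   # identity above
            (ident_min, 90.0, 1e-20, True),         # identity at boundary
            (75.0, 79.0, 1e-20, False),             # coverage below
            (75.0, 81.0, 1e-20, True),              # coverage above
            (75.0, 80.0, 1e-20, True),              # coverage at boundary
            (75.0, 90.0, 1e-9, False),              # evalue above max
            (75.0, 90.0, 1e-11, True),              # evalue below max
            (75.0, 90.0, 1e-10, True),              # evalue at boundary
        ]
        for ident, cov, ev, keep in probes:
            add(sample, gene, ident, cov, ev, keep, f"probe_{probe_read:05d}")
            probe_read += 1

    # planted group-differential survivors
    for gene in GENE_CLASSES:
        lam = np.full(len(samples), base_hits, dtype=float)
        if gene in H2_OXIDATION_GENES:
            lam[high.to_numpy()] *= h2_fold
        counts = rng.poisson(lam)
        for s, c in zip(samples, counts):
            for i in range(int(c)):
                add(s, gene, float(rng.uniform(70, 95)),
                    float(rng.uniform(85, 100)),
                    float(10.0 ** rng.uniform(-40, -12)), True,
                    f"{s}_{gene}_{i:04d}")

    hits = pd.DataFrame(
        rows,
        columns=["read_id", "sample_id", "gene_class", "pct_identity",
                 "pct_query_coverage", "evalue", "bitscore"],
    )
    mask = pd.Series(survive, index=hits.index, name="survives")
    expected = (
        hits.loc[mask]
        .groupby(["sample_id", "gene_class"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=samples, columns=list(GENE_CLASSES), fill_value=0)
        .fillna(0)
        .astype(int)
        .rename_axis(index=None, columns=None)
    )
    totals = pd.Series(total_reads, index=samples, name="total_reads")
    return hits, totals, HitTruth(survivor_mask=mask, expected_counts=expected)


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two partitions of the same elements.

    Partitions may be dicts (group -> members) or label Series/mappings.
    1 for identical partitions; ~0 for independent random ones.
    """

    def to_labels(p) -> pd.Series:
        if isinstance(p, dict) and p and not np.isscalar(next(iter(p.values()))):
            pairs = [(el, g) for g, els in p.items() for el in els]
            els, gs = zip(*pairs)
            s = pd.Series(gs, index=list(els))
            if s.index.has_duplicates:
                raise ValueError("partition groups overlap")
            return s
        return pd.Series(p)

    la, lb = to_labels(a), to_labels(b)
    if set(la.index) != set(lb.index):
        raise ValueError("partitions cover different element universes")
    lb = lb.reindex(la.index)
    return float(adjusted_rand_score(la.to_numpy(), lb.to_numpy()))
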