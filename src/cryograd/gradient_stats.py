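"""Statistical engines shared across pipeline stages.

Rank and linear correlation, the Mantel permutation test, the exhaustive
BIOENV best-subset search, Mann-Whitney U contrasts, and per-feature
Z-standardization.  These are thin, carefully specified layers over
scipy/numpy so every stage uses identical conventions (mid-rank ties,
sample standard deviation, one-sided Mantel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from skbio import DistanceMatrix

__all__ = [
    "BioenvResult",
    "MantelResult",
    "correlation",
    "mantel_test",
    "bioenv_search",
    "mann_whitney_u",
    "zscore_table",
]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


@dataclass
class BioenvResult:
    """Best variable subset and the full per-subset correlation table."""

    best_subset: frozenset[str]
    rho: float
    table: pd.DataFrame  # columns: subset (tuple), size, rho


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman (mid-rank ties) correlation of two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def _lower_triangle(dm: DistanceMatrix) -> np.ndarray:
    data = dm.data
    idx = np.tril_indices(data.shape[0], k=-1)
    return data[idx]


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-sided (greater) Mantel test on Pearson correlation of distances.

    The null distribution is built by jointly permuting rows and columns of
    ``d2``; p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices cover different sample sets")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    d2 = d2.filter(d1.ids)  # align orderings
    v1 = _lower_triangle(d1)
    m2 = d2.data
    n = m2.shape[0]
    tril = np.tril_indices(n, k=-1)
    r_obs = float(stats.pearsonr(v1, m2[tril]).statistic)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2 = m2[np.ix_(perm, perm)][tril]
        if stats.pearsonr(v1, v2).statistic >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm)


def bioenv_search(
    d_community: DistanceMatrix,
    env: pd.DataFrame,
    variables: list[str] | None = None,
    max_subset: int | None = None,
) -> BioenvResult:
    """Exhaustive BIOENV: the variable subset whose Euclidean distances best
    rank-correlate (Spearman) with the community dissimilarities.

    Variables are standardized to mean 0, sd 1 before distance computation
    (callers log-transform concentrations first).  Ties in rho break toward
    the smaller subset, then lexicographically.
    """
    variables = list(variables) if variables is not None else list(env.columns)
    missing = [v for v in variables if v not in env.columns]
    if missing:
        raise ValueError(f"variables not in metadata: {missing}")
    sub = env.loc[list(d_community.ids), variables]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()][0]
        raise ValueError(
            f"variable {bad!r} has missing values among included samples; "
            "pre-filter to complete cases"
        )
    z = (sub - sub.mean()) / sub.std(ddof=1)
    if z.isna().any().any():
        bad = sub.columns[z.isna().any()][0]
        raise ValueError(f"variable {bad!r} has zero variance")
    max_subset = max_subset or len(variables)
    community = _lower_triangle(d_community)
    comm_ranks = stats.rankdata(community)

    rows = []
    zvals = z.to_numpy()
    for k in range(1, max_subset + 1):
        for subset in combinations(range(len(variables)), k):
            env_d = pdist(zvals[:, subset], metric="euclidean")
            # pdist order matches upper triangle; use consistent ordering
            rho = _spearman_prepranked(comm_ranks_lower=comm_ranks,
                                       other=_pdist_to_lower(env_d, len(d_community.ids)))
            rows.append((tuple(variables[i] for i in subset), k, rho))
    table = pd.DataFrame(rows, columns=["subset", "size", "rho"])
    # argmax with parsimony tie-break: highest rho, smallest size, lexicographic
    order = table.sort_values(
        by=["rho", "size", "subset"], ascending=[False, True, True],
        kind="mergesort",
    )
    best = order.iloc[0]
    return BioenvResult(best_subset=frozenset(best["subset"]),
                        rho=float(best["rho"]), table=table)


def _pdist_to_lower(condensed: np.ndarray, n: int) -> np.ndarray:
    from scipy.spatial.distance import squareform

    full = squareform(condensed)
    return full[np.tril_indices(n, k=-1)]


def _spearman_prepranked(comm_ranks_lower: np.ndarray, other: np.ndarray) -> float:
    other_ranks = stats.rankdata(other)
    return float(stats.pearsonr(comm_ranks_lower, other_ranks).statistic)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with mid-rank ties.

    Exact p by enumeration when n+m <= 20 with no ties; otherwise normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def zscore_table(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each feature (column) across samples: (x - mean) / sd.

    Uses the sample standard deviation (ddof=1).  A zero-variance feature
    becomes all zeros, with a warning.
    """
    if table.shape[0] < 2:
        raise ValueError("Z-scores require at least 2 samples")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s) standardized to 0",
            UserWarning,
            stacklevel=2,
        )
        sd = sd.where(~zero, other=1.0)
    z = (table - mean) / sd
    z.loc[:, zero[zero].index] = 0.0
    return z
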