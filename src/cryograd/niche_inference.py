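"""Random-forest niche inference for co-occurrence modules.

Each module's per-sample presence (1 if any member ASV has reads in the
sample) is regressed on the standardized environmental variables with a
bagged ensemble of regression trees.  Variable importance is the classic
out-of-bag permutation importance (%IncMSE): the relative increase in a
tree's OOB mean squared error when one predictor is shuffled, averaged over
trees.  A module's niche model is accepted only if the forest explains more
than ``min_var_explained_pct`` of the response variance AND the top variable
has %IncMSE >= ``min_inc_mse_pct`` with a response-permutation p-value below
``importance_alpha``.  Presence is a binary indicator, but the study design
reports percent variance explained and MSE, so a regression forest on the
0/1 response is used deliberately (a Brier-score view of presence).

Accepted modules are then classified as high-, low-, or mid-elevation from
their mean Z-score profile along the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .cooccurrence import ModulePartition
from .data_model import AsvTable, PipelineConfig
from .gradient_stats import correlation

__all__ = [
    "PreferenceResult",
    "module_presence",
    "fit_preference_forest",
    "select_predictive_variable",
    "module_z_profile",
    "classify_elevation_class",
    "infer_module_preferences",
]


@dataclass
class PreferenceResult:
    """Outcome of one module's niche-model fit (and, later, selection)."""

    module_id: str | None
    var_explained_pct: float
    importance: pd.Series  # %IncMSE per variable
    importance_p: pd.Series  # permutation p-value per variable
    selected_variable: str | None = None
    elevation_class: str | None = None


def module_presence(table: AsvTable, part: ModulePartition) -> pd.DataFrame:
    """Sample x module 0/1 matrix: 1 iff any member ASV has reads > 0."""
    unknown = set(part.membership().index) - set(table.data.columns)
    if unknown:
        raise ValueError(f"partition references ASVs absent from table: "
                         f"{sorted(unknown)[:5]}")
    out = {}
    nonzero = table.data > 0
    for module_id, members in part.modules.items():
        out[module_id] = nonzero[members].any(axis=1).astype(np.int8)
    return pd.DataFrame(out, index=table.data.index)


def _forest_oob_importance(
    y: np.ndarray,
    x: np.ndarray,
    n_trees: int,
    mtry: int,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Fit a bagged regression forest; return OOB MSE and %IncMSE per variable.

    Per tree: OOB MSE is computed on the held-out bootstrap complement;
    permuting one predictor among the OOB rows gives the per-tree relative
    MSE increase, averaged over trees (x100 -> %IncMSE).  The ensemble OOB
    MSE aggregates mean predictions per sample over trees where it was OOB.
    """
    n, p = x.shape
    x32 = np.ascontiguousarray(x, dtype=np.float32)
    y64 = np.ascontiguousarray(y, dtype=np.float64)
    inc = np.zeros(p)
    inc_trees = np.zeros(p, dtype=np.int64)
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n, dtype=np.int64)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[boot] = False
        tree = DecisionTreeRegressor(
            max_features=mtry,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        # inputs pre-validated once above; skip sklearn's per-fit checks
        tree.fit(x32[boot], y64[boot], check_input=False)
        if not oob_mask.any():
            continue
        x_oob = x32[oob_mask]
        y_oob = y64[oob_mask]
        m = x_oob.shape[0]
        # one raw Cython predict per tree: block 0 is the intact OOB matrix,
        # block j+1 has variable j permuted within the OOB rows
        stacked = np.tile(x_oob, (p + 1, 1))
        for j in range(p):
            block = stacked[(j + 1) * m: (j + 2) * m]
            block[:, j] = x_oob[rng.permutation(m), j]
        preds = tree.tree_.predict(stacked).ravel()
        pred = preds[:m]
        oob_sum[oob_mask] += pred
        oob_count[oob_mask] += 1
        mse = float(np.mean((y_oob - pred) ** 2))
        for j in range(p):
            perm_pred = preds[(j + 1) * m: (j + 2) * m]
            mse_perm = float(np.mean((y_oob - perm_pred) ** 2))
            if mse > 0:
                inc[j] += (mse_perm - mse) / mse
                inc_trees[j] += 1
            elif mse_perm > 0:
                inc[j] += 1.0  # any increase from a perfect tree counts fully
                inc_trees[j] += 1
            else:
                inc_trees[j] += 1
    seen = oob_count > 0
    oob_pred = np.where(seen, oob_sum / np.maximum(oob_count, 1), np.mean(y))
    oob_mse = float(np.mean((y - oob_pred) ** 2))
    with np.errstate(invalid="ignore"):
        pct_inc = 100.0 * np.where(inc_trees > 0, inc / np.maximum(inc_trees, 1), 0.0)
    return oob_mse, pct_inc


def fit_preference_forest(
    y: pd.Series,
    env: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    module_id: str | None = None,
    n_importance_perm: int | None = None,
) -> PreferenceResult:
    """Regression forest of a module's presence on environmental variables.

    Returns percent variance explained (OOB), %IncMSE per variable, and a
    response-permutation p-value per variable (the fraction of permuted-y
    refits whose importance meets or exceeds the observed one).
    """
    cfg = cfg or PipelineConfig()
    b = cfg.n_importance_perm if n_importance_perm is None else n_importance_perm
    env = env.loc[y.index]
    if env.isna().any().any():
        bad = env.columns[env.isna().any()][0]
        raise ValueError(f"environment variable {bad!r} has missing values")
    if len(y) < 20:
        raise ValueError("need at least 20 samples for a stable forest fit")
    if cfg.mtry > env.shape[1]:
        raise ValueError(f"mtry={cfg.mtry} exceeds {env.shape[1]} variables")
    x = env.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    variables = list(env.columns)
    if np.ptp(yv) == 0:
        return PreferenceResult(
            module_id=module_id,
            var_explained_pct=0.0,
            importance=pd.Series(0.0, index=variables),
            importance_p=pd.Series(1.0, index=variables),
        )
    rng = np.random.default_rng(seed)
    oob_mse, imp = _forest_oob_importance(yv, x, cfg.n_trees, cfg.mtry, rng)
    var_y = float(np.var(yv))
    var_explained = 100.0 * (1.0 - oob_mse / var_y)
    exceed = np.zeros(len(variables), dtype=np.int64)
    for _ in range(b):
        y_perm = rng.permutation(yv)
        _, imp_perm = _forest_oob_importance(y_perm, x, cfg.n_trees, cfg.mtry, rng)
        exceed += imp_perm >= imp
    pvals = (1 + exceed) / (1 + b)
    return PreferenceResult(
        module_id=module_id,
        var_explained_pct=var_explained,
        importance=pd.Series(imp, index=variables),
        importance_p=pd.Series(pvals, index=variables),
    )


def select_predictive_variable(
    fit: PreferenceResult, cfg: PipelineConfig | None = None
) -> PreferenceResult:
    """Apply the model-acceptance rules; sets ``selected_variable`` or None.

    Accepted iff variance explained > threshold (strict), the top-importance
    variable has %IncMSE >= the minimum, and its permutation p < alpha.
    """
    cfg = cfg or PipelineConfig()
    selected = None
    if fit.var_explained_pct > cfg.min_var_explained_pct and len(fit.importance):
        top = fit.importance.idxmax()
        if (
            fit.importance[top] >= cfg.min_inc_mse_pct
            and fit.importance_p[top] < cfg.importance_alpha
        ):
            selected = top
    return replace(fit, selected_variable=selected)


def module_z_profile(ztable: pd.DataFrame, part: ModulePartition) -> pd.DataFrame:
    """Per-sample mean Z-score over each module's member ASVs."""
    out = {}
    for module_id, members in part.modules.items():
        if not members:
            raise ValueError(f"module {module_id!r} is empty")
        missing = [m for m in members if m not in ztable.columns]
        if missing:
            raise ValueError(f"module {module_id!r} references ASVs absent "
                             f"from the Z table: {missing[:5]}")
        out[module_id] = ztable[members].mean(axis=1)
    return pd.DataFrame(out, index=ztable.index)


def classify_elevation_class(
    profile: pd.Series,
    meta: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    rho_threshold: float = 0.3,
    n_bins: int = 10,
) -> str:
    """Classify a module's gradient response as 'high', 'low', or 'mid'.

    rho_e is the Spearman correlation of the mean-Z profile with elevation;
    E* is the mean elevation of the highest-mean bin among ``n_bins``
    equal-count elevation bins.  'high' needs rho_e > +threshold and E*
    above the split; 'low' needs rho_e < -threshold and E* below it;
    anything else (e.g. a unimodal mid-gradient peak) is 'mid'.
    """
    cfg = cfg or PipelineConfig()
    elev = meta.loc[profile.index, "elevation"]
    if profile.size < 10:
        raise ValueError("need >= 10 samples to classify a gradient response")
    split = cfg.elevation_split_m
    if (elev > split).all() or (elev < split).all():
        raise ValueError("samples must span both sides of the elevation split")
    rho_e = correlation(profile.to_numpy(), elev.to_numpy(), method="spearman")
    bins = pd.qcut(elev, q=min(n_bins, elev.nunique()), duplicates="drop")
    binned = profile.groupby(bins, observed=True).mean()
    elev_binned = elev.groupby(bins, observed=True).mean()
    e_star = float(elev_binned[binned.idxmax()])
    if rho_e > rho_threshold and e_star > split:
        return "high"
    if rho_e < -rho_threshold and e_star < split:
        return "low"
    return "mid"


def infer_module_preferences(
    table: AsvTable,
    part: ModulePartition,
    env: pd.DataFrame,
    meta: pd.DataFrame,
    ztable: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> list[PreferenceResult]:
    """Full niche stage: presence -> forest -> selection -> elevation class.

    ``env`` holds the standardized predictors used by the forest; ``meta``
    supplies raw elevation for the gradient classification.  Modules whose
    selected predictor passes the acceptance rules get an elevation class;
    others keep ``elevation_class=None``.
    """
    cfg = cfg or PipelineConfig()
    presence = module_presence(table, part)
    profiles = module_z_profile(ztable, part)
    rng = np.random.default_rng(seed)
    results = []
    for module_id in part.modules:
        fit = fit_preference_forest(
            presence[module_id], env, cfg,
            seed=int(rng.integers(0, 2**31 - 1)), module_id=module_id,
        )
        fit = select_predictive_variable(fit, cfg)
        if fit.selected_variable is not None:
            fit = replace(
                fit,
                elevation_class=classify_elevation_class(
                    profiles[module_id], meta, cfg
                ),
            )
        results.append(fit)
    return results
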