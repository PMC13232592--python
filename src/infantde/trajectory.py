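"""Gene-module scoring and cell-type proportion dynamics over age.

The module score of a nucleus is the mean normalized expression of the
module genes minus that of expression-matched control genes: genes are
binned by mean expression and each module gene contributes ``n_ctrl``
controls drawn from its bin, so a random module scores zero in
expectation. Proportion dynamics compute per-individual cell-type
fractions within a denominator lineage and the infant-versus-adult
log2 fold change of the group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ModuleScoreResult",
    "ProportionTable",
    "score_module",
    "proportions_by_age",
    "fit_trend",
]

#: default log-age offset in years, admitting prenatal/0-year samples
AGE_LOG_OFFSET = 0.1


@dataclass
class ModuleScoreResult:
    module_name: str
    scores: np.ndarray            # per nucleus
    background_seed: int
    n_bins: int
    n_ctrl: int
    control_genes: dict           # module gene -> tuple of control genes
    group_summary: pd.DataFrame | None = None


@dataclass
class ProportionTable:
    """Per-individual cell-type fractions within a denominator lineage."""

    fractions: pd.DataFrame       # individual, age_group, cell_type, fraction
    group_means: pd.DataFrame     # age_group, cell_type, mean_fraction
    log2fc_infant_vs_adult: pd.DataFrame
    denominator: str


def _bin_by_mean(gene_means: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-occupancy bins; robust to ties/constant input."""
    order = np.argsort(gene_means, kind="stable")
    bins = np.empty(len(gene_means), dtype=int)
    bins[order] = np.minimum(
        (np.arange(len(gene_means)) * n_bins) // max(len(gene_means), 1),
        n_bins - 1,
    )
    return bins


def score_module(
    expression,
    gene_ids,
    module,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    module_name: str = "module",
) -> ModuleScoreResult:
    """Control-subtracted module score per nucleus.

    ``expression`` is nuclei x genes, already library-size normalized and
    log-transformed. Module genes missing from ``gene_ids`` raise; a bin
    holding fewer non-module genes than ``n_ctrl`` is sampled with
    replacement and warned about. Deterministic for a fixed seed.
    """
    X = np.asarray(expression, dtype=float)
    gene_ids = list(gene_ids)
    if X.ndim != 2 or X.shape[1] != len(gene_ids):
        raise ValueError("expression must be nuclei x genes matching gene_ids")
    index = {g: i for i, g in enumerate(gene_ids)}
    module = sorted(set(module))
    missing = [g for g in module if g not in index]
    if missing:
        raise ValueError(f"module genes not measured: {missing}")
    if not module:
        raise ValueError("empty module")

    rng = np.random.default_rng(seed)
    gene_means = X.mean(axis=0)
    bins = _bin_by_mean(gene_means, n_bins)
    module_idx = np.array([index[g] for g in module])
    in_module = np.zeros(len(gene_ids), bool)
    in_module[module_idx] = True

    ctrl_map: dict = {}
    ctrl_rows = []
    for gi in module_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_module & (np.arange(len(bins)) != gi))
        if len(pool) == 0:
            pool = np.flatnonzero(np.arange(len(bins)) != gi)
        if len(pool) < n_ctrl:
            warnings.warn(
                f"bin of gene {gene_ids[gi]} holds {len(pool)} candidate controls "
                f"< n_ctrl={n_ctrl}; sampling with replacement",
                stacklevel=2,
            )
            chosen = rng.choice(pool, size=n_ctrl, replace=True)
        else:
            chosen = rng.choice(pool, size=n_ctrl, replace=False)
        ctrl_map[gene_ids[gi]] = tuple(gene_ids[j] for j in chosen)
        ctrl_rows.append(chosen)
    ctrl_idx = np.concatenate(ctrl_rows)
    scores = X[:, module_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return ModuleScoreResult(
        module_name=module_name, scores=scores, background_seed=seed,
        n_bins=n_bins, n_ctrl=n_ctrl, control_genes=ctrl_map,
    )


def summarize_by_group(scores: np.ndarray, groups) -> pd.DataFrame:
    """Mean/sd/count of per-nucleus scores per group, in group order."""
    df = pd.DataFrame({"group": list(groups), "score": scores})
    out = (
        df.groupby("group", sort=False)["score"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def proportions_by_age(
    cell_labels: pd.DataFrame,
    denominator_lineage: str,
    lineage_of: dict,
    pseudo_fraction: float = 0.0,
    infant_group: str = "infant",
    adult_group: str = "adult",
) -> ProportionTable:
    """Per-individual cell-type fractions within a denominator lineage.

    ``cell_labels`` has one row per cell with individual, age_group and
    cell_type; ``lineage_of`` maps cell types to lineage tags and the
    denominator is the per-individual count of cells whose lineage is
    ``denominator_lineage``. Individuals without denominator cells are
    excluded with a warning. The infant-vs-adult log2FC per cell type
    uses group means, optionally floored by ``pseudo_fraction``.
    """
    need = {"individual", "age_group", "cell_type"}
    if not need <= set(cell_labels.columns):
        raise ValueError(f"cell_labels missing columns: {sorted(need - set(cell_labels.columns))}")
    df = cell_labels.copy()
    df["lineage"] = df["cell_type"].map(lineage_of)
    denom_cells = df[df["lineage"] == denominator_lineage]
    denom_n = denom_cells.groupby("individual").size()
    all_inds = df["individual"].unique()
    excluded = sorted(set(all_inds) - set(denom_n.index))
    if excluded:
        warnings.warn(
            f"excluding individuals with zero {denominator_lineage} cells: {excluded}",
            stacklevel=2,
        )

    counts = (
        denom_cells.groupby(["individual", "age_group", "cell_type"])
        .size().rename("n").reset_index()
    )
    counts["fraction"] = counts["n"] / counts["individual"].map(denom_n)
    # complete the grid so absent types count as 0 for each individual
    cts = sorted(denom_cells["cell_type"].unique())
    grid = (
        counts[["individual", "age_group"]].drop_duplicates()
        .merge(pd.DataFrame({"cell_type": cts}), how="cross")
    )
    fractions = grid.merge(counts, on=["individual", "age_group", "cell_type"], how="left")
    fractions["fraction"] = fractions["fraction"].fillna(0.0)
    fractions["n"] = fractions["n"].fillna(0).astype(int)

    group_means = (
        fractions.groupby(["age_group", "cell_type"])["fraction"]
        .mean().rename("mean_fraction").reset_index()
    )
    piv = group_means.pivot(index="cell_type", columns="age_group", values="mean_fraction")
    rows = []
    for ct in piv.index:
        mi = piv.get(infant_group, pd.Series(dtype=float)).get(ct, np.nan)
        ma = piv.get(adult_group, pd.Series(dtype=float)).get(ct, np.nan)
        mi_f = (mi if mi > 0 else pseudo_fraction) if np.isfinite(mi) else np.nan
        ma_f = (ma if ma > 0 else pseudo_fraction) if np.isfinite(ma) else np.nan
        lfc = (
            np.log2(mi_f / ma_f)
            if np.isfinite(mi_f) and np.isfinite(ma_f) and mi_f > 0 and ma_f > 0
            else np.nan
        )
        rows.append({"cell_type": ct, "infant_mean": mi, "adult_mean": ma, "log2fc": lfc})
    return ProportionTable(
        fractions=fractions,
        group_means=group_means,
        log2fc_infant_vs_adult=pd.DataFrame(rows),
        denominator=denominator_lineage,
    )


def fit_trend(
    x,
    y,
    method: str = "lowess",
    frac: float = 0.4,
    log_age: bool = True,
    age_offset: float = AGE_LOG_OFFSET,
    n_grid: int = 100,
):
    """Descriptive smoothed trend of scores or fractions over age.

    Default: lowess over log2(age + offset). ``method='group_means'``
    averages y at each distinct x instead. Returns (grid, fitted).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    xt = np.log2(x + age_offset) if log_age else x
    uniq = np.unique(xt)
    if len(uniq) == 1:
        warnings.warn("single age value: returning its mean", stacklevel=2)
        return uniq.copy(), np.array([y.mean()])
    if method == "group_means":
        grid = uniq
        fitted = np.array([y[xt == u].mean() for u in uniq])
        return grid, fitted
    if method != "lowess":
        raise ValueError(f"unknown method {method!r}")
    sm = lowess(y, xt, frac=frac, return_sorted=True)
    grid = np.linspace(uniq[0], uniq[-1], n_grid)
    fitted = np.interp(grid, sm[:, 0], sm[:, 1])
    return grid, fitted
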