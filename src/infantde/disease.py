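"""Intersection of evolutionary DE sets with disease genetics and patient DE.

Covers risk-gene overrepresentation grids (cell types x disease lists),
the gene-level join of evolutionary and patient log2 fold changes on a
cell-type/lineage-matched basis, the directionality contingency
(evolutionary gains by species versus patient up/down), and the
developmental module-score trajectory of a DE set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import DESet
from .stats import bh_fdr, chi_square_independence, combined_score, enrich
from .trajectory import score_module, summarize_by_group

__all__ = [
    "LineageMap",
    "risk_gene_overrepresentation",
    "patient_de_scatter",
    "directionality_contingency",
    "module_trajectory_table",
]


@dataclass
class LineageMap:
    """Explicit mapping from evolutionary cell types to disease labels.

    ``mapping`` maps each evolutionary-analysis cell type to the disease
    dataset labels it corresponds to (possibly many, possibly none);
    ``lineage_of`` tags cell types with lineage names (neural, OL, ...).
    Labels are matched exactly; nothing is inferred from string
    similarity.
    """

    mapping: dict
    lineage_of: dict = field(default_factory=dict)

    def labels_for(self, evo_cell_type: str) -> list:
        if evo_cell_type not in self.mapping:
            warnings.warn(f"unmapped evolutionary cell type: {evo_cell_type!r}",
                          stacklevel=2)
            return []
        return list(self.mapping[evo_cell_type])

    def labels_for_lineage(self, lineage: str) -> set:
        labels: set = set()
        for ct, lin in self.lineage_of.items():
            if lin == lineage:
                labels.update(self.mapping.get(ct, []))
        return labels


def load_patient_de(table: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Validate and significance-filter a patient DE table.

    Requires columns gene, disease, cell_type, direction, log2fc, fdr;
    checks direction/sign consistency and (gene, disease, cell_type)
    uniqueness, then keeps rows with fdr below the threshold (patient
    significance is taken as given, not re-derived).
    """
    need = {"gene", "disease", "cell_type", "direction", "log2fc", "fdr"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"patient DE table missing columns: {sorted(missing)}")
    bad_dir = ~(
        ((table["direction"] == "up") & (table["log2fc"] > 0))
        | ((table["direction"] == "down") & (table["log2fc"] < 0))
    )
    if bad_dir.any():
        raise ValueError(
            f"{int(bad_dir.sum())} rows have direction inconsistent with log2fc sign"
        )
    key = table[["gene", "disease", "cell_type"]]
    if key.duplicated().any():
        raise ValueError("duplicate (gene, disease, cell_type) rows in patient DE table")
    return table[table["fdr"] < fdr_threshold].reset_index(drop=True)


def risk_gene_overrepresentation(
    desets,
    risk_lists: dict,
    universe_by_celltype: dict,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation grid of risk lists in DE sets.

    One row per (cell type, direction, disease list): overlap, odds
    ratio, upper-tail p, combined score, and BH-FDR applied across the
    whole grid within each direction. Risk genes absent from a cell
    type's universe are excluded from the list size with a logged count.
    """
    rows = []
    for ds in desets:
        universe = set(universe_by_celltype[ds.cell_type])
        if not set(ds.genes) <= universe:
            raise ValueError(
                f"DE set for {ds.cell_type} contains genes outside its universe"
            )
        for name in sorted(risk_lists):
            risk = set(risk_lists[name])
            n_out = len(risk - universe)
            res = enrich(ds.genes, risk, universe, name=name)
            rows.append(
                {"cell_type": ds.cell_type, "direction": ds.direction,
                 "disease_list": name, "k": res.k, "list_size": res.K,
                 "deset_size": res.n, "universe": res.N,
                 "risk_genes_outside_universe": n_out,
                 "odds_ratio": res.odds_ratio, "p": res.p,
                 "combined_score": res.combined_score}
            )
    grid = pd.DataFrame(rows)
    if grid.empty:
        return grid
    grid["fdr"] = np.nan
    for direction, idx in grid.groupby("direction").groups.items():
        grid.loc[idx, "fdr"] = bh_fdr(grid.loc[idx, "p"].to_numpy())
    return grid


def patient_de_scatter(
    evo_calls: pd.DataFrame,
    patient_table: pd.DataFrame,
    lineage_map: LineageMap,
) -> pd.DataFrame:
    """Join evolutionary and patient log2FCs gene-by-gene.

    ``evo_calls`` rows carry gene, cell_type, species_a, log2fc (one row
    per gene per evolutionary cell type); each evolutionary cell type is
    joined against the patient rows of its mapped disease labels. One
    output row per (gene, evolutionary cell type, matched label).
    """
    unmapped = sorted(
        set(patient_table["cell_type"])
        - {lab for labs in lineage_map.mapping.values() for lab in labs}
    )
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} patient labels map to no evolutionary cell type: "
            f"{unmapped[:10]}",
            stacklevel=2,
        )
    out = []
    for ct, sub in evo_calls.groupby("cell_type"):
        for label in lineage_map.labels_for(ct):
            pt = patient_table[patient_table["cell_type"] == label]
            merged = sub.merge(pt, on="gene", suffixes=("_evo", "_disease"))
            for _, row in merged.iterrows():
                out.append(
                    {"gene": row["gene"], "evo_cell_type": ct,
                     "disease_label": label, "disease": row["disease"],
                     "species": row["species_a"],
                     "evo_log2fc": row["log2fc_evo"],
                     "disease_log2fc": row["log2fc_disease"],
                     "disease_direction": row["direction"]}
                )
    return pd.DataFrame(
        out, columns=["gene", "evo_cell_type", "disease_label", "disease",
                      "species", "evo_log2fc", "disease_log2fc",
                      "disease_direction"],
    )


def directionality_contingency(
    matched_table: pd.DataFrame,
    focal_species: str,
    comparison_species,
    include_losses: bool = False,
) -> dict:
    """Per-cell-type chi-square of species category versus disease direction.

    ``matched_table`` comes from `patient_de_scatter` run on the focal
    and comparison species' gain (and optionally loss) calls; rows are
    species categories (focal gain, comparison gain, optionally losses),
    columns patient up/down. Cell types whose table degenerates to fewer
    than 2 non-empty rows or columns are dropped with a warning; the
    returned dict maps cell type to a Chi2Result and lists the drops
    under ``"dropped"``.
    """
    comparison_species = (
        [comparison_species] if isinstance(comparison_species, str)
        else list(comparison_species)
    )
    df = matched_table.copy()
    direction = np.where(df["evo_log2fc"] > 0, "gain", "loss")
    if not include_losses:
        df = df[direction == "gain"]
        direction = np.full(len(df), "gain")
    df = df.assign(
        category=[f"{sp}_{d}" for sp, d in zip(df["species"], direction)]
    )
    results: dict = {"dropped": []}
    for ct, sub in df.groupby("evo_cell_type"):
        table = pd.crosstab(sub["category"], sub["disease_direction"])
        table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
        if table.shape[0] < 2 or table.shape[1] < 2:
            warnings.warn(f"cell type {ct} dropped: degenerate contingency",
                          stacklevel=2)
            results["dropped"].append(ct)
            continue
        results[ct] = chi_square_independence(
            table.to_numpy(), row_labels=list(table.index),
            col_labels=list(table.columns),
        )
    return results


def module_trajectory_table(
    deset,
    expression,
    gene_ids,
    age_groups,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
):
    """Developmental trajectory of a DE-set module score.

    Scores the module and a size-matched randomized background module
    (seeded from ``seed``) per nucleus, and summarizes both per age
    group. Returns (per-nucleus frame, per-age-group summary frame).
    """
    genes = sorted(deset.genes if isinstance(deset, DESet) else deset)
    measured = set(gene_ids)
    module = [g for g in genes if g in measured]
    if not module:
        raise ValueError("no module gene is measured in the expression matrix")
    res = score_module(expression, gene_ids, module, n_bins=n_bins,
                       n_ctrl=n_ctrl, seed=seed, module_name="module")
    rng = np.random.default_rng(seed + 1)
    pool = sorted(measured - set(module))
    background = list(rng.choice(pool, size=min(len(module), len(pool)), replace=False))
    bg = score_module(expression, gene_ids, background, n_bins=n_bins,
                      n_ctrl=n_ctrl, seed=seed + 1, module_name="background")
    per_nucleus = pd.DataFrame(
        {"age_group": list(age_groups), "module_score": res.scores,
         "background_score": bg.scores}
    )
    summ_m = summarize_by_group(res.scores, age_groups).assign(module="module")
    summ_b = summarize_by_group(bg.scores, age_groups).assign(module="background")
    summary = pd.concat([summ_m, summ_b], ignore_index=True)
    res.group_summary = summary
    return per_nucleus, summary
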