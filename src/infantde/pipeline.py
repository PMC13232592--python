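"""Stage orchestration: simulate -> de -> sets -> enrich -> intersect ->
hidecore -> score, with a machine-readable run log.

Each stage writes its outputs under the configured output directory and
records parameters, seeds and file checksums; a rerun with an identical
configuration reproduces identical outputs. The stage functions are
plain library calls so tests and scripts can reuse them without the
filesystem side effects.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iomod
from .config import PipelineConfig
from .de import Contrast, PseudobulkDE
from .disease import (
    LineageMap,
    directionality_contingency,
    load_patient_de,
    module_trajectory_table,
    patient_de_scatter,
    risk_gene_overrepresentation,
)
from .network import (
    annotate_disease,
    annotate_regions,
    build_hidecore,
    capture_concordance,
    lineage_disease_enrichment,
    lineage_overlap_stats,
    per_tf_disease_proportions,
    region_coords,
)
from .sets import age_specific_sets, species_specific_de, upset_counts
from .simulate import SimConfig, simulate_bundle, simulate_development, \
    write_fixture_bundle

__all__ = [
    "compute_de_calls",
    "build_divergence_sets",
    "build_core_networks",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

AGE_GROUPS = ("infant", "adult")


def compute_de_calls(matrix, focal_species, comparison_species, cell_types,
                     mu_floor: float = 0.5) -> dict:
    """NB Wald calls for every (focal, other, age, cell type) contrast.

    Returns a dict keyed (focal, other, age_group, cell_type) holding the
    per-gene call frames for ``focal_species`` against each comparison
    species, in infants and adults separately.
    """
    calls = {}
    for ct in cell_types:
        sub = matrix.for_cell_type(ct)
        for other in comparison_species:
            for age in AGE_GROUPS:
                model = PseudobulkDE(sub, Contrast(focal_species, other, age),
                                     cell_type=ct, mu_floor=mu_floor)
                calls[(focal_species, other, age, ct)] = model.fit().frame
    return calls


def build_divergence_sets(calls: dict, focal: str, others, cell_types,
                          lfc_threshold=0.5, fdr_threshold=0.05,
                          mode="both_contrasts"):
    """Species-specific sets per age, then the infant-specific split."""
    b, c = others
    per_age = {}
    for age in AGE_GROUPS:
        sets = {}
        for ct in cell_types:
            gain, loss = species_specific_de(
                calls[(focal, b, age, ct)], calls[(focal, c, age, ct)],
                lfc_threshold, fdr_threshold, mode=mode,
            )
            sets[(ct, "gain")], sets[(ct, "loss")] = gain, loss
        per_age[age] = sets
    split = age_specific_sets(per_age["infant"], per_age["adult"])
    return {"per_age": per_age, "split": split,
            "infant_specific": split.infant_specific}


def build_core_networks(regulons, annotations, infant_specific_sets,
                        cell_type_lineages: dict, universe=None):
    """Annotate regions and filter regulon edges per lineage.

    ``infant_specific_sets`` maps (cell_type, direction) to DESets (the
    infant-specific split); a lineage's gain set is the union over its
    cell types.
    """
    regions = {}
    for e in regulons:
        if e.region not in regions:
            regions[e.region] = region_coords(e.region)
    region_ann = annotate_regions(regions, annotations)
    gains = {}
    for ct, lin in cell_type_lineages.items():
        s = infant_specific_sets.get((ct, "gain"))
        if s is not None:
            gains.setdefault(lin, set()).update(s.genes)
    nets = build_hidecore(regulons, gains, region_ann, universe=universe)
    return nets, region_ann


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sets_frame(sets: dict, label: str) -> pd.DataFrame:
    rows = []
    for (ct, direction), ds in sorted(sets.items()):
        for g in sorted(ds.genes):
            rows.append({"set": label, "cell_type": ct, "direction": direction,
                         "gene": g})
    return pd.DataFrame(rows, columns=["set", "cell_type", "direction", "gene"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic bundle; return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.out
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    # --- simulate ---------------------------------------------------------
    sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
    bundle = simulate_bundle(sim_cfg)
    bundle_dir = out / "bundle"
    bundle_manifest = write_fixture_bundle(bundle, bundle_dir)
    manifest["stages"]["simulate"] = {
        "out": str(bundle_dir), "files": bundle_manifest["files"],
        "seed": sim_cfg.seed,
    }

    cell_types = [ct for ct, _ in sim_cfg.cell_types]
    lineage_of = dict(sim_cfg.cell_types)
    focal, chimp = sim_cfg.focal, sim_cfg.chimp
    rhesus = sim_cfg.species[2]

    # --- de ---------------------------------------------------------------
    calls_h = compute_de_calls(bundle.matrix, focal, (chimp, rhesus), cell_types,
                               mu_floor=config.mu_floor)
    calls_c = compute_de_calls(bundle.matrix, chimp, (focal, rhesus), cell_types,
                               mu_floor=config.mu_floor)
    de_path = out / "de_calls.tsv"
    iomod.write_tsv(pd.concat(list(calls_h.values()) + list(calls_c.values()),
                              ignore_index=True), de_path)
    manifest["stages"]["de"] = {"out": str(de_path), "checksum": _checksum(de_path),
                                "n_contrasts": len(calls_h) + len(calls_c)}

    # --- sets -------------------------------------------------------------
    hres = build_divergence_sets(calls_h, focal, (chimp, rhesus), cell_types,
                                 config.lfc_threshold, config.fdr_threshold,
                                 config.set_logic_mode)
    cres = build_divergence_sets(calls_c, chimp, (focal, rhesus), cell_types,
                                 config.lfc_threshold, config.fdr_threshold,
                                 config.set_logic_mode)
    hide, cide = hres["infant_specific"], cres["infant_specific"]
    sets_path = out / "divergence_sets.tsv"
    iomod.write_tsv(pd.concat([_sets_frame(hide, "hiDE"), _sets_frame(cide, "ciDE")],
                              ignore_index=True), sets_path)
    upset = upset_counts({ct: hide[(ct, "gain")] for ct in cell_types})
    upset["pattern"] = upset["pattern"].map(lambda p: "+".join(p))
    upset_path = out / "upset_gains.tsv"
    iomod.write_tsv(upset, upset_path)
    manifest["stages"]["sets"] = {
        "out": str(sets_path), "checksum": _checksum(sets_path),
        "upset": str(upset_path),
        "hiDE_sizes": {f"{ct}|{d}": len(s) for (ct, d), s in sorted(hide.items())},
    }

    # --- enrich -----------------------------------------------------------
    universe = {ct: set(bundle.matrix.gene_ids) for ct in cell_types}
    grid = risk_gene_overrepresentation(
        [hide[(ct, "gain")] for ct in cell_types] +
        [hide[(ct, "loss")] for ct in cell_types],
        bundle.risk_lists, universe,
    )
    enrich_path = out / "risk_enrichment.tsv"
    iomod.write_tsv(grid, enrich_path)
    manifest["stages"]["enrich"] = {
        "out": str(enrich_path), "checksum": _checksum(enrich_path),
        "fdr_scope": "BH across (cell type x disease list) grid per direction",
    }

    # --- intersect --------------------------------------------------------
    lineage_map = LineageMap(
        mapping={ct: [bundle.truth.patient_labels[lineage_of[ct]]]
                 for ct in cell_types},
        lineage_of=lineage_of,
    )
    patient = load_patient_de(bundle.patient_de, config.patient_fdr_threshold)
    evo_rows = []
    for ct in cell_types:
        for sp, res in ((focal, hres), (chimp, cres)):
            gains = res["infant_specific"][(ct, "gain")].genes
            calls = (calls_h if sp == focal else calls_c)[(sp, rhesus, "infant", ct)]
            sub = calls[calls["gene"].isin(gains)]
            evo_rows.append(sub[["gene", "cell_type", "species_a", "log2fc"]])
    evo_calls = pd.concat(evo_rows, ignore_index=True)
    matched = patient_de_scatter(evo_calls, patient, lineage_map)
    matched_path = out / "patient_matched.tsv"
    iomod.write_tsv(matched, matched_path)
    contingency = directionality_contingency(
        matched, focal, [chimp], include_losses=config.contingency_include_losses
    )
    cont_rows = []
    for ct, res in contingency.items():
        if ct == "dropped":
            continue
        for i, rlab in enumerate(res.row_labels):
            for j, clab in enumerate(res.col_labels):
                cont_rows.append(
                    {"cell_type": ct, "category": rlab, "disease_direction": clab,
                     "observed": res.observed[i, j],
                     "pearson_residual": res.pearson_residuals[i, j],
                     "chi2": res.chi2, "p": res.p}
                )
    cont_path = out / "directionality_contingency.tsv"
    iomod.write_tsv(pd.DataFrame(cont_rows), cont_path)
    manifest["stages"]["intersect"] = {
        "out": str(matched_path), "checksum": _checksum(matched_path),
        "contingency": str(cont_path),
        "dropped_cell_types": contingency.get("dropped", []),
    }

    # --- hidecore ---------------------------------------------------------
    nets, _region_ann = build_core_networks(
        bundle.regulons, bundle.annotations, hide, lineage_of,
        universe=set(bundle.matrix.gene_ids),
    )
    for net in nets.values():
        annotate_disease(net, patient, lineage_map)
    net_stats: dict = {"provenance": {lin: n.provenance for lin, n in nets.items()}}
    lineages = sorted(nets)
    if len(lineages) == 2:
        a, b = (nets[lin] for lin in lineages)
        net_stats["overlap"] = lineage_overlap_stats(a, b, bundle.matrix.gene_ids)
        for disease in ("ASD", "PD"):
            for tfs_only in (False, True):
                key = f"{disease}_{'tfs' if tfs_only else 'genes'}"
                fe = lineage_disease_enrichment(a, b, disease, tfs_only=tfs_only)
                net_stats[key] = {
                    "table": fe["table"].as_array().tolist(),
                    "odds_ratio": fe["odds_ratio"],
                    "p_two_sided": fe["p_two_sided"],
                    "p_greater": fe["p_greater"],
                }
    for lin, net in nets.items():
        iomod.write_network(net, out / f"hidecore_{lin}.json")
        tf_table = per_tf_disease_proportions(net)
        iomod.write_tsv(tf_table, out / f"hidecore_{lin}_tfs.tsv")
        try:
            net_stats[f"capture_{lin}"] = capture_concordance(
                net, bundle.capture_pairs, tested_regions=bundle.truth.capture_tested
            )
        except ValueError:
            net_stats[f"capture_{lin}"] = None
    stats_path = out / "hidecore_stats.json"
    with open(stats_path, "w", encoding="utf-8") as fh:
        json.dump(net_stats, fh, indent=1, sort_keys=True, default=str)
    manifest["stages"]["hidecore"] = {
        "out": str(stats_path), "checksum": _checksum(stats_path),
        "lineages": lineages,
    }

    # --- score ------------------------------------------------------------
    neural_cts = [ct for ct, lin in sim_cfg.cell_types if lin == "neural"]
    module = sorted(set().union(*(hide[(ct, "gain")].genes for ct in neural_cts))) \
        if neural_cts else []
    module = [g for g in module if g in set(f"G{i:05d}" for i in range(2000))][:50]
    if module:
        X, gene_ids, ages = simulate_development(sim_cfg, module)
        per_nucleus, summary = module_trajectory_table(
            set(module), X, gene_ids, ages,
            n_bins=config.module_n_bins, n_ctrl=config.module_n_ctrl,
            seed=config.seed,
        )
        traj_path = out / "module_trajectory.tsv"
        iomod.write_tsv(summary, traj_path)
        manifest["stages"]["score"] = {"out": str(traj_path),
                                       "checksum": _checksum(traj_path),
                                       "module_size": len(module)}
    else:
        manifest["stages"]["score"] = {"out": None, "module_size": 0}

    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
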