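"""Synthetic data with planted ground truth for the full pipeline.

The generator emulates every statistical structure the downstream stages
assume: negative-binomial pseudobulk counts for three species x two age
groups x several cell types with planted species- and age-specific log2
fold changes, a regulon table whose edges pass or fail each core-network
retention rule by design, interval annotations overlapping a known
subset of regions, patient DE tables and risk-gene lists with controlled
overlap with the planted expression gains, and capture pairs with a
planted concordance. Counts are simulated directly at the pseudobulk
level (individual x cell type) under the same NB2 model the DE engine
fits (variance = mean + dispersion * mean^2); a thin multinomial
cell-splitter exists only to exercise aggregation.

All randomness flows from ``SimConfig.seed`` through named child
streams, so every artifact is reproducible bit-for-bit and adding
samples does not perturb existing ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ANNOTATION_CLASSES, AnnotatedInterval, RegulonEdge
from .de import PseudobulkMatrix

__all__ = [
    "ConfigError",
    "SimConfig",
    "GroundTruth",
    "Bundle",
    "generate_truth",
    "simulate_counts",
    "simulate_cells",
    "simulate_regulons",
    "simulate_annotations",
    "simulate_disease_tables",
    "simulate_capture_pairs",
    "simulate_risk_lists",
    "simulate_development",
    "simulate_bundle",
    "write_fixture_bundle",
    "read_fixture_bundle",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


# child-stream tags: one independent generator per artifact
_STREAM = {
    "truth": 1, "size_factors": 2, "counts": 3, "extra_counts": 4,
    "cells": 5, "regulons": 6, "disease": 7, "risk": 8, "capture": 9,
    "development": 10,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults are the conditions the pipeline is validated under: 3
    species x 2 age groups x 4 cell types (two neural, two OL lineage),
    10 individuals per species per age, 2000 genes, planted effects of
    |log2FC| = 1 against a calling threshold of 0.5.
    """

    n_genes: int = 2000
    n_individuals_per_species_per_age: int = 10
    cell_types: tuple = (
        ("L2_3", "neural"), ("InhN", "neural"), ("OPC", "OL"), ("COP", "OL"),
    )
    species: tuple = ("human", "chimp", "rhesus")
    effect_size_lfc: float = 1.0
    dispersion_range: tuple = (0.01, 0.1)
    fraction_hiDE: float = 0.1
    fraction_shared_adult: float = 0.05
    fraction_adult_only: float = 0.05
    baseline_mean_range: tuple = (10.0, 1000.0)
    size_factor_sigma: float = 0.2
    n_core_genes: int = 40
    core_edge_fraction: float = 0.8
    n_tfs_per_lineage: int = 6
    n_pass_edges_per_lineage: int = 30
    n_fail_edges_per_rule: int = 5
    n_background_edges_per_lineage: int = 40
    capture_concordance: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigError("n_genes must be >= 10")
        if self.n_individuals_per_species_per_age < 2:
            raise ConfigError("n_individuals_per_species_per_age must be >= 2")
        if not self.cell_types:
            raise ConfigError("cell_types must be non-empty")
        for item in self.cell_types:
            if len(item) != 2:
                raise ConfigError("cell_types entries must be (name, lineage) pairs")
        if len(self.species) < 3:
            raise ConfigError("species must list the focal and two comparison species")
        if self.effect_size_lfc <= 0:
            raise ConfigError("effect_size_lfc must be > 0")
        lo, hi = self.dispersion_range
        if not (0 < lo <= hi):
            raise ConfigError("dispersion_range must be positive with lo <= hi")
        if not 0 <= self.fraction_hiDE < 0.5:
            raise ConfigError("fraction_hiDE must lie in [0, 0.5)")
        if not 0 <= self.capture_concordance <= 1:
            raise ConfigError("capture_concordance must lie in [0, 1]")
        if not 0 <= self.core_edge_fraction <= 1:
            raise ConfigError("core_edge_fraction must lie in [0, 1]")
        if self.n_core_genes < 0:
            raise ConfigError("n_core_genes must be >= 0")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ConfigError("baseline_mean_range must be positive with lo <= hi")

    @property
    def focal(self) -> str:
        return self.species[0]

    @property
    def chimp(self) -> str:
        return self.species[1]

    @property
    def lineages(self) -> tuple:
        seen = []
        for _, lin in self.cell_types:
            if lin not in seen:
                seen.append(lin)
        return tuple(seen)

    def rng(self, stream: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream], extra])


@dataclass
class GroundTruth:
    """Planted structure the downstream stages must recover."""

    genes: list
    baseline_means: dict
    dispersions: dict
    planted_hiDE: dict          # (cell_type, direction) -> frozenset
    planted_ciDE: dict
    shared_adult_DE: dict
    adult_only_DE: dict
    planted_lfc: dict           # (gene, species, age_group, cell_type) -> float
    regulon_edges: list         # list of RegulonEdge
    edge_ids: list              # parallel to regulon_edges
    regulon_truth: dict         # edge id -> {rule: bool, ..., "pass": bool}
    regions: dict               # region id -> (chrom, start, end)
    annotation_truth: dict      # region id -> frozenset of classes
    disease_truth: dict         # (gene, lineage, disease) -> "up" | "down"
    patient_labels: dict        # lineage -> patient dataset label
    risk_truth: dict            # disease -> frozenset of genes
    capture_tested: frozenset   # region ids baited in the capture assay
    capture_pairs: frozenset    # (region, gene) pairs observed
    core_genes: frozenset = frozenset()  # gains planted in both lineages
    seed: int = 0

    def hide_gains_by_lineage(self, config: SimConfig) -> dict:
        out = {}
        for lin in config.lineages:
            cts = [ct for ct, l in config.cell_types if l == lin]
            out[lin] = frozenset().union(
                *(self.planted_hiDE.get((ct, "gain"), frozenset()) for ct in cts)
            )
        return out


def _draw_sets(rng, genes, fraction):
    """Split a Bernoulli draw over genes into gain/loss halves."""
    hit = np.asarray(genes)[rng.random(len(genes)) < fraction]
    gain_mask = rng.random(len(hit)) < 0.5
    return frozenset(hit[gain_mask]), frozenset(hit[~gain_mask])


def generate_truth(config: SimConfig) -> GroundTruth:
    """Draw the planted ground truth for a configuration (deterministic)."""
    rng = config.rng("truth")
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    garr = np.array(genes)
    lo, hi = config.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_genes))
    dlo, dhi = config.dispersion_range
    disp = np.exp(rng.uniform(np.log(dlo), np.log(dhi), config.n_genes))

    focal, chimp = config.focal, config.chimp
    eff = config.effect_size_lfc
    planted_hiDE, planted_ciDE = {}, {}
    shared_adult, adult_only = {}, {}
    lfc: dict = {}

    for ct, _lin in config.cell_types:
        h_gain, h_loss = _draw_sets(rng, garr, config.fraction_hiDE)
        taken = h_gain | h_loss
        rest = garr[~np.isin(garr, sorted(taken))]
        c_gain, c_loss = _draw_sets(rng, rest, config.fraction_hiDE)
        taken |= c_gain | c_loss
        rest = garr[~np.isin(garr, sorted(taken))]
        s_gain, s_loss = _draw_sets(rng, rest, config.fraction_shared_adult)
        taken |= s_gain | s_loss
        rest = garr[~np.isin(garr, sorted(taken))]
        a_gain, a_loss = _draw_sets(rng, rest, config.fraction_adult_only)

        planted_hiDE[(ct, "gain")], planted_hiDE[(ct, "loss")] = h_gain, h_loss
        planted_ciDE[(ct, "gain")], planted_ciDE[(ct, "loss")] = c_gain, c_loss
        shared_adult[(ct, "gain")], shared_adult[(ct, "loss")] = s_gain, s_loss
        adult_only[(ct, "gain")], adult_only[(ct, "loss")] = a_gain, a_loss

        for g in h_gain:
            lfc[(g, focal, "infant", ct)] = eff
        for g in h_loss:
            lfc[(g, focal, "infant", ct)] = -eff
        for g in c_gain:
            lfc[(g, chimp, "infant", ct)] = eff
        for g in c_loss:
            lfc[(g, chimp, "infant", ct)] = -eff
        for g in s_gain:
            lfc[(g, focal, "infant", ct)] = eff
            lfc[(g, focal, "adult", ct)] = eff
        for g in s_loss:
            lfc[(g, focal, "infant", ct)] = -eff
            lfc[(g, focal, "adult", ct)] = -eff
        for g in a_gain:
            lfc[(g, focal, "adult", ct)] = eff
        for g in a_loss:
            lfc[(g, focal, "adult", ct)] = -eff

    # a lineage-shared core: genes planted as gains in one cell type of
    # every lineage, emulating the lack of lineage specificity the core
    # network displays; drawn from genes free of any per-cell-type role
    core: frozenset = frozenset()
    if config.fraction_hiDE > 0 and config.n_core_genes > 0:
        used = set()
        for d in (planted_hiDE, planted_ciDE, shared_adult, adult_only):
            for s in d.values():
                used |= s
        free = garr[~np.isin(garr, sorted(used))]
        if len(free) < config.n_core_genes:
            raise ConfigError("n_core_genes too large for n_genes at these fractions")
        core = frozenset(rng.choice(free, size=config.n_core_genes, replace=False))
        first_ct_of = {}
        for ct, lin in config.cell_types:
            first_ct_of.setdefault(lin, ct)
        for lin, ct in first_ct_of.items():
            planted_hiDE[(ct, "gain")] = planted_hiDE[(ct, "gain")] | core
            for g in core:
                lfc[(g, focal, "infant", ct)] = eff

    truth = GroundTruth(
        genes=genes,
        baseline_means=dict(zip(genes, baseline.tolist())),
        dispersions=dict(zip(genes, disp.tolist())),
        planted_hiDE=planted_hiDE,
        planted_ciDE=planted_ciDE,
        shared_adult_DE=shared_adult,
        adult_only_DE=adult_only,
        planted_lfc=lfc,
        regulon_edges=[], edge_ids=[], regulon_truth={}, regions={},
        annotation_truth={}, disease_truth={}, patient_labels={},
        risk_truth={}, capture_tested=frozenset(), capture_pairs=frozenset(),
        core_genes=core, seed=config.seed,
    )
    _design_regulons(truth, config)
    _design_disease(truth, config)
    _design_capture(truth, config)
    return truth


def _design_regulons(truth: GroundTruth, config: SimConfig) -> None:
    """Plant regulon edges so every retention rule has designed passes/fails."""
    rng = config.rng("regulons")
    gains = truth.hide_gains_by_lineage(config)
    garr = np.array(truth.genes)
    region_counter = 0
    pos = lambda n: rng.uniform(0.2, 1.0, n)  # noqa: E731

    def new_region(annotated: bool):
        nonlocal region_counter
        start = 1000 * region_counter
        rid = f"chrS:{start}-{start + 500}"
        truth.regions[rid] = ("chrS", start, start + 500)
        if annotated:
            n_cls = rng.integers(1, 3)
            cls = frozenset(rng.choice(ANNOTATION_CLASSES, size=n_cls, replace=False))
        else:
            cls = frozenset()
        truth.annotation_truth[rid] = cls
        region_counter += 1
        return rid

    def add_edge(lineage, tf, target, tf2g, r2g, role, annotated):
        eid = f"E{len(truth.edge_ids):05d}"
        rid = new_region(annotated)
        tf, target = str(tf), str(target)
        edge = RegulonEdge(tf=tf, region=rid, target=target,
                           tf2g_score=float(tf2g), r2g_score=float(r2g),
                           role=role, cell_context=lineage)
        rules = {
            "node": tf in gains[lineage] and target in gains[lineage],
            "i": bool(truth.annotation_truth[rid]),
            "ii": edge.tf2g_score > 0,
            "iii": edge.r2g_score > 0,
            "role": role == "activator",
        }
        rules["pass"] = all(rules.values())
        truth.regulon_edges.append(edge)
        truth.edge_ids.append(eid)
        truth.regulon_truth[eid] = rules

    core = np.array(sorted(truth.core_genes))
    shared_tfs = (
        rng.choice(core, size=min(config.n_tfs_per_lineage, len(core)), replace=False)
        if len(core) else np.array([])
    )
    n_designed = (config.n_pass_edges_per_lineage
                  + 5 * config.n_fail_edges_per_rule
                  + config.n_background_edges_per_lineage)
    if n_designed == 0:
        return
    for lin in config.lineages:
        pool = np.array(sorted(gains[lin]))
        if len(pool) < config.n_tfs_per_lineage + 2:
            raise ConfigError(
                f"fraction_hiDE too small: lineage {lin} has only {len(pool)} "
                "planted gains, not enough for regulon design"
            )
        # TFs are the lineage-shared core regulators; targets come mostly
        # from the core with a lineage-private minority
        tfs = shared_tfs if len(shared_tfs) else rng.choice(
            pool, size=config.n_tfs_per_lineage, replace=False
        )
        core_targets = np.array(sorted((set(core) & set(pool)) - set(tfs)))
        private = np.array(sorted(set(pool) - set(core) - set(tfs)))
        targets = core_targets if len(core_targets) else private
        non_gains = garr[~np.isin(garr, pool)]

        for i in range(config.n_pass_edges_per_lineage):
            use_core = len(core_targets) and (
                rng.random() < config.core_edge_fraction or not len(private)
            )
            tgt = rng.choice(core_targets if use_core else private)
            add_edge(lin, tfs[i % len(tfs)], tgt,
                     pos(1)[0], pos(1)[0], "activator", True)
        for _ in range(config.n_fail_edges_per_rule):   # fail node only
            add_edge(lin, rng.choice(tfs), rng.choice(non_gains),
                     pos(1)[0], pos(1)[0], "activator", True)
        for _ in range(config.n_fail_edges_per_rule):   # fail rule i only
            add_edge(lin, rng.choice(tfs), rng.choice(targets),
                     pos(1)[0], pos(1)[0], "activator", False)
        for _ in range(config.n_fail_edges_per_rule):   # fail rule ii only
            add_edge(lin, rng.choice(tfs), rng.choice(targets),
                     -pos(1)[0], pos(1)[0], "activator", True)
        for _ in range(config.n_fail_edges_per_rule):   # fail rule iii only
            add_edge(lin, rng.choice(tfs), rng.choice(targets),
                     pos(1)[0], -pos(1)[0], "activator", True)
        for _ in range(config.n_fail_edges_per_rule):   # fail role only
            add_edge(lin, rng.choice(tfs), rng.choice(targets),
                     pos(1)[0], pos(1)[0], "repressor", True)
        # background edges: random genes/scores/roles, ~50% annotated
        for _ in range(config.n_background_edges_per_lineage):
            add_edge(
                lin, rng.choice(garr), rng.choice(garr),
                rng.uniform(-1, 1), rng.uniform(-1, 1),
                "activator" if rng.random() < 0.7 else "repressor",
                bool(rng.random() < 0.5),
            )


def _design_disease(truth: GroundTruth, config: SimConfig) -> None:
    """Plant patient deregulation and risk lists around the expression gains."""
    rng = config.rng("disease")
    truth.patient_labels = {lin: f"{lin}_patient" for lin in config.lineages}
    gains = truth.hide_gains_by_lineage(config)
    cgains = {
        lin: frozenset().union(
            *(truth.planted_ciDE.get((ct, "gain"), frozenset())
              for ct, l in config.cell_types if l == lin)
        )
        for lin in config.lineages
    }
    core = {
        lin: frozenset(
            g for e, eid in zip(truth.regulon_edges, truth.edge_ids)
            if e.cell_context == lin and truth.regulon_truth[eid]["pass"]
            for g in (e.tf, e.target)
        )
        for lin in config.lineages
    }
    # hit rates: network genes carry a strong lineage-matched disease
    # signal (ASD in OL, PD in neural); non-network gains carry a weaker
    # one with a planted down-excess for focal gains; background is flat.
    rates = {"OL": {"ASD": 0.5, "PD": 0.1}, "neural": {"ASD": 0.08, "PD": 0.5}}
    for lin in config.lineages:
        lin_rates = rates.get(lin, {"ASD": 0.1, "PD": 0.1})
        for g in truth.genes:
            for disease in ("ASD", "PD"):
                if g in core[lin]:
                    p_hit, p_down = lin_rates[disease], 0.6
                elif g in gains[lin]:
                    p_hit, p_down = 0.15, 0.7
                elif g in cgains[lin]:
                    p_hit, p_down = 0.15, 0.5
                else:
                    p_hit, p_down = 0.05, 0.5
                if rng.random() < p_hit:
                    direction = "down" if rng.random() < p_down else "up"
                    truth.disease_truth[(g, lin, disease)] = direction

    rng_r = config.rng("risk")
    ol_gains = set().union(*(gains[l] for l in config.lineages if l == "OL")) \
        if "OL" in config.lineages else set()
    neural_gains = set().union(*(gains[l] for l in config.lineages if l == "neural")) \
        if "neural" in config.lineages else set()
    risk = {}
    for disease, enriched in (("ASD", ol_gains), ("PD", neural_gains)):
        members = [
            g for g in truth.genes
            if rng_r.random() < (0.3 if g in enriched else 0.1)
        ]
        risk[disease] = frozenset(members)
    truth.risk_truth = risk


def _design_capture(truth: GroundTruth, config: SimConfig) -> None:
    """Bait the annotated pass-edge regions; plant edge-level concordance."""
    rng = config.rng("capture")
    tested, pairs = set(), set()
    for e, eid in zip(truth.regulon_edges, truth.edge_ids):
        if truth.regulon_truth[eid]["pass"]:
            tested.add(e.region)
            if rng.random() < config.capture_concordance:
                pairs.add((e.region, e.target))
            if rng.random() < 0.3:  # decoy capture target
                pairs.add((e.region, str(rng.choice(truth.genes))))
    truth.capture_tested = frozenset(tested)
    truth.capture_pairs = frozenset(pairs)


def _sample_grid(config: SimConfig, extra_individuals: dict | None = None):
    rows = []
    for sp in config.species:
        for age in ("infant", "adult"):
            n = config.n_individuals_per_species_per_age
            n += (extra_individuals or {}).get((sp, age), 0)
            for i in range(n):
                for ct, _lin in config.cell_types:
                    rows.append(
                        {"species": sp, "age_group": age,
                         "individual": f"{sp}_{age}_{i:02d}", "cell_type": ct}
                    )
    return pd.DataFrame(rows)


def simulate_counts(
    truth: GroundTruth,
    config: SimConfig,
    extra_individuals: dict | None = None,
) -> PseudobulkMatrix:
    """NB2 pseudobulk counts under the planted model.

    mean(g, sample) = baseline_mean(g) * 2^planted_lfc * size_factor;
    variance = mean + dispersion * mean^2. ``extra_individuals`` maps
    (species, age_group) to a number of additional individuals drawn
    from an independent stream, leaving the base columns untouched.
    """
    if len(truth.genes) != config.n_genes:
        raise ValueError(
            f"truth holds {len(truth.genes)} genes but config expects {config.n_genes}"
        )
    meta = _sample_grid(config, extra_individuals)
    base = np.array([truth.baseline_means[g] for g in truth.genes])
    alpha = np.array([truth.dispersions[g] for g in truth.genes])
    gene_pos = {g: i for i, g in enumerate(truth.genes)}

    lfc_cols = np.zeros((config.n_genes, len(meta)))
    groups = meta.groupby(["species", "age_group", "cell_type"]).groups
    for (sp, age, ct), idx in groups.items():
        v = np.zeros(config.n_genes)
        for (g, s, a, c), val in truth.planted_lfc.items():
            if (s, a, c) == (sp, age, ct):
                v[gene_pos[g]] = val
        lfc_cols[:, np.asarray(list(idx))] = v[:, None]

    n_base = config.n_individuals_per_species_per_age
    is_extra = meta["individual"].str.rsplit("_", n=1).str[-1].astype(int) >= n_base
    sf = np.empty(len(meta))
    rng_sf = config.rng("size_factors")
    sf[~is_extra.to_numpy()] = np.exp(
        rng_sf.normal(0.0, config.size_factor_sigma, int((~is_extra).sum()))
    )
    counts = np.empty((config.n_genes, len(meta)), dtype=np.int64)
    rng_c = config.rng("counts")
    base_idx = np.flatnonzero(~is_extra.to_numpy())
    mu = base[:, None] * 2.0 ** lfc_cols[:, base_idx] * sf[base_idx][None, :]
    r = (1.0 / alpha)[:, None]
    counts[:, base_idx] = rng_c.negative_binomial(r, r / (r + mu))
    extra_idx = np.flatnonzero(is_extra.to_numpy())
    if extra_idx.size:
        rng_e = config.rng("extra_counts")
        sf[extra_idx] = np.exp(
            rng_e.normal(0.0, config.size_factor_sigma, extra_idx.size)
        )
        mu_e = base[:, None] * 2.0 ** lfc_cols[:, extra_idx] * sf[extra_idx][None, :]
        counts[:, extra_idx] = rng_e.negative_binomial(r, r / (r + mu_e))
    return PseudobulkMatrix(counts, list(truth.genes), meta)


def simulate_cells(
    matrix: PseudobulkMatrix,
    config: SimConfig,
    cells_per_sample: int = 20,
):
    """Multinomially split pseudobulk columns into cells (for aggregation)."""
    rng = config.rng("cells")
    cols, meta_rows = [], []
    for j in range(matrix.n_samples):
        col = matrix.counts[:, j]
        total = int(col.sum())
        if total == 0:
            split = np.zeros((matrix.n_genes, cells_per_sample), dtype=np.int64)
        else:
            assign = rng.integers(0, cells_per_sample, size=total)
            reps = np.repeat(np.arange(matrix.n_genes), col)
            split = np.zeros((matrix.n_genes, cells_per_sample), dtype=np.int64)
            np.add.at(split, (reps, assign), 1)
        cols.append(split)
        row = matrix.sample_meta.iloc[j]
        for c in range(cells_per_sample):
            meta_rows.append(
                {"species": row["species"], "age_group": row["age_group"],
                 "individual": row["individual"], "cell_type": row["cell_type"],
                 "cell_id": f"{row['individual']}.{row['cell_type']}.{c}"}
            )
    return np.concatenate(cols, axis=1), pd.DataFrame(meta_rows)


def simulate_regulons(truth: GroundTruth) -> list:
    """Materialize the designed regulon edge list."""
    return list(truth.regulon_edges)


def simulate_annotations(truth: GroundTruth) -> list:
    """Emit annotation intervals overlapping the regions truth marks.

    Each (region, class) pair yields one interval nested inside the
    region; decoy intervals are placed in the gaps between regions so
    unannotated regions stay unannotated.
    """
    intervals = []
    for rid in sorted(truth.regions):
        chrom, start, end = truth.regions[rid]
        for k, cls in enumerate(sorted(truth.annotation_truth.get(rid, ()))):
            intervals.append(
                AnnotatedInterval(chrom, start + 100 + 60 * k,
                                  start + 100 + 60 * k + 50, cls, source=rid)
            )
        # decoy in the inter-region gap: [start+500, start+1000) is free
        intervals.append(
            AnnotatedInterval(chrom, end + 100, end + 200,
                              ANNOTATION_CLASSES[0], source=f"decoy_{rid}")
        )
    return intervals


def simulate_disease_tables(truth: GroundTruth) -> pd.DataFrame:
    """Patient DE table consistent with the planted disease truth."""
    rng = np.random.default_rng([truth.seed, _STREAM["disease"], 1])
    rows = []
    for (g, lin, disease), direction in sorted(truth.disease_truth.items()):
        mag = rng.uniform(0.5, 2.0)
        rows.append(
            {"gene": g, "disease": disease,
             "cell_type": truth.patient_labels[lin],
             "direction": direction,
             "log2fc": mag if direction == "up" else -mag,
             "fdr": rng.uniform(0.0, 0.04)}
        )
    return pd.DataFrame(
        rows, columns=["gene", "disease", "cell_type", "direction", "log2fc", "fdr"]
    )


def simulate_capture_pairs(truth: GroundTruth) -> pd.DataFrame:
    """Capture pairs plus the tested (baited) region set as a frame."""
    rows = [{"region": r, "gene": g} for r, g in sorted(truth.capture_pairs)]
    return pd.DataFrame(rows, columns=["region", "gene"])


def simulate_risk_lists(truth: GroundTruth) -> dict:
    return {f"{d}_risk": set(v) for d, v in truth.risk_truth.items()}


def simulate_development(
    config: SimConfig,
    module,
    age_groups=("prenatal", "0-1y", "1-20y", "gt20y"),
    age_weights=(1.2, 1.0, 0.4, 0.0),
    n_per_group: int = 100,
    n_genes: int = 2000,
    effect: float = 1.0,
):
    """Normalized log-expression for nuclei across developmental ages.

    Module genes are shifted by ``effect * age_weight`` in each age
    group, emulating an early-peaking program; all other genes are
    stationary noise. Returns (expression, gene_ids, age labels).
    """
    rng = config.rng("development")
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    idx = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in module if g not in idx]
    if missing:
        raise ValueError(f"module genes outside the simulated panel: {missing[:5]}")
    n_nuclei = n_per_group * len(age_groups)
    X = rng.normal(0.0, 1.0, size=(n_nuclei, n_genes))
    ages = np.repeat(list(age_groups), n_per_group)
    for k, (grp, w) in enumerate(zip(age_groups, age_weights)):
        rows = slice(k * n_per_group, (k + 1) * n_per_group)
        for g in module:
            X[rows, idx[g]] += effect * w
    return X, gene_ids, ages


@dataclass
class Bundle:
    """In-memory fixture bundle: ground truth plus every input artifact."""

    config: SimConfig
    truth: GroundTruth
    matrix: PseudobulkMatrix
    regulons: list
    annotations: list
    patient_de: pd.DataFrame
    capture_pairs: pd.DataFrame
    risk_lists: dict


def simulate_bundle(config: SimConfig) -> Bundle:
    truth = generate_truth(config)
    return Bundle(
        config=config,
        truth=truth,
        matrix=simulate_counts(truth, config),
        regulons=simulate_regulons(truth),
        annotations=simulate_annotations(truth),
        patient_de=simulate_disease_tables(truth),
        capture_pairs=simulate_capture_pairs(truth),
        risk_lists=simulate_risk_lists(truth),
    )


# ---------------------------------------------------------------------------
# serialization

def _truth_to_json(truth: GroundTruth) -> dict:
    enc_sets = lambda d: {  # noqa: E731
        f"{ct}|{direction}": sorted(v) for (ct, direction), v in d.items()
    }
    return {
        "seed": truth.seed,
        "genes": truth.genes,
        "baseline_means": truth.baseline_means,
        "dispersions": truth.dispersions,
        "planted_hiDE": enc_sets(truth.planted_hiDE),
        "planted_ciDE": enc_sets(truth.planted_ciDE),
        "shared_adult_DE": enc_sets(truth.shared_adult_DE),
        "adult_only_DE": enc_sets(truth.adult_only_DE),
        "planted_lfc": [
            {"gene": g, "species": s, "age_group": a, "cell_type": c, "lfc": v}
            for (g, s, a, c), v in sorted(truth.planted_lfc.items())
        ],
        "edges": [
            {"edge_id": eid, **asdict(e)}
            for eid, e in zip(truth.edge_ids, truth.regulon_edges)
        ],
        "regulon_truth": truth.regulon_truth,
        "regions": {r: list(v) for r, v in truth.regions.items()},
        "annotation_truth": {r: sorted(v) for r, v in truth.annotation_truth.items()},
        "disease_truth": [
            {"gene": g, "lineage": lin, "disease": d, "direction": v}
            for (g, lin, d), v in sorted(truth.disease_truth.items())
        ],
        "patient_labels": truth.patient_labels,
        "risk_truth": {d: sorted(v) for d, v in truth.risk_truth.items()},
        "capture_tested": sorted(truth.capture_tested),
        "capture_pairs": sorted(map(list, truth.capture_pairs)),
        "core_genes": sorted(truth.core_genes),
    }


def _truth_from_json(d: dict) -> GroundTruth:
    dec_sets = lambda m: {  # noqa: E731
        (k.split("|")[0], k.split("|")[1]): frozenset(v) for k, v in m.items()
    }
    return GroundTruth(
        genes=list(d["genes"]),
        baseline_means=dict(d["baseline_means"]),
        dispersions=dict(d["dispersions"]),
        planted_hiDE=dec_sets(d["planted_hiDE"]),
        planted_ciDE=dec_sets(d["planted_ciDE"]),
        shared_adult_DE=dec_sets(d["shared_adult_DE"]),
        adult_only_DE=dec_sets(d["adult_only_DE"]),
        planted_lfc={
            (r["gene"], r["species"], r["age_group"], r["cell_type"]): r["lfc"]
            for r in d["planted_lfc"]
        },
        regulon_edges=[
            RegulonEdge(tf=r["tf"], region=r["region"], target=r["target"],
                        tf2g_score=r["tf2g_score"], r2g_score=r["r2g_score"],
                        role=r["role"], cell_context=r["cell_context"])
            for r in d["edges"]
        ],
        edge_ids=[r["edge_id"] for r in d["edges"]],
        regulon_truth={k: dict(v) for k, v in d["regulon_truth"].items()},
        regions={r: tuple(v) for r, v in d["regions"].items()},
        annotation_truth={r: frozenset(v) for r, v in d["annotation_truth"].items()},
        disease_truth={
            (r["gene"], r["lineage"], r["disease"]): r["direction"]
            for r in d["disease_truth"]
        },
        patient_labels=dict(d["patient_labels"]),
        risk_truth={k: frozenset(v) for k, v in d["risk_truth"].items()},
        capture_tested=frozenset(d["capture_tested"]),
        capture_pairs=frozenset(tuple(p) for p in d["capture_pairs"]),
        core_genes=frozenset(d.get("core_genes", [])),
        seed=int(d.get("seed", 0)),
    )


def write_fixture_bundle(bundle: Bundle, directory) -> dict:
    """Write the bundle to disk and return a checksum manifest."""
    from . import io as iomod

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iomod.write_counts(bundle.matrix, directory / "counts.mtx",
                       directory / "genes.tsv", directory / "samples.tsv")
    iomod.write_regulons(bundle.regulons, directory / "regulons.tsv")
    iomod.write_bed(bundle.annotations, directory / "annotations.bed")
    iomod.write_tsv(bundle.patient_de, directory / "disease_de.tsv")
    iomod.write_tsv(bundle.capture_pairs, directory / "capture_pairs.tsv")
    iomod.write_gmt(bundle.risk_lists, directory / "risk_genes.gmt")
    with open(directory / "truth.json", "w") as fh:
        json.dump(_truth_to_json(bundle.truth), fh, indent=0, sort_keys=True)
    with open(directory / "config.json", "w") as fh:
        cfg = asdict(bundle.config)
        cfg["cell_types"] = [list(x) for x in bundle.config.cell_types]
        json.dump(cfg, fh, indent=0, sort_keys=True)

    manifest = {"files": {}}
    for path in sorted(directory.iterdir()):
        if path.name == "manifest.json":
            continue
        manifest["files"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=0, sort_keys=True)
    return manifest


def read_fixture_bundle(directory) -> Bundle:
    """Read a bundle written by `write_fixture_bundle`."""
    from . import io as iomod

    directory = Path(directory)
    with open(directory / "truth.json") as fh:
        truth = _truth_from_json(json.load(fh))
    with open(directory / "config.json") as fh:
        cfg = json.load(fh)
    cfg["cell_types"] = tuple(tuple(x) for x in cfg["cell_types"])
    for key in ("species", "dispersion_range", "baseline_mean_range"):
        cfg[key] = tuple(cfg[key])
    config = SimConfig(**cfg)
    return Bundle(
        config=config,
        truth=truth,
        matrix=iomod.read_counts(directory / "counts.mtx",
                                 directory / "genes.tsv",
                                 directory / "samples.tsv"),
        regulons=iomod.read_regulons(directory / "regulons.tsv"),
        annotations=iomod.read_bed(directory / "annotations.bed"),
        patient_de=iomod.read_patient_de(directory / "disease_de.tsv"),
        capture_pairs=iomod.read_tsv(directory / "capture_pairs.tsv"),
        risk_lists=iomod.read_gmt(directory / "risk_genes.gmt"),
    )
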