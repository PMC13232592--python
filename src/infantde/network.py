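"""Construction of the hiDECORE regulatory network.

Starting from regulon edges (TF -> accessible region -> target gene),
the core network of a lineage keeps an edge only when

* node rule -- both TF and target are infant-specific expression gains
  (hiDE gains) in that lineage,
* rule i    -- the mediating region overlaps at least one annotated
  human-specific sequence change (HAR, hINS or hDEL),
* rule ii   -- the TF-to-gene score is positive,
* rule iii  -- the region-to-gene score is positive,
* role      -- the regulon acts as an activator.

Failures are attributed to the first failing rule in the fixed order
(node, i, ii, iii, role) so provenance counts are reproducible and sum
to the input edge count.
"""

from __future__ import annotations

import heapq
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .stats import (
    ContingencyTable2x2,
    fisher_exact,
    hypergeom_upper_tail,
    odds_ratio,
)

__all__ = [
    "RegulonEdge",
    "AnnotatedInterval",
    "HiDECORENetwork",
    "RULE_ORDER",
    "ANNOTATION_CLASSES",
    "region_coords",
    "annotate_regions",
    "build_hidecore",
    "lineage_overlap_stats",
    "annotate_disease",
    "lineage_disease_enrichment",
    "per_tf_disease_proportions",
    "capture_concordance",
]

ANNOTATION_CLASSES = ("HAR", "hINS", "hDEL")
RULE_ORDER = ("node", "i", "ii", "iii", "role")


def region_coords(region_id: str):
    """Parse a coordinate-encoded region id 'chrom:start-end'."""
    try:
        chrom, span = region_id.split(":")
        start, end = span.split("-")
        return chrom, int(start), int(end)
    except ValueError as err:
        raise ValueError(
            f"region id {region_id!r} is not coordinate-encoded (chrom:start-end)"
        ) from err


@dataclass(frozen=True)
class RegulonEdge:
    """One TF -> region -> target relationship with signed scores."""

    tf: str
    region: str
    target: str
    tf2g_score: float
    r2g_score: float
    role: str            # "activator" | "repressor"
    cell_context: str    # lineage label

    def __post_init__(self) -> None:
        if self.role not in ("activator", "repressor"):
            raise ValueError(f"role must be activator or repressor, got {self.role!r}")


@dataclass(frozen=True)
class AnnotatedInterval:
    """A 0-based half-open genomic interval with an annotation class."""

    chrom: str
    start: int
    end: int
    annotation_class: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start >= end: {self.chrom}:{self.start}-{self.end}")
        if self.annotation_class not in ANNOTATION_CLASSES:
            raise ValueError(
                f"annotation class must be one of {ANNOTATION_CLASSES}, "
                f"got {self.annotation_class!r}"
            )


@dataclass
class HiDECORENetwork:
    """Retained activator edges of one lineage plus provenance counts."""

    lineage: str
    edges: list                 # retained RegulonEdge objects
    edge_annotations: dict      # edge index -> frozenset of annotation classes
    provenance: dict            # rule -> failure count, plus retained/input
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    node_disease: dict = field(default_factory=dict)

    @property
    def genes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def tfs(self) -> frozenset:
        return frozenset(e.tf for e in self.edges)

    @property
    def targets(self) -> frozenset:
        return frozenset(e.target for e in self.edges)

    @property
    def regions(self) -> frozenset:
        return frozenset(e.region for e in self.edges)


def annotate_regions(regions: dict, annotations) -> dict:
    """Map each region to the annotation classes it overlaps.

    ``regions`` maps region id -> (chrom, start, end), 0-based half-open;
    overlap requires at least one shared base (touching intervals do not
    overlap). Implemented as a sort-and-sweep per chromosome; regions
    with no overlap map to an empty set.
    """
    by_chrom_regions: dict = {}
    for rid, (chrom, start, end) in regions.items():
        if start >= end:
            raise ValueError(f"region {rid} has start >= end: {start}-{end}")
        by_chrom_regions.setdefault(chrom, []).append((int(start), int(end), rid))
    by_chrom_iv: dict = {}
    for iv in annotations:
        by_chrom_iv.setdefault(iv.chrom, []).append(iv)

    unknown = set(by_chrom_regions) ^ set(by_chrom_iv)
    if unknown and by_chrom_regions and by_chrom_iv:
        warnings.warn(
            f"chromosomes present in only one input: {sorted(unknown)}", stacklevel=2
        )

    result = {rid: set() for rid in regions}
    for chrom, regs in by_chrom_regions.items():
        ivs = sorted(by_chrom_iv.get(chrom, []), key=lambda iv: iv.start)
        regs.sort()
        active: list = []  # heap of (end, start, class)
        j = 0
        for start, end, rid in regs:
            while j < len(ivs) and ivs[j].start < end:
                heapq.heappush(active, (ivs[j].end, ivs[j].start, ivs[j].annotation_class))
                j += 1
            while active and active[0][0] <= start:
                heapq.heappop(active)
            # intervals on the heap end after this region's start; regions
            # are start-sorted but not end-sorted, so re-check iv.start <
            # region.end before claiming the >= 1 bp overlap
            result[rid].update(cls for (_e, s, cls) in active if s < end)
    return {rid: frozenset(v) for rid, v in result.items()}


def build_hidecore(
    regulon_edges,
    hide_gains_by_lineage: dict,
    region_annotations: dict,
    universe=None,
    rules=RULE_ORDER,
) -> dict:
    """Filter regulon edges into per-lineage hiDECORE networks.

    ``hide_gains_by_lineage`` maps lineage -> set of hiDE gain genes;
    ``region_annotations`` maps region id -> set of annotation classes.
    ``rules`` lets callers disable individual retention rules (used for
    monotonicity checks); disabling any rule can only grow the network.
    Edges whose TF or target is outside ``universe`` (when given) are
    excluded up front and counted separately.
    """
    rules = tuple(rules)
    unknown_rules = set(rules) - set(RULE_ORDER)
    if unknown_rules:
        raise ValueError(f"unknown rules: {sorted(unknown_rules)}")
    universe = set(universe) if universe is not None else None

    by_lineage: dict = {lin: [] for lin in hide_gains_by_lineage}
    prov: dict = {
        lin: Counter({r: 0 for r in RULE_ORDER} | {"outside_universe": 0, "retained": 0})
        for lin in hide_gains_by_lineage
    }
    for edge in regulon_edges:
        lin = edge.cell_context
        if lin not in by_lineage:
            continue
        gains = hide_gains_by_lineage[lin]
        counts = prov[lin]
        counts["input"] += 1
        if universe is not None and (edge.tf not in universe or edge.target not in universe):
            counts["outside_universe"] += 1
            continue
        checks = {
            "node": edge.tf in gains and edge.target in gains,
            "i": bool(region_annotations.get(edge.region)),
            "ii": edge.tf2g_score > 0,
            "iii": edge.r2g_score > 0,
            "role": edge.role == "activator",
        }
        failed = next((r for r in RULE_ORDER if r in rules and not checks[r]), None)
        if failed is not None:
            counts[failed] += 1
            continue
        counts["retained"] += 1
        by_lineage[lin].append(edge)

    networks = {}
    for lin, edges in by_lineage.items():
        g = nx.DiGraph()
        annots = {}
        for i, e in enumerate(edges):
            cls = frozenset(region_annotations.get(e.region, frozenset()))
            annots[i] = cls
            for node in (e.tf, e.target):
                if node not in g:
                    g.add_node(node, kind=set())
            g.nodes[e.tf]["kind"].add("TF")
            g.nodes[e.target]["kind"].add("target")
            if g.has_edge(e.tf, e.target):
                g[e.tf][e.target]["regions"].add(e.region)
                g[e.tf][e.target]["annotation_classes"] |= cls
            else:
                g.add_edge(e.tf, e.target, regions={e.region}, annotation_classes=set(cls))
            if e.tf == e.target:
                warnings.warn(f"self-loop regulon edge on {e.tf} in {lin}", stacklevel=2)
        networks[lin] = HiDECORENetwork(
            lineage=lin, edges=edges, edge_annotations=annots,
            provenance=dict(prov[lin]), graph=g,
        )
    return networks


def lineage_overlap_stats(net_a: HiDECORENetwork, net_b: HiDECORENetwork, universe):
    """Gene-overlap fraction between two lineage networks, with enrichment.

    Returns a dict with the Jaccard-style union fraction, per-lineage
    directional fractions, the hypergeometric upper-tail p of the overlap
    in the stated universe, and the odds ratio.
    """
    universe = set(universe)
    a, b = set(net_a.genes) & universe, set(net_b.genes) & universe
    inter, union = a & b, a | b
    N = len(universe)
    k, K, n = len(inter), len(a), len(b)
    p = hypergeom_upper_tail(k, K, n, N) if K and n else 1.0
    table = ContingencyTable2x2(k, n - k, K - k, N - K - n + k) if union else None
    return {
        "fraction_union": (len(inter) / len(union)) if union else 1.0,
        "fraction_of_a": (len(inter) / len(a)) if a else float("nan"),
        "fraction_of_b": (len(inter) / len(b)) if b else float("nan"),
        "n_overlap": k,
        "p_hypergeom": p,
        "odds_ratio": odds_ratio(table) if table else float("nan"),
    }


def annotate_disease(
    network: HiDECORENetwork,
    patient_table: pd.DataFrame,
    lineage_map,
) -> HiDECORENetwork:
    """Set each node's disease status from lineage-matched patient DE.

    A node is ASD/PD-deregulated when the patient table lists the gene
    for that disease under a label mapping to the network's lineage; hits
    under unmatched labels do not count. Statuses are none, ASD, PD or
    both; counts per status are stored in ``provenance['disease_counts']``.
    """
    labels = lineage_map.labels_for_lineage(network.lineage)
    matched = patient_table[patient_table["cell_type"].isin(labels)]
    by_disease = {
        dis: set(sub["gene"]) for dis, sub in matched.groupby("disease")
    }
    status = {}
    for gene in network.graph.nodes:
        hits = {d for d, genes in by_disease.items() if gene in genes}
        if hits >= {"ASD", "PD"}:
            status[gene] = "both"
        elif "ASD" in hits:
            status[gene] = "ASD"
        elif "PD" in hits:
            status[gene] = "PD"
        else:
            status[gene] = "none"
    network.node_disease = status
    counts = Counter(status.values())
    network.provenance = dict(network.provenance)
    network.provenance["disease_counts"] = {
        k: counts.get(k, 0) for k in ("ASD", "PD", "both", "none")
    }
    return network


def _disease_hits(network: HiDECORENetwork, disease: str, tfs_only: bool):
    genes = network.tfs if tfs_only else network.genes
    if not network.node_disease:
        raise ValueError("network has no disease annotation; run annotate_disease first")
    hits = {g for g in genes if network.node_disease.get(g) in (disease, "both")}
    return genes, hits


def lineage_disease_enrichment(
    net_a: HiDECORENetwork,
    net_b: HiDECORENetwork,
    disease: str,
    tfs_only: bool = False,
) -> dict:
    """Fisher's exact test of disease-hit rates between two lineages.

    Rows are lineages, columns disease-hit versus not, over network genes
    (or TFs only). Both the one-sided (greater) and two-sided p are
    returned alongside the unconditional odds ratio.
    """
    genes_a, hits_a = _disease_hits(net_a, disease, tfs_only)
    genes_b, hits_b = _disease_hits(net_b, disease, tfs_only)
    table = ContingencyTable2x2(
        len(hits_a), len(genes_a) - len(hits_a),
        len(hits_b), len(genes_b) - len(hits_b),
    )
    return {
        "table": table,
        "odds_ratio": odds_ratio(table),
        "p_two_sided": fisher_exact(table, "two_sided"),
        "p_greater": fisher_exact(table, "greater"),
        "lineages": (net_a.lineage, net_b.lineage),
        "disease": disease,
        "tfs_only": tfs_only,
    }


def per_tf_disease_proportions(network: HiDECORENetwork) -> pd.DataFrame:
    """Per-TF proportions of retained targets deregulated in each disease.

    Ranked by total disease-hit proportion (PD + ASD proportions; a gene
    deregulated in both diseases counts toward each), ties broken by
    target count then TF id. TFs without targets are excluded with a
    warning.
    """
    if not network.node_disease:
        raise ValueError("network has no disease annotation; run annotate_disease first")
    targets_of: dict = {}
    for e in network.edges:
        targets_of.setdefault(e.tf, set()).add(e.target)
    rows = []
    for tf in sorted(targets_of):
        targets = targets_of[tf]
        if not targets:
            warnings.warn(f"TF {tf} has no retained targets; excluded", stacklevel=2)
            continue
        n_pd = sum(network.node_disease.get(t) in ("PD", "both") for t in targets)
        n_asd = sum(network.node_disease.get(t) in ("ASD", "both") for t in targets)
        rows.append(
            {"tf": tf, "n_targets": len(targets), "n_PD_hits": n_pd,
             "n_ASD_hits": n_asd, "prop_PD": n_pd / len(targets),
             "prop_ASD": n_asd / len(targets),
             "total_proportion": (n_pd + n_asd) / len(targets)}
        )
    df = pd.DataFrame(rows, columns=["tf", "n_targets", "n_PD_hits", "n_ASD_hits",
                                     "prop_PD", "prop_ASD", "total_proportion"])
    if df.empty:
        return df
    return (
        df.sort_values(
            ["total_proportion", "n_targets", "tf"], ascending=[False, False, True]
        ).reset_index(drop=True)
    )


def capture_concordance(
    network: HiDECORENetwork,
    capture_pairs: pd.DataFrame,
    tested_regions=None,
) -> dict:
    """Concordance of network region->target links with capture pairs.

    ``capture_pairs`` has columns region, gene; ``tested_regions`` is the
    assay's bait set (defaults to regions present in the pairs). Only
    network regions in the tested set enter the denominators:
    ``fraction_regions`` is the share with at least one captured target,
    ``fraction_edges`` the share of network region->gene pairs found in
    the capture pairs.
    """
    pairs = {(r, g) for r, g in zip(capture_pairs["region"], capture_pairs["gene"])}
    if tested_regions is None:
        tested_regions = {r for r, _ in pairs}
    tested_regions = set(tested_regions)
    net_regions = network.regions & tested_regions
    if not net_regions:
        raise ValueError("no network region is in the capture assay's tested set")
    captured_regions = {r for r, _ in pairs}
    n_with_target = sum(1 for r in net_regions if r in captured_regions)

    net_pairs = {
        (e.region, e.target) for e in network.edges if e.region in tested_regions
    }
    n_matched = sum(1 for p in net_pairs if p in pairs)
    return {
        "n_tested_regions": len(net_regions),
        "fraction_regions": n_with_target / len(net_regions),
        "n_tested_edges": len(net_pairs),
        "fraction_edges": (n_matched / len(net_pairs)) if net_pairs else float("nan"),
    }
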