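"""Interval annotation, core-network retention rules and network statistics."""

import numpy as np
import pandas as pd
import pytest

from infantde.disease import LineageMap
from infantde.network import (
    AnnotatedInterval,
    RULE_ORDER,
    RegulonEdge,
    annotate_disease,
    annotate_regions,
    build_hidecore,
    capture_concordance,
    lineage_disease_enrichment,
    lineage_overlap_stats,
    per_tf_disease_proportions,
    region_coords,
)


def brute_force_overlap(regions, intervals):
    out = {rid: set() for rid in regions}
    for rid, (chrom, start, end) in regions.items():
        for iv in intervals:
            if iv.chrom == chrom and start < iv.end and iv.start < end:
                out[rid].add(iv.annotation_class)
    return {k: frozenset(v) for k, v in out.items()}


def _edge(tf="T1", region="chrS:0-100", target="G1", tf2g=0.5, r2g=0.5,
          role="activator", lineage="OL"):
    return RegulonEdge(tf, region, target, tf2g, r2g, role, lineage)


class TestAnnotateRegions:
    def test_half_open_touching_does_not_overlap(self):
        regions = {"r": ("chrS", 100, 200)}
        ivs = [AnnotatedInterval("chrS", 200, 300, "HAR")]
        assert annotate_regions(regions, ivs)["r"] == frozenset()

    def test_single_base_overlap_counts(self):
        regions = {"r": ("chrS", 100, 200)}
        ivs = [AnnotatedInterval("chrS", 199, 300, "HAR")]
        assert annotate_regions(regions, ivs)["r"] == {"HAR"}

    def test_nested_regions_with_shared_sweep(self):
        regions = {"wide": ("chrS", 0, 1000), "nested": ("chrS", 10, 20)}
        ivs = [AnnotatedInterval("chrS", 500, 600, "hINS")]
        out = annotate_regions(regions, ivs)
        assert out["wide"] == {"hINS"} and out["nested"] == frozenset()

    def test_matches_quadratic_oracle_on_random_inputs(self, rng):
        starts = rng.integers(0, 5000, size=300)
        regions = {
            f"r{i}": ("chrS", int(s), int(s + rng.integers(1, 120)))
            for i, s in enumerate(starts)
        }
        ivs = [
            AnnotatedInterval("chrS", int(s), int(s + rng.integers(1, 80)),
                              ["HAR", "hINS", "hDEL"][int(rng.integers(0, 3))])
            for s in rng.integers(0, 5000, size=300)
        ]
        assert annotate_regions(regions, ivs) == brute_force_overlap(regions, ivs)

    def test_region_coords_roundtrip_and_errors(self):
        assert region_coords("chrS:10-20") == ("chrS", 10, 20)
        with pytest.raises(ValueError):
            region_coords("not-a-region")


class TestBuildHidecore:
    def test_three_edge_toy(self):
        edges = [
            _edge(region="chrS:0-100"),                      # passes all
            _edge(region="chrS:100-200", tf2g=-0.5),         # fails rule ii
            _edge(region="chrS:200-300"),                    # unannotated: fails i
        ]
        ann = {"chrS:0-100": {"HAR"}, "chrS:100-200": {"HAR"},
               "chrS:200-300": frozenset()}
        nets = build_hidecore(edges, {"OL": {"T1", "G1"}}, ann)
        net = nets["OL"]
        assert net.edges == [edges[0]]
        assert net.provenance["ii"] == 1 and net.provenance["i"] == 1
        assert net.provenance["retained"] == 1

    def test_empty_gains_all_fail_node_rule(self):
        edges = [_edge(), _edge(target="G2")]
        nets = build_hidecore(edges, {"OL": set()}, {"chrS:0-100": {"HAR"}})
        assert nets["OL"].provenance["node"] == 2
        assert len(nets["OL"].edges) == 0

    def test_provenance_conserved_and_universe_exclusion(self):
        edges = [_edge(), _edge(target="ZZ"), _edge(tf2g=-1.0)]
        nets = build_hidecore(edges, {"OL": {"T1", "G1"}}, {"chrS:0-100": {"HAR"}},
                              universe={"T1", "G1"})
        p = nets["OL"].provenance
        assert p["input"] == 3
        assert p["retained"] + sum(p[r] for r in RULE_ORDER) + p["outside_universe"] == 3
        assert p["outside_universe"] == 1

    def test_rule_toggling_is_monotone(self, small_config, small_truth):
        from infantde.simulate import simulate_annotations

        gains = small_truth.hide_gains_by_lineage(small_config)
        ann = annotate_regions(small_truth.regions,
                               simulate_annotations(small_truth))
        full = build_hidecore(small_truth.regulon_edges, gains, ann)
        for dropped in RULE_ORDER:
            rules = tuple(r for r in RULE_ORDER if r != dropped)
            relaxed = build_hidecore(small_truth.regulon_edges, gains, ann,
                                     rules=rules)
            for lin in full:
                assert set(map(id, full[lin].edges)) <= set(map(id, relaxed[lin].edges))

    def test_retained_set_equals_planted_truth(self, small_config, small_truth):
        from infantde.simulate import simulate_annotations

        gains = small_truth.hide_gains_by_lineage(small_config)
        ann = annotate_regions(small_truth.regions,
                               simulate_annotations(small_truth))
        nets = build_hidecore(small_truth.regulon_edges, gains, ann)
        retained = {
            eid
            for lin, net in nets.items()
            for e in net.edges
            for eid, e2 in zip(small_truth.edge_ids, small_truth.regulon_edges)
            if e2 is e
        }
        expected = {eid for eid, r in small_truth.regulon_truth.items() if r["pass"]}
        assert retained == expected

    def test_every_rule_has_designed_pass_and_fail(self, small_truth):
        for rule in RULE_ORDER:
            vals = [r[rule] for r in small_truth.regulon_truth.values()]
            assert any(vals) and not all(vals)


def _toy_networks():
    edges_ol = [
        _edge("T1", "chrS:0-100", "A"), _edge("T1", "chrS:100-200", "B"),
        _edge("T2", "chrS:200-300", "C"),
    ]
    ann = {e.region: frozenset({"HAR"}) for e in edges_ol}
    edges_n = [
        _edge("T1", "chrS:300-400", "A", lineage="neural"),
        _edge("T3", "chrS:400-500", "D", lineage="neural"),
    ]
    ann.update({e.region: frozenset({"hINS"}) for e in edges_n})
    gains = {"OL": {"T1", "T2", "A", "B", "C"}, "neural": {"T1", "T3", "A", "D"}}
    nets = build_hidecore(edges_ol + edges_n, gains, ann)
    return nets["OL"], nets["neural"]


class TestDiseaseAnnotation:
    lmap = LineageMap(
        mapping={"COP": ["OL_patient"], "L2_3": ["neural_patient"]},
        lineage_of={"COP": "OL", "L2_3": "neural"},
    )

    def _patient(self):
        return pd.DataFrame(
            {"gene": ["A", "A", "B", "D"],
             "disease": ["ASD", "PD", "ASD", "PD"],
             "cell_type": ["OL_patient", "OL_patient", "neural_patient",
                           "neural_patient"],
             "direction": ["down", "up", "down", "down"],
             "log2fc": [-1.0, 1.0, -1.0, -1.0],
             "fdr": [0.01] * 4}
        )

    def test_status_respects_lineage_matching(self):
        ol, _ = _toy_networks()
        annotate_disease(ol, self._patient(), self.lmap)
        assert ol.node_disease["A"] == "both"
        # B is ASD-deregulated only under the neural label: no OL hit
        assert ol.node_disease["B"] == "none"

    def test_enrichment_and_proportions(self):
        ol, neural = _toy_networks()
        annotate_disease(ol, self._patient(), self.lmap)
        annotate_disease(neural, self._patient(), self.lmap)
        fe = lineage_disease_enrichment(ol, neural, "ASD")
        assert fe["table"].a == 1  # only A hits ASD in the OL lineage
        tf_table = per_tf_disease_proportions(ol)
        row = tf_table.set_index("tf").loc["T1"]
        assert row["n_targets"] == 2
        assert row["prop_PD"] == pytest.approx(0.5)
        assert row["prop_ASD"] == pytest.approx(0.5)

    def test_proportions_arithmetic_and_ranking(self):
        ol, _ = _toy_networks()
        ol.node_disease = {"A": "PD", "B": "PD", "C": "ASD", "T1": "none",
                           "T2": "none"}
        out = per_tf_disease_proportions(ol)
        # both TFs total 1.0; the tie breaks by target count (T1 has 2)
        assert list(out["tf"]) == ["T1", "T2"]
        t1 = out.set_index("tf").loc["T1"]
        assert t1["prop_PD"] == pytest.approx(1.0)
        assert t1["total_proportion"] == pytest.approx(1.0)


class TestOverlapAndCapture:
    def test_identical_and_disjoint_networks(self):
        ol, neural = _toy_networks()
        universe = [f"g{i}" for i in range(100)] + list(ol.genes | neural.genes)
        same = lineage_overlap_stats(ol, ol, universe)
        assert same["fraction_union"] == 1.0
        cross = lineage_overlap_stats(ol, neural, universe)
        assert cross["n_overlap"] == len(ol.genes & neural.genes)
        assert 0 < cross["p_hypergeom"] < 1

    def test_capture_superset_and_empty(self):
        ol, _ = _toy_networks()
        pairs = pd.DataFrame(
            [{"region": e.region, "gene": e.target} for e in ol.edges]
        )
        out = capture_concordance(ol, pairs)
        assert out["fraction_regions"] == 1.0 and out["fraction_edges"] == 1.0
        with pytest.raises(ValueError, match="tested set"):
            capture_concordance(ol, pairs.iloc[:0], tested_regions=set())

    def test_planted_concordance_recovered(self, small_config, small_truth):
        from infantde.simulate import simulate_annotations, simulate_capture_pairs

        gains = small_truth.hide_gains_by_lineage(small_config)
        ann = annotate_regions(small_truth.regions,
                               simulate_annotations(small_truth))
        nets = build_hidecore(small_truth.regulon_edges, gains, ann)
        pairs = simulate_capture_pairs(small_truth)
        fractions = []
        for net in nets.values():
            out = capture_concordance(net, pairs,
                                      tested_regions=small_truth.capture_tested)
            fractions.append(out["fraction_edges"])
        pooled = np.mean(fractions)
        assert abs(pooled - small_config.capture_concordance) < 0.2
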