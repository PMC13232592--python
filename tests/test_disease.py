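"""Risk-gene grids, patient-DE joins, directionality and module trajectories."""

import math

import numpy as np
import pandas as pd
import pytest

from infantde.de import DESet
from infantde.disease import (
    LineageMap,
    directionality_contingency,
    load_patient_de,
    module_trajectory_table,
    patient_de_scatter,
    risk_gene_overrepresentation,
)
from infantde.simulate import SimConfig, simulate_development


class TestLoadPatientDe:
    def _table(self, **over):
        base = {"gene": ["g1"], "disease": ["ASD"], "cell_type": ["OL_patient"],
                "direction": ["down"], "log2fc": [-1.0], "fdr": [0.01]}
        base.update(over)
        return pd.DataFrame(base)

    def test_direction_sign_mismatch_raises(self):
        with pytest.raises(ValueError, match="inconsistent"):
            load_patient_de(self._table(direction=["up"]))

    def test_duplicates_raise(self):
        t = pd.concat([self._table(), self._table()], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            load_patient_de(t)

    def test_fdr_prefilter(self):
        t = self._table(fdr=[0.2])
        assert load_patient_de(t, fdr_threshold=0.05).empty


class TestRiskGeneOverrepresentation:
    def test_maximal_enrichment_point_probability(self):
        universe = {f"g{i}" for i in range(100)}
        ds = DESet("human", "infant", "COP", "gain", frozenset(list(universe)[:5]))
        grid = risk_gene_overrepresentation(
            [ds], {"disease": set(ds.genes)}, {"COP": universe}
        )
        assert grid.loc[0, "p"] == pytest.approx(1 / math.comb(100, 5), rel=1e-9)

    def test_disjoint_list_is_unenriched(self):
        universe = {f"g{i}" for i in range(100)}
        ds = DESet("human", "infant", "COP", "gain", frozenset({"g0", "g1"}))
        grid = risk_gene_overrepresentation(
            [ds], {"disease": {"g50", "g51", "g52"}}, {"COP": universe}
        )
        assert grid.loc[0, "p"] >= 0.5
        assert grid.loc[0, "odds_ratio"] <= 1.0

    def test_outside_universe_risk_genes_counted(self):
        universe = {"g0", "g1", "g2", "g3"}
        ds = DESet("human", "infant", "COP", "gain", frozenset({"g0"}))
        grid = risk_gene_overrepresentation(
            [ds], {"d": {"g0", "zz"}}, {"COP": universe}
        )
        assert grid.loc[0, "risk_genes_outside_universe"] == 1
        assert grid.loc[0, "list_size"] == 1

    def test_planted_enrichment_recovered(self, rng):
        universe = [f"g{i}" for i in range(1000)]
        ors = []
        for _ in range(20):
            gains = set(rng.choice(universe, size=100, replace=False))
            # risk list hits gains at 3x the background rate
            risk = {g for g in universe
                    if rng.random() < (0.3 if g in gains else 0.1)}
            grid = risk_gene_overrepresentation(
                [DESet("human", "infant", "ct", "gain", frozenset(gains))],
                {"d": risk}, {"ct": set(universe)},
            )
            ors.append(grid.loc[0, "odds_ratio"])
        assert 2.0 <= np.median(ors) <= 4.5


def _lineage_map():
    return LineageMap(
        mapping={"COP": ["OL_patient"], "L2_3": ["neural_patient", "neural_extra"]},
        lineage_of={"COP": "OL", "L2_3": "neural"},
    )


class TestPatientDeScatter:
    def _evo(self, rows):
        return pd.DataFrame(rows, columns=["gene", "cell_type", "species_a", "log2fc"])

    def _patient(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "disease", "cell_type", "direction", "log2fc", "fdr"]
        )

    def test_empty_patient_table(self):
        out = patient_de_scatter(
            self._evo([("g1", "COP", "human", 1.0)]), self._patient([]), _lineage_map()
        )
        assert out.empty

    def test_mapping_multiplicity_gives_two_rows(self):
        evo = self._evo([("g1", "L2_3", "human", 1.0)])
        pat = self._patient(
            [("g1", "PD", "neural_patient", "up", 1.0, 0.01),
             ("g1", "PD", "neural_extra", "down", -1.0, 0.01)]
        )
        out = patient_de_scatter(evo, pat, _lineage_map())
        assert len(out) == 2
        assert set(out["disease_label"]) == {"neural_patient", "neural_extra"}

    def test_matches_bruteforce_join(self, rng):
        genes = [f"g{i}" for i in range(60)]
        evo = self._evo(
            [(g, ct, "human", float(rng.normal()))
             for g in rng.choice(genes, 40)
             for ct in (["COP"] if rng.random() < 0.5 else ["L2_3"])]
        ).drop_duplicates(subset=["gene", "cell_type"])
        pat = self._patient(
            [(g, "ASD", lab, "up", 1.0, 0.01)
             for g in rng.choice(genes, 30)
             for lab in (["OL_patient"] if rng.random() < 0.5 else ["neural_patient"])]
        ).drop_duplicates(subset=["gene", "disease", "cell_type"])
        lmap = _lineage_map()
        out = patient_de_scatter(evo, pat, lmap)
        brute = []
        for _, er in evo.iterrows():
            for _, pr in pat.iterrows():
                if er["gene"] == pr["gene"] and pr["cell_type"] in lmap.mapping[er["cell_type"]]:
                    brute.append((er["gene"], er["cell_type"], pr["cell_type"]))
        assert sorted(zip(out["gene"], out["evo_cell_type"], out["disease_label"])) \
            == sorted(brute)

    def test_unmapped_patient_label_warns(self):
        evo = self._evo([("g1", "COP", "human", 1.0)])
        pat = self._patient([("g1", "ASD", "mystery", "up", 1.0, 0.01)])
        with pytest.warns(UserWarning, match="map to no"):
            patient_de_scatter(evo, pat, _lineage_map())


class TestDirectionalityContingency:
    def _matched(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene", "evo_cell_type", "disease_label", "disease", "species",
                     "evo_log2fc", "disease_log2fc", "disease_direction"],
        )

    def test_balanced_table_null(self):
        rows = []
        for sp in ("human", "chimp"):
            for d in ("up", "down"):
                rows += [(f"g{sp}{d}{i}", "COP", "lab", "ASD", sp, 1.0,
                          1.0 if d == "up" else -1.0, d) for i in range(10)]
        res = directionality_contingency(self._matched(rows), "human", ["chimp"])
        np.testing.assert_allclose(res["COP"].pearson_residuals, 0.0, atol=1e-12)

    def test_planted_down_excess_is_largest_positive_residual(self):
        rows = []
        rows += [(f"h{i}", "COP", "lab", "ASD", "human", 1.0, -1.0, "down")
                 for i in range(30)]
        rows += [(f"h{i}", "COP", "lab", "ASD", "human", 1.0, 1.0, "up")
                 for i in range(30, 40)]
        rows += [(f"c{i}", "COP", "lab", "ASD", "chimp", 1.0, -1.0, "down")
                 for i in range(10)]
        rows += [(f"c{i}", "COP", "lab", "ASD", "chimp", 1.0, 1.0, "up")
                 for i in range(10, 40)]
        res = directionality_contingency(self._matched(rows), "human", ["chimp"])
        r = res["COP"]
        i = r.row_labels.index("human_gain")
        j = r.col_labels.index("down")
        assert r.pearson_residuals[i, j] == r.pearson_residuals.max()
        assert r.pearson_residuals[i, j] > 0

    def test_degenerate_cell_type_dropped(self):
        rows = [("g1", "COP", "lab", "ASD", "human", 1.0, -1.0, "down")]
        with pytest.warns(UserWarning, match="degenerate"):
            res = directionality_contingency(self._matched(rows), "human", ["chimp"])
        assert res["dropped"] == ["COP"]


class TestModuleTrajectory:
    def test_background_flat_and_module_declines(self):
        cfg = SimConfig(seed=3)
        module = [f"G{i:05d}" for i in range(40)]
        X, genes, ages = simulate_development(cfg, module)
        per_nucleus, summary = module_trajectory_table(
            set(module), X, genes, ages, seed=4
        )
        mod = summary[summary["module"] == "module"].set_index("group")["mean"]
        bg = summary[summary["module"] == "background"]["mean"]
        order = ["prenatal", "0-1y", "1-20y", "gt20y"]
        assert list(mod[order]) == sorted(mod[order], reverse=True)
        assert np.all(np.abs(bg) < 0.1)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=3)
        module = [f"G{i:05d}" for i in range(10)]
        X, genes, ages = simulate_development(cfg, module)
        a, _ = module_trajectory_table(set(module), X, genes, ages, seed=9)
        b, _ = module_trajectory_table(set(module), X, genes, ages, seed=9)
        pd.testing.assert_frame_equal(a, b)
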