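"""Pseudobulk aggregation, normalization and the NB Wald engine."""

import logging

import numpy as np
import pandas as pd
import pytest

from infantde.de import (
    ALPHA_MIN,
    Contrast,
    PseudobulkDE,
    PseudobulkMatrix,
    aggregate_pseudobulk,
    call_de,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
)
from infantde.simulate import simulate_cells, simulate_counts


def _matrix(counts, species, ages, cell_type="ct"):
    counts = np.asarray(counts)
    n = counts.shape[1]
    meta = pd.DataFrame(
        {"species": species, "age_group": ages,
         "individual": [f"i{j}" for j in range(n)],
         "cell_type": [cell_type] * n}
    )
    return PseudobulkMatrix(counts, [f"g{i}" for i in range(counts.shape[0])], meta)


def _two_group_matrix(rng, n_genes, n_per_group, mu, alpha, lfc=0.0):
    """NB counts for a human-vs-chimp infant contrast, no size factors."""
    mu_a = mu * 2.0 ** lfc
    r = 1.0 / alpha
    ya = rng.negative_binomial(r, r / (r + mu_a), size=(n_genes, n_per_group))
    yb = rng.negative_binomial(r, r / (r + mu), size=(n_genes, n_per_group))
    return _matrix(
        np.hstack([ya, yb]),
        ["human"] * n_per_group + ["chimp"] * n_per_group,
        ["infant"] * (2 * n_per_group),
    )


class TestAggregatePseudobulk:
    def test_sums_cells_within_group(self):
        counts = np.array([[1, 3], [2, 4]])
        meta = pd.DataFrame(
            {"species": ["human"] * 2, "age_group": ["infant"] * 2,
             "individual": ["a", "a"], "cell_type": ["ct", "ct"]}
        )
        pm = aggregate_pseudobulk(counts, meta, min_cells=1)
        np.testing.assert_array_equal(pm.counts[:, 0], [4, 6])

    def test_small_groups_dropped_and_logged(self, caplog):
        counts = np.ones((3, 12), dtype=int)
        meta = pd.DataFrame(
            {"species": ["human"] * 12, "age_group": ["infant"] * 12,
             "individual": ["a"] * 10 + ["b"] * 2,
             "cell_type": ["ct"] * 12}
        )
        with caplog.at_level(logging.INFO, logger="infantde.de"):
            pm = aggregate_pseudobulk(counts, meta, min_cells=10)
        assert list(pm.sample_meta["individual"]) == ["a"]
        assert any("dropping pseudobulk group" in r.message for r in caplog.records)

    def test_unlabeled_cells_raise(self):
        meta = pd.DataFrame(
            {"species": ["human", None], "age_group": ["infant"] * 2,
             "individual": ["a", "a"], "cell_type": ["ct", "ct"]}
        )
        with pytest.raises(ValueError, match="unlabeled"):
            aggregate_pseudobulk(np.ones((2, 2), dtype=int), meta)

    def test_multinomial_split_roundtrip(self, small_config, small_truth):
        pm = simulate_counts(small_truth, small_config)
        keep = pm.subset_samples(np.arange(8))
        cells, cell_meta = simulate_cells(keep, small_config, cells_per_sample=7)
        back = aggregate_pseudobulk(cells, cell_meta, min_cells=1,
                                    gene_ids=keep.gene_ids)
        order = back.sample_meta[["individual", "cell_type"]].apply(tuple, axis=1)
        want = keep.sample_meta[["individual", "cell_type"]].apply(tuple, axis=1)
        col_of = {key: j for j, key in enumerate(want)}
        perm = [col_of[key] for key in order]
        np.testing.assert_array_equal(back.counts, keep.counts[:, perm])


class TestSizeFactors:
    def test_doubling_a_sample_doubles_its_factor(self, rng):
        base = rng.integers(5, 100, size=(50, 3))
        counts = np.column_stack([base[:, 0], 2 * base[:, 0], base[:, 2]])
        sf = size_factors(_matrix(counts, ["human"] * 3, ["infant"] * 3))
        assert sf[1] / sf[0] == pytest.approx(2.0, rel=1e-9)

    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[5], [10], [20]], (1, 4))
        np.testing.assert_allclose(
            size_factors(_matrix(counts, ["human"] * 4, ["infant"] * 4)), 1.0
        )

    def test_hand_median_of_ratios(self):
        counts = np.array(
            [[10, 20, 30], [5, 10, 15], [8, 16, 24], [100, 200, 300], [1, 2, 3]]
        )
        # every gene has ratios proportional to (1, 2, 3) -> factors too
        sf = size_factors(_matrix(counts, ["human"] * 3, ["infant"] * 3))
        expected = np.array([1.0, 2.0, 3.0]) / np.exp(np.mean(np.log([1, 2, 3])))
        np.testing.assert_allclose(sf, expected, rtol=1e-12)

    def test_fallback_warns_when_no_common_gene(self):
        counts = np.array([[3, 0], [0, 4]])
        with pytest.warns(UserWarning, match="total-count"):
            sf = size_factors(_matrix(counts, ["human"] * 2, ["infant"] * 2))
        assert sf[0] > 0 and sf[1] > 0


class TestEstimateDispersion:
    def test_nb_alpha_recovered_at_large_n(self, rng):
        pm = _two_group_matrix(rng, 300, 100, mu=200.0, alpha=0.5)
        sf = np.ones(pm.n_samples)
        alpha = estimate_dispersion(pm, sf, shrink=False)
        assert np.median(alpha) == pytest.approx(0.5, rel=0.2)

    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        counts = rng.poisson(500.0, size=(300, 100))
        pm = _matrix(counts, ["human"] * 100, ["infant"] * 100)
        alpha = estimate_dispersion(pm, np.ones(100), shrink=False)
        assert np.median(alpha) < 0.01

    def test_constant_counts_hit_floor(self):
        counts = np.full((5, 6), 7)
        pm = _matrix(counts, ["human"] * 6, ["infant"] * 6)
        alpha = estimate_dispersion(pm, np.ones(6), shrink=False)
        np.testing.assert_allclose(alpha, ALPHA_MIN)


class TestNbWaldTest:
    def test_identical_groups_yield_null_calls(self, rng):
        pm = _two_group_matrix(rng, 400, 20, mu=100.0, alpha=0.05, lfc=0.0)
        out = nb_wald_test(pm, Contrast("human", "chimp", "infant"))
        assert abs(np.median(out["log2fc"])) < 0.05
        assert np.median(out["wald_p"]) > 0.2

    def test_planted_effect_recovered(self, rng):
        # effect in 100 of 1000 genes so normalization cannot absorb it
        lfc = np.zeros((1000, 1))
        lfc[:100] = 1.0
        mu = 150.0 * 2.0 ** lfc
        r = 1.0 / 0.1
        ya = rng.negative_binomial(r, r / (r + mu), size=(1000, 10))
        yb = rng.negative_binomial(r, r / (r + 150.0), size=(1000, 10))
        pm = _matrix(np.hstack([ya, yb]), ["human"] * 10 + ["chimp"] * 10,
                     ["infant"] * 20)
        out = nb_wald_test(pm, Contrast("human", "chimp", "infant"))
        assert 0.8 <= out.loc[:99, "log2fc"].mean() <= 1.2

    def test_type_one_error_calibrated(self, rng):
        # dispersions drawn over the generator's default range
        alphas = np.exp(rng.uniform(np.log(0.01), np.log(0.1), 2000))
        mus = np.exp(rng.uniform(np.log(10), np.log(1000), 2000))
        r = 1.0 / alphas[:, None]
        mu = mus[:, None]
        y = rng.negative_binomial(r, r / (r + mu), size=(2000, 20))
        pm = _matrix(y, ["human"] * 10 + ["chimp"] * 10, ["infant"] * 20)
        out = nb_wald_test(pm, Contrast("human", "chimp", "infant"))
        frac = (out["wald_p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_zero_group_flagged_and_floored(self):
        counts = np.vstack(
            [np.hstack([np.zeros(4, int), np.full(4, 40)]),
             np.full(8, 30)]
        )
        pm = _matrix(counts, ["human"] * 4 + ["chimp"] * 4, ["infant"] * 8)
        out = nb_wald_test(pm, Contrast("human", "chimp", "infant"))
        assert out.loc[0, "flag"] == "floored"
        assert out.loc[0, "log2fc"] < 0

    def test_too_few_samples_raise(self):
        pm = _matrix(np.ones((3, 3), int), ["human", "human", "chimp"], ["infant"] * 3)
        with pytest.raises(ValueError, match=">= 2 samples"):
            nb_wald_test(pm, Contrast("human", "chimp", "infant"))


class TestCallDe:
    def _frame(self, lfcs, fdrs):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(lfcs))],
             "cell_type": "ct", "species_a": "human", "species_b": "chimp",
             "age_group": "infant", "log2fc": lfcs, "fdr": fdrs}
        )

    def test_thresholds_are_strict_and_joint(self):
        frame = self._frame(
            [0.5, 2.0, 0.6, -0.7, -0.5, 1.0],
            [0.01, 0.2, 0.01, 0.04, 0.01, 0.05],
        )
        gain, loss = call_de(frame)
        # 0.5 exactly excluded; fdr 0.2 excluded; fdr == 0.05 excluded
        assert set(gain.genes) == {"g2"}
        assert set(loss.genes) == {"g3"}

    def test_empty_calls_warn(self):
        with pytest.warns(UserWarning, match="empty"):
            gain, loss = call_de(self._frame([], []))
        assert len(gain) == len(loss) == 0


class TestModelObject:
    def test_fit_summary_and_scaling_invariance(self, rng):
        pm = _two_group_matrix(rng, 120, 8, mu=80.0, alpha=0.05, lfc=0.5)
        model = PseudobulkDE(pm, Contrast("human", "chimp", "infant"))
        res = model.fit()
        text = res.summary()
        assert "genes tested: 120" in text and "gains" in text
        # rescale one sample: its size factor scales, log2fc barely moves
        counts2 = pm.counts.copy()
        counts2[:, 0] *= 3
        pm2 = PseudobulkMatrix(counts2, pm.gene_ids, pm.sample_meta)
        res2 = PseudobulkDE(pm2, Contrast("human", "chimp", "infant")).fit()
        assert res2.size_factors[0] / res.size_factors[0] == pytest.approx(
            3.0 * (res2.size_factors[1:] / res.size_factors[1:]).mean(), rel=0.01
        )
        assert np.quantile(np.abs(res2.frame["log2fc"] - res.frame["log2fc"]), 0.9) < 0.25

    def test_from_dataframe(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
        )
        meta = pd.DataFrame(
            {"species": ["human"] * 3 + ["chimp"] * 3, "age_group": ["infant"] * 6,
             "individual": [f"i{j}" for j in range(6)], "cell_type": ["ct"] * 6}
        )
        res = PseudobulkDE.from_dataframe(
            counts, meta, Contrast("human", "chimp", "infant")
        ).fit()
        assert len(res.frame) == 10


class TestRecoveryOnPlantedTruth:
    def test_planted_human_gains_recovered(self, small_config, small_truth):
        pm = simulate_counts(small_truth, small_config)
        ct = small_config.cell_types[0][0]
        res = PseudobulkDE(pm, Contrast("human", "chimp", "infant"), cell_type=ct).fit()
        gain, _ = res.call()
        planted = small_truth.planted_hiDE[(ct, "gain")]
        recovered = len(planted & gain.genes) / len(planted)
        assert recovered >= 0.7
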