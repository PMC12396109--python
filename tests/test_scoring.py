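"""RCC scores, mean fluxes and differential reaction comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from carveflux.sampling import FluxSampleMatrix
from carveflux.scoring import (
    correlation_matrix,
    differential_reactions,
    mean_fluxes,
    rank_by_rcc,
    rcc_histogram,
    rcc_scores,
    reaction_score_table,
)


def fsm(values, ids=None, method="global"):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"r{i}" for i in range(values.shape[1])]
    return FluxSampleMatrix(values=values, reaction_ids=ids, method=method, thinning=1, seed=0)


def brute_force_corr(V):
    """Double-loop covariance/sd correlation with the zero-variance convention."""
    n, p = V.shape
    out = np.zeros((p, p))
    sd = [np.sqrt(np.mean((V[:, j] - V[:, j].mean()) ** 2)) for j in range(p)]
    for i in range(p):
        for j in range(p):
            if sd[i] == 0 or sd[j] == 0:
                continue
            cov = np.mean((V[:, i] - V[:, i].mean()) * (V[:, j] - V[:, j].mean()))
            out[i, j] = cov / (sd[i] * sd[j])
    return out


class TestCorrelationMatrix:
    def test_identical_columns_fully_correlated(self, rng):
        x = rng.standard_normal(50)
        corr = correlation_matrix(fsm(np.column_stack([x, x])))
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_constant_column_zero_even_against_itself(self, rng):
        V = np.column_stack([np.full(30, 2.0), rng.standard_normal(30)])
        corr = correlation_matrix(fsm(V))
        assert (corr.iloc[0] == 0).all()
        assert corr.iloc[0, 0] == 0.0
        assert corr.iloc[1, 1] == 1.0

    def test_matches_double_loop_oracle(self, rng):
        V = rng.standard_normal((50, 8))
        V[:, 3] = 1.5  # one constant column
        corr = correlation_matrix(fsm(V))
        assert np.abs(corr.to_numpy() - brute_force_corr(V)).max() < 1e-10

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3"):
            correlation_matrix(fsm(np.zeros((2, 3))))


class TestRcc:
    def test_all_columns_equal_attains_reaction_count(self, rng):
        x = rng.uniform(size=40)
        V = np.column_stack([x, x, x])
        rcc = rcc_scores(correlation_matrix(fsm(V)))
        assert np.allclose(rcc, 3.0)  # upper endpoint: the number of reactions

    def test_constant_reaction_attains_zero(self, rng):
        V = np.column_stack([np.full(40, 5.0), rng.standard_normal(40)])
        rcc = rcc_scores(correlation_matrix(fsm(V)))
        assert rcc.iloc[0] == 0.0  # lower endpoint

    def test_bounded_by_reaction_count(self, rng):
        V = rng.standard_normal((60, 7))
        rcc = rcc_scores(correlation_matrix(fsm(V)))
        assert (rcc >= 0).all() and (rcc <= 7).all()

    def test_independent_reactions_approach_one(self, rng):
        V = rng.standard_normal((10_000, 2))
        rcc = rcc_scores(correlation_matrix(fsm(V)))
        assert np.allclose(rcc, 1.0, atol=0.05)  # self term + vanishing cross term


class TestMeanFluxes:
    def test_constant_column(self):
        mf = mean_fluxes(fsm(np.full((4, 1), 5.0)))
        assert mf["mean_flux"].iloc[0] == 5.0
        assert mf["flux_sd"].iloc[0] == 0.0

    def test_two_point_column(self):
        mf = mean_fluxes(fsm(np.array([[0.0], [10.0]])))
        assert mf["mean_flux"].iloc[0] == pytest.approx(5.0)
        assert mf["flux_sd"].iloc[0] == pytest.approx(7.0710678, abs=1e-6)

    def test_matches_accumulation_oracle(self, rng):
        V = rng.standard_normal((100, 5)) * 3 + 1
        mf = mean_fluxes(fsm(V))
        for j in range(5):
            assert mf["mean_flux"].iloc[j] == pytest.approx(V[:, j].sum() / 100, abs=1e-10)
            sd = np.sqrt(((V[:, j] - V[:, j].mean()) ** 2).sum() / 99)
            assert mf["flux_sd"].iloc[j] == pytest.approx(sd, abs=1e-10)


class TestDifferentialReactions:
    def scored(self, V, ids):
        samples = fsm(V, ids)
        return reaction_score_table(samples), samples

    def test_identical_matrices_show_no_difference(self, rng):
        V = rng.standard_normal((200, 3))
        ids = ["r0", "r1", "r2"]
        diff = differential_reactions(self.scored(V, ids), self.scored(V.copy(), ids))
        assert np.allclose(diff["delta_mean_flux"], 0.0)
        assert (diff["p_value"] >= 0.999).all()

    def test_constant_columns_use_degenerate_convention(self):
        a = self.scored(np.full((50, 1), 5.0), ["r0"])
        b = self.scored(np.zeros((50, 1)), ["r0"])
        diff = differential_reactions(a, b)
        assert diff.at["r0", "delta_mean_flux"] == 5.0
        assert diff.at["r0", "p_value"] == 0.0

    def test_welch_matches_reference_computation(self, rng):
        xa = rng.uniform(4, 6, size=1000)
        xb = rng.uniform(0, 1, size=1000)
        diff = differential_reactions(
            self.scored(xa[:, None], ["r0"]), self.scored(xb[:, None], ["r0"]),
            test_stride=1,
        )
        assert diff.at["r0", "delta_mean_flux"] == pytest.approx(xa.mean() - xb.mean())
        ref = stats.ttest_ind(xa, xb, equal_var=False).pvalue
        assert diff.at["r0", "p_value"] == pytest.approx(ref, rel=1e-9)
        assert diff.at["r0", "p_value"] < 1e-10

    def test_reaction_absent_from_one_model(self, rng):
        a = self.scored(np.column_stack([rng.uniform(2, 3, 100), rng.uniform(0, 1, 100)]),
                        ["r0", "only_a"])
        b = self.scored(rng.uniform(2, 3, 100)[:, None], ["r0"])
        diff = differential_reactions(a, b)
        row = diff.loc["only_a"]
        assert row["in_model_a"] and not row["in_model_b"]
        assert row["delta_mean_flux"] == pytest.approx(0.5, abs=0.1)
        assert row["p_value"] == 0.0  # mean far beyond sd/sqrt(n) of zero

    def test_antisymmetry(self, rng):
        ids = ["r0", "r1"]
        a = self.scored(rng.standard_normal((150, 2)), ids)
        b = self.scored(rng.standard_normal((150, 2)) + 1, ids)
        ab = differential_reactions(a, b)
        ba = differential_reactions(b, a)
        assert np.allclose(ab["delta_mean_flux"], -ba["delta_mean_flux"])
        assert np.allclose(ab["delta_rcc"], -ba["delta_rcc"])

    def test_disjoint_namespaces_rejected(self, rng):
        a = self.scored(rng.standard_normal((10, 1)), ["x"])
        b = self.scored(rng.standard_normal((10, 1)), ["y"])
        with pytest.raises(ValueError, match="disjoint"):
            differential_reactions(a, b)


class TestInvariantsAndViews:
    def test_rcc_scale_invariance_mean_scales(self, rng):
        V = rng.standard_normal((300, 4)) + 2
        t1 = reaction_score_table(fsm(V))
        t2 = reaction_score_table(fsm(V * 3.5))
        assert np.allclose(t1["rcc"], t2["rcc"], atol=1e-10)
        assert np.allclose(t1["mean_flux"] * 3.5, t2["mean_flux"], atol=1e-10)

    def test_rcc_brute_force_double_loop(self, rng):
        V = rng.standard_normal((50, 20))
        rcc = rcc_scores(correlation_matrix(fsm(V)))
        expected = np.abs(brute_force_corr(V)).sum(axis=1)
        # diagonal of the oracle is 1 for non-constant columns
        assert np.abs(rcc.to_numpy() - expected).max() < 1e-8

    def test_histogram_and_ranking(self, rng):
        V = rng.standard_normal((100, 6))
        table = reaction_score_table(fsm(V))
        hist = rcc_histogram(table["rcc"], bins=10)
        assert hist["count"].sum() == 6
        ranked = rank_by_rcc(table)
        assert ranked["rcc"].is_monotonic_decreasing
        assert ranked["rank"].tolist() == list(range(1, 7))

    def test_spearman_option(self, rng):
        V = rng.standard_normal((100, 3))
        c = correlation_matrix(fsm(V), method="spearman")
        ref = stats.spearmanr(V).statistic
        assert np.allclose(c.to_numpy(), ref, atol=1e-10)
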