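import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from hormnet import corrnet
from hormnet.io import (ExpressionMatrix, HormoneTable, InputError,
                        PathwayTable, SampleSheet)


class TestPearson:
    def test_perfect_linearity(self):
        r, p = corrnet.pearson_with_p([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r == 1.0 and p == 0.0

    def test_perfect_antilinearity(self):
        r, _ = corrnet.pearson_with_p([1, 2, 3], [3, 2, 1])
        assert r == -1.0

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            r, p = corrnet.pearson_with_p(x, y)
            r0, p0 = oracles.pearson_direct(x, y)
            assert r == pytest.approx(r0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            corrnet.pearson_with_p([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            corrnet.pearson_with_p([1, 2], [3, 4])


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.arange(1.0, 9.0)
        rho, _ = corrnet.spearman_with_p(x, np.exp(x))
        assert rho == 1.0

    def test_ties_match_midrank_oracle(self):
        rho, p = corrnet.spearman_with_p([1, 1, 2], [1, 2, 3])
        rho0, p0 = oracles.spearman_direct([1, 1, 2], [1, 2, 3])
        assert rho == pytest.approx(rho0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    @given(st.lists(st.integers(0, 5), min_size=4, max_size=12))
    @settings(max_examples=50)
    def test_symmetry(self, xs):
        rng = np.random.default_rng(sum(xs) + len(xs))
        ys = rng.integers(0, 5, len(xs))
        if len(set(xs)) < 2 or len(set(ys.tolist())) < 2:
            return
        r1, _ = corrnet.spearman_with_p(xs, ys)
        r2, _ = corrnet.spearman_with_p(ys, xs)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestConsensusRule:
    def test_spearman_failure_blocks_edge(self):
        assert not corrnet.passes_consensus(0.9, 0.01, 0.65, 0.04)

    def test_both_pass(self):
        assert corrnet.passes_consensus(0.95, 0.001, 0.92, 0.002)

    def test_strict_inequalities(self):
        assert not corrnet.passes_consensus(0.7, 0.01, 0.9, 0.01)
        assert not corrnet.passes_consensus(0.9, 0.05, 0.9, 0.01)


class TestZscoreRows:
    def test_constant_row_maps_to_zero(self):
        assert np.allclose(corrnet.zscore_rows([[1, 1, 1]]), 0.0)

    def test_normalization_identity(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 100, (4, 10))
        z = corrnet.zscore_rows(m)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_hand_computed_row(self):
        z = corrnet.zscore_rows([[0.0, 3.0]])
        assert np.allclose(z, [[-0.70710678, 0.70710678]])


def _net_inputs(n_nodes=6, n_days=4, n_reps=3, seed=0, values=None):
    """Build sheet/expr/pathway for one variety with gene nodes only."""
    from conftest import make_sheet
    sheet = make_sheet(n_days=n_days, n_reps=n_reps)
    samples = sheet.sample_ids
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_nodes)]
    if values is None:
        values = rng.uniform(1, 100, (n_nodes, len(samples)))
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            sheet=sheet)
    pw = PathwayTable(pd.DataFrame(
        [dict(gene_id=g, pathway="abscisic acid", family=f"F{i}")
         for i, g in enumerate(genes)]))
    return sheet, expr, pw, set(genes)


class TestBuildNetwork:
    def test_consensus_subset_of_single_method_networks(self):
        for seed in range(10):
            sheet, expr, pw, genes = _net_inputs(seed=seed)
            net = corrnet.build_network(expr, None, pw, genes, sheet, "V1",
                                        "drought")
            pairs = net.pairs
            pearson_only = set(map(tuple, pairs.loc[
                (pairs.pearson_r.abs() > 0.7) & (pairs.pearson_p < 0.05),
                ["node_a", "node_b"]].to_numpy()))
            spearman_only = set(map(tuple, pairs.loc[
                (pairs.spearman_rho.abs() > 0.7) & (pairs.spearman_p < 0.05),
                ["node_a", "node_b"]].to_numpy()))
            edges = {e.endpoints for e in net.edges}
            assert edges <= pearson_only and edges <= spearman_only

    def test_pair_stats_match_scalar_functions(self):
        sheet, expr, pw, genes = _net_inputs(seed=3)
        net = corrnet.build_network(expr, None, pw, genes, sheet, "V1", "control")
        data = np.log2(expr.subset(samples=sheet.samples_for("V1", "control"))
                       .to_numpy() + 1.0)
        labels = expr.gene_ids
        for row in net.pairs.itertuples(index=False):
            i, j = labels.index(row.node_a), labels.index(row.node_b)
            r, p = corrnet.pearson_with_p(data[i], data[j])
            rho, sp = corrnet.spearman_with_p(data[i], data[j])
            assert row.pearson_r == pytest.approx(r, abs=1e-10)
            assert row.pearson_p == pytest.approx(p, abs=1e-10)
            assert row.spearman_rho == pytest.approx(rho, abs=1e-10)
            assert row.spearman_p == pytest.approx(sp, abs=1e-10)

    def test_sample_permutation_invariance(self):
        sheet, expr, pw, genes = _net_inputs(seed=9)
        net1 = corrnet.build_network(expr, None, pw, genes, sheet, "V1", "drought")
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.df.shape[1])
        expr2 = ExpressionMatrix(expr.df.iloc[:, perm], sheet=sheet)
        net2 = corrnet.build_network(expr2, None, pw, genes, sheet, "V1", "drought")
        assert net1.edge_pairs() == net2.edge_pairs()

    def test_small_n_threshold_consistency(self):
        # with n=5 samples, p<0.05 requires |r| > 0.8783 (t boundary)
        for seed in range(100):
            sheet, expr, pw, genes = _net_inputs(n_nodes=4, n_days=4, n_reps=3,
                                                 seed=seed)
            net = corrnet.build_network(expr, None, pw, genes, sheet, "V1",
                                        "drought", per_stage_means=True)
            for e in net.edges:
                assert abs(e.pearson_r) > 0.8783
                assert abs(e.spearman_rho) > 0.8783

    def test_constant_node_dropped(self):
        sheet, expr, pw, genes = _net_inputs(seed=4)
        vals = expr.df.copy()
        vals.loc["g0"] = 7.0
        expr2 = ExpressionMatrix(vals, sheet=sheet)
        net = corrnet.build_network(expr2, None, pw, genes, sheet, "V1", "drought")
        assert "g0" not in net.nodes

    def test_too_few_samples_error(self):
        sheet, expr, pw, genes = _net_inputs(n_days=1, n_reps=1)
        with pytest.raises(InputError):
            corrnet.build_network(expr, None, pw, genes, sheet, "V1", "drought")

    def test_hormones_become_nodes(self, small_dataset):
        ds = small_dataset
        genes = set(ds.pathways.gene_ids[:8])
        net = corrnet.build_network(ds.expression, ds.hormones, ds.pathways,
                                    genes, ds.sheet, "V1", "drought")
        kinds = {info.kind for info in net.nodes.values()}
        assert "hormone" in kinds
        assert {"ZR", "IAA", "GA3", "ABA", "BR", "JA-me"} <= set(net.nodes)

    def test_per_stage_means_degenerate_replicates(self):
        # identical replicates: per-stage means equal replicate values,
        # so pairwise coefficients agree between the two modes
        sheet, expr, pw, genes = _net_inputs(seed=6)
        day_of = sheet.day_of()
        cond = dict(zip(sheet.df["sample_id"], sheet.df["condition"]))
        vals = expr.df.copy()
        for day in {d for d in day_of.values()}:
            cols = [s for s in vals.columns
                    if day_of[s] == day and (day == 0 or cond[s] == "drought")]
            if cols:
                vals[cols] = np.tile(vals[cols[0]].to_numpy()[:, None],
                                     (1, len(cols)))
        expr2 = ExpressionMatrix(vals, sheet=sheet)
        net_rep = corrnet.build_network(expr2, None, pw, genes, sheet, "V1",
                                        "drought")
        net_mean = corrnet.build_network(expr2, None, pw, genes, sheet, "V1",
                                         "drought", per_stage_means=True)
        rep = net_rep.pairs.set_index(["node_a", "node_b"])["pearson_r"]
        mean = net_mean.pairs.set_index(["node_a", "node_b"])["pearson_r"]
        assert np.allclose(rep.sort_index(), mean.sort_index(), atol=1e-9)
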