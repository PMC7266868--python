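import filecmp

import numpy as np
import pytest

import oracles
from hormnet import deg, synthio
from hormnet.io import ConfigError


class TestGenerateDesign:
    def test_full_design_row_count(self):
        cfg = synthio.SimConfig()
        sheet = synthio.generate_design(cfg)
        # 2 varieties x (1 shared d0 slot + 2 conditions x 4 days) x 3 reps
        assert len(sheet.df) == 2 * (1 + 2 * 4) * 3 == 54

    def test_minimal_design_single_row(self):
        cfg = synthio.SimConfig(n_varieties=1, conditions=("control",),
                                days=(0,), n_replicates=1, hub_partners=(),
                                deg_fraction=0.0)
        assert len(synthio.generate_design(cfg).df) == 1

    def test_non_increasing_days_rejected(self):
        with pytest.raises(ConfigError):
            synthio.generate_design(synthio.SimConfig(days=(0, 5, 2)))

    def test_days_must_start_at_zero(self):
        with pytest.raises(ConfigError):
            synthio.SimConfig(days=(2, 5)).validate()

    def test_day0_shared_selection(self):
        sheet = synthio.generate_design(synthio.SimConfig())
        ctrl = set(sheet.samples_for("V1", "control"))
        drt = set(sheet.samples_for("V1", "drought"))
        assert len(ctrl & drt) == 3  # the three d0 replicates

    def test_invalid_planted_r_rejected(self):
        with pytest.raises(ConfigError):
            synthio.SimConfig(planted_r=0.5).validate()

    def test_partner_overlap_rejected(self):
        with pytest.raises(ConfigError):
            synthio.SimConfig(hub_gene="G002").validate()


class TestSimulateExpression:
    def test_reproducibility(self, small_cfg):
        d = synthio.generate_design(small_cfg)
        e1, _ = synthio.simulate_expression(small_cfg, d)
        e2, _ = synthio.simulate_expression(small_cfg, d)
        assert e1.df.equals(e2.df)

    def test_noiseless_planted_fold_change(self):
        cfg = synthio.SimConfig(n_varieties=1, n_genes=20, n_pathway_genes=5,
                                deg_fraction=0.5, deg_log2fc=2.0,
                                dispersion=0.0, hub_partners=(), seed=6)
        design = synthio.generate_design(cfg)
        expr, truth = synthio.simulate_expression(cfg, design)
        up = next(g for g, fc in truth.deg_genes[2].items() if fc > 0)
        treat = expr.subset(genes=[up],
                            samples=design.replicates_at("V1", "drought", 2))
        ctrl = expr.subset(genes=[up],
                           samples=design.replicates_at("V1", "control", 2))
        lfc = deg.log2fc(treat.to_numpy().ravel(), ctrl.to_numpy().ravel(), 1.0)
        assert lfc == pytest.approx(2.0, abs=1e-9)

    def test_truth_edges_symmetric_and_hub_dominant(self, small_dataset):
        truth = small_dataset.truth
        for a, b, s in truth.planted_edges:
            assert (b, a, s) in truth.planted_edges
        counts = {}
        for a, _b, _s in truth.planted_edges:
            counts[a] = counts.get(a, 0) + 1
        hub_count = counts.pop(truth.hub)
        assert hub_count > max(counts.values())

    def test_non_negative_fpkm(self, small_dataset):
        assert (small_dataset.expression.df.to_numpy() >= 0).all()

    def _drought_control_r(self, seed):
        cfg = synthio.SimConfig(n_varieties=1, n_genes=20, n_pathway_genes=10,
                                deg_fraction=0.5, planted_r=0.95, seed=seed,
                                hub_partners=(("G002", "+"), ("G005", "-")))
        design = synthio.generate_design(cfg)
        expr, _ = synthio.simulate_expression(cfg, design)
        out = {}
        for cond in ("drought", "control"):
            sel = design.samples_for("V1", cond)
            m = np.log2(expr.subset(genes=["G001", "G002"], samples=sel)
                        .to_numpy() + 1.0)
            out[cond], _ = oracles.pearson_direct(m[0], m[1])
        return out

    def test_planted_pair_monte_carlo(self):
        drought_hits = control_hits = 0
        for seed in range(100):
            r = self._drought_control_r(seed)
            drought_hits += r["drought"] > 0.7
            control_hits += abs(r["control"]) > 0.7
        assert drought_hits >= 95
        assert control_hits <= 10

    def test_planted_separation_stochastic_dominance(self):
        dr, cr = [], []
        for seed in range(40):
            r = self._drought_control_r(seed + 500)
            dr.append(r["drought"])
            cr.append(abs(r["control"]))
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert np.quantile(dr, q) > np.quantile(cr, q)


class TestSimulateHormones:
    def test_noiseless_effect_ratio(self):
        cfg = synthio.SimConfig(n_varieties=1, hub_partners=(), seed=3)
        design = synthio.generate_design(cfg)
        horm = synthio.simulate_hormones(cfg, design, aba_effect=3.0,
                                         noise_sd=0.0)
        d2_d = horm.df[design.replicates_at("V1", "drought", 2)].loc["ABA"]
        d2_c = horm.df[design.replicates_at("V1", "control", 2)].loc["ABA"]
        assert d2_d.mean() / d2_c.mean() == pytest.approx(3.0, abs=1e-9)

    def test_positivity_and_required_contrasts(self, small_dataset):
        horm = small_dataset.hormones
        sheet = small_dataset.sheet
        assert (horm.df.to_numpy() > 0).all()
        for day in (2, 5, 15):
            d = horm.df[sheet.replicates_at("V1", "drought", day)].loc["ABA"].mean()
            c = horm.df[sheet.replicates_at("V1", "control", day)].loc["ABA"].mean()
            assert d > c
        for day in (5, 15, 30):
            d = horm.df[sheet.replicates_at("V1", "drought", day)].loc["IAA"].mean()
            c = horm.df[sheet.replicates_at("V1", "control", day)].loc["IAA"].mean()
            assert d > c

    def test_aba_hub_coupling_sign(self):
        rs = []
        for seed in range(30):
            cfg = synthio.SimConfig(n_varieties=1, n_genes=20,
                                    n_pathway_genes=10, deg_fraction=0.5,
                                    seed=seed,
                                    hub_partners=(("G002", "+"),))
            design = synthio.generate_design(cfg)
            expr, _ = synthio.simulate_expression(cfg, design)
            sel = design.samples_for("V1", "drought")
            hub_vals = np.log2(expr.subset(genes=["G001"], samples=sel)
                               .to_numpy().ravel() + 1.0)
            latent = dict(zip(sel, hub_vals))
            horm = synthio.simulate_hormones(cfg, design, aba_hub_r=0.8,
                                             latent=latent)
            aba = np.log2(horm.df[sel].loc["ABA"].to_numpy() + 1.0)
            r, _ = oracles.pearson_direct(hub_vals, aba)
            rs.append(r)
        assert np.mean(rs) > 0.4
        assert np.mean(np.array(rs) > 0) >= 0.9


class TestFixture:
    def test_fixture_deterministic_outputs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synthio.write_fixture(d1)
        synthio.write_fixture(d2)
        files = [p.name for p in d1.iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
        assert sorted(match) == sorted(files)
        assert not mismatch and not errors

    def test_fixture_pivotal_hub_is_pp2c(self, fig4_run):
        assert fig4_run["result"].pivotal() == ["PP2C"]

    def test_fixture_pp2c_aarr_negative(self, fig4_run):
        edges = {e.pair: e for e in fig4_run["result"].common.edges}
        assert edges[frozenset({"PP2C", "A-ARR"})].sign == "-"
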