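"""Property-based validation experiments over synthetic data.

Each function runs the pipeline on freshly generated data and returns
measured quantities (recovery rates, false-positive rates, subset-law
violation counts); thresholds are asserted by the callers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import corrnet, deg, hubs, pipeline, synthio
from .io import ExpressionMatrix, PathwayTable


def _random_net_inputs(n_nodes: int, rng: np.random.Generator):
    cfg = synthio.SimConfig(n_varieties=1, days=(0, 2, 5, 15), n_replicates=3,
                            hub_partners=(), deg_fraction=0.0, n_genes=n_nodes,
                            n_pathway_genes=n_nodes)
    sheet = synthio.generate_design(cfg)
    genes = [f"g{i}" for i in range(n_nodes)]
    values = rng.uniform(1.0, 100.0, (n_nodes, len(sheet.sample_ids)))
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=sheet.sample_ids), sheet=sheet)
    pw = PathwayTable(pd.DataFrame(
        [dict(gene_id=g, pathway="abscisic acid", family=f"F{i}")
         for i, g in enumerate(genes)]))
    return sheet, expr, pw, set(genes)


def consensus_subset_check(n_seeds: int = 200, n_nodes: int = 8,
                           seed: int = 0) -> dict:
    """Count violations of: consensus edges form a subset of each
    single-method edge set at the same thresholds."""
    violations = 0
    total_edges = 0
    for i in range(n_seeds):
        rng = np.random.default_rng([seed, 100, i])
        sheet, expr, pw, genes = _random_net_inputs(n_nodes, rng)
        net = corrnet.build_network(expr, None, pw, genes, sheet, "V1", "drought")
        pairs = net.pairs
        pearson_ok = set(map(tuple, pairs.loc[
            (pairs.pearson_r.abs() > 0.7) & (pairs.pearson_p < 0.05),
            ["node_a", "node_b"]].to_numpy()))
        spearman_ok = set(map(tuple, pairs.loc[
            (pairs.spearman_rho.abs() > 0.7) & (pairs.spearman_p < 0.05),
            ["node_a", "node_b"]].to_numpy()))
        edges = {e.endpoints for e in net.edges}
        total_edges += len(edges)
        if not (edges <= pearson_ok and edges <= spearman_ok):
            violations += 1
    return {"n_seeds": n_seeds, "violations": violations,
            "total_edges": total_edges}


def null_calibration(n_seeds: int = 50, n_genes: int = 200,
                     n_pathway_genes: int = 25, seed: int = 0) -> dict:
    """DEG flag rate and consensus edge density on fully null data."""
    deg_rates, densities = [], []
    for i in range(n_seeds):
        cfg = synthio.SimConfig(n_varieties=1, n_genes=n_genes,
                                n_pathway_genes=n_pathway_genes,
                                deg_fraction=0.0, hub_partners=(),
                                seed=seed * 1_000_003 + i)
        ds_sheet = synthio.generate_design(cfg)
        expr, _ = synthio.simulate_expression(cfg, ds_sheet)
        table = deg.call_stages(expr, ds_sheet, "V1")
        deg_rates.append(len(deg.deg_union(table)) / n_genes)
        pw = synthio.pathway_table(cfg)
        pathway_genes = {g for g, p in pw.pathway_of().items() if p}
        net = corrnet.build_network(expr, None, pw, pathway_genes, ds_sheet,
                                    "V1", "drought")
        k = len(net.nodes)
        densities.append(len(net.edges) / (k * (k - 1) / 2))
    return {"n_seeds": n_seeds, "n_genes": n_genes,
            "mean_deg_rate": float(np.mean(deg_rates)),
            "max_deg_rate": float(np.max(deg_rates)),
            "mean_density": float(np.mean(densities)),
            "max_density": float(np.max(densities))}


def planted_recovery(n_runs: int = 100, seed: int = 0, *,
                     n_genes: int = 200, n_pathway_genes: int = 30,
                     planted_r: float = 0.95, deg_log2fc: float = 3.0) -> dict:
    """Recovery of planted edges, planted DEGs and the planted hub."""
    edge_hits = edge_total = 0
    deg_hits = deg_total = 0
    false_pairs = possible_null_pairs = 0
    hub_pivotal_runs = 0
    for i in range(n_runs):
        cfg = synthio.SimConfig(
            n_varieties=1, n_genes=n_genes, n_pathway_genes=n_pathway_genes,
            deg_fraction=0.1, deg_log2fc=deg_log2fc, planted_r=planted_r,
            seed=seed * 1_000_003 + i)
        sheet = synthio.generate_design(cfg)
        expr, truth = synthio.simulate_expression(cfg, sheet)
        table = deg.call_stages(expr, sheet, "V1")
        called = deg.deg_union(table)
        planted_degs = set(truth.deg_genes[2])
        deg_hits += len(called & planted_degs)
        deg_total += len(planted_degs)
        pw = synthio.pathway_table(cfg)
        net = corrnet.build_network(expr, None, pw, called, sheet, "V1",
                                    "drought")
        found = net.edge_pairs()
        planted_pairs = truth.edge_pairs()
        edge_hits += len(found & planted_pairs)
        edge_total += len(planted_pairs)
        k = len(net.nodes)
        possible = k * (k - 1) / 2 - len(planted_pairs)
        if possible > 0:
            false_pairs += len(found - planted_pairs)
            possible_null_pairs += possible
        reports = hubs.degree_centrality(net)
        if truth.hub in hubs.pivotal_nodes(reports):
            hub_pivotal_runs += 1
    return {"n_runs": n_runs,
            "edge_recovery": edge_hits / edge_total,
            "deg_recovery": deg_hits / deg_total,
            "false_edge_rate": (false_pairs / possible_null_pairs
                                if possible_null_pairs else 0.0),
            "hub_pivotal_runs": hub_pivotal_runs}


def fixture_report() -> dict:
    """Deterministic fixture pushed end to end, with sign/degree checks."""
    expr, horm, pathways, _ = synthio.fig4_fixture()
    sheet = synthio.fixture_design()
    res = pipeline.run_pipeline(expr, horm, pathways, sheet)
    truth = synthio.fixture_truth()
    edges = {e.pair: e for e in res.common.edges}
    degrees = {r.node: r.degree for r in res.hub_reports}
    hub_degree = degrees.get("PP2C", 0)
    others = [d for n, d in degrees.items() if n != "PP2C"]
    signs_ok = all(
        frozenset({"PP2C", fam}) in edges
        and edges[frozenset({"PP2C", fam})].sign == "+"
        for fam in truth["positive"]) and all(
        frozenset({"PP2C", fam}) in edges
        and edges[frozenset({"PP2C", fam})].sign == "-"
        for fam in truth["negative"])
    return {"pivotal": res.pivotal(),
            "hub_degree": hub_degree,
            "max_other_degree": max(others) if others else 0,
            "strictly_maximal": bool(others) and hub_degree > max(others),
            "signs_ok": signs_ok,
            "n_common_edges": len(res.common.edges)}
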