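"""End-to-end orchestration: DEG calling -> per-condition networks ->
differential comparison -> cross-variety common network -> hub report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import corrnet, deg, diffnet, hubs
from .io import (ExpressionMatrix, HomologMap, HormoneTable, PathwayTable,
                 SampleSheet)

log = logging.getLogger("hormnet")


@dataclass(frozen=True)
class PipelineResult:
    deg_tables: dict[str, pd.DataFrame]                 # variety -> DEG table
    networks: dict[tuple[str, str], corrnet.CorrelationNetwork]
    differential: dict[str, diffnet.DifferentialNetwork]
    common: diffnet.CommonNetwork
    hub_reports: list[hubs.HubReport]
    hub_summary: dict = field(default_factory=dict)

    def pivotal(self) -> list[str]:
        return hubs.pivotal_nodes(self.hub_reports)


def run_pipeline(expr: ExpressionMatrix, hormones: HormoneTable | None,
                 pathways: PathwayTable, sheet: SampleSheet, *,
                 varieties: list[str] | None = None,
                 fc_threshold: float = deg.FC_THRESHOLD,
                 fdr_threshold: float = deg.FDR_THRESHOLD,
                 pseudocount: float = deg.PSEUDOCOUNT,
                 r_threshold: float = corrnet.R_THRESHOLD,
                 p_threshold: float = corrnet.P_THRESHOLD,
                 per_stage_means: bool = False,
                 mode: str = "drought-present",
                 deg_genes: dict[str, set[str]] | None = None
                 ) -> PipelineResult:
    """Run the full analysis for the given varieties.

    The network node set per variety is the union of its stage DEG sets
    (overridable via ``deg_genes``) intersected with pathway-annotated
    genes, plus all hormones.
    """
    varieties = varieties or sheet.varieties
    deg_tables: dict[str, pd.DataFrame] = {}
    networks: dict[tuple[str, str], corrnet.CorrelationNetwork] = {}
    differential: dict[str, diffnet.DifferentialNetwork] = {}

    for variety in varieties:
        table = deg.call_stages(expr, sheet, variety,
                                fc_threshold=fc_threshold,
                                fdr_threshold=fdr_threshold,
                                pseudocount=pseudocount)
        deg_tables[variety] = table
        genes = (deg_genes[variety] if deg_genes is not None
                 else deg.deg_union(table))
        for condition in ("control", "drought"):
            networks[(variety, condition)] = corrnet.build_network(
                expr, hormones, pathways, genes, sheet, variety, condition,
                r_threshold=r_threshold, p_threshold=p_threshold,
                per_stage_means=per_stage_means)
        differential[variety] = diffnet.differential_edges(
            networks[(variety, "control")], networks[(variety, "drought")])

    common = diffnet.common_network(
        {v: networks[(v, "drought")] for v in varieties},
        mode=mode, diff_nets=differential)
    reports = hubs.degree_centrality(common)
    summary = hubs.hub_summary(reports, common)
    return PipelineResult(deg_tables=deg_tables, networks=networks,
                          differential=differential, common=common,
                          hub_reports=reports, hub_summary=summary)
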