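"""Connectivity ranking and pivotal-hub identification.

Degree is the count of distinct neighbor nodes (a mixed family edge counts
once).  Ranks use competition ranking (ties share the smallest applicable
rank); all maximal-degree nodes are flagged pivotal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class HubReport:
    node: str
    degree: int
    rank: int
    is_pivotal: bool
    pathway: str = ""


def degree_centrality(net) -> list[HubReport]:
    """Degree report for a correlation or common network, sorted by
    (degree desc, label asc)."""
    neighbors: dict[str, set[str]] = {n: set() for n in net.node_labels()}
    for e in net.edges:
        a, b = e.endpoints
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    if not neighbors:
        return []
    ordered = sorted(neighbors, key=lambda n: (-len(neighbors[n]), n))
    max_deg = len(neighbors[ordered[0]])

    pathways = getattr(net, "pathways", None) or {}
    if not pathways:
        nodes_attr = getattr(net, "nodes", None)
        if isinstance(nodes_attr, dict):
            pathways = {n: getattr(info, "pathway", "")
                        for n, info in nodes_attr.items()}

    reports = []
    prev_deg, prev_rank = None, 0
    for i, node in enumerate(ordered, start=1):
        deg = len(neighbors[node])
        rank = prev_rank if deg == prev_deg else i
        prev_deg, prev_rank = deg, rank
        reports.append(HubReport(node=node, degree=deg, rank=rank,
                                 is_pivotal=(deg == max_deg),
                                 pathway=pathways.get(node, "")))
    return reports


def pivotal_nodes(reports: list[HubReport]) -> list[str]:
    return [r.node for r in reports if r.is_pivotal]


def hub_summary(reports: list[HubReport], net=None) -> dict:
    """JSON-ready summary: pivotal node(s) with degree and incident-edge signs."""
    if not reports:
        return {"pivotal": [], "message": "no hub: network is empty"}
    pivots = [r for r in reports if r.is_pivotal]
    out = {"pivotal": [], "n_nodes": len(reports)}
    for r in pivots:
        entry = {"node": r.node, "degree": r.degree, "pathway": r.pathway}
        if net is not None:
            signs = {"+": 0, "-": 0, "mixed": 0}
            for e in net.edges:
                if r.node in e.endpoints:
                    signs[e.sign] += 1
            entry["edge_signs"] = signs
        out["pivotal"].append(entry)
    return out


def write_hub_report(reports: list[HubReport], path) -> None:
    import pandas as pd
    pd.DataFrame([asdict(r) for r in reports]).to_csv(path, sep="\t", index=False)


def write_hub_summary(summary: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
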