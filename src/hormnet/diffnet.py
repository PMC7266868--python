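"""Differential edge comparison and the cross-variety common family network.

Edges are compared between conditions by canonical endpoint pair
(gained = drought only, lost = control only, stable = both).  The common
network collapses gene-level drought edges to protein-family level: a
family pair qualifies iff every variety's drought network contains at least
one qualifying gene-level edge between those families; mean coefficients
are the arithmetic means of the contributing Pearson r values per sign, and
family pairs carrying both signs become a single "mixed" edge labelled with
the variety (or varieties) contributing the minority sign.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from .corrnet import CorrelationNetwork, Edge
from .io import InputError

log = logging.getLogger("hormnet")

MODES = ("drought-present", "drought-specific")


@dataclass(frozen=True)
class DifferentialNetwork:
    variety: str
    gained_edges: tuple[Edge, ...]   # drought only
    lost_edges: tuple[Edge, ...]     # control only
    stable_edges: tuple[Edge, ...]   # both (drought attributes kept)

    def gained_pairs(self) -> set[frozenset]:
        return {e.pair for e in self.gained_edges}

    def summary(self) -> dict:
        return {"variety": self.variety, "gained": len(self.gained_edges),
                "lost": len(self.lost_edges), "stable": len(self.stable_edges)}


def differential_edges(control_net: CorrelationNetwork,
                       drought_net: CorrelationNetwork) -> DifferentialNetwork:
    """Classify edges as gained / lost / stable between the two conditions."""
    if control_net.variety != drought_net.variety:
        raise InputError(
            f"variety mismatch: {control_net.variety!r} vs {drought_net.variety!r}")
    ctrl = control_net.by_pair()
    drt = drought_net.by_pair()
    gained = tuple(e for e in drought_net.edges if e.pair not in ctrl)
    lost = tuple(e for e in control_net.edges if e.pair not in drt)
    stable = tuple(e for e in drought_net.edges if e.pair in ctrl)
    return DifferentialNetwork(variety=drought_net.variety, gained_edges=gained,
                               lost_edges=lost, stable_edges=stable)


# ---------------------------------------------------------------------------
# family-level collapse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyEdge:
    """Protein-family-level edge with per-sign mean Pearson coefficients."""

    family_a: str
    family_b: str
    sign: str                      # "+", "-", or "mixed"
    mean_pos: float | None = None  # mean of positive contributing r
    mean_neg: float | None = None  # mean of negative contributing r
    n_pos: int = 0
    n_neg: int = 0
    variety_labels: tuple[str, ...] = ()

    @property
    def endpoints(self) -> tuple[str, str]:
        return (self.family_a, self.family_b)

    @property
    def pair(self) -> frozenset:
        return frozenset(self.endpoints)

    @property
    def mean_coefficient(self) -> float | None:
        if self.sign == "+":
            return self.mean_pos
        if self.sign == "-":
            return self.mean_neg
        return None  # mixed: both components carried separately


def _family_key(edge: Edge, family_of: dict[str, str]) -> tuple[str, str] | None:
    fa = family_of.get(edge.node_a)
    fb = family_of.get(edge.node_b)
    if not fa or not fb:
        return None
    if fa == fb:
        return None  # within-family copies collapse to a self-pair; dropped
    return tuple(sorted((fa, fb)))


def collapse_to_family(edges, family_of: dict[str, str]) -> tuple[FamilyEdge, ...]:
    """Collapse gene-level edges to family level (hormones are their own family).

    Per (family pair, sign) group the mean coefficient is the arithmetic mean
    of member pearson_r; pairs with both signs merge into one mixed edge.
    Idempotent on already family-level edges (family_of maps a family to
    itself for labels absent from the table).
    """
    groups: dict[tuple[str, str], dict[str, list[float]]] = defaultdict(
        lambda: {"+": [], "-": []})
    skipped = []
    for e in edges:
        key = _family_key(e, family_of)
        if key is None:
            fa = family_of.get(e.node_a)
            fb = family_of.get(e.node_b)
            if not fa or not fb:
                skipped.append(e.endpoints)
            continue
        groups[key][e.sign].append(e.pearson_r)
    if skipped:
        log.warning("collapse_to_family: %d edge(s) with unannotated endpoint "
                    "excluded: %s", len(skipped), skipped[:5])
    out = []
    for (fa, fb), by_sign in sorted(groups.items()):
        pos, neg = by_sign["+"], by_sign["-"]
        sign = "mixed" if pos and neg else ("+" if pos else "-")
        out.append(FamilyEdge(
            family_a=fa, family_b=fb, sign=sign,
            mean_pos=sum(pos) / len(pos) if pos else None,
            mean_neg=sum(neg) / len(neg) if neg else None,
            n_pos=len(pos), n_neg=len(neg)))
    return tuple(out)


@dataclass(frozen=True)
class CommonNetwork:
    """Family-level edges shared by all varieties' drought networks."""

    varieties: tuple[str, ...]
    mode: str
    nodes: tuple[str, ...]
    edges: tuple[FamilyEdge, ...]
    pathways: dict[str, str] = None  # family/hormone label -> pathway

    def node_labels(self) -> list[str]:
        return list(self.nodes)

    def edge_pairs(self) -> set[frozenset]:
        return {e.pair for e in self.edges}


def _node_family_map(net: CorrelationNetwork) -> dict[str, str]:
    out = {}
    for label, info in net.nodes.items():
        out[label] = info.family if info.family else (
            label if info.kind == "hormone" else "")
    return out


def common_network(drought_nets: dict[str, CorrelationNetwork], *,
                   mode: str = "drought-present",
                   diff_nets: dict[str, DifferentialNetwork] | None = None
                   ) -> CommonNetwork:
    """Build the family-level network common to all varieties under drought.

    ``mode="drought-present"`` (default): a family pair qualifies if every
    variety's drought network has >= 1 gene-level edge between those
    families.  ``mode="drought-specific"``: the contributing edges must also
    be in the variety's gained (drought-only) edge set, which requires
    ``diff_nets``.  Mean coefficients pool contributing edges from all
    varieties per sign.
    """
    if mode not in MODES:
        raise InputError(f"unknown mode {mode!r}; choose one of {MODES}")
    if mode == "drought-specific" and diff_nets is None:
        raise InputError("drought-specific mode requires diff_nets")
    varieties = tuple(sorted(drought_nets))

    # per-variety qualifying gene-level edges, keyed by family pair
    per_variety: dict[str, dict[tuple[str, str], list[Edge]]] = {}
    for v in varieties:
        net = drought_nets[v]
        fam = _node_family_map(net)
        allowed = None
        if mode == "drought-specific":
            allowed = diff_nets[v].gained_pairs()
        bucket: dict[tuple[str, str], list[Edge]] = defaultdict(list)
        for e in net.edges:
            if allowed is not None and e.pair not in allowed:
                continue
            key = _family_key(e, fam)
            if key is not None:
                bucket[key].append(e)
        per_variety[v] = bucket

    shared = set.intersection(*(set(per_variety[v]) for v in varieties)) \
        if varieties else set()

    edges = []
    for key in sorted(shared):
        fa, fb = key
        pos_all, neg_all = [], []
        pos_vars, neg_vars = set(), set()
        for v in varieties:
            for e in per_variety[v][key]:
                if e.sign == "+":
                    pos_all.append(e.pearson_r)
                    pos_vars.add(v)
                else:
                    neg_all.append(e.pearson_r)
                    neg_vars.add(v)
        if pos_all and neg_all:
            sign = "mixed"
            # label the variety(ies) contributing the minority sign
            if len(pos_vars) != len(neg_vars):
                labels = pos_vars if len(pos_vars) < len(neg_vars) else neg_vars
            elif len(pos_all) != len(neg_all):
                labels = pos_vars if len(pos_all) < len(neg_all) else neg_vars
            else:
                labels = pos_vars | neg_vars
            labels = tuple(sorted(labels))
        else:
            sign = "+" if pos_all else "-"
            labels = ()
        edges.append(FamilyEdge(
            family_a=fa, family_b=fb, sign=sign,
            mean_pos=sum(pos_all) / len(pos_all) if pos_all else None,
            mean_neg=sum(neg_all) / len(neg_all) if neg_all else None,
            n_pos=len(pos_all), n_neg=len(neg_all), variety_labels=labels))

    nodes = tuple(sorted({n for e in edges for n in e.endpoints}))
    pathways: dict[str, str] = {}
    for v in varieties:
        for info in drought_nets[v].nodes.values():
            label = info.family
            if label and label not in pathways:
                pathways[label] = info.pathway
    pathways = {n: pathways.get(n, "") for n in nodes}
    return CommonNetwork(varieties=varieties, mode=mode, nodes=nodes,
                         edges=tuple(edges), pathways=pathways)
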