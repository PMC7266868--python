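"""Consensus (Pearson AND Spearman) correlation networks per variety x condition.

An edge between two nodes (hormone-pathway gene or hormone) is retained iff
|pearson_r| > r_threshold AND pearson_p < p_threshold AND
|spearman_rho| > r_threshold AND spearman_p < p_threshold
(strict inequalities).  p-values for both methods come from the t
approximation  t = r * sqrt((n-2) / (1 - r^2))  with n-2 degrees of freedom;
for Spearman this is approximate and documented as such.

Correlations are computed on log2(x + 1)-transformed values (genes and
hormones alike); Spearman is invariant to this monotone transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import (HORMONES, ExpressionMatrix, HormoneTable, InputError,
                 PathwayTable, SampleSheet)

log = logging.getLogger("hormnet")

R_THRESHOLD = 0.7
P_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# scalar correlation primitives
# ---------------------------------------------------------------------------

def _t_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation coefficient via the Student-t transform."""
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * _sps.t.sf(abs(t), n - 2)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided t-approximation p-value.

    Raises :class:`InputError` for n < 3, non-finite values, or zero
    variance in either vector (such pairs are excluded upstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("pearson_with_p: x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise InputError(f"pearson_with_p: need n >= 3, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("pearson_with_p: non-finite values")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise InputError("pearson_with_p: zero variance")
    r = float(np.clip(float(xc @ yc) / denom, -1.0, 1.0))
    return r, _t_pvalue(r, n)


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho (mid-ranks for ties) with the same t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = _sps.rankdata(x, method="average")
    ry = _sps.rankdata(y, method="average")
    return pearson_with_p(rx, ry)


def passes_consensus(pearson_r: float, pearson_p: float, spearman_rho: float,
                     spearman_p: float, r_threshold: float = R_THRESHOLD,
                     p_threshold: float = P_THRESHOLD) -> bool:
    """Edge retention rule: coefficient above threshold and significant
    under BOTH methods (strict inequalities)."""
    return (abs(pearson_r) > r_threshold and pearson_p < p_threshold and
            abs(spearman_rho) > r_threshold and spearman_p < p_threshold)


def zscore_rows(m) -> np.ndarray:
    """Per-row z-scores of log2(x + 1) values (display transform).

    Uses the sample standard deviation (ddof=1); rows with zero sd map to
    all-zeros.
    """
    m = np.asarray(m, dtype=float)
    lg = np.log2(m + 1.0)
    mean = lg.mean(axis=1, keepdims=True)
    sd = lg.std(axis=1, ddof=1, keepdims=True) if lg.shape[1] > 1 else np.zeros_like(mean)
    out = np.zeros_like(lg)
    np.divide(lg - mean, sd, out=out, where=sd > 0)
    return out


# ---------------------------------------------------------------------------
# network containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edge:
    """Undirected consensus edge in canonical form (node_a < node_b)."""

    node_a: str
    node_b: str
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise InputError(f"edge not canonical: {self.node_a!r} >= {self.node_b!r}")

    @property
    def sign(self) -> str:
        return "+" if self.pearson_r >= 0 else "-"

    @property
    def endpoints(self) -> tuple[str, str]:
        return (self.node_a, self.node_b)

    @property
    def pair(self) -> frozenset:
        return frozenset(self.endpoints)


@dataclass(frozen=True)
class NodeInfo:
    kind: str  # "gene" | "hormone"
    pathway: str = ""
    family: str = ""


@dataclass(frozen=True)
class CorrelationNetwork:
    variety: str
    condition: str
    nodes: dict[str, NodeInfo]
    edges: tuple[Edge, ...]
    pairs: pd.DataFrame = field(repr=False, default=None)  # all evaluated pairs

    def node_labels(self) -> list[str]:
        return list(self.nodes)

    def edge_pairs(self) -> set[frozenset]:
        return {e.pair for e in self.edges}

    def by_pair(self) -> dict[frozenset, Edge]:
        return {e.pair: e for e in self.edges}


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _corr_and_p(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise correlation matrix and two-sided t-approx p matrix."""
    n = mat.shape[1]
    r = np.corrcoef(mat)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _sps.t.sf(np.abs(t), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def build_network(expr: ExpressionMatrix, hormones: HormoneTable | None,
                  pathway: PathwayTable, deg_genes: set[str],
                  sheet: SampleSheet, variety: str, condition: str, *,
                  r_threshold: float = R_THRESHOLD,
                  p_threshold: float = P_THRESHOLD,
                  per_stage_means: bool = False) -> CorrelationNetwork:
    """Build the consensus network for one variety x condition.

    Nodes are the DEG genes annotated to any hormone-signaling pathway plus
    all hormones present in ``hormones``.  Samples are all replicate-level
    samples of the variety x condition (day 0 shared); with
    ``per_stage_means`` replicates are averaged per day first.
    Constant-valued nodes are dropped with a warning.
    """
    sample_ids = sheet.samples_for(variety, condition)
    pathway_genes = {g for g, p in pathway.pathway_of().items() if p}
    node_genes = sorted((set(deg_genes) & pathway_genes) & set(expr.gene_ids))

    blocks = [expr.subset(genes=node_genes, samples=sample_ids)]
    if hormones is not None:
        blocks.append(hormones.df[sample_ids])
    data = pd.concat(blocks, axis=0)

    if per_stage_means:
        day_of = sheet.day_of()
        groups = pd.Series({s: day_of[s] for s in sample_ids})
        data = data.T.groupby(groups).mean().T
        data = data[sorted(data.columns)]

    n = data.shape[1]
    if n < 3:
        raise InputError(
            f"{variety}/{condition}: only {n} usable samples (< 3)")

    values = np.log2(data.to_numpy(dtype=float) + 1.0)
    labels = list(data.index)

    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [l for l, k in zip(labels, keep) if not k]
        log.warning("%s/%s: dropping constant node(s): %s", variety, condition, dropped)
        values = values[keep]
        labels = [l for l, k in zip(labels, keep) if k]

    fam = pathway.family_of()
    pway = pathway.pathway_of()
    hormone_set = set(hormones.hormone_ids) if hormones is not None else set()
    nodes = {}
    for l in labels:
        if l in hormone_set:
            nodes[l] = NodeInfo("hormone", pathway="hormone", family=l)
        else:
            nodes[l] = NodeInfo("gene", pathway=pway.get(l, ""), family=fam.get(l, ""))

    k = len(labels)
    edges: list[Edge] = []
    rows: list[dict] = []
    if k >= 2:
        r_mat, rp_mat = _corr_and_p(values)
        ranks = np.apply_along_axis(_sps.rankdata, 1, values)
        rho_mat, sp_mat = _corr_and_p(ranks)
        iu = np.triu_indices(k, 1)
        for i, j in zip(*iu):
            a, b = sorted((labels[i], labels[j]))
            r, rp = float(r_mat[i, j]), float(rp_mat[i, j])
            rho, sp = float(rho_mat[i, j]), float(sp_mat[i, j])
            ok = passes_consensus(r, rp, rho, sp, r_threshold, p_threshold)
            rows.append({"node_a": a, "node_b": b, "pearson_r": r, "pearson_p": rp,
                         "spearman_rho": rho, "spearman_p": sp, "edge": ok})
            if ok:
                edges.append(Edge(a, b, r, rp, rho, sp))

    pairs = pd.DataFrame(rows, columns=["node_a", "node_b", "pearson_r", "pearson_p",
                                        "spearman_rho", "spearman_p", "edge"])
    return CorrelationNetwork(variety=variety, condition=condition, nodes=nodes,
                              edges=tuple(edges), pairs=pairs)
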