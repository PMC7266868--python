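"""Stage-wise differential expression (drought vs control) and overlap accounting.

Selection rule: a gene is a DEG at a stage iff |log2 fold change| >= 1
(i.e. at least twofold on the abundance scale) AND BH-adjusted FDR < 0.01.
The per-gene test is Welch's two-sample t on log2(FPKM + 1); BH adjustment
is applied across genes within a stage (per variety).  Day 0 is the shared
baseline and is never tested.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import ExpressionMatrix, HomologMap, InputError, SampleSheet

log = logging.getLogger("hormnet")

FC_THRESHOLD = 2.0
FDR_THRESHOLD = 0.01
PSEUDOCOUNT = 1.0


def log2fc(treat_values, control_values, pseudocount: float = PSEUDOCOUNT) -> float:
    """log2((mean(treat) + pc) / (mean(control) + pc)) on the abundance scale."""
    t = np.asarray(treat_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.size == 0 or c.size == 0:
        raise InputError("log2fc: empty group")
    if pseudocount <= 0 and (t.mean() <= 0 or c.mean() <= 0):
        raise InputError("log2fc: non-positive mean with zero pseudocount")
    return float(np.log2((t.mean() + pseudocount) / (c.mean() + pseudocount)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputError("bh_adjust: p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _welch_p(t_mat: np.ndarray, c_mat: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-test p per row; both-groups-constant rows get p=1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = _sps.ttest_ind(t_mat, c_mat, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # constant within both groups (up to fp rounding) -> untestable
    t_tol = 1e-12 * (1.0 + np.abs(t_mat.mean(axis=1)))
    c_tol = 1e-12 * (1.0 + np.abs(c_mat.mean(axis=1)))
    both_const = (t_mat.std(axis=1) <= t_tol) & (c_mat.std(axis=1) <= c_tol)
    p[both_const] = 1.0
    p[~np.isfinite(p)] = 1.0
    return p


def test_stage(expr: ExpressionMatrix, sheet: SampleSheet, variety: str, day: int, *,
               fc_threshold: float = FC_THRESHOLD, fdr_threshold: float = FDR_THRESHOLD,
               pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """DEG table rows for one variety x day (drought vs control).

    Returns a DataFrame with columns gene_id, variety, day, log2fc, p_raw,
    fdr, is_deg.  Raises :class:`InputError` if day is 0 or either group has
    fewer than two replicates.
    """
    if day == 0:
        raise InputError("day 0 is the shared baseline and is never tested")
    treat_ids = sheet.replicates_at(variety, "drought", day)
    ctrl_ids = sheet.replicates_at(variety, "control", day)
    if len(treat_ids) < 2 or len(ctrl_ids) < 2:
        raise InputError(
            f"{variety} d{day}: need >=2 replicates per group "
            f"(got {len(treat_ids)} drought, {len(ctrl_ids)} control)")

    t_raw = expr.df[treat_ids].to_numpy(dtype=float)
    c_raw = expr.df[ctrl_ids].to_numpy(dtype=float)
    lfc = np.log2((t_raw.mean(axis=1) + pseudocount) /
                  (c_raw.mean(axis=1) + pseudocount))
    p_raw = _welch_p(np.log2(t_raw + 1.0), np.log2(c_raw + 1.0))
    fdr = bh_adjust(p_raw)
    is_deg = (np.abs(lfc) >= np.log2(fc_threshold)) & (fdr < fdr_threshold)
    return pd.DataFrame({
        "gene_id": expr.gene_ids, "variety": variety, "day": day,
        "log2fc": lfc, "p_raw": p_raw, "fdr": fdr, "is_deg": is_deg})


def call_stages(expr: ExpressionMatrix, sheet: SampleSheet, variety: str,
                **kwargs) -> pd.DataFrame:
    """DEG table across all testable stages (days > 0) of a variety.

    Stages lacking a full pair of replicate groups are skipped with a warning.
    """
    tables = []
    for day in sheet.days(variety):
        if day == 0:
            continue
        try:
            tables.append(test_stage(expr, sheet, variety, day, **kwargs))
        except InputError as exc:
            log.warning("skipping stage: %s", exc)
    if not tables:
        return pd.DataFrame(columns=["gene_id", "variety", "day", "log2fc",
                                     "p_raw", "fdr", "is_deg"])
    return pd.concat(tables, ignore_index=True)


def deg_sets(deg_table: pd.DataFrame) -> dict[int, set[str]]:
    """Per-stage sets of DEG gene ids from a stacked DEG table."""
    out: dict[int, set[str]] = {}
    for day, sub in deg_table.groupby("day"):
        out[int(day)] = set(sub.loc[sub["is_deg"], "gene_id"])
    return out


def deg_union(deg_table: pd.DataFrame) -> set[str]:
    return set(deg_table.loc[deg_table["is_deg"], "gene_id"])


def stage_overlaps(stage_sets: dict[int, set[str]]) -> dict:
    """Venn region counts across stages plus adjacent-stage shared counts.

    Venn regions are keyed by the sorted tuple of member stages; counts over
    all 2^k - 1 non-empty membership patterns.
    """
    days = sorted(stage_sets)
    if len(days) < 2:
        raise InputError("stage_overlaps: need >= 2 stages")
    universe = set().union(*stage_sets.values())
    venn = {comb: 0 for r in range(1, len(days) + 1)
            for comb in itertools.combinations(days, r)}
    for gene in universe:
        pattern = tuple(d for d in days if gene in stage_sets[d])
        venn[pattern] += 1
    adjacent = {(a, b): len(stage_sets[a] & stage_sets[b])
                for a, b in zip(days, days[1:])}
    return {"days": days, "venn": venn, "adjacent_shared": adjacent,
            "union_size": len(universe)}


def cross_variety_common(deg_v1: set[str], deg_v2: set[str], map: HomologMap,
                         ) -> set[tuple[str, str]]:
    """Pairs (g1, g2): g1 a DEG in variety 1, g2 its homolog and a DEG in v2."""
    resolved = map.resolve()
    out = set()
    unmapped = []
    for g1 in sorted(deg_v1):
        g2 = resolved.get(g1)
        if g2 is None:
            unmapped.append(g1)
        elif g2 in deg_v2:
            out.add((g1, g2))
    if unmapped:
        log.info("cross_variety_common: %d DEG(s) without homolog excluded: %s",
                 len(unmapped), unmapped[:10])
    return out
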