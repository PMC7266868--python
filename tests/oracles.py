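"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from first principles (explicit
loops, direct formulas) and independently of the implementation paths it
checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as _t
from scipy.stats import studentized_range as _srange


def pearson_direct(x, y) -> tuple[float, float]:
    """Pearson r via the raw covariance formula; p via the t CDF."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2.0 * float(_t.sf(abs(t), n - 2))


def midrank(values) -> list[float]:
    """Mid-ranks (average ranks for ties), written without scipy.rankdata."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_direct(x, y) -> tuple[float, float]:
    """Mid-rank then direct-Pearson oracle."""
    return pearson_direct(midrank(list(x)), midrank(list(y)))


def bh_stepup_bruteforce(p) -> list[float]:
    """O(m^2) Benjamini-Hochberg step-up, no vectorization tricks."""
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    raw = [p[indexed[k]] * m / (k + 1) for k in range(m)]
    adj_sorted = []
    for k in range(m):
        adj_sorted.append(min(min(raw[k:]), 1.0))
    out = [0.0] * m
    for k, i in enumerate(indexed):
        out[i] = adj_sorted[k]
    return out


def degree_bruteforce(nodes, edges) -> dict[str, int]:
    """Distinct-neighbor counts by direct adjacency enumeration."""
    out = {}
    for n in nodes:
        neigh = set()
        for a, b in edges:
            if a == n:
                neigh.add(b)
            elif b == n:
                neigh.add(a)
        out[n] = len(neigh)
    return out


def anova_bruteforce(groups: list) -> tuple[float, int]:
    """(mse, df_error) by textbook sums of squares."""
    sse = 0.0
    n_total = 0
    for g in groups:
        g = [float(v) for v in g]
        mean = sum(g) / len(g)
        sse += sum((v - mean) ** 2 for v in g)
        n_total += len(g)
    df = n_total - len(groups)
    return sse / df, df


def venn_bruteforce(stage_sets: dict) -> dict:
    """Per-gene membership-pattern counting."""
    days = sorted(stage_sets)
    counts: dict[tuple, int] = {}
    for gene in set().union(*stage_sets.values()):
        pattern = tuple(d for d in days if gene in stage_sets[d])
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def duncan_decisions_bruteforce(means_desc, df_error, mse, n_h, alpha=0.05
                                ) -> set[tuple[int, int]]:
    """Manual Duncan step-down over all spans, largest first.

    Returns significant (i, j) index pairs into the descending-mean order.
    A span within an interval already declared homogeneous is skipped.
    """
    k = len(means_desc)
    homogeneous: list[tuple[int, int]] = []
    sig: set[tuple[int, int]] = set()
    for size in range(k, 1, -1):
        alpha_p = 1.0 - (1.0 - alpha) ** (size - 1)
        q = float(_srange.ppf(1.0 - alpha_p, size, df_error))
        r_p = q * math.sqrt(mse / n_h)
        for i in range(0, k - size + 1):
            j = i + size - 1
            if any(a <= i and j <= b for a, b in homogeneous):
                continue
            if means_desc[i] - means_desc[j] > r_p:
                sig.add((i, j))
            else:
                homogeneous.append((i, j))
    return sig


def tukey_decisions(means_desc, sizes, df_error, mse, alpha=0.05
                    ) -> set[tuple[int, int]]:
    """Tukey HSD pairwise decisions (balanced n via harmonic mean)."""
    k = len(means_desc)
    n_h = k / sum(1.0 / s for s in sizes)
    q = float(_srange.ppf(1.0 - alpha, k, df_error))
    crit = q * math.sqrt(mse / n_h)
    return {(i, j) for i in range(k) for j in range(i + 1, k)
            if abs(means_desc[i] - means_desc[j]) > crit}
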