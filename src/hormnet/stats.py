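"""One-way ANOVA and Duncan's multiple range test with compact letter displays.

Critical ranges use studentized-range quantiles from
``scipy.stats.studentized_range`` at Duncan's protection levels
alpha_p = 1 - (1 - alpha)^(p-1) for a span of p ordered means, with the
harmonic-mean group size for unbalanced designs.  The step-down
non-contradiction rule applies: a pair inside a span already declared
homogeneous is never declared different.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import HormoneTable, InputError, SampleSheet

log = logging.getLogger("hormnet")

ALPHA = 0.05

FACTORS = ("condition-within-day", "day-within-condition")


@dataclass(frozen=True)
class AnovaResult:
    mse: float
    df_error: int
    f_stat: float
    p: float


def one_way_anova(groups: dict[str, np.ndarray] | list) -> AnovaResult:
    """Standard within/between sum-of-squares decomposition.

    ``groups`` is a mapping label -> values or a list of value arrays.
    Every group needs >= 2 values.  All-constant data (zero within- and
    between-group variance) is rejected.
    """
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    if len(arrays) < 2:
        raise InputError("one_way_anova: need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise InputError("one_way_anova: every group needs >= 2 values")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    sse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    df_error = n_total - len(arrays)
    df_between = len(arrays) - 1
    mse = sse / df_error
    if mse == 0.0 and ssb == 0.0:
        raise InputError("one_way_anova: no variance in data")
    msb = ssb / df_between
    if mse == 0.0:
        f, p = np.inf, 0.0
    else:
        f = msb / mse
        p = float(_sps.f.sf(f, df_between, df_error))
    return AnovaResult(mse=mse, df_error=df_error, f_stat=float(f), p=p)


@dataclass(frozen=True)
class DuncanResult:
    groups: tuple[str, ...]          # ordered by descending mean
    means: tuple[float, ...]
    n_per_group: tuple[int, ...]
    mse: float
    df_error: int
    alpha: float
    letters: tuple[str, ...]         # compact letter display, aligned to groups
    critical_ranges: dict[int, float] = field(default_factory=dict)
    significant_pairs: frozenset = frozenset()  # frozensets of group labels

    def letter_of(self) -> dict[str, str]:
        return dict(zip(self.groups, self.letters))

    def differs(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.significant_pairs


def duncan_critical_range(p_span: int, df_error: int, mse: float, n_h: float,
                          alpha: float = ALPHA) -> float:
    """R_p = q(1 - alpha_p; p, df) * sqrt(mse / n_h), Duncan protection level."""
    alpha_p = 1.0 - (1.0 - alpha) ** (p_span - 1)
    q = _sps.studentized_range.ppf(1.0 - alpha_p, p_span, df_error)
    return float(q * np.sqrt(mse / n_h))


def _step_down(means: np.ndarray, ranges: dict[int, float]) -> set[tuple[int, int]]:
    """Duncan step-down on descending means; returns significant index pairs."""
    k = means.size
    sig: set[tuple[int, int]] = set()
    homog: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()

    def covered(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in homog)

    def rec(i: int, j: int) -> None:
        if j - i < 1 or (i, j) in seen:
            return
        seen.add((i, j))
        if covered(i, j):
            return
        span = j - i + 1
        if means[i] - means[j] > ranges[span]:
            sig.add((i, j))
            rec(i, j - 1)
            rec(i + 1, j)
        else:
            homog.append((i, j))

    rec(0, k - 1)
    # non-contradiction: drop any pair inside a homogeneous span
    return {(i, j) for i, j in sig if not covered(i, j)}


def _letters(k: int, sig_pairs: set[tuple[int, int]]) -> list[str]:
    """Insert-and-absorb compact letter display for k ordered groups."""
    columns: list[set[int]] = [set(range(k))]
    for i, j in sorted(sig_pairs):
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
            # absorb columns that became subsets
            columns = [c for c in columns
                       if not any(c < d for d in columns)]
    # deduplicate, order by smallest member (highest mean first)
    uniq: list[set[int]] = []
    for c in sorted(columns, key=lambda c: sorted(c)):
        if c and c not in uniq:
            uniq.append(c)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = []
    for g in range(k):
        out.append("".join(alphabet[ci] for ci, c in enumerate(uniq) if g in c))
    return out


def duncan_mrt(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> DuncanResult:
    """Duncan's multiple range test over labelled groups.

    Requires ANOVA preconditions and mse > 0.  Group means are ordered
    descending; pairwise decisions follow the step-down rule with span-wise
    critical ranges; letters come from the insert-and-absorb algorithm.
    """
    anova = one_way_anova(groups)
    if anova.mse == 0.0:
        raise InputError("duncan_mrt: zero within-group variance")
    labels = list(groups)
    means = np.array([np.mean(np.asarray(groups[l], dtype=float)) for l in labels])
    sizes = np.array([np.asarray(groups[l]).size for l in labels])
    order = np.argsort(-means, kind="mergesort")
    labels = [labels[i] for i in order]
    means = means[order]
    sizes = sizes[order]

    k = len(labels)
    n_h = k / float((1.0 / sizes).sum())  # harmonic mean group size
    ranges = {p: duncan_critical_range(p, anova.df_error, anova.mse, n_h, alpha)
              for p in range(2, k + 1)}
    sig_idx = _step_down(means, ranges)
    letters = _letters(k, sig_idx)
    sig_pairs = frozenset(frozenset((labels[i], labels[j])) for i, j in sig_idx)
    return DuncanResult(
        groups=tuple(labels), means=tuple(float(m) for m in means),
        n_per_group=tuple(int(s) for s in sizes), mse=anova.mse,
        df_error=anova.df_error, alpha=alpha, letters=tuple(letters),
        critical_ranges=ranges, significant_pairs=sig_pairs)


def group_compare_table(table: HormoneTable | pd.DataFrame, sheet: SampleSheet,
                        factor: str = "condition-within-day",
                        alpha: float = ALPHA) -> pd.DataFrame:
    """Duncan results for every measured variable per factor slice.

    ``factor="condition-within-day"`` compares conditions at each day;
    ``"day-within-condition"`` compares days within each condition.  Slices
    with insufficient replication are skipped with a warning.  Returns a
    long DataFrame: variable, variety, slice, group, mean, n, letters.
    """
    if factor not in FACTORS:
        raise InputError(f"unknown factor {factor!r}; choose one of {FACTORS}")
    values = table.df if isinstance(table, HormoneTable) else table
    sdf = sheet.df.set_index("sample_id")
    rows = []
    for variety in sheet.varieties:
        if factor == "condition-within-day":
            slices = [(f"d{day}",
                       {cond: sheet.replicates_at(variety, cond, day)
                        for cond in ("control", "drought")})
                      for day in sheet.days(variety) if day > 0]
        else:
            slices = [(cond,
                       {f"d{day}": sheet.replicates_at(variety, cond, day)
                        for day in sheet.days(variety)})
                      for cond in ("control", "drought")]
        for slice_name, group_ids in slices:
            group_ids = {g: [s for s in ids if s in values.columns]
                         for g, ids in group_ids.items()}
            if any(len(ids) < 2 for ids in group_ids.values()) or len(group_ids) < 2:
                log.warning("%s/%s: insufficient replication, slice skipped",
                            variety, slice_name)
                continue
            for var in values.index:
                groups = {g: values.loc[var, ids].to_numpy(dtype=float)
                          for g, ids in group_ids.items()}
                try:
                    res = duncan_mrt(groups, alpha=alpha)
                except InputError as exc:
                    log.warning("%s/%s/%s: %s", variety, slice_name, var, exc)
                    continue
                for g, m, n, letter in zip(res.groups, res.means,
                                           res.n_per_group, res.letters):
                    rows.append({"variable": var, "variety": variety,
                                 "slice": slice_name, "group": g, "mean": m,
                                 "n": n, "letters": letter})
    return pd.DataFrame(rows, columns=["variable", "variety", "slice", "group",
                                       "mean", "n", "letters"])
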