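"""Tabular input/output and shared data containers.

All on-disk tables are tab-separated, UTF-8, ``.`` decimal, no quoting;
lines starting with ``#`` are comments (used for provenance headers).
Readers validate and reject malformed input rather than coercing it;
writers round-trip losslessly at float precision ``%.10g``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger("hormnet")

#: canonical hormone identifiers, in display order
HORMONES = ("ZR", "IAA", "GA3", "ABA", "BR", "JA-me")

CONDITIONS = ("control", "drought")

FLOAT_FMT = "%.10g"


class InputError(ValueError):
    """Malformed or invariant-violating input data."""


class ConfigError(ValueError):
    """Invalid configuration."""


# ---------------------------------------------------------------------------
# low-level TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)
    except Exception as exc:  # pandas raises a zoo of parser errors
        raise InputError(f"cannot parse TSV {path}: {exc}") from exc


def _write_tsv(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = (),
               index: bool = False) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSheet:
    """Design metadata: one row per sample (variety, condition, day, replicate).

    Day-0 samples are the shared baseline for both condition groups: they
    appear once in the sheet and :meth:`samples_for` includes them in the
    selection for every condition.
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "variety", "condition", "day", "replicate")

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise InputError(f"sample sheet missing columns: {missing}")
        df = df.copy()
        df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
        if df["sample_id"].duplicated().any():
            dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise InputError(f"duplicate sample_id(s): {dups}")
        bad = set(df["condition"]) - set(CONDITIONS)
        if bad:
            raise InputError(f"unknown condition label(s): {sorted(bad)}")
        if (df["day"] < 0).any():
            raise InputError("negative day in sample sheet")
        if (df["replicate"] < 1).any():
            raise InputError("replicate numbers must be >= 1")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    # -- selection ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    @property
    def varieties(self) -> list[str]:
        return sorted(self.df["variety"].unique())

    def days(self, variety: str) -> list[int]:
        return sorted(self.df.loc[self.df["variety"] == variety, "day"].unique())

    def samples_for(self, variety: str, condition: str) -> list[str]:
        """Sample ids for one variety x condition, day 0 included (shared)."""
        df = self.df
        v = df["variety"] == variety
        d0 = df.loc[v & (df["day"] == 0)].drop_duplicates("sample_id")
        rest = df.loc[v & (df["condition"] == condition) & (df["day"] > 0)]
        return list(d0["sample_id"]) + list(rest["sample_id"])

    def replicates_at(self, variety: str, condition: str, day: int) -> list[str]:
        """Sample ids of one experimental cell (variety x condition x day)."""
        df = self.df
        v = df["variety"] == variety
        if day == 0:
            sub = df.loc[v & (df["day"] == 0)].drop_duplicates("sample_id")
        else:
            sub = df.loc[v & (df["condition"] == condition) & (df["day"] == day)]
        return list(sub["sample_id"])

    def day_of(self) -> dict[str, int]:
        return dict(zip(self.df["sample_id"], self.df["day"]))

    # -- io ----------------------------------------------------------------

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(_read_tsv(path))

    def write(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        _write_tsv(self.df, path, header_lines)


# ---------------------------------------------------------------------------
# matrices (expression, hormones)
# ---------------------------------------------------------------------------

def _validate_matrix(df: pd.DataFrame, *, kind: str, sheet: SampleSheet | None,
                     positive: bool) -> pd.DataFrame:
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise InputError(f"duplicate {kind} id(s): {dups}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric value in {kind} matrix: {exc}") from exc
    if not np.isfinite(values.to_numpy()).all():
        raise InputError(f"non-finite value in {kind} matrix")
    arr = values.to_numpy()
    if positive:
        if (arr <= 0).any():
            r, c = np.argwhere(arr <= 0)[0]
            raise InputError(
                f"non-positive value in {kind} matrix at row "
                f"{values.index[r]!r}, column {values.columns[c]!r}")
    elif (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise InputError(
            f"negative value in {kind} matrix at row {values.index[r]!r}, "
            f"column {values.columns[c]!r}")
    if sheet is not None:
        unknown = set(values.columns) - set(sheet.sample_ids)
        if unknown:
            raise InputError(f"{kind} matrix has samples not in sheet: {sorted(unknown)}")
    return values


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples abundance matrix on the FPKM scale (non-negative)."""

    df: pd.DataFrame  # index: gene ids, columns: sample ids, float values
    sheet: SampleSheet | None = None

    def __post_init__(self) -> None:
        values = _validate_matrix(self.df, kind="gene", sheet=self.sheet, positive=False)
        zero_rows = values.index[(values == 0).all(axis=1)]
        if len(zero_rows):
            log.warning("all-zero expression rows retained: %s", list(zero_rows))
        object.__setattr__(self, "df", values)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def subset(self, genes: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> pd.DataFrame:
        out = self.df
        if genes is not None:
            out = out.loc[[g for g in genes if g in out.index]]
        if samples is not None:
            out = out[list(samples)]
        return out

    def write(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        df = self.df.copy()
        df.index.name = "gene_id"
        _write_tsv(df, path, header_lines, index=True)


@dataclass(frozen=True)
class HormoneTable:
    """Hormones x samples levels in ng per gram fresh weight (positive)."""

    df: pd.DataFrame
    sheet: SampleSheet | None = None

    def __post_init__(self) -> None:
        values = _validate_matrix(self.df, kind="hormone", sheet=self.sheet, positive=True)
        object.__setattr__(self, "df", values)

    @property
    def hormone_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def write(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        df = self.df.copy()
        df.index.name = "hormone_id"
        _write_tsv(df, path, header_lines, index=True)


def read_expression(path: str | Path, sample_sheet: SampleSheet | None = None
                    ) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene ids, header sample ids)."""
    df = _read_tsv(path, index_col=0)
    return ExpressionMatrix(df, sheet=sample_sheet)


def read_hormones(path: str | Path, sample_sheet: SampleSheet | None = None
                  ) -> HormoneTable:
    df = _read_tsv(path, index_col=0)
    return HormoneTable(df, sheet=sample_sheet)


# ---------------------------------------------------------------------------
# PathwayTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayTable:
    """Gene id -> hormone-signaling pathway and protein family annotation."""

    df: pd.DataFrame  # columns: gene_id, pathway, family

    REQUIRED = ("gene_id", "pathway", "family")

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise InputError(f"pathway table missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dups = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"])
            raise InputError(f"duplicate gene_id(s) in pathway table: {dups}")
        bad = df.loc[df["pathway"].astype(bool) & ~df["family"].astype(bool), "gene_id"]
        if len(bad):
            raise InputError(f"family missing for pathway genes: {sorted(bad)}")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df["gene_id"])

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.df["gene_id"], self.df["family"]))

    def pathway_of(self) -> dict[str, str]:
        return dict(zip(self.df["gene_id"], self.df["pathway"]))

    @classmethod
    def read(cls, path: str | Path) -> "PathwayTable":
        return cls(_read_tsv(path))

    def write(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        _write_tsv(self.df, path, header_lines)


# ---------------------------------------------------------------------------
# HomologMap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologMap:
    """Cross-variety gene correspondence (sequence-similar transcripts).

    :meth:`resolve` reduces a many-to-many table to a one-to-one map by
    greedily keeping the highest-similarity pair, ties broken
    lexicographically by partner id.
    """

    df: pd.DataFrame  # columns: gene_id_v1, gene_id_v2, optional similarity

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("gene_id_v1", "gene_id_v2"):
            if col not in df.columns:
                raise InputError(f"homolog map missing column {col!r}")
        if "similarity" not in df.columns:
            df["similarity"] = 1.0
        df["similarity"] = pd.to_numeric(df["similarity"], errors="raise")
        if ((df["similarity"] < 0) | (df["similarity"] > 1)).any():
            raise InputError("homolog similarity outside [0, 1]")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    def resolve(self) -> dict[str, str]:
        """One-to-one mapping gene_id_v1 -> gene_id_v2."""
        ranked = self.df.sort_values(
            ["similarity", "gene_id_v1", "gene_id_v2"],
            ascending=[False, True, True], kind="mergesort")
        used_v1: set[str] = set()
        used_v2: set[str] = set()
        out: dict[str, str] = {}
        for row in ranked.itertuples(index=False):
            if row.gene_id_v1 in used_v1 or row.gene_id_v2 in used_v2:
                continue
            out[row.gene_id_v1] = row.gene_id_v2
            used_v1.add(row.gene_id_v1)
            used_v2.add(row.gene_id_v2)
        return out

    @classmethod
    def read(cls, path: str | Path) -> "HomologMap":
        return cls(_read_tsv(path))

    def write(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        _write_tsv(self.df, path, header_lines)


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

_SIGN_WORD = {"+": "pos", "-": "neg", "mixed": "mixed"}

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def _edge_records(net) -> list[dict]:
    """Normalize Edge / FamilyEdge objects to flat dicts."""
    records = []
    for e in net.edges:
        a, b = e.endpoints
        rec = {"node_a": a, "node_b": b, "sign": e.sign}
        for attr in ("pearson_r", "pearson_p", "spearman_rho", "spearman_p",
                     "mean_pos", "mean_neg", "n_pos", "n_neg"):
            if hasattr(e, attr):
                val = getattr(e, attr)
                rec[attr] = "" if val is None else val
        if hasattr(e, "variety_labels"):
            rec["variety_labels"] = ",".join(e.variety_labels)
        records.append(rec)
    return records


def write_network(net, path: str | Path, format: str = "tsv",
                  header_lines: Sequence[str] = ()) -> None:
    """Write a correlation/common network as SIF, GraphML or a TSV edge table.

    SIF lines are ``nodeA <pos|neg|mixed> nodeB`` (Cytoscape-ingestible);
    isolated nodes are written as bare single-token lines.  GraphML carries
    all edge attributes.  TSV is the full edge table.
    """
    if format not in NETWORK_FORMATS:
        raise InputError(f"unknown network format {format!r}; "
                         f"choose one of {NETWORK_FORMATS}")
    path = Path(path)
    records = _edge_records(net)
    nodes = list(net.node_labels())
    touched = {r["node_a"] for r in records} | {r["node_b"] for r in records}

    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for r in records:
                fh.write(f"{r['node_a']}\t{_SIGN_WORD[r['sign']]}\t{r['node_b']}\n")
            for n in nodes:
                if n not in touched:
                    fh.write(f"{n}\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for r in records:
            attrs = {k: v for k, v in r.items()
                     if k not in ("node_a", "node_b") and v != ""}
            g.add_edge(r["node_a"], r["node_b"], **attrs)
        nx.write_graphml(g, path)
    else:
        cols = sorted({k for r in records for k in r}) if records else [
            "node_a", "node_b", "sign"]
        lead = [c for c in ("node_a", "node_b", "sign") if c in cols]
        cols = lead + [c for c in cols if c not in lead]
        df = pd.DataFrame(records, columns=cols)
        _write_tsv(df, path, header_lines)


def read_network_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a TSV edge table written by :func:`write_network`."""
    df = _read_tsv(path)
    for col in df.columns:
        if col not in ("node_a", "node_b", "sign", "variety_labels"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
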