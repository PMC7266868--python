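"""Synthetic study-design data with planted statistical structure.

Emulates the analysis design — 2 varieties x {control, drought} x 5 time
points (day 0 shared between conditions) x 3 replicates — with planted
>=2-fold DEGs, hormone time profiles (drought-elevated ABA/IAA) and a
planted hub-centred correlation structure among pathway genes that exists
under drought only.

Abundances are log-normal on the log2(FPKM+1) scale: values are generated
as x ~ Normal(mu + effects, dispersion) and stored as FPKM = 2^x - 1, so
the pipeline's log2(FPKM+1) transform recovers x exactly and planted
correlations are exact on the analysis scale.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (CONDITIONS, HORMONES, ConfigError, ExpressionMatrix,
                 HomologMap, HormoneTable, PathwayTable, SampleSheet)

log = logging.getLogger("hormnet")

DEFAULT_SEED = 20200527

#: protein families cycled over pathway genes, and their pathways
FAMILY_CYCLE = ("PP2C", "ABF", "SnRK2", "PYR", "IAA", "SAUR", "AUX1",
                "A-ARR", "GID", "BZR")
FAMILY_PATHWAY = {
    "PP2C": "abscisic acid", "ABF": "abscisic acid", "SnRK2": "abscisic acid",
    "PYR": "abscisic acid", "IAA": "auxin", "SAUR": "auxin", "AUX1": "auxin",
    "A-ARR": "cytokinin", "GID": "gibberellin", "BZR": "brassinosteroid",
}

HORMONE_BASE = {"ZR": 12.0, "IAA": 55.0, "GA3": 6.0, "ABA": 110.0,
                "BR": 2.5, "JA-me": 9.0}


def _gene_labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study."""

    n_varieties: int = 2
    conditions: tuple[str, ...] = CONDITIONS
    days: tuple[int, ...] = (0, 2, 5, 15, 30)
    n_replicates: int = 3
    n_genes: int = 60
    n_pathway_genes: int = 20
    deg_fraction: float = 0.25
    deg_log2fc: float = 3.0
    dispersion: float = 0.25
    hub_gene: str = "G001"
    hub_partners: tuple[tuple[str, str], ...] = (
        ("G002", "+"), ("G003", "+"), ("G004", "+"),
        ("G005", "-"), ("G006", "-"), ("G007", "+"))
    planted_r: float = 0.95
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if not self.days or self.days[0] != 0:
            raise ConfigError("days must start at 0")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ConfigError("days must be strictly increasing")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.n_varieties < 1:
            raise ConfigError("n_varieties must be >= 1")
        if not set(self.conditions) <= set(CONDITIONS):
            raise ConfigError(f"conditions must be among {CONDITIONS}")
        if self.deg_log2fc < 1:
            raise ConfigError("deg_log2fc must be >= 1 (>=2-fold in expectation)")
        if self.hub_partners and not 0.7 < abs(self.planted_r) <= 1:
            raise ConfigError("|planted_r| must lie in (0.7, 1]")
        if not 0 <= self.deg_fraction <= 1:
            raise ConfigError("deg_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        partners = [g for g, _ in self.hub_partners]
        if self.hub_gene in partners or len(set(partners)) != len(partners):
            raise ConfigError("hub_partners must be distinct from hub_gene "
                              "and from each other")
        if any(s not in ("+", "-") for _, s in self.hub_partners):
            raise ConfigError("partner signs must be '+' or '-'")
        labels = set(self.gene_labels())
        missing = ({self.hub_gene} | set(partners)) - labels
        if self.hub_partners and missing:
            raise ConfigError(f"hub/partner genes not in gene universe: {sorted(missing)}")

    def gene_labels(self) -> list[str]:
        return _gene_labels(self.n_genes)

    def varieties(self) -> list[str]:
        return [f"V{i + 1}" for i in range(self.n_varieties)]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of the planted structure, for recovery tests."""

    deg_genes: dict[int, dict[str, float]]      # day -> gene -> expected log2fc
    planted_edges: frozenset                    # (node, node, sign), both orders
    hub: str
    hormone_profiles: dict                      # hormone -> condition -> day -> level

    def edge_pairs(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _ in self.planted_edges}

    def to_json(self) -> str:
        return json.dumps({
            "hub": self.hub,
            "deg_genes": {str(d): g for d, g in self.deg_genes.items()},
            "planted_edges": sorted(map(list, self.planted_edges)),
            "hormone_profiles": self.hormone_profiles,
        }, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(cfg: SimConfig) -> SampleSheet:
    """One row per variety x condition x day x replicate; day 0 shared.

    Day-0 samples appear once per variety x replicate (the shared baseline
    for both condition groups), labelled with the first configured
    condition.
    """
    cfg.validate()
    rows = []
    for variety in cfg.varieties():
        for rep in range(1, cfg.n_replicates + 1):
            rows.append({"sample_id": f"{variety}-0d-r{rep}", "variety": variety,
                         "condition": cfg.conditions[0], "day": 0, "replicate": rep})
        for condition in cfg.conditions:
            tag = "D" if condition == "drought" else "C"
            for day in cfg.days[1:]:
                for rep in range(1, cfg.n_replicates + 1):
                    rows.append({"sample_id": f"{variety}-{tag}{day}d-r{rep}",
                                 "variety": variety, "condition": condition,
                                 "day": day, "replicate": rep})
    return SampleSheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _trend(cfg: SimConfig) -> dict[int, float]:
    """Planted drought time trend (log2 units): 0 at day 0, then evenly
    spaced steps of deg_log2fc/2 (first treated stage at half amplitude,
    reaching full amplitude by the second stage)."""
    out = {0: 0.0}
    for i, day in enumerate(cfg.days[1:]):
        out[day] = cfg.deg_log2fc * 0.5 * (i + 1)
    return out


def simulate_expression(cfg: SimConfig, design: SampleSheet
                        ) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate FPKM-scale abundances with planted DEGs and hub structure.

    Non-DEG genes share expected abundance between conditions at every
    stage.  Plain planted DEGs get a +/- deg_log2fc shift at every treated
    stage.  Hub/partner genes follow a shared latent day trend under
    drought: partner = sign * (planted_r * z + sd(z) * sqrt(1 - r^2) * eps),
    giving population correlation ~ planted_r under drought and none under
    control.  With empty hub_partners no network structure is planted.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    genes = cfg.gene_labels()
    samples = design.sample_ids
    n_g, n_s = len(genes), len(samples)
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: i for i, s in enumerate(samples)}
    day_of = design.day_of()

    mu = rng.uniform(3.0, 8.0, n_g)
    # hub/partner genes need headroom so the planted drought excursion
    # (up to ~2 * deg_log2fc either way) never clips at FPKM = 0
    structural_mu = {g: float(rng.uniform(9.0, 10.5))
                     for g in ([cfg.hub_gene] + [g for g, _ in cfg.hub_partners]
                               if cfg.hub_partners else [])}
    for g, m in structural_mu.items():
        mu[cfg.gene_labels().index(g)] = m
    x = mu[:, None] + rng.normal(0.0, cfg.dispersion, (n_g, n_s))

    # choose plain planted DEGs (hub/partners handled structurally below);
    # drawn outside the pathway-annotated block: the planted pathway
    # correlation structure is the hub's, plain DEGs model genome-wide
    # regulation for the stage-overlap accounting
    structural = ([cfg.hub_gene] + [g for g, _ in cfg.hub_partners]
                  if cfg.hub_partners else [])
    n_deg = int(round(cfg.deg_fraction * n_g))
    annotated = set(genes[:cfg.n_pathway_genes]) | set(structural)
    pool = [g for g in genes if g not in annotated]
    if not pool:
        pool = [g for g in genes if g not in structural]
    n_plain = max(0, n_deg - len(structural)) if n_deg > 0 else 0
    plain = list(rng.choice(pool, size=min(n_plain, len(pool)), replace=False)) \
        if n_plain else []
    plain_sign = {g: (1.0 if i % 2 == 0 else -1.0) for i, g in enumerate(plain)}

    trend = _trend(cfg)
    planted = bool(cfg.hub_partners) and "drought" in cfg.conditions
    deg_truth: dict[int, dict[str, float]] = {d: {} for d in cfg.days if d > 0}
    edges: set[tuple[str, str, str]] = set()

    # plain DEGs: per-day random direction so planted genes do not share a
    # single step profile (which would correlate every DEG with every other)
    plain_day_sign = {g: {d: (1.0 if rng.random() < 0.5 else -1.0)
                          for d in cfg.days if d > 0} for g in plain}

    if "drought" in cfg.conditions:
        for variety in design.varieties:
            if n_deg > 0:
                for day in cfg.days[1:]:
                    cols = [si[s] for s in
                            design.replicates_at(variety, "drought", day)]
                    for g in plain:
                        x[gi[g], cols] += plain_day_sign[g][day] * cfg.deg_log2fc
            if planted and n_deg > 0:
                dsel = design.samples_for(variety, "drought")  # incl. day 0
                cols = [si[s] for s in dsel]
                days = np.array([day_of[s] for s in dsel])
                z = np.array([trend[d] for d in days])
                z = z + rng.normal(0.0, 0.05 * cfg.deg_log2fc, len(cols))
                sd_z = z.std()
                x[gi[cfg.hub_gene], cols] = mu[gi[cfg.hub_gene]] + z
                r = cfg.planted_r
                uniq_days = sorted(set(days))
                for partner, sgn in cfg.hub_partners:
                    s = 1.0 if sgn == "+" else -1.0
                    # day-level dominant residual: replicates stay tight so
                    # the per-stage Welch test retains power
                    eps_day = dict(zip(uniq_days,
                                       rng.normal(0.0, 1.0, len(uniq_days))))
                    eps = (0.93 * np.array([eps_day[d] for d in days])
                           + 0.35 * rng.normal(0.0, 1.0, len(cols)))
                    x[gi[partner], cols] = (
                        mu[gi[partner]]
                        + s * (r * z + sd_z * np.sqrt(1.0 - r * r) * eps))

    if n_deg > 0:
        for day in deg_truth:
            for g in plain:
                deg_truth[day][g] = plain_day_sign[g][day] * cfg.deg_log2fc
            if planted:
                deg_truth[day][cfg.hub_gene] = trend[day]
                for partner, sgn in cfg.hub_partners:
                    s = 1.0 if sgn == "+" else -1.0
                    deg_truth[day][partner] = s * cfg.planted_r * trend[day]
        if planted:
            for partner, sgn in cfg.hub_partners:
                edges.add((cfg.hub_gene, partner, sgn))
                edges.add((partner, cfg.hub_gene, sgn))

    fpkm = np.clip(np.exp2(x) - 1.0, 0.0, None)
    expr = ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=samples),
                            sheet=design)
    truth = SimTruth(deg_genes=deg_truth, planted_edges=frozenset(edges),
                     hub=cfg.hub_gene if planted and n_deg > 0 else "",
                     hormone_profiles={})
    return expr, truth


# ---------------------------------------------------------------------------
# hormones
# ---------------------------------------------------------------------------

def hormone_profiles(cfg: SimConfig, aba_effect: float = 3.0,
                     iaa_effect: float = 2.5) -> dict:
    """Expected hormone level per hormone x condition x day (ng/g)."""
    out: dict = {}
    for h, base in HORMONE_BASE.items():
        out[h] = {}
        for condition in cfg.conditions:
            out[h][condition] = {}
            for day in cfg.days:
                mult = 1.0
                if condition == "drought" and day > 0:
                    if h == "ABA" and day >= 2:
                        mult = aba_effect
                    elif h == "IAA" and day >= 5:
                        mult = iaa_effect
                out[h][condition][str(day)] = base * mult
    return out


def simulate_hormones(cfg: SimConfig, design: SampleSheet, *,
                      aba_effect: float = 3.0, iaa_effect: float = 2.5,
                      noise_sd: float = 0.15, aba_hub_r: float | None = None,
                      latent: dict[str, float] | None = None) -> HormoneTable:
    """Six hormone levels (ng/g, positive) per sample.

    Drought elevates ABA from day 2 and IAA from day 5 (multiplicative
    effects); multiplicative lognormal noise with sd ``noise_sd`` on the
    log2 scale.  With ``aba_hub_r`` and a per-sample ``latent`` mapping, the
    drought-side ABA values are coupled to the latent hub factor with the
    configured correlation sign.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    profiles = hormone_profiles(cfg, aba_effect, iaa_effect)
    day_of = design.day_of()
    cond_of = dict(zip(design.df["sample_id"], design.df["condition"]))
    var_of = dict(zip(design.df["sample_id"], design.df["variety"]))
    d0_shared = {s for s in design.sample_ids if day_of[s] == 0}

    samples = design.sample_ids
    values = np.zeros((len(HORMONES), len(samples)))
    for i, h in enumerate(HORMONES):
        for j, s in enumerate(samples):
            cond = "control" if s in d0_shared else cond_of[s]
            base = profiles[h][cond if cond in profiles[h] else cfg.conditions[0]]
            lvl = base[str(day_of[s])]
            values[i, j] = lvl * np.exp2(rng.normal(0.0, noise_sd))

    if aba_hub_r is not None and latent:
        if not -1.0 <= aba_hub_r <= 1.0:
            raise ConfigError("aba_hub_r must lie in [-1, 1]")
        i = HORMONES.index("ABA")
        for variety in design.varieties:
            dsel = [s for s in design.samples_for(variety, "drought")
                    if s in latent]
            if len(dsel) < 3:
                continue
            z = np.array([latent[s] for s in dsel])
            zc = (z - z.mean()) / z.std() if z.std() > 0 else z * 0.0
            eps = rng.normal(0.0, 1.0, len(dsel))
            struct = aba_hub_r * zc + np.sqrt(1 - aba_hub_r ** 2) * eps
            for s, v in zip(dsel, struct):
                j = samples.index(s)
                values[i, j] *= np.exp2(0.8 * v)

    return HormoneTable(pd.DataFrame(values, index=list(HORMONES),
                                     columns=samples), sheet=design)


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def pathway_table(cfg: SimConfig) -> PathwayTable:
    """Annotate the first n_pathway_genes: hub -> PP2C, partners and the rest
    cycle through the family list."""
    genes = cfg.gene_labels()
    annotated = genes[:cfg.n_pathway_genes]
    # make sure hub and partners are annotated
    extras = [g for g in [cfg.hub_gene] + [g for g, _ in cfg.hub_partners]
              if g in genes and g not in annotated]
    annotated = annotated + extras
    fam_iter = [f for f in FAMILY_CYCLE if f != "PP2C"]
    rows = []
    k = 0
    for g in genes:
        if g not in annotated:
            rows.append({"gene_id": g, "pathway": "", "family": ""})
            continue
        if g == cfg.hub_gene:
            fam = "PP2C"
        else:
            fam = fam_iter[k % len(fam_iter)]
            k += 1
        rows.append({"gene_id": g, "pathway": FAMILY_PATHWAY[fam], "family": fam})
    return PathwayTable(pd.DataFrame(rows))


def homolog_map(cfg: SimConfig) -> HomologMap:
    """Identity homolog map (both varieties share the synthetic gene universe)."""
    genes = cfg.gene_labels()
    return HomologMap(pd.DataFrame({
        "gene_id_v1": genes, "gene_id_v2": genes,
        "similarity": [1.0] * len(genes)}))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dataset:
    sheet: SampleSheet
    expression: ExpressionMatrix
    hormones: HormoneTable
    pathways: PathwayTable
    homologs: HomologMap
    truth: SimTruth

    def write(self, directory: str | Path, header_lines=()) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.sheet.write(directory / "samples.tsv", header_lines)
        self.expression.write(directory / "expression.tsv", header_lines)
        self.hormones.write(directory / "hormones.tsv", header_lines)
        self.pathways.write(directory / "pathways.tsv", header_lines)
        self.homologs.write(directory / "homologs.tsv", header_lines)
        (directory / "truth.json").write_text(self.truth.to_json() + "\n")


def simulate_dataset(cfg: SimConfig, **hormone_kwargs) -> Dataset:
    """Full synthetic dataset: design, expression, hormones, annotation, truth."""
    design = generate_design(cfg)
    expr, truth = simulate_expression(cfg, design)
    horm = simulate_hormones(cfg, design, **hormone_kwargs)
    truth = dataclasses.replace(truth, hormone_profiles=hormone_profiles(cfg))
    return Dataset(sheet=design, expression=expr, hormones=horm,
                   pathways=pathway_table(cfg), homologs=homolog_map(cfg),
                   truth=truth)


# ---------------------------------------------------------------------------
# deterministic hub fixture (two varieties, PP2C-centred sign structure)
# ---------------------------------------------------------------------------

FIXTURE_SEED = 20200527

#: per-variety partner families with target hub correlations (log2 scale);
#: |c| <= 0.83 keeps any partner-partner Pearson ~ c_i*c_j below 0.7
_FIXTURE_PARTNERS = {
    "K326": (("ABF", 0.83), ("SnRK2", 0.82), ("GID", 0.80),
             ("A-ARR", -0.82), ("BZR", -0.80), ("IAA", 0.81), ("SAUR", 0.80)),
    "BX": (("ABF", 0.82), ("SnRK2", 0.83), ("GID", 0.81),
           ("A-ARR", -0.81), ("BZR", -0.82), ("IAA", 0.80), ("SAUR", 0.81)),
}
#: BX carries a second, negatively correlated IAA-family copy -> mixed edge
_FIXTURE_EXTRA = {"BX": (("IAA", -0.78, 2),)}

_FIXTURE_DAY_TREND = {0: -1.5, 2: -0.8, 5: 0.0, 15: 0.8, 30: 1.5}


def _fixture_gene_rows(variety: str) -> list[tuple[str, str, float | None, int]]:
    """(gene_id, family, hub-correlation-or-None, copy) rows for one variety."""
    tag = "K" if variety == "K326" else "B"
    rows = [(f"{tag}_PP2C_1", "PP2C", None, 1)]
    for fam, c in _FIXTURE_PARTNERS[variety]:
        rows.append((f"{tag}_{fam.replace('-', '')}_1", fam, c, 1))
    for fam, c, copy in _FIXTURE_EXTRA.get(variety, ()):
        rows.append((f"{tag}_{fam.replace('-', '')}_{copy}", fam, c, copy))
    rows.append((f"{tag}_AUX1_1", "AUX1", None, 1))  # inert transient DEG
    return rows


def fig4_fixture() -> tuple[ExpressionMatrix, HormoneTable, PathwayTable, HomologMap]:
    """Deterministic two-variety dataset with a PP2C-centred common network.

    Running the full pipeline on it yields a common drought network in which
    the PP2C family node has strictly the highest degree, positive edges to
    ABF/SnRK2/GID, negative edges to A-ARR/BZR, and a mixed PP2C-IAA edge
    contributed by the BX-only negative IAA copy.  Fully reproducible
    (hard-coded seed).
    """
    return _fig4_data(FIXTURE_SEED)


def _fig4_data(seed: int) -> tuple[ExpressionMatrix, HormoneTable, PathwayTable, HomologMap]:
    design = fixture_design()
    rng = np.random.default_rng([seed, 7])
    day_of = design.day_of()

    all_rows = {v: _fixture_gene_rows(v) for v in ("K326", "BX")}
    gene_ids = [g for v in ("K326", "BX") for g, *_ in all_rows[v]]
    samples = design.sample_ids
    si = {s: i for i, s in enumerate(samples)}
    x = np.zeros((len(gene_ids), len(samples)))
    gi = {g: i for i, g in enumerate(gene_ids)}

    b_amp = 1.3      # latent amplitude, log2 units
    base = 5.5       # baseline log2 abundance
    ctrl_sd = 0.30   # control replicate noise

    for variety in ("K326", "BX"):
        dsel = design.samples_for(variety, "drought")
        csel = [s for s in design.samples_for(variety, "control") if day_of[s] > 0]
        other = [s for s in samples if s not in set(dsel) | set(csel)]
        dcols = [si[s] for s in dsel]

        z = np.array([_FIXTURE_DAY_TREND[day_of[s]] for s in dsel])
        z = z + rng.normal(0.0, 0.08, len(z))
        z = (z - z.mean()) / z.std()

        for gene, fam, c, _copy in all_rows[variety]:
            row = gi[gene]
            if fam == "PP2C":
                struct = z
                d0_level = float(z[:3].mean())
            elif fam == "AUX1" and c is None:
                # transient, trend-orthogonal profile: DEG at d2/d5 only
                prof = {0: 0.0, 2: 1.8, 5: 1.8, 15: 0.0, 30: 0.0}
                struct = (np.array([prof[day_of[s]] for s in dsel])
                          + rng.normal(0.0, 0.12, len(dsel))) / b_amp
                d0_level = float(struct[:3].mean())
            else:
                # residual: day-level dominant (tight replicates for the
                # Welch+BH stage) and orthogonalized against the latent
                # trend so the hub-partner sample Pearson r equals c exactly
                u_day = rng.normal(0.0, 1.0, len(_FIXTURE_DAY_TREND))
                u = (np.array([u_day[sorted(_FIXTURE_DAY_TREND).index(day_of[s])]
                               for s in dsel]) * 0.25
                     + rng.normal(0.0, 0.95, len(dsel)))
                u = u - u.mean()
                u = u - (u @ z) / (z @ z) * z
                u = u / u.std()
                struct = c * z + np.sqrt(1.0 - c * c) * u
                d0_level = float(struct[:3].mean())
            x[row, dcols] = base + b_amp * struct
            # control: flat at the gene's day-0 level
            ccols = [si[s] for s in csel]
            x[row, ccols] = (base + b_amp * d0_level
                             + rng.normal(0.0, ctrl_sd, len(ccols)))
            # other variety's samples: inert baseline noise
            ocols = [si[s] for s in other]
            x[row, ocols] = base + rng.normal(0.0, ctrl_sd, len(ocols))

    fpkm = np.clip(np.exp2(x) - 1.0, 0.0, None)
    expr = ExpressionMatrix(pd.DataFrame(fpkm, index=gene_ids, columns=samples),
                            sheet=design)

    # hormones: flat-ish profiles with day-level noise; ABA/IAA drought effects
    hvalues = np.zeros((len(HORMONES), len(samples)))
    cond_of = dict(zip(design.df["sample_id"], design.df["condition"]))
    for i, h in enumerate(HORMONES):
        day_noise = {(v, c, d): rng.normal(0.0, 0.35)
                     for v in ("K326", "BX") for c in CONDITIONS
                     for d in _FIXTURE_DAY_TREND}
        for j, s in enumerate(samples):
            day = day_of[s]
            cond = "control" if day == 0 else cond_of[s]
            v = design.df.loc[design.df["sample_id"] == s, "variety"].iloc[0]
            mult = 1.0
            if cond == "drought":
                if h == "ABA" and day >= 2:
                    mult = 3.0
                elif h == "IAA" and day >= 5:
                    mult = 2.5
            lvl = HORMONE_BASE[h] * mult
            hvalues[i, j] = lvl * np.exp2(day_noise[(v, cond, day)]
                                          + rng.normal(0.0, 0.10))
    horm = HormoneTable(pd.DataFrame(hvalues, index=list(HORMONES),
                                     columns=samples), sheet=design)

    prows = [{"gene_id": g, "pathway": FAMILY_PATHWAY[fam], "family": fam}
             for v in ("K326", "BX") for g, fam, *_ in all_rows[v]]
    pathways = PathwayTable(pd.DataFrame(prows))

    hrows = []
    bx_by_fam: dict[str, list[str]] = {}
    for g, fam, *_ in all_rows["BX"]:
        bx_by_fam.setdefault(fam, []).append(g)
    for g, fam, *_ in all_rows["K326"]:
        for g2 in bx_by_fam.get(fam, []):
            hrows.append({"gene_id_v1": g, "gene_id_v2": g2, "similarity": 1.0})
    homologs = HomologMap(pd.DataFrame(hrows))

    return expr, horm, pathways, homologs


def fixture_design() -> SampleSheet:
    # 5 replicates (vs the study's 3) so the consensus thresholds have
    # comfortable sampling margins in a deterministic fixture
    cfg = SimConfig(seed=FIXTURE_SEED, n_replicates=5)
    design = generate_design(cfg)
    df = design.df.copy()
    df["variety"] = df["variety"].map({"V1": "K326", "V2": "BX"})
    df["sample_id"] = [sid.replace("V1", "K326").replace("V2", "BX")
                       for sid in df["sample_id"]]
    return SampleSheet(df)


def fixture_truth() -> dict:
    """Planted sign structure of the fixture's common network."""
    return {
        "hub": "PP2C",
        "positive": ["ABF", "SnRK2", "GID", "SAUR"],
        "negative": ["A-ARR", "BZR"],
        "mixed": {"IAA": ["BX"]},
    }


def write_fixture(directory: str | Path) -> None:
    """Write the fixture as a self-contained TSV/JSON directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr, horm, pathways, homologs = fig4_fixture()
    fixture_design().write(directory / "samples.tsv")
    expr.write(directory / "expression.tsv")
    horm.write(directory / "hormones.tsv")
    pathways.write(directory / "pathways.tsv")
    homologs.write(directory / "homologs.tsv")
    (directory / "truth.json").write_text(
        json.dumps(fixture_truth(), indent=2, sort_keys=True) + "\n")
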