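# hormnet

A tested, reusable pipeline from time-course expression matrices and hormone
measurements to a cross-variety **common hormone-signaling regulatory
network** and its pivotal hub, for two-variety drought time-course designs
(2 varieties × {control, drought} × 5 sampling days × replicates, with day 0
as the shared baseline).

Stages:

1. **deg** — stage-wise differential expression (drought vs control at the
   same day): Welch's t on log2(FPKM+1), BH adjustment per stage, DEG rule
   `|log2FC| ≥ 1 AND FDR < 0.01`; Venn/adjacent-stage overlap accounting and
   cross-variety common-DEG counting via a homolog map.
2. **corrnet** — per variety × condition consensus correlation network over
   hormone-pathway DEGs and hormone levels: an edge requires
   `|r| > 0.7 AND p < 0.05` under **both** Pearson and Spearman
   (t-approximation p-values; correlations computed on log2(x+1) values).
3. **diffnet** — gained / lost / stable edge classification between
   conditions, and the cross-variety **common network**: gene-level drought
   edges collapsed to protein-family level, kept only if present in every
   variety, with per-sign mean coefficients and mixed-sign edges labelled by
   the variety contributing the minority sign.
4. **hubs** — degree (distinct-neighbor) ranking; maximal-degree node(s)
   flagged pivotal.
5. **stats** — one-way ANOVA + Duncan's multiple range test (studentized-
   range quantiles, protection levels `α_p = 1 − (1−α)^(p−1)`, step-down
   non-contradiction) with compact letter displays, for hormone/phenotype
   group comparisons.
6. **synthio** — synthetic data with the design's statistical structure:
   planted ≥2-fold DEGs, drought-elevated ABA/IAA hormone profiles, a
   planted hub-centred correlation structure (drought only), plus a
   deterministic fixture whose end-to-end common network has a strictly
   maximal PP2C-family hub with positive PP2C–ABF/SnRK2/GID and negative
   PP2C–A-ARR/BZR edges.

## CLI

```sh
hormnet simulate --out data/ --seed 1          # synthetic dataset (TSVs + truth.json)
hormnet simulate --fixture --out fixture/      # deterministic hub fixture
hormnet run-all --data fixture/ --out results/ # full pipeline
hormnet deg --expression data/expression.tsv --samples data/samples.tsv \
    --variety K326 --out deg.tsv --summary overlaps.json
hormnet network --expression ... --hormones ... --pathways ... \
    --deg-table deg.tsv --samples ... --variety K326 --condition drought \
    --format sif --out net.sif
hormnet hubs --network net.tsv --out hubs.tsv --summary hub.json
hormnet duncan --table data/hormones.tsv --samples data/samples.tsv \
    --factor condition-within-day --out duncan.tsv
```

Networks export as SIF / GraphML (Cytoscape-ingestible) or full TSV edge
tables. A YAML config (`hormnet --config cfg.yaml ...`) supplies defaults
that flags override; outputs carry provenance headers.

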