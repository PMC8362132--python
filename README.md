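# sizehab

Multi-scale phylogenetic comparison of body size between habitat-use
categories, with a rule-based classifier for candidate mechanism suites.

Given a rooted phylogeny (Newick) and a taxon table (TSV) assigning each
species a habitat-use category — `marine`, `freshwater`, `brackish`,
`marine_brackish`, `freshwater_brackish`, `euryhaline` — a maximum length
and optional trophic level / migratory flag / taxonomy labels, the pipeline:

1. **partitions** the dataset into named *observation scales*: per-family,
   per-order, deterministic tree partitions into 13/9/5/3 monophyletic
   sections (`tax3`–`tax6`), the full dataset, and transition *hotspots*
   (clades ranked by stochastic-map habitat changes per tip, optionally
   merged with their sisters);
2. **counts habitat transitions** by fitting an Mk model (ER/SYM/ARD,
   pruning likelihood, multi-start ML) and averaging stochastic character
   maps sampled by endpoint-conditioned uniformization;
3. **compares** every habitat pair within every clade of every scale under
   five size metrics: difference of log10 means, difference of
   phylogenetic (GLS) means, Wilcoxon rank-sum, simulation-based
   phylogenetic ANOVA with a Brownian null, and PGLS ANOVA with residual
   randomisation — plus observed-vs-simulated variance and per-habitat
   summaries (richness, migratory %, mean tip branch duration);
4. applies the **reduce-and-retain** protocol: prune to trophic-complete
   taxa, rerun the size comparisons, and keep only comparisons whose size
   direction survives the pruning;
5. computes **percentage alignments** between metric pairs and
   signed-difference regressions with sign-quadrant counts and a
   leave-one-out influence report;
6. **classifies mechanism support** per retained comparison (trophic rule
   A/A′, migration rule Bi with a 20-percentage-point threshold, the
   derived Bii/Biii splits, tip-duration rule C, richness rule D) and
   aggregates per-pair and overall percentages including the Bii′/Biii′
   ratios and the A∨Biii and any-of-four unions.

A seeded synthetic-data generator (birth–death tree, Mk habitat evolution
with a full event log, habitat-shifted Brownian sizes, size-correlated
trophic levels, habitat-specific migratory fractions, nested monophyletic
taxonomy labels) makes every stage testable without external data.

## CLI

Each subcommand consumes the previous stages' TSVs; `run` does everything:

```bash
# synthetic dataset: tree.nwk, taxa.tsv, truth.json
sizehab simulate --n-tips 300 --seed 1 --out data/

# Mk fit + stochastic maps -> transitions.tsv, tip_events.tsv
sizehab transitions --tree data/tree.nwk --taxa data/taxa.tsv \
    --constraint ARD --n-maps 100 --seed 1 --out trans/

# observation scales (hotspots need the transitions output)
sizehab partition --tree data/tree.nwk --taxa data/taxa.tsv \
    --scales order,tax3,tax4,tax5,tax6,full,hotspot \
    --transitions-dir trans/ --out scales.tsv

# all clade x habitat-pair comparisons
sizehab compare --tree data/tree.nwk --taxa data/taxa.tsv \
    --scales-tsv scales.tsv --out results.tsv --majority-out majority.tsv

# full pipeline from a config file
sizehab run --config config.yaml --out outdir/
```

Minimal `config.yaml`:

```yaml
simulate: {n_tips: 300}     # or: tree_path: ..., taxa_path: ...
scales: [order, tax3, tax4, tax5, tax6, full]
metrics: [mean_log10, phylo_mean, wilcoxon]
mk_constraint: ER
n_maps: 100
seed: 1
```

Outputs are TSVs (long-format comparison results, majority summaries,
alignment cells, mechanism ledger/summary, transition counts) plus a
`manifest.json` with per-stage counts and derived seeds; identical
config + seed reproduces byte-identical outputs.

## Taxon table format

Tab-separated with header columns `species`, `habitat`, `max_length_cm`
(required) and `trophic_level`, `migratory`, `family`, `order` (optional).
Sizes are log10-transformed once at ingest. Species names match tree tips
exactly after space/underscore normalisation.

## Package layout

| module | contents |
|---|---|
| `sizehab.model` | `TaxonRecord`, `Dataset`, taxon-table I/O, tree-table matching |
| `sizehab.tree` | `Phylogeny`, Newick I/O, Brownian covariance, BM simulation |
| `sizehab.simulate` | seeded synthetic-data generator + true history |
| `sizehab.scales` | observation scales, deterministic tree partitioner, hotspots |
| `sizehab.stats` | the five size metrics, variance-vs-sim, habitat summaries |
| `sizehab.transitions` | Mk likelihood/fit, stochastic character mapping |
| `sizehab.engine` | comparison enumeration/running, majorities, reduce-and-retain |
| `sizehab.mechanisms` | alignments, regressions, mechanism classifier/aggregator |
| `sizehab.pipeline`, `sizehab.cli` | config-driven orchestration and CLI |
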