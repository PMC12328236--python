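# linpert

Linear baselines, genetic-interaction statistics and a benchmark harness for
predicting transcriptome changes after single and double genetic
perturbations (Perturb-seq style data).

The package provides:

- **Data model** (`linpert.data_model`) — condition-label parsing
  (`"ctrl"` / `"GENE+ctrl"` / `"GENEA+GENEB"`), h5ad and tab-separated
  pseudobulk readers, per-condition pseudobulk aggregation, read-out gene
  selection and seeded test–train splits.
- **Embeddings** (`linpert.embeddings`) — PCA gene embeddings, perturbation
  rows derived from gene coordinates, spectral embeddings of pathway
  membership matrices, PCA perturbation embeddings from reference
  perturbation data, random embeddings, and loaders for external
  tab-separated embedding tables.
- **Baselines** (`linpert.baselines`) — the no-change, mean and additive
  models, the bilinear ridge linear model
  `Y ≈ G W Pᵀ + b` with its closed-form two-sided ridge solve
  (default penalty 0.1), and a generic per-gene ridge decoder from
  perturbation-level embeddings.
- **Interactions** (`linpert.interactions`) — deviation-from-additivity
  matrices, an empirical-null mixture decomposition (spline-Poisson density
  estimate, truncated-Normal central fit, local and tail-area false
  discovery rates), FDR-thresholded interaction calling and the
  buffering / synergistic / opposite / other classification.
- **Evaluation** (`linpert.evaluation`) — L2 and Pearson-delta metrics,
  FDP–TPR benchmark curves with the monotone-envelope transform, and
  bootstrap relative-error confidence intervals against a baseline model.
- **Synthetic data** (`linpert.synthetic`) — a seeded generator of
  cell-level datasets with known low-rank structure, additive double
  perturbations and planted interactions of chosen classes, plus a direct
  two-component delta-mixture sampler.
- **CLI** (`linpert.cli` / `linpert.pipeline`) — subcommands `simulate`,
  `pseudobulk`, `split`, `fit`, `predict`, `interactions`, `evaluate`,
  `benchmark-double` and `benchmark-single`, with YAML benchmark configs.

## CLI quick start

```sh
# generate a synthetic dataset with planted interactions
linpert simulate out/sim --n-genes 1000 --n-singles 100 --n-doubles 124 \
    --cells-per-condition 4 --interaction-fraction 0.05 --seed 0

# call genetic interactions at FDR 5%
linpert interactions out/sim/pseudobulk.tsv out/calls.tsv --fdr-level 0.05

# run the double-perturbation benchmark from a config
linpert benchmark-double config.yaml
```

A minimal `config.yaml`:

```yaml
dataset: out/sim/pseudobulk.tsv
protocol: double-holdout
n_replicates: 5
test_fraction: 0.5
top_n_genes: 1000
output_dir: out/benchmark
```

External model predictions are ingested as genes × perturbations
tab-separated matrices (`{"name": ..., "type": "external", "path": ...}`
entries in the config's `models` list), so arbitrary predictors can be
scored without being re-run here.

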