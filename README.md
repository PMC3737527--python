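# conet

Enhancer co-activity networks from binary chromatin-accessibility profiles.

`conet` re-implements, as a tested and reusable pipeline, a network-level
analysis of correlated enhancer activity across cell types:

* **Activity matrix** — enhancer regions are built from P300-style peaks
  (merge overlaps, fixed-length re-centering) and crossed with per-cell-type
  DHS peak sets into a binary enhancer × cell-type matrix; cell types can be
  reduced to cluster representatives (average linkage, Russell–Rao
  dissimilarity, inconsistency cut).
* **Co-activity calling** — enhancer pairs are scored with plug-in mutual
  information (bits). A distance-binned autocorrelation model, estimated from
  random genomic segments, drives a synthetic-partner null that preserves
  per-cell-type marginals and along-genome correlation; pairs are called per
  distance bin at a monotonized empirical FDR and optionally reduced to a
  matching by greedy transitive pruning.
* **Motif analysis** — per-motif co-occurrence scores (observed / p²),
  1-df chi-squared significance with BH correction, a three-step
  foreground-specific filter (BH, empirical FDR against background p-values,
  background-significance removal), motif similarity clustering, pair
  classification by cross-validated linear SVM, and CME interaction
  preference (Fisher exact).
* **Network analysis** — dual-threshold degrees (strict/relaxed FDR), strong
  fraction by degree bin, strong/weak assortativity, MI-thresholded
  connected-component clusters with motif-sharing filters and
  footprint-matched background clusters.
* **Target & spatial analysis** — nearest-TSS gene mapping, target
  co-expression contrasts (Spearman/rank-sum), motif-Jaccard vs
  co-expression regression, annotation-term sharing and hypergeometric
  cluster enrichment, tissue-class concordance ranks, and contact (Hi-C-like)
  enrichment against accessibility-matched uncorrelated pairs.
* **Synthetic data** — a generator that plants co-active enhancer modules
  (shared latent activity, driver motifs, coupled target-gene expression,
  coherent strength labels, within-module contacts, shared annotation terms)
  on a genome whose background accessibility follows a two-state Markov
  process with exponential distance decay. It emits every input the pipeline
  consumes, plus ground truth for recovery tests.

## Tests

```
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the
statistical contracts end to end: MI oracle equivalence, synthetic-null
fidelity (KS), distance decay, FDR calibration on null genomes, planted
module and driver-motif recovery, direction-of-effect reproduction for all
downstream contrasts, classification behaviour and exact-test oracles.

## CLI

```
conet all --config pipeline.yaml --seed 1 --out results/
```

Stages (`simulate`, `matrix`, `pairs`, `motifs`, `network`, `targets`,
`spatial`, `all`) run in dependency order; each stage command runs exactly
its stage and expects earlier outputs to exist in the output directory.
The YAML config mirrors `conet.pipeline.PipelineConfig`; flags override
config values. Every stage writes TSV outputs plus a JSON metadata sidecar,
and identical config + seed reproduce byte-identical outputs.

Minimal config example:

```yaml
seed: 1
simulation:
  n_enhancers: 2000
  n_modules: 20
  module_size: 10
  flip_noise: 0.1
bin_edges: [25000, 300000, 1000000, 3000000, 12500000]
alpha_strict: 0.01
alpha_relaxed: 0.05
```

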