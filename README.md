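# braincoex

Signed weighted gene co-expression network analysis for developmental brain
transcriptomes, with resampling-based tests for rare-variant gene-set
enrichment in co-expression modules.

## Scientific background

Genes that act together in a developing tissue tend to be co-expressed
across samples. `braincoex` builds a **signed weighted co-expression
network** from a genes × samples expression matrix, detects **modules** of
tightly co-expressed genes, summarizes each module by its **eigengene**
(first principal component), and asks whether externally defined gene sets
— for example, genes hit by rare coding or regulatory variants in cases
versus controls — are over-represented in particular modules.

The statistical pipeline is:

1. **Adjacency.** Pairwise Pearson (or Spearman) correlations r_ij are
   mapped to a signed adjacency a_ij = ((1 + r_ij)/2)^β, so strongly
   anti-correlated genes get near-zero weight rather than high weight. The
   soft-threshold power β is chosen as the smallest candidate whose
   connectivity distribution satisfies an approximate scale-free topology
   criterion (R² ≥ 0.8 on a log–log frequency fit).
2. **Topological overlap.** The adjacency is transformed into the
   topological overlap measure ω_ij, which rewards shared network
   neighborhoods, and modules are cut from an average-linkage hierarchical
   clustering of the dissimilarity 1 − ω.
3. **Module refinement.** Modules whose eigengenes are closer than a merge
   height (default 0.15, i.e. correlation > 0.85) are merged iteratively;
   modules that are too small or whose genes are weakly correlated with
   their own eigengene (mean kME below 0.75) are dropped.
4. **Enrichment.** For each (module, gene set) pair the test statistic is a
   resampling z-score: draw a fixed number of genes (default 800) without
   replacement from the gene set, standardize the module overlap of each
   draw against its binomial expectation under uniform sampling from the
   background, and average over iterations (default 10,000). Subsampling
   equalizes the sizes of case and control sets so their z-scores are
   directly comparable. One-tailed binomial overlap tests against curated
   reference sets and hypergeometric GO term over-representation are also
   provided. Multiple testing uses Holm's step-down Bonferroni procedure.

Samples can be stratified by developmental stage (five bins from early
fetal to adult) or by anatomical region cluster (four groups covering 16
brain region codes), and the full pipeline runs per stratum with a
deterministic manifest of output hashes.

## Worked example

Simulate expression data with four planted modules, detect them, and test a
planted "case" variant set against a uniform "control" set:

```python
from braincoex.simulate import generate_expression, generate_variant_sets
from braincoex.network import (
    pairwise_correlation, signed_adjacency, topological_overlap,
)
from braincoex.modules import detect_modules
from braincoex.enrichment import enrichment_table

expr, truth = generate_expression(n_modules=4, module_size=50,
                                  n_background_genes=0, n_samples=100,
                                  kme_target=0.85, seed=0)
cor = pairwise_correlation(expr)
adj = signed_adjacency(cor, beta=12)
tom = topological_overlap(adj)
modules = detect_modules(expr, tom, merge_height=0.15)
print("module sizes:", modules.module_sizes)

case = generate_variant_sets(truth, 60, 1, fold=2.5, seed=1, name="case")
ctrl = generate_variant_sets(truth, 60, 1, fold=1.0, seed=2,
                             name="control", category="control")
table = enrichment_table(
    {m: modules.genes_in(m) for m in modules.module_labels},
    [case, ctrl], expr.gene_ids, sample_size=50, n_iter=2000, seed=3,
)
print(table.round(3).to_string(index=False))
```

Output:

```text
module sizes: {1: 50, 2: 50, 3: 50, 4: 50}
 module     set  observed  expected  null_mean  null_sd      z     p  p_adj
      1    case        37      12.5     30.895    1.437  6.008 0.000  0.000
      2    case         5      12.5      4.166    0.797 -2.722 0.997  1.000
      3    case         9      12.5      7.477    0.994 -1.641 0.950  1.000
      4    case         9      12.5      7.509    1.055 -1.630 0.948  1.000
      1 control        13      12.5     10.850    1.210 -0.539 0.705  1.000
      2 control        10      12.5      8.320    1.083 -1.365 0.914  1.000
      3 control        20      12.5     16.639    1.371  1.352 0.088  0.618
      4 control        17      12.5     14.174    1.305  0.547 0.292  1.000
```

All four planted modules are recovered exactly, and the case set — drawn
with 2.5-fold enrichment for genes of planted module 1 — is flagged in that
module (z = 6.0, Holm-adjusted p < 0.001) while the uniform control set is
not.

## Command-line interface

The same workflow is available as a CLI:

```bash
braincoex simulate --n-modules 3 --module-size 40 --n-samples 60 \
    --seed 4 --out simdata/
braincoex run-all --config config.yaml --out run/
```

`run-all` reads a YAML configuration (paths to expression, metadata,
GMT gene sets and optional GO annotation, plus network and enrichment
parameters), applies RIN-based quality filtering and the chosen sample
stratification, and writes per-stratum TSV outputs together with a
`manifest.json` listing SHA-256 hashes of every output file. Runs are
byte-for-byte reproducible for a fixed configuration and seed.

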