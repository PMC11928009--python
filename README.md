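# moglearn

Multi-omics graph learning for tumor-type classification: statistical
feature selection, two graph constructions, and three graph neural
network classifiers, with a reproducible training, evaluation, and
comparison harness.

## The problem

Tumor typing from molecular profiles improves when several omics layers
— mRNA expression, miRNA expression, DNA methylation — are analyzed
jointly, because each layer captures partly complementary biology. The
practical obstacles are dimensionality (10^4–10^5 features per layer
against 10^3–10^4 samples) and finding a representation that exposes
relationships between samples or between genes. `moglearn` addresses
both with a three-stage selection cascade and graph-based classifiers:

1. **Feature selection.**
   * mRNA counts: per-gene negative-binomial GLM (log link, library-size
     offset, method-of-moments dispersion) with a Wald test,
     keeping features at p < 0.001.
   * Methylation: per-CpG empirical-Bayes **moderated t** — residual
     variances shrunk toward a scaled-F prior fitted across features —
     keeping features at p < 0.05.
   * Both filtered sets then pass through **LASSO**,
     `min_b 1/(2n)·||y − Xb||² + λ·||b||₁`, solved by cyclic coordinate
     descent with soft-thresholding, one-vs-rest over classes with λ
     chosen by internal cross-validation; the union of nonzero supports
     is the final feature set. miRNA passes through unselected.
2. **Integration.** Inner join of the selected layers on sample ID.
3. **Graphs.** Either a *sample-correlation graph* (edge between samples
   with Pearson r ≥ 0.9 on the integrated features; transductive node
   classification) or a *protein-interaction graph* (genes as nodes,
   STRING-style scored edges, per-sample multi-omics channel vectors on
   each node; per-sample graph classification).
4. **Classifiers.** GCN (symmetric-normalized convolutions,
   `σ(D^-1/2(A+I)D^-1/2 H W)`), GAT (multi-head softmax attention over
   neighborhoods, schedule 1024/8 → 512/4 → 256/2 → 32/1), and a graph
   transformer (two layers of masked scaled-dot-product attention,
   `softmax(QKᵀ/√d_k)V`). All three are implemented in NumPy with
   explicit backpropagation, verified against dense-matrix oracles and
   finite-difference gradients.
5. **Comparison.** Paired Wilcoxon signed-rank tests (exact by dynamic
   programming for n ≤ 25, Pratt zero handling) with Benjamini–Hochberg
   adjustment decide whether multi-omics integration significantly beats
   each single layer on accuracy, precision, recall, F1, ROC-AUC, and
   AUPR.

A seeded synthetic-data module generates NB-distributed counts,
beta-scale methylation, partially overlapping sample IDs, and a planted
interaction network, so the entire pipeline is testable end to end
without any external download. See `docs/methods.md` for models,
defaults, and limitations.

## Worked example

```bash
moglearn simulate --out run/ds --samples-per-class 25 --classes 4 --seed 7
moglearn select   --data run/ds --out run/sel --seed 7
moglearn integrate --data run/ds --selection run/sel --out run/integ
moglearn build-graph --integrated run/integ --out run/graph --correlation-threshold 0.4
moglearn train    --integrated run/integ --out run/gcn --arch gcn --correlation-threshold 0.4 --seed 7
```

The `select` stage writes `selection_report.tsv` summarizing the cascade
(this run):

```
layer        original  post_filter  post_lasso
mrna              200           22          22
mirna              60           60          60
methylation       200           26          26
```

200 mRNA features shrink to 22 at the Wald filter; methylation shrinks
200 → 26; miRNA passes through. `integrate` reports the inner join
(`integrated 73 samples x 108 features`: 100 simulated samples, 10%
dropped per layer independently), `build-graph` the resulting topology
(`73 nodes, 101 edges, density 0.0384`, with a warning about isolated
nodes at this threshold), and `train` prints 5-fold cross-validated test
metrics for the GCN on the sample graph:

```
accuracy     0.9867
precision    0.9900
recall       0.9875
f1           0.9873
roc_auc      1.0000
aupr         1.0000
```

High scores are expected here: the simulated signal is strong and all
four classes carry it in every layer jointly.

The full multi- vs single-omics comparison (all architectures, all
omics combinations, Wilcoxon tests) is one command:

```bash
moglearn compare --data run/ds --out run/compare --seed 7
```

which writes per-fold metrics, a mean±sd summary, and per-architecture
Wilcoxon tables (`report.md`, `comparisons.json`). On synthetic data
with class signal split across the three layers, the three-layer
combination outperforms every single layer for each architecture, and
the attention model's advantage is significant at BH-adjusted p < 0.05
on all six metrics.

The same workflow is available as a library — `simulate_multiomics`,
`run_selection`, `integrate`, `build_sample_graph` /
`build_feature_graph`, `build_model`, `train_model`,
`run_comparison_suite` — see the docstrings.

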