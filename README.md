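# epmkit

Sample-specific **edge perturbation** in gene interaction networks: a toolkit
for stratifying tumor samples by how far each network edge's relative
expression deviates from a healthy benchmark, and for turning those strata
into a prognostic score.

It is aimed at computational biologists who have (a) a background
gene–gene interaction network (e.g. merged pathway interactions), (b)
TPM-like expression matrices for a tumor cohort and a normal cohort, and
optionally (c) survival data — and who want a network-level, rank-based
alternative to plain expression clustering. Everything is also runnable on
built-in synthetic data, so the whole analysis can be exercised and tested
without any external download.

## The statistic

Within each sample *s*, genes in the network are ranked by expression
(ascending, average ranks on ties): rᵢ,ₛ. For an edge *e = (i, j)* the
**delta rank** is

    δₑ,ₛ = rᵢ,ₛ − rⱼ,ₛ

A **benchmark** δ̄ₑ is the same quantity computed from the single vector of
per-gene mean expression over the normal cohort. The **edge perturbation** of
sample *s* is

    Δₑ,ₛ = δₑ,ₛ − δ̄ₑ

and the edges × samples matrix of Δₑ,ₛ is the **edge-perturbation matrix
(EPM)** — near zero for healthy-like samples (gene rankings in normal tissue
are highly conserved), large where a sample's relative expression order is
rewired. Because it is rank-based, the EPM is invariant under any strictly
increasing per-sample transform of expression.

Downstream of the EPM:

- **feature edges** — intersection of the top-K edges by Kruskal–Wallis
  tumor-vs-normal significance and the top-K by SD across tumor samples;
- **consensus clustering** — subsampled PAM (k-medoids, Euclidean) aggregated
  into consensus matrices; the cluster number is read off the relative change
  in the area under the consensus CDF;
- **IGP validation** — in-group proportion of each cluster in an independent
  cohort (fraction of assigned validation samples whose nearest neighbour
  gets the same assignment);
- **characteristic groups** — complete-linkage groups of feature edges in
  which > 70 % of edges have |mean z-scored perturbation| > 0.5 for a
  cluster, plus hypergeometric gene-set enrichment of their endpoint genes;
- **SPGIScore** — pairwise cluster DEGs recurrent in ≥ 4 comparisons →
  univariate Cox screen (p < 0.05) → LASSO-Cox with 10-fold cross-validated
  penalty; score = Σᵢ Coefᵢ·xᵢ, dichotomized at the training median and
  evaluated by log-rank test, concordance, and IPCW time-dependent AUC.

## Worked example

`examples/` contains one short script per capability. From
`examples/02_cluster_and_validate.py` (synthetic data, 300 genes, 4 planted
tumor clusters of 20 samples, 50 perturbed edges each):

```
187 feature edges over 158 genes
relative CDF-area change: {2: 0.415, 3: 0.563, 4: 0.172, 5: 0.044, 6: 0.04}
chosen k = 4; ARI vs planted truth = 1.000
per-cluster IGP in the validation cohort: {0: 1.0, 1: 1.0, 2: 1.0, 3: 1.0}
```

The CDF-area increase stays above the 0.05 floor up to k = 4 and collapses
after, so 4 clusters are chosen; they match the planted truth exactly
(adjusted Rand index 1.0), and every cluster reappears intact (IGP 1.0) in an
independently generated validation cohort. `examples/04_prognostic_score.py`
then builds the signature and prints, for a held-out cohort:

```
held-out: concordance 0.875, log-rank p 5.93e-35, 1y AUC 0.968
```

i.e. the learned score orders unseen patients' survival correctly 87 % of the
time and the median split separates their survival curves decisively.

The full pipeline is one call (or `epmkit run --out DIR --seed 17` from the
shell): it simulates data, builds the EPM, selects features, clusters,
characterizes, fits the signature, and writes plain-text artifacts plus a
manifest; the same seed reproduces every output byte for byte.

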