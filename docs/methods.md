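# Methods

## Model and assumptions

The analysis rests on one premise: in healthy tissue the relative expression
order of interacting gene pairs is conserved across individuals, whereas
tumors rewire it. Edge perturbation quantifies the rewiring per sample and
per edge as Δₑ,ₛ = δₑ,ₛ − δ̄ₑ, where δₑ,ₛ = rᵢ,ₛ − rⱼ,ₛ is the within-sample
rank difference of the edge's endpoints and δ̄ₑ is the same quantity computed
from the rank vector of per-gene **mean** expression over the normal cohort
(a single benchmark vector, not a mean of per-sample deltas). Ranks are
ascending over exactly the network-aligned gene universe, with average ranks
on ties, so per sample they sum to n(n+1)/2 and |δ| ≤ n − 1. Only the order
of expression values matters: any strictly increasing per-sample transform
leaves a sample's EPM column bit-identical, which is what makes the statistic
robust to monotone normalization differences between platforms.

Edges are stored in a canonical orientation (lexicographically smaller gene
first, edge IDs `geneA|geneB`, edge list sorted). The orientation convention
is arbitrary but must be applied identically to tumor, normal and benchmark:
flipping an edge negates both δ and δ̄ and hence only flips the sign of Δ.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `zero_fraction_threshold` | 0.7 | drop genes with exact zeros in **more than** this fraction of a cohort's samples (strict inequality; the boundary gene is kept) |
| `top_k_test`, `top_k_sd` | 60 000 | top-K edges by KW significance / by tumor SD; feature edges are the intersection. K is clipped to the edge count with a warning on small networks |
| `reps`, `sample_fraction` | 1000, 0.8 | consensus resampling: repetitions and per-repetition fraction of samples (all features kept) |
| `min_rel_increase` | 0.05 | floor on the relative CDF-area increase for choosing k (largest k above the floor wins; the full Δ(k) profile is reported for manual override) |
| `n_groups`, `min_size` | 100, 30 | complete-linkage edge groups and the size filter; characteristic rule: fraction of member edges with \|mean z\| > 0.5 must exceed 0.7 |
| `deg_fdr`, `min_abs_log2fc` | 0.05, 1.0 | DEG call per cluster pair (Welch t on log2(x+1), BH within pair) |
| `deg_min_occurrences` | 4 | recurrence filter over the pairwise DEG lists |
| `cox_p_threshold` | 0.05 | univariate Cox screen (Efron ties, Wald p) |
| `n_folds` | 10 | cross-validation folds for the LASSO-Cox penalty |

Time is in days; AUC horizons are specified in years (365.25 d/y).

## Numerical and design choices

- **Tie handling** — average ranks throughout (rank sums invariant; dominant
  convention).
- **KW scan** — vectorized tie-corrected H over all edges with a χ²(1)
  p-value (two groups); `scipy.stats.kruskal` is used only as a per-edge test
  oracle. Ranking for selection is by ascending p, ties broken by descending
  H then edge ID, so selection is deterministic; SD is computed over tumor
  samples only.
- **PAM** — deterministic: greedy BUILD (start at the point minimizing total
  distance, add the largest-gain point), then best-improvement SWAP; all ties
  break to the lowest sample index. Implemented here because no installed
  dependency provides k-medoids; verified against exhaustive medoid
  enumeration on small instances.
- **Consensus** — entries are co-cluster counts over co-subsample counts;
  pairs never co-subsampled get 0 with a warning. Final per-k labels come
  from average-linkage hierarchical clustering of 1 − consensus. The CDF area
  uses the empirical CDF of the off-diagonal entries; Δ(k) is A(k_min) for
  the smallest k and the relative increase thereafter. Constant input (zero
  baseline area) degrades gracefully to k_min with a warning.
- **IGP** — validation samples are assigned to the nearest discovery centroid
  in Euclidean distance on per-edge z-scored values; a cluster's IGP is the
  fraction of its assigned samples whose nearest validation neighbour
  (self excluded) shares the assignment. Clusters receiving < 2 validation
  samples report NaN rather than a misleading number.
- **Edge grouping** — complete linkage with Euclidean distance (the linkage
  method is prescribed by the workflow; the metric was an open choice and
  Euclidean is the natural companion on z-scored rows). Cluster/group means
  are per-cluster means of globally z-scored values.
- **DEG engine** — Welch t on log2(x+1) with BH, not a moderated-variance
  fit: the DEG step is a feeder whose thresholds are configurable and
  recorded in the run manifest, and a plain two-sample test keeps it
  dependency-light and transparent.
- **LASSO-Cox** — genes standardized internally; `CoxnetSurvivalAnalysis`
  (l1_ratio = 1) lays out the descending α path on the full data; per fold,
  held-out deviance −2·ℓ(test linear predictor) is computed with a Breslow
  partial likelihood and averaged; α* minimizes the mean. Coefficients are
  reported on the standardized scale; the model also exposes
  `raw_coefficients` (= coef / training SD) so that scoring is an exact
  affine function of raw log2(x+1) expression — adding c to one gene's
  expression shifts every score by raw_coef·c exactly. The cutoff is the
  median training score.
- **Degenerate inputs** — all-identical samples rank to the common average
  with a warning; zero-variance rows z-score to zero with a warning; constant
  or non-converging genes are dropped from the Cox screen with warnings,
  never exceptions.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the method assumes:

- **Network** — preferential attachment from a complete seed graph on m
  nodes (edge count exactly C(m,2) + m(n−m)), giving a right-skewed degree
  distribution with log–log fit R² ≥ 0.8 for n ≥ 500.
- **Normal cohort** — fixed per-gene baseline log2 levels evenly spread over
  [2, 12] (≈ 4–4000 TPM) plus i.i.d. Gaussian noise (default SD 0.3 log2
  units), so per-sample rankings are conserved up to local jitter. Defaults
  were chosen once as a realistic contrast: the 10-log2-unit baseline spread
  dwarfs the noise, mirroring the strong conservation of healthy-tissue
  rankings.
- **Tumor cohort** — k clusters (default 4 × 20 samples), each with a private
  pairwise-disjoint set of 50 network edges; for a cluster's samples each
  planted edge's lower endpoint moves up and higher endpoint moves down by
  `flip_strength` (default 1.0 log2 units ≈ 3× noise SD), inverting the
  pair's order when 2·flip_strength exceeds the baseline gap. Perturbation by
  mean shifts (rather than value swapping) keeps marginal distributions
  realistic while directly controlling the sign flips the EPM measures; at
  flip_strength = 0 the cohort is distributionally identical to normal.
  A side effect worth knowing: shifting a gene also moves it past other
  genes, so edges *incident* to shifted genes are collaterally perturbed at
  roughly half the planted magnitude. This mirrors real propagation of
  dysregulation through a network, but it means "planted edges" are not the
  only truly perturbed edges, and edge-level recall through the full
  generator is bounded by that physics; the feature-selection operation is
  therefore validated on Δ-level plants where ground truth is unambiguous.
- **Survival** — exponential times with log hazard = cluster effect + Σ
  planted-gene effects on standardized log2 expression (default |log HR| = 1
  per SD for 5 planted genes, among 20 graded "decoy" genes with no hazard
  that the Cox/LASSO steps must reject); uniform censoring calibrated by
  bisection to the target censoring fraction (default 0.3). Overlay genes
  carry their own within-cluster variability (default SD 1.5 log2 units,
  comparable to the grade spread): with 4 clusters the graded means span
  only 3 dimensions, so without per-gene variance the overlay genes would be
  collinear and their individual hazard effects unidentifiable by any
  method.

Not emulated: count-level noise (negative binomial, library size), batch
effects, correlated co-expression modules, or non-proportional hazards.
Passing tests therefore demonstrate correctness and statistical behaviour of
the algorithms under the assumed structure, not performance on any real
cohort.

## Problem sizes

Tests and the acceptance script run the analysis at desk scale, chosen as the
package's default study conditions: 300-gene networks (~600 edges), 50
normal + 80 tumor samples for clustering (4 × 20), 300 tumor samples for the
survival chain, consensus with 250 repetitions, 200 replicates for the Cox
null calibration and 100 held-out replicates for log-rank power. Results are
deterministic given the seed; the EPM computation itself is exact (integer
and half-integer rank arithmetic), and chunk-by-sample computation is
guaranteed identical to whole-matrix computation because each sample's ranks
depend only on its own column.

## Known limitations

- PAM is O(k·n²) per SWAP pass on a dense distance matrix; fine for hundreds
  of samples, not tuned for tens of thousands.
- The consensus subsampling resamples samples only (all features kept);
  feature resampling is not implemented.
- The IGP defaults to Euclidean nearest-centroid assignment;
  ``metric="correlation"`` switches to the correlation convention of the
  classical cluster-reproducibility implementation.
- `batch_median_center` is a crude convenience, not a substitute for proper
  batch correction upstream.
- The hypergeometric enrichment treats gene sets as flat lists; no
  redundancy trimming or multi-database meta-analysis.
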