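"""Consensus clustering of tumor samples on feature edges, and IGP validation.

Consensus clustering follows the resampling scheme of Monti et al.: repeatedly
subsample columns (samples), partition each subsample with PAM (k-medoids,
Euclidean distance), and record for every sample pair the fraction of
co-subsampled runs in which the pair co-clustered. The number of clusters is
chosen from the relative change in the area under the consensus CDF.

PAM is implemented here deterministically (greedy BUILD, then best-improvement
SWAP with lowest-index tie-breaks) so that a seed fully determines the result.

The in-group proportion (IGP) measures cluster reproducibility in an
independent cohort: each validation sample is assigned to the nearest
discovery centroid, and a cluster's IGP is the fraction of its assigned
samples whose nearest validation neighbour received the same assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform


def pam(dist: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    BUILD: start from the point minimizing total distance, then greedily add
    the point with the largest cost reduction. SWAP: apply the single
    (medoid, non-medoid) exchange with the largest cost reduction until no
    exchange improves. All ties break to the lowest index, so the result is
    deterministic. Returns labels 0..k-1 (cluster c = points nearest to the
    c-th medoid in ascending medoid-index order).
    """
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:
        d_near = dist[:, medoids].min(axis=1)
        gains = np.maximum(d_near[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    for _ in range(max_iter):
        med_d = dist[:, medoids]  # n x k
        order = np.argsort(med_d, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = med_d[np.arange(n), nearest]
        d2 = med_d[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = 1e-9, None  # require a real improvement
        for mi in range(k):
            is_mine = nearest == mi
            # cost per point after removing medoid mi and adding candidate h
            base = np.where(is_mine, d2, d1)[:, None]
            new_cost = np.minimum(base, dist)  # n x n (candidate h in columns)
            # deltas[h] = cost(current) - cost(swap mi->h); positive = improvement
            deltas = d1.sum() - new_cost.sum(axis=0)
            deltas[medoids] = -np.inf
            h = int(np.argmax(deltas))
            if deltas[h] > best_delta:
                best_delta, best_swap = deltas[h], (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)
    med_d = dist[:, medoids]
    return np.argmin(med_d, axis=1)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels, CDF areas, and the chosen k."""

    sample_ids: list[str]
    consensus: dict[int, np.ndarray]
    labels: dict[int, pd.Series]
    cdf_area: dict[int, float] = field(default_factory=dict)
    delta_area: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range=range(2, 7),
    reps: int = 1000,
    sample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Subsampled PAM consensus over a feature x sample matrix.

    Per repetition, a fraction ``sample_fraction`` of samples is drawn without
    replacement (all features retained) and PAM partitions the subsample for
    each k. The consensus entry (a, b) is co-cluster count / co-subsample
    count; pairs never co-subsampled get 0 with a warning. Final labels per k
    come from average-linkage hierarchical clustering of (1 - consensus).
    """
    k_range = sorted(k_range)
    n = matrix.shape[1]
    if n < max(k_range) + 1:
        raise ValueError("need more samples than the largest k")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(sample_fraction * n)))
    full_dist = cdist(matrix.T.to_numpy(dtype=float), matrix.T.to_numpy(dtype=float))

    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sampled = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sampled[np.ix_(idx, idx)] += 1
        sub = full_dist[np.ix_(idx, idx)]
        for k in k_range:
            lab = pam(sub, k)
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same
    if np.any((co_sampled == 0) & ~np.eye(n, dtype=bool)):
        warnings.warn("some sample pairs were never co-subsampled; consensus set to 0")

    result = ConsensusResult(sample_ids=list(matrix.columns), consensus={}, labels={})
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in k_range:
            cons = np.where(co_sampled > 0, co_cluster[k] / np.maximum(co_sampled, 1), 0.0)
            cons = (cons + cons.T) / 2
            np.fill_diagonal(cons, 1.0)
            result.consensus[k] = cons
            link = linkage(squareform(1.0 - cons, checks=False), method="average")
            lab = fcluster(link, t=k, criterion="maxclust") - 1
            result.labels[k] = pd.Series(lab, index=matrix.columns, name=f"k{k}")
    _fill_cdf_areas(result)
    return result


def _fill_cdf_areas(result: ConsensusResult) -> None:
    """Area under the empirical CDF of off-diagonal consensus entries per k."""
    ks = sorted(result.consensus)
    for k in ks:
        cons = result.consensus[k]
        iu = np.triu_indices_from(cons, k=1)
        vals = np.sort(cons[iu])
        m = len(vals)
        # A(k) = sum over sorted values of (x_i - x_{i-1}) * CDF(x_{i-1})
        xs = np.concatenate([[0.0], vals, [1.0]])
        cdf = np.concatenate([[0.0], (np.arange(1, m + 1)) / m, [1.0]])
        result.cdf_area[k] = float(np.sum(np.diff(xs) * cdf[: len(xs) - 1]))


def select_k(result: ConsensusResult, min_rel_increase: float = 0.05) -> int:
    """Choose k from the relative change in the area under the consensus CDF.

    Delta(k_min) = A(k_min); Delta(k) = (A(k) - A(k-1)) / A(k-1) for larger k.
    The chosen k is the largest k whose relative increase exceeds
    ``min_rel_increase``. Degenerate profiles (non-positive baseline area)
    fall back to k_min with a warning. The full Delta(k) profile is stored on
    the result for manual override.
    """
    ks = sorted(result.cdf_area)
    if len(ks) < 3:
        raise ValueError("select_k needs at least 3 evaluated k values")
    areas = result.cdf_area
    delta: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        if areas[prev] <= 0:
            warnings.warn("degenerate consensus CDF; falling back to smallest k")
            result.delta_area = delta
            result.chosen_k = ks[0]
            return ks[0]
        delta[k] = (areas[k] - areas[prev]) / areas[prev]
    result.delta_area = delta
    eligible = [k for k in ks if delta[k] > min_rel_increase]
    chosen = max(eligible) if eligible else ks[0]
    result.chosen_k = chosen
    return chosen


def zscore_by_edge(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score: subtract the mean, divide by the (ddof=1) SD.

    Zero-variance rows become all-zero with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance rows z-scored to all-zero")
        sd = sd.mask(flat, 1.0)
    out = matrix.sub(mu, axis=0).div(sd, axis=0)
    out.loc[flat] = 0.0
    return out


@dataclass(frozen=True)
class IGPResult:
    """Per-cluster in-group proportion and validation-sample assignments."""

    igp: dict[int, float]
    assignments: pd.Series


def igp(
    discovery_matrix: pd.DataFrame,
    discovery_labels: pd.Series,
    validation_matrix: pd.DataFrame,
    metric: str = "euclidean",
) -> IGPResult:
    """In-group proportion of discovery clusters in a validation cohort.

    Both matrices must share the edge index (and should each be z-scored per
    edge within cohort). Validation samples are assigned to the nearest
    discovery-cluster centroid; IGP of cluster c is the fraction of its
    assigned samples whose nearest validation neighbour (excluding self) is
    also assigned to c. Clusters receiving <2 validation samples report NaN.

    ``metric``: "euclidean" (default) or "correlation" (assign to the
    centroid with the highest Pearson correlation, the convention of the
    classical cluster-reproducibility implementation). The neighbour step
    uses the same metric.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown IGP metric {metric!r}")
    if validation_matrix.shape[1] == 0:
        raise ValueError("no validation samples")
    if not discovery_matrix.index.equals(validation_matrix.index):
        raise ValueError("discovery and validation matrices must share the edge index")
    labels = discovery_labels.reindex(discovery_matrix.columns)
    if labels.isna().any():
        raise ValueError("discovery labels must cover all discovery samples")

    clusters = sorted(labels.unique())
    centroids = np.stack(
        [discovery_matrix.loc[:, labels == c].mean(axis=1).to_numpy() for c in clusters]
    )
    v = validation_matrix.T.to_numpy(dtype=float)
    assign_idx = np.argmin(cdist(v, centroids, metric=metric), axis=1)
    assignments = pd.Series(
        [clusters[i] for i in assign_idx], index=validation_matrix.columns, name="cluster"
    )

    vd = cdist(v, v, metric=metric)
    np.fill_diagonal(vd, np.inf)
    nn = np.argmin(vd, axis=1)
    same = assign_idx == assign_idx[nn]
    igp_values: dict[int, float] = {}
    for ci, c in enumerate(clusters):
        mask = assign_idx == ci
        if mask.sum() < 2:
            warnings.warn(f"cluster {c} received <2 validation samples; IGP undefined")
            igp_values[c] = float("nan")
        else:
            igp_values[c] = float(same[mask].mean())
    return IGPResult(igp=igp_values, assignments=assignments)
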