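"""Synthetic networks, cohorts, planted clusters, and survival.

The generator reproduces the statistical structure the edge-perturbation
analysis assumes, so every stage is testable without external cohorts:

* a scale-free background network (preferential attachment);
* a normal cohort whose per-sample gene rankings are conserved up to i.i.d.
  log-scale noise around a fixed baseline;
* a tumor cohort with k planted clusters, each defined by a private set of
  edges whose endpoint genes are shifted toward/past each other on the log
  scale (rank-order inversion for large shifts);
* survival times whose log hazard depends on cluster membership and on a
  small set of planted prognostic genes.

Everything is reproducible from (parameters, seed); generators return a
:class:`SyntheticTruth` carrying the planted structure and a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import GeneInteractionNetwork, canonical_edge

LOG2_BASELINE_RANGE = (2.0, 12.0)  # log2-TPM-like spread of gene baselines


@dataclass
class SyntheticTruth:
    """Planted structure of a generated dataset, for recovery metrics."""

    true_cluster: pd.Series | None = None
    perturbed_edges: dict[int, list[tuple[str, str]]] = field(default_factory=dict)
    prognostic_genes: dict[str, float] = field(default_factory=dict)
    cluster_log_hazards: dict[int, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def all_perturbed_edge_ids(self) -> set[str]:
        return {f"{i}|{j}" for edges in self.perturbed_edges.values() for i, j in edges}


def generate_network(n_genes: int, attach_m: int, seed: int = 0) -> GeneInteractionNetwork:
    """Preferential-attachment network over zero-padded gene symbols.

    Growth rule: start from a complete graph on ``attach_m`` seed nodes, then
    attach each new node to ``attach_m`` existing nodes preferentially, so
    the edge count is exactly C(attach_m, 2) + attach_m * (n_genes -
    attach_m). Gene names G0001.. are zero-padded, making lexicographic and
    numeric order coincide.
    """
    if not n_genes > attach_m >= 1:
        raise ValueError("need n_genes > attach_m >= 1")
    initial = nx.complete_graph(attach_m) if attach_m >= 2 else nx.star_graph(1)
    g = nx.barabasi_albert_graph(n_genes, attach_m, seed=int(seed), initial_graph=initial)
    width = len(str(n_genes))
    name = {i: f"G{i:0{width}d}" for i in g.nodes}
    edges = [canonical_edge(name[a], name[b]) for a, b in g.edges]
    return GeneInteractionNetwork.from_pairs(edges)


def gene_baseline(
    network: GeneInteractionNetwork,
    spread: tuple[float, float] = LOG2_BASELINE_RANGE,
    seed: int = 0,
) -> pd.Series:
    """Fixed per-gene baseline log2 expression: evenly spaced, seeded order."""
    genes = sorted(network.nodes)
    levels = np.linspace(spread[0], spread[1], len(genes))
    rng = np.random.default_rng(seed)
    rng.shuffle(levels)
    return pd.Series(levels, index=genes, name="baseline_log2")


def _expression_from_log2(log2_means: np.ndarray, genes, samples) -> pd.DataFrame:
    return pd.DataFrame(
        np.exp2(log2_means), index=genes, columns=samples
    )


def generate_normal_cohort(
    network: GeneInteractionNetwork,
    n_samples: int,
    noise_sd: float = 0.3,
    seed: int = 0,
    baseline: pd.Series | None = None,
    prefix: str = "N",
) -> pd.DataFrame:
    """Conserved-ranking cohort: baseline log2 means + i.i.d. Gaussian noise.

    The baseline spread (10 log2 units by default) dwarfs ``noise_sd``, so
    per-sample rankings stay close to the baseline ranking; at noise_sd = 0
    every sample ranks identically to the baseline and the cohort's EPM
    against its own benchmark is exactly zero.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if baseline is None:
        baseline = gene_baseline(network, seed=seed)
    rng = np.random.default_rng(seed)
    log2 = baseline.to_numpy()[:, None] + rng.normal(0, noise_sd, (len(baseline), n_samples))
    samples = [f"{prefix}{s + 1:04d}" for s in range(n_samples)]
    return _expression_from_log2(log2, baseline.index, samples)


def generate_tumor_cohort(
    network: GeneInteractionNetwork,
    normal_baseline: pd.Series,
    k_clusters: int = 4,
    n_per_cluster: int = 20,
    edges_per_cluster: int = 50,
    flip_strength: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    prefix: str = "T",
    perturbed_edges: dict[int, list[tuple[str, str]]] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Tumor cohort with k planted clusters of rank-shifting edge perturbations.

    Each cluster draws a private (pairwise-disjoint) set of network edges
    (pass ``perturbed_edges`` to reuse a previous draw, e.g. for a validation
    cohort sharing the discovery cohort's cluster definitions).
    For samples of that cluster, each planted edge's lower-baseline endpoint
    is shifted up by ``flip_strength`` log2 units and the higher endpoint
    down by the same amount, inverting the endpoints' rank order once
    2 * flip_strength exceeds their baseline gap. All other genes behave as
    in the normal cohort. ``flip_strength = 0`` leaves the cohort
    distributionally identical to a normal cohort.
    """
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    total = edges_per_cluster * k_clusters
    if total > network.n_edges:
        raise ValueError(
            f"{total} planted edges requested but the network has {network.n_edges}"
        )
    rng = np.random.default_rng(seed)
    if perturbed_edges is not None:
        all_edges = set(network.edges)
        for c, es in perturbed_edges.items():
            if not set(es) <= all_edges:
                raise ValueError(f"cluster {c} reuses edges not in the network")
        perturbed = {c: list(es) for c, es in perturbed_edges.items()}
    else:
        chosen = rng.choice(network.n_edges, size=total, replace=False)
        perturbed = {
            c: [
                network.edges[i]
                for i in chosen[c * edges_per_cluster : (c + 1) * edges_per_cluster]
            ]
            for c in range(k_clusters)
        }

    genes = normal_baseline.index
    cols, labels, blocks = [], [], []
    for c in range(k_clusters):
        mu = normal_baseline.copy()
        for i, j in perturbed[c]:
            lo, hi = (i, j) if mu[i] <= mu[j] else (j, i)
            mu[lo] += flip_strength
            mu[hi] -= flip_strength
        noise = rng.normal(0, noise_sd, (len(genes), n_per_cluster))
        blocks.append(mu.to_numpy()[:, None] + noise)
        cols += [f"{prefix}{c + 1}_{s + 1:03d}" for s in range(n_per_cluster)]
        labels += [c] * n_per_cluster
    expr = _expression_from_log2(np.concatenate(blocks, axis=1), genes, cols)
    truth = SyntheticTruth(
        true_cluster=pd.Series(labels, index=cols, name="cluster"),
        perturbed_edges=perturbed,
        params={
            "k_clusters": k_clusters,
            "n_per_cluster": n_per_cluster,
            "edges_per_cluster": edges_per_cluster,
            "flip_strength": flip_strength,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    return expr, truth


def plant_prognostic_genes(
    expr: pd.DataFrame,
    truth: SyntheticTruth,
    n_prognostic: int = 5,
    n_decoy: int = 20,
    grade_step: float = 1.5,
    log_hazards: tuple[float, ...] = (1.0, -1.0, 1.0, -1.0, 1.0),
    within_sd: float = 1.5,
    seed: int = 0,
    template: SyntheticTruth | None = None,
) -> pd.DataFrame:
    """Overlay cluster-graded expression on selected genes; mark hazards in truth.

    ``n_prognostic`` genes receive a cluster-graded log2 shift (a seeded
    permutation of 0, step, 2*step, ... per cluster) and a planted per-SD log
    hazard; ``n_decoy`` further genes receive graded shifts but no hazard
    (they pass the DEG funnel and must be rejected by the Cox/LASSO steps).
    Each overlay gene additionally gets its own within-cluster variability
    (``within_sd`` log2 units): with 4 clusters the graded means span only 3
    dimensions, so without per-gene variance the overlay genes would be
    collinear and their individual hazards unidentifiable. Genes are drawn
    from endpoints NOT involved in planted edges, so the overlay leaves the
    planted edge perturbations untouched. Pass ``template`` (a truth from a
    previous call) to reuse the same genes, grades and hazards for a
    held-out cohort (fresh per-sample variability is still drawn).
    """
    if truth.true_cluster is None:
        raise ValueError("truth must carry tumor cluster labels")
    clusters = sorted(truth.true_cluster.unique())
    out = expr.copy()
    log2 = np.log2(out.to_numpy())
    gene_pos = {g: i for i, g in enumerate(out.index)}
    rng = np.random.default_rng(seed)

    if template is not None:
        grade_map: dict[str, dict] = template.params["grades"]
        within_sd = float(template.params.get("overlay_within_sd", within_sd))
        truth.prognostic_genes = dict(template.prognostic_genes)
        truth.params["decoy_genes"] = list(template.params["decoy_genes"])
    else:
        if len(log_hazards) != n_prognostic:
            raise ValueError("one log hazard per prognostic gene required")
        involved = {g for eids in truth.perturbed_edges.values() for e in eids for g in e}
        free = [g for g in expr.index if g not in involved]
        if len(free) < n_prognostic + n_decoy:
            raise ValueError("not enough perturbation-free genes for the overlay")
        picked = list(rng.choice(free, size=n_prognostic + n_decoy, replace=False))
        grade_map = {
            g: {
                int(c): float(v * grade_step)
                for c, v in zip(clusters, rng.permutation(len(clusters)))
            }
            for g in picked
        }
        truth.prognostic_genes = {
            g: float(h) for g, h in zip(picked[:n_prognostic], log_hazards)
        }
        truth.params["decoy_genes"] = picked[n_prognostic:]
    for g, per_cluster in grade_map.items():
        shift = truth.true_cluster.map(per_cluster).to_numpy(dtype=float)
        shift = shift + rng.normal(0, within_sd, len(shift))
        log2[gene_pos[g], :] += shift
    truth.params["grades"] = grade_map
    truth.params["overlay_within_sd"] = float(within_sd)
    return _expression_from_log2(log2, out.index, out.columns)


def generate_survival(
    truth: SyntheticTruth,
    expr: pd.DataFrame,
    cluster_log_hazards: dict[int, float] | None = None,
    censor_rate: float = 0.3,
    base_median_days: float = 400.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with cluster and planted-gene effects.

    log hazard(sample) = cluster effect + sum over planted genes of
    log_hazard * standardized log2 expression. Censoring is independent
    uniform on (0, U) with U calibrated by bisection so the realized
    censoring fraction approximates ``censor_rate``; censor_rate = 0 means
    no censoring.
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if truth.true_cluster is None:
        raise ValueError("truth must carry cluster labels")
    rng = np.random.default_rng(seed)
    samples = expr.columns
    loghaz = np.zeros(len(samples))
    cluster_log_hazards = cluster_log_hazards or {}
    loghaz += truth.true_cluster.reindex(samples).map(
        lambda c: cluster_log_hazards.get(c, 0.0)
    ).to_numpy(dtype=float)
    log2x = np.log2(expr + 1.0)
    for gene, beta in truth.prognostic_genes.items():
        x = log2x.loc[gene]
        z = (x - x.mean()) / x.std(ddof=1)
        loghaz += beta * z.to_numpy(dtype=float)
    base_rate = np.log(2.0) / base_median_days
    t = rng.exponential(1.0, size=len(samples)) / (base_rate * np.exp(loghaz))

    if censor_rate == 0:
        time, event = t, np.ones(len(t), dtype=int)
    else:
        u = rng.uniform(0, 1, size=len(t))
        lo, hi = 1e-6, float(t.max()) * 100
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            frac = float(np.mean(u * mid < t))
            if frac > censor_rate:  # too much censoring -> lengthen the window
                lo = mid
            else:
                hi = mid
        c = u * 0.5 * (lo + hi)
        event = (t <= c).astype(int)
        time = np.minimum(t, c)
    truth.cluster_log_hazards = dict(cluster_log_hazards)
    truth.params["censor_rate"] = censor_rate
    return pd.DataFrame({"time": time, "event": event}, index=samples)
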