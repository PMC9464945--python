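import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import epmkit as ek

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_network() -> ek.GeneInteractionNetwork:
    return ek.GeneInteractionNetwork.from_pairs(
        [("g1", "g2"), ("g2", "g3"), ("g1", "g3"), ("g3", "g4")]
    )


@pytest.fixture(scope="session")
def random_instance():
    """30-gene / 60-edge network with matched tumor and normal cohorts."""
    rng = np.random.default_rng(12345)
    genes = [f"g{i:02d}" for i in range(30)]
    pairs = set()
    while len(pairs) < 60:
        i, j = rng.choice(30, size=2, replace=False)
        pairs.add((genes[min(i, j)], genes[max(i, j)]))
    net = ek.GeneInteractionNetwork.from_pairs(sorted(pairs))
    tumor = pd.DataFrame(
        rng.gamma(2.0, 50.0, (30, 8)), index=genes, columns=[f"t{s}" for s in range(8)]
    )
    normal = pd.DataFrame(
        rng.gamma(2.0, 50.0, (30, 6)), index=genes, columns=[f"n{s}" for s in range(6)]
    )
    return net, tumor, normal


@pytest.fixture(scope="session")
def paperlike():
    """Scale-free network, conserved normal cohort, 4 planted tumor clusters."""
    net = ek.generate_network(300, 2, seed=11)
    base = ek.gene_baseline(net, seed=11)
    normal = ek.generate_normal_cohort(net, 50, noise_sd=0.3, seed=12, baseline=base)
    tumor, truth = ek.generate_tumor_cohort(
        net, base, k_clusters=4, n_per_cluster=20, edges_per_cluster=50,
        flip_strength=1.0, noise_sd=0.3, seed=13,
    )
    return net, base, normal, tumor, truth


# --- independent oracles (kept free of epmkit internals) -------------------

def rank_with_ties(values):
    """Average-tie ascending ranks via explicit sort-and-bookkeep."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_epm(tumor: pd.DataFrame, normal: pd.DataFrame, edges):
    """Double-loop recomputation of Delta_e,s = (r_i,s - r_j,s) - delta_bar_e."""
    gene_ranks = {
        s: dict(zip(tumor.index, rank_with_ties(tumor[s].tolist()))) for s in tumor.columns
    }
    mean_profile = normal.mean(axis=1)
    bench_rank = dict(zip(normal.index, rank_with_ties(mean_profile.tolist())))
    out = {}
    for i, j in edges:
        delta_bar = bench_rank[i] - bench_rank[j]
        out[f"{i}|{j}"] = {
            s: (gene_ranks[s][i] - gene_ranks[s][j]) - delta_bar for s in tumor.columns
        }
    return pd.DataFrame(out).T[tumor.columns]
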