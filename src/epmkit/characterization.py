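"""Characteristic-group analysis: which blocks of feature edges define each cluster.

Feature edges (rows of the z-scored EPM) are grouped by complete-linkage
hierarchical clustering into a fixed number of groups; small groups are
dropped. For each (cluster, group) pair, the fraction of the group's edges
whose |mean normalized perturbation| over the cluster's samples exceeds a
threshold is computed; groups where that fraction exceeds 0.7 are
"characteristic" of the cluster, and their endpoint genes form the cluster's
gene list (e.g. for enrichment analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EdgeGrouping:
    """Partition of feature edges into hierarchical groups.

    ``group_of_edge`` maps every feature edge to a group ID (1..n_groups);
    ``retained_groups`` lists the groups with at least ``min_size`` members.
    """

    group_of_edge: pd.Series
    retained_groups: list[int]
    min_size: int


@dataclass(frozen=True)
class CharacteristicGroups:
    """Per (cluster, group) coherent-perturbation fractions and selections."""

    fractions: pd.DataFrame  # clusters x retained groups
    selected: pd.DataFrame  # boolean, same shape
    group_means: dict[tuple[int, int], pd.Series]  # (cluster, group) -> per-edge mean
    genes_per_cluster: dict[int, set[str]]


def group_edges(
    normalized_epm: pd.DataFrame, n_groups: int = 100, min_size: int = 30
) -> EdgeGrouping:
    """Complete-linkage grouping of edges (rows) by Euclidean distance.

    The dendrogram is cut into ``n_groups``; groups with fewer than
    ``min_size`` edges are excluded from ``retained_groups`` (but keep their
    IDs in the partition).
    """
    n_edges = normalized_epm.shape[0]
    if n_groups > n_edges:
        raise ValueError(f"n_groups={n_groups} exceeds edge count {n_edges}")
    link = linkage(normalized_epm.to_numpy(dtype=float), method="complete", metric="euclidean")
    groups = fcluster(link, t=n_groups, criterion="maxclust")
    group_of_edge = pd.Series(groups, index=normalized_epm.index, name="group")
    sizes = group_of_edge.value_counts()
    retained = sorted(sizes[sizes >= min_size].index.tolist())
    return EdgeGrouping(group_of_edge=group_of_edge, retained_groups=retained, min_size=min_size)


def characteristic_groups(
    grouping: EdgeGrouping,
    normalized_epm: pd.DataFrame,
    labels: pd.Series,
    mean_threshold: float = 0.5,
    frac_threshold: float = 0.7,
) -> CharacteristicGroups:
    """Select, per cluster, the edge groups that are coherently perturbed.

    For cluster c and retained group g: compute each member edge's mean
    normalized perturbation over c's samples; the group is characteristic for
    c iff the fraction of member edges with |mean| > ``mean_threshold``
    exceeds ``frac_threshold``. A cluster's gene list is the union of
    endpoint genes over its characteristic groups' edges.
    """
    labels = labels.reindex(normalized_epm.columns)
    if labels.isna().any():
        raise ValueError("cluster labels must cover all samples")
    clusters = sorted(labels.unique())
    for c in clusters:
        if (labels == c).sum() == 0:
            raise ValueError(f"cluster {c} has no samples")

    fractions = pd.DataFrame(index=clusters, columns=grouping.retained_groups, dtype=float)
    selected = pd.DataFrame(False, index=clusters, columns=grouping.retained_groups)
    group_means: dict[tuple[int, int], pd.Series] = {}
    genes: dict[int, set[str]] = {c: set() for c in clusters}
    for g in grouping.retained_groups:
        member_edges = grouping.group_of_edge.index[grouping.group_of_edge == g]
        block = normalized_epm.loc[member_edges]
        for c in clusters:
            means = block.loc[:, labels == c].mean(axis=1)
            group_means[(c, g)] = means
            frac = float((means.abs() > mean_threshold).mean())
            fractions.loc[c, g] = frac
            if frac > frac_threshold:
                selected.loc[c, g] = True
                genes[c] |= {gene for eid in member_edges for gene in eid.split("|")}
    return CharacteristicGroups(
        fractions=fractions, selected=selected, group_means=group_means, genes_per_cluster=genes
    )


def hypergeometric_enrichment(
    genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query against named gene sets.

    p = P[X >= overlap] with X ~ Hypergeom(|universe|, |set ∩ universe|,
    |query|). BH-adjusted q-values are reported, but the ``retained`` flag
    follows the raw p < ``p_threshold`` rule.
    """
    if not universe:
        raise ValueError("empty universe")
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    m = len(universe)
    nq = len(genes)
    rows = []
    for name, members in gene_sets.items():
        members_in = members & universe
        overlap = genes & members_in
        p = float(hypergeom.sf(len(overlap) - 1, m, len(members_in), nq))
        rows.append(
            {
                "gene_set": name,
                "set_size": len(members_in),
                "overlap": len(overlap),
                "p": min(p, 1.0),
                "genes": ",".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows).set_index("gene_set")
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table["retained"] = table["p"] < p_threshold
        table = table.sort_values(["p", "set_size"])
    return table
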