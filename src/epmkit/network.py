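"""Background gene-interaction network: loading, merging, filtering, diagnostics.

The background network is an undirected, deduplicated set of gene pairs
(typically merged from pathway-derived interaction lists). All edge statistics
downstream are computed over its canonical edge order, so canonicalization
lives here: within an edge the two gene symbols are stored in lexicographic
order, and the edge list is sorted. Gene identity is the raw symbol string,
case-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_edge_list

EDGE_SEP = "|"


def edge_id(i: str, j: str) -> str:
    return f"{i}{EDGE_SEP}{j}"


def canonical_edge(i: str, j: str) -> tuple[str, str]:
    """Order the two endpoints lexicographically (fixed total order)."""
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class GeneInteractionNetwork:
    """Undirected network over gene symbols with canonical, sorted edges.

    Invariants: no self-loops, no duplicate edges after canonicalization,
    every endpoint is in ``nodes``.
    """

    edges: tuple[tuple[str, str], ...]
    nodes: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        endpoints = frozenset(g for e in self.edges for g in e)
        object.__setattr__(self, "nodes", endpoints)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on {i!r}")
            if j < i:
                raise ValueError(f"edge ({i!r}, {j!r}) not in canonical order")

    @classmethod
    def from_pairs(cls, pairs) -> "GeneInteractionNetwork":
        """Canonicalize, drop self-loops, dedupe, and sort raw gene pairs."""
        canon = {canonical_edge(i, j) for i, j in pairs if i != j}
        return cls(edges=tuple(sorted(canon)))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_ids(self) -> list[str]:
        return [edge_id(i, j) for i, j in self.edges]

    def degrees(self) -> pd.Series:
        deg: dict[str, int] = {g: 0 for g in self.nodes}
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return pd.Series(deg, dtype=int).sort_index()


@dataclass(frozen=True)
class DegreeDiagnostics:
    """Node degrees plus the R^2 of the log10 P(k) ~ log10 k regression."""

    degree_of_node: pd.Series
    r_squared: float
    slope: float
    intercept: float


def load_and_merge_edge_lists(
    paths: list[str | Path], header: bool = False
) -> GeneInteractionNetwork:
    """Union of edge-list files, canonicalized and deduplicated.

    Self-loops are dropped; duplicate edges (in either orientation) collapse
    to one. Raises on an empty file list or malformed rows.
    """
    if not paths:
        raise ValueError("no edge-list files given")
    pairs: list[tuple[str, str]] = []
    for p in paths:
        pairs.extend(read_edge_list(p, header=header))
    return GeneInteractionNetwork.from_pairs(pairs)


def filter_to_universe(
    network: GeneInteractionNetwork, genes: set[str]
) -> GeneInteractionNetwork:
    """Keep only edges whose both endpoints lie in ``genes``.

    Isolated nodes are dropped (the node set of the result is exactly the
    endpoints of the surviving edges).
    """
    if not genes:
        raise ValueError("empty gene universe")
    kept = tuple(e for e in network.edges if e[0] in genes and e[1] in genes)
    if not kept:
        raise ValueError(
            "no network edge has both endpoints in the gene universe; "
            "the expression matrix and the network share too few genes"
        )
    return GeneInteractionNetwork(edges=kept)


def scale_free_fit(network: GeneInteractionNetwork) -> DegreeDiagnostics:
    """Goodness of a power-law degree distribution.

    The empirical degree distribution P(k) is taken over the distinct observed
    positive degrees (no binning), and ordinary least squares of
    log10 P(k) on log10 k gives the coefficient of determination. A value
    near 1 indicates an approximately scale-free network.
    """
    deg = network.degrees()
    pos = deg[deg > 0]
    ks, counts = np.unique(pos.to_numpy(), return_counts=True)
    if len(ks) < 2:
        raise ValueError("degree-distribution fit undefined: all nodes share one degree")
    pk = counts / counts.sum()
    x = np.log10(ks.astype(float))
    y = np.log10(pk)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DegreeDiagnostics(
        degree_of_node=deg, r_squared=float(r2), slope=float(slope), intercept=float(intercept)
    )
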