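"""Feature-edge selection: discriminative (tumor vs normal) AND variable within tumors.

Edges are ranked two ways on the edge-perturbation values: by Kruskal-Wallis
significance between the tumor and normal cohorts, and by the standard
deviation across tumor samples. The feature set is the intersection of the
two top-K lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata


@dataclass(frozen=True)
class FeatureEdgeSet:
    """Selected edges with their selection scores.

    ``table`` has one row per background edge with columns H, p, sd and a
    boolean ``selected``; ``edge_ids`` is the selected subset in canonical
    edge order.
    """

    edge_ids: list[str]
    table: pd.DataFrame

    @property
    def genes(self) -> set[str]:
        return {g for eid in self.edge_ids for g in eid.split("|")}


def kw_edge_scan(epm_tumor: pd.DataFrame, epm_normal: pd.DataFrame) -> pd.DataFrame:
    """Per-edge tie-corrected Kruskal-Wallis H across the two cohorts.

    Vectorized over edges: each edge's pooled values are ranked, H is computed
    from the group rank sums and corrected for ties, and the p-value comes
    from the chi-square distribution with 1 degree of freedom (two groups).
    Returns a DataFrame indexed by edge with columns ``H`` and ``p``.
    """
    if not epm_tumor.index.equals(epm_normal.index):
        raise ValueError("tumor and normal EPMs must share the edge index")
    n1, n2 = epm_tumor.shape[1], epm_normal.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each cohort needs at least 2 samples")
    pooled = np.concatenate(
        [epm_tumor.to_numpy(dtype=float), epm_normal.to_numpy(dtype=float)], axis=1
    )
    n = n1 + n2
    ranks = rankdata(pooled, axis=1, method="average")
    r1 = ranks[:, :n1].sum(axis=1)
    r2 = ranks[:, n1:].sum(axis=1)
    h = 12.0 / (n * (n + 1)) * (r1**2 / n1 + r2**2 / n2) - 3.0 * (n + 1)
    # tie correction: 1 - sum(t^3 - t) / (n^3 - n), per edge
    sorted_rows = np.sort(pooled, axis=1)
    new_run = np.ones_like(sorted_rows, dtype=bool)
    new_run[:, 1:] = sorted_rows[:, 1:] != sorted_rows[:, :-1]
    correction = np.empty(pooled.shape[0])
    for idx in range(pooled.shape[0]):
        starts = np.flatnonzero(new_run[idx])
        t = np.diff(np.append(starts, n))
        correction[idx] = 1.0 - (t**3 - t).sum() / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(correction > 0, h / correction, 0.0)
    h = np.maximum(h, 0.0)  # guard tiny negative float noise
    p = chi2.sf(h, df=1)
    p = np.where(correction > 0, p, 1.0)
    return pd.DataFrame({"H": h, "p": p}, index=epm_tumor.index)


def select_feature_edges(
    kw_results: pd.DataFrame,
    epm_tumor: pd.DataFrame,
    top_k_test: int = 60000,
    top_k_sd: int = 60000,
) -> FeatureEdgeSet:
    """Intersect the top-K most significant edges with the top-K highest-SD edges.

    Significance ranking is by ascending p (ties broken by descending H, then
    edge ID); variability ranking is by descending SD of the perturbation
    across tumor samples only (ties by edge ID). K values larger than the edge
    count are clipped with a warning (small networks). Deterministic.
    """
    if not kw_results.index.equals(epm_tumor.index):
        raise ValueError("KW results and tumor EPM must share the edge index")
    n_edges = len(kw_results)
    if top_k_test > n_edges or top_k_sd > n_edges:
        warnings.warn(
            f"top-K ({top_k_test}/{top_k_sd}) exceeds edge count {n_edges}; clipping"
        )
        top_k_test = min(top_k_test, n_edges)
        top_k_sd = min(top_k_sd, n_edges)
    sd = epm_tumor.std(axis=1, ddof=1)
    table = kw_results.assign(sd=sd)

    top_test = set(
        table.assign(_eid=table.index)
        .sort_values(by=["p", "H", "_eid"], ascending=[True, False, True])
        .index[:top_k_test]
    )
    top_sd = set(
        table.assign(_eid=table.index)
        .sort_values(by=["sd", "_eid"], ascending=[False, True])
        .index[:top_k_sd]
    )
    chosen = top_test & top_sd
    if not chosen:
        raise ValueError(
            "the significance and SD top lists are disjoint; increase top_k_test/top_k_sd"
        )
    table = table.assign(selected=table.index.isin(chosen))
    edge_ids = [e for e in table.index if e in chosen]  # canonical edge order
    return FeatureEdgeSet(edge_ids=edge_ids, table=table)
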