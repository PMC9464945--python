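"""Expression-cohort filtering and alignment onto the network gene universe."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .network import GeneInteractionNetwork, filter_to_universe


def _check_expression(expr: pd.DataFrame) -> None:
    if expr.empty:
        raise ValueError("empty expression matrix")
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene IDs in expression matrix")
    if expr.columns.has_duplicates:
        raise ValueError("duplicate sample IDs in expression matrix")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative (TPM-like)")


def filter_low_expressed_genes(
    expr: pd.DataFrame, zero_fraction_threshold: float = 0.7
) -> pd.DataFrame:
    """Drop genes with exact zeros in more than ``zero_fraction_threshold`` of samples.

    The boundary is strict: a gene whose zero fraction equals the threshold is
    kept. Applied per cohort, before alignment.
    """
    _check_expression(expr)
    if not 0 < zero_fraction_threshold <= 1:
        raise ValueError("zero_fraction_threshold must be in (0, 1]")
    zero_frac = (expr == 0).mean(axis=1)
    kept = expr.loc[zero_frac <= zero_fraction_threshold]
    if kept.empty:
        raise ValueError("all genes removed by the zero-expression filter")
    return kept


def align_cohorts(
    exprs: list[pd.DataFrame], network: GeneInteractionNetwork
) -> tuple[list[pd.DataFrame], GeneInteractionNetwork]:
    """Restrict all cohorts and the network to their shared gene universe.

    Returns cohorts with identical row order (sorted shared genes restricted
    to the filtered network's node set) and the network filtered to that
    universe.
    """
    if not exprs:
        raise ValueError("need at least one cohort")
    shared: set[str] = set(exprs[0].index)
    for e in exprs[1:]:
        shared &= set(e.index)
    shared &= set(network.nodes)
    if not shared:
        raise ValueError("no genes shared between the cohorts and the network")
    net = filter_to_universe(network, shared)
    order = sorted(net.nodes)
    return [e.loc[order] for e in exprs], net


def batch_median_center(expr: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Subtract the per-batch per-gene median (crude convenience, not ComBat).

    Values are shifted back by the per-gene global median and clipped at zero
    so the output stays TPM-like nonnegative. For real batch correction run
    ComBat upstream and feed the corrected matrix in.
    """
    _check_expression(expr)
    batches = batches.reindex(expr.columns)
    if batches.isna().any():
        raise ValueError("every sample needs a batch label")
    out = expr.copy().astype(float)
    global_med = expr.median(axis=1)
    for b, cols in expr.columns.to_series().groupby(batches).groups.items():
        med = expr[cols].median(axis=1)
        out[cols] = expr[cols].sub(med - global_med, axis=0)
    neg = (out.to_numpy() < 0).mean()
    if neg > 0:
        warnings.warn(f"batch centering clipped {neg:.1%} of values at zero")
        out = out.clip(lower=0)
    return out
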