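"""Readers and writers for the plain-text formats the toolkit consumes.

All tabular formats are TSV. Expression matrices are genes x samples with the
gene symbol in the first column and sample IDs in the header row. Edge lists
are two tab-separated gene symbols per line. Gene-set collections use the GMT
convention (set name, description, then member genes).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def read_edge_list(path: str | Path, header: bool = False) -> list[tuple[str, str]]:
    """Read raw gene pairs from a TSV edge list.

    Lines starting with ``#`` are ignored. Rows with fewer than two columns
    raise a ValueError naming the file and line number. No canonicalization
    is performed here; see :func:`epmkit.network.load_and_merge_edge_lists`.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header and lineno == 1:
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: edge-list row needs >=2 gene columns, got {line!r}"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def write_edge_list(edges, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, j in edges:
            fh.write(f"{i}\t{j}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_epm(path: str | Path) -> pd.DataFrame:
    """Read an edge-perturbation matrix TSV (first column = edge ID ``a|b``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_epm(epm: pd.DataFrame, path: str | Path) -> None:
    # repr-precision floats so a TSV round trip is lossless
    epm.to_csv(path, sep="\t", index_label="edge", float_format="%.17g")


def read_samples_table(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, cohort, batch, time, event)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT row needs name, description, >=1 gene")
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
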