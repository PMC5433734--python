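"""Readers, writers, pre-processing filters and universe alignment.

Canonical in-memory containers are plain pandas objects:

* mutation matrix  -- DataFrame, rows = samples, columns = genes, values 0/1
* expression matrix -- DataFrame, rows = samples, columns = genes, floats
* clinical table   -- DataFrame indexed by sample with columns
  ``time`` (days), ``event`` (1 = death observed, 0 = censored) and optional
  ``stage`` / ``grade`` categoricals
* gene network     -- :class:`netstrat.network.GeneNetwork`

All on-disk formats are TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_mutation_pairs",
    "read_edge_list",
    "write_edge_list",
    "read_clinical",
    "validate_mutation_matrix",
    "filter_samples_min_mutations",
    "filter_zero_expression_genes",
    "align_universes",
]


def read_matrix(path, orientation: str = "samples-in-rows") -> pd.DataFrame:
    """Read a sample-by-gene numeric matrix from TSV.

    The file has one header row of gene symbols and a first column of sample
    IDs (transposed if ``orientation='genes-in-rows'``).  The returned frame
    is always samples x genes.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate gene column headers in {path}: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if orientation == "genes-in-rows":
        df = df.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene columns in {path}: {dup}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dup}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError):
        bad = df.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(bad.isna().values & df.notna().values)[0]
        raise ValueError(
            f"non-numeric cell in {path} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        ) from None
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return values


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_mutation_pairs(path) -> pd.DataFrame:
    """Build a binary mutation matrix from a (sample, gene) pair list.

    One mutation event per line; duplicate pairs collapse to 1.
    """
    pairs = pd.read_csv(
        path, sep=r"\s+", header=None, names=["sample", "gene"], dtype=str
    )
    if pairs.empty:
        raise ValueError(f"empty mutation pair file: {path}")
    mat = pd.crosstab(pairs["sample"], pairs["gene"])
    mat = (mat > 0).astype(float)
    mat.index.name = None
    mat.columns.name = None
    return mat


def validate_mutation_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Check a candidate mutation matrix is binary with unique IDs."""
    vals = df.values
    if not np.isin(np.unique(vals), [0.0, 1.0]).all():
        raise ValueError("mutation matrix entries must be 0/1")
    return df


def read_edge_list(path, weighted: bool = False) -> GeneNetwork:
    """Read a whitespace/tab-delimited edge list into a :class:`GeneNetwork`.

    Self-loops are dropped (the diagonal stays zero) and repeated edges keep
    the maximum weight, making the result independent of line order.
    """
    ncols = 3 if weighted else 2
    names = ["gene_a", "gene_b", "weight"][:ncols]
    edges = pd.read_csv(path, sep=r"\s+", header=None, names=names, dtype={0: str, 1: str})
    if edges.empty:
        raise ValueError(f"empty edge list: {path}")
    if weighted:
        edges["weight"] = edges["weight"].astype(float)
        if (edges["weight"] < 0).any():
            raise ValueError("negative edge weight in edge list")
    else:
        edges["weight"] = 1.0
    genes = pd.Index(sorted(set(edges["gene_a"]) | set(edges["gene_b"])))
    A = np.zeros((len(genes), len(genes)))
    ia = genes.get_indexer(edges["gene_a"])
    ib = genes.get_indexer(edges["gene_b"])
    w = edges["weight"].to_numpy()
    keep = ia != ib  # self-loops dropped
    for i, j, wij in zip(ia[keep], ib[keep], w[keep]):
        A[i, j] = A[j, i] = max(A[i, j], wij)
    return GeneNetwork(genes=genes, adjacency=A, weighted=weighted)


def write_edge_list(net: GeneNetwork, path) -> None:
    net.edge_list().to_csv(path, sep="\t", index=False, header=False)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table (sample, time, event[, stage, grade]) from TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str},
                     float_precision="round_trip")
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample IDs in clinical table")
    df = df.set_index("sample")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time"] < 0).any():
        raise ValueError("negative survival time in clinical table")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df


def filter_samples_min_mutations(F: pd.DataFrame, min_mut: int = 10) -> pd.DataFrame:
    """Drop samples with fewer than ``min_mut`` mutated genes.

    'Fewer than' is strict: a sample with exactly ``min_mut`` mutations is
    retained.  Sample order is preserved.
    """
    counts = F.sum(axis=1)
    keep = counts >= min_mut
    removed = F.index[~keep]
    if len(removed):
        logger.info(
            "filter_samples_min_mutations: removed %d/%d samples (< %d mutations): %s",
            len(removed), len(F), min_mut, list(removed[:10]),
        )
    if not keep.any():
        raise ValueError(
            f"all {len(F)} samples have fewer than {min_mut} mutations; "
            "review the threshold"
        )
    return F.loc[keep]


def filter_zero_expression_genes(E: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero expression in every sample."""
    keep = (E != 0).any(axis=0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_zero_expression_genes: removed %d all-zero genes", n_drop)
    if not keep.any():
        logger.warning("filter_zero_expression_genes: every gene is all-zero")
    return E.loc[:, keep]


def align_universes(F: pd.DataFrame, net: GeneNetwork):
    """Restrict a mutation matrix and a network to their common genes.

    Matching is exact, case-sensitive string equality; unmatched genes on
    either side are logged and dropped.  Both outputs share the same gene
    ordering (sorted intersection).
    """
    common = pd.Index(sorted(set(F.columns) & set(net.genes)))
    if common.empty:
        raise ValueError("mutation matrix and network share no genes")
    drop_f = len(F.columns) - len(common)
    drop_n = net.n_genes - len(common)
    if drop_f or drop_n:
        logger.warning(
            "align_universes: dropped %d mutation genes and %d network genes "
            "outside the intersection (%d kept)", drop_f, drop_n, len(common),
        )
    return F.loc[:, common], net.subset(common)
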