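"""Co-expression networks from expression profiles.

Two graphs are derived from one all-pairs Spearman correlation pass:

* the weighted co-expression network (CN) with edge weights ``|rho|``, and
* the unweighted significant co-expression network (SCN) whose edges are the
  gene pairs whose Bonferroni-corrected correlation p-value is below 0.05.

Mutation profiles are propagated over the SCN, while the manifold
regulariser of the factorisation uses the p-nearest-neighbour graph of the
weighted CN — deliberately two different graphs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "spearman_all_pairs",
    "build_cn",
    "build_scn",
    "knn_graph",
    "graph_laplacian",
]


@dataclass
class CorrelationResult:
    """All-pairs Spearman correlations with two-sided p-values.

    ``rho`` and ``pvalues`` are symmetric gene x gene matrices;
    ``diag(rho) = 1`` and ``diag(pvalues) = 0`` by convention.
    """

    genes: pd.Index
    rho: np.ndarray
    pvalues: np.ndarray
    n_samples: int

    @property
    def n_pairs(self) -> int:
        g = len(self.genes)
        return g * (g - 1) // 2


def spearman_all_pairs(E: pd.DataFrame, block_size: int = 1024) -> CorrelationResult:
    """Spearman rank correlation and p-value for every gene pair.

    Columns are mid-ranked (average ranks for ties), centred and scaled, so
    the correlation is a plain inner product computed in column blocks to
    bound peak memory.  P-values use the two-sided t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom; |rho| = 1
    maps to p = 0.  Constant genes get rho = 0 / p = 1 against all partners.
    """
    n, g = E.shape
    if n < 4:
        raise ValueError(f"need >= 4 samples for Spearman p-values, got {n}")
    ranks = stats.rankdata(E.to_numpy(dtype=float), axis=0)
    ranks -= ranks.mean(axis=0)
    norms = np.sqrt((ranks**2).sum(axis=0))
    constant = norms == 0
    if constant.any():
        logger.warning(
            "spearman_all_pairs: %d constant genes get rho=0, p=1",
            int(constant.sum()),
        )
    norms[constant] = 1.0
    Z = ranks / norms

    rho = np.empty((g, g))
    for start in range(0, g, block_size):
        stop = min(start + block_size, g)
        rho[:, start:stop] = Z.T @ Z[:, start:stop]
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    pvalues = np.where(
        np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    )
    pvalues[constant, :] = 1.0
    pvalues[:, constant] = 1.0
    np.fill_diagonal(pvalues, 0.0)
    return CorrelationResult(
        genes=pd.Index(E.columns), rho=rho, pvalues=pvalues, n_samples=n
    )


def build_cn(corr: CorrelationResult) -> GeneNetwork:
    """Weighted co-expression network: edge weight ``|rho|``, zero diagonal."""
    W = np.abs(corr.rho.copy())
    np.fill_diagonal(W, 0.0)
    return GeneNetwork(genes=corr.genes, adjacency=W, weighted=True)


def build_scn(corr: CorrelationResult, alpha_level: float = 0.05) -> GeneNetwork:
    """Significant co-expression network under Bonferroni correction.

    An edge is kept iff ``p_ij * m < alpha_level`` with ``m = g(g-1)/2`` the
    number of tested pairs (q-values implicitly capped at 1).
    """
    m = corr.n_pairs
    q = np.minimum(corr.pvalues * m, 1.0)
    A = (q < alpha_level).astype(float)
    np.fill_diagonal(A, 0.0)
    net = GeneNetwork(genes=corr.genes, adjacency=A, weighted=False)
    net.meta["alpha_level"] = alpha_level
    net.meta["n_tested_pairs"] = m
    return net


def knn_graph(cn: GeneNetwork, p: int = 11) -> GeneNetwork:
    """p-nearest-neighbour graph of a weighted network, symmetrised by OR.

    ``w_ij = 1`` iff i is among the p highest-weight neighbours of j or
    vice versa.  Ties at the p-th weight are broken by ascending gene index;
    zero-weight pairs are never neighbours, so for p >= n-1 the p-NN graph
    equals the support of the weighted network.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    g = cn.n_genes
    if p >= g:
        warnings.warn(
            f"knn p={p} >= {g} genes: p-NN graph is the complete graph",
            stacklevel=2,
        )
    W = cn.adjacency.copy().astype(float)
    np.fill_diagonal(W, -np.inf)  # a gene is never its own neighbour
    # lexsort: primary key descending weight, secondary ascending gene index
    order = np.lexsort((np.broadcast_to(np.arange(g), (g, g)), -W), axis=1)
    A = np.zeros((g, g))
    rows = np.repeat(np.arange(g), min(p, g - 1))
    cols = order[:, : min(p, g - 1)].ravel()
    A[rows, cols] = 1.0            # col is among row's p nearest
    A *= cn.adjacency > 0          # zero-weight pairs are not neighbours
    A = np.maximum(A, A.T)         # OR rule
    np.fill_diagonal(A, 0.0)
    knn = GeneNetwork(genes=cn.genes, adjacency=A, weighted=False)
    knn.meta["p"] = p
    return knn


def graph_laplacian(knn: GeneNetwork) -> np.ndarray:
    """Combinatorial Laplacian ``L = D(w) - w`` with ``D_ii = sum_j w_ij``."""
    w = knn.adjacency
    return np.diag(w.sum(axis=0)) - w
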