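"""Undirected gene networks as symmetric adjacency matrices.

A :class:`GeneNetwork` carries an ordered gene index and a dense symmetric
adjacency with zero diagonal.  Weighted networks (co-expression networks with
|Spearman rho| weights, or prior interaction networks with confidence scores)
and unweighted networks (the significant co-expression network, p-NN graphs)
share the same container, distinguished by the ``weighted`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneNetwork"]


@dataclass
class GeneNetwork:
    """Undirected gene graph.

    Parameters
    ----------
    genes : pandas.Index
        Ordered, unique gene symbols.
    adjacency : numpy.ndarray
        Symmetric non-negative matrix with zero diagonal, aligned to ``genes``.
    weighted : bool
        If False every off-diagonal entry must be 0 or 1.
    """

    genes: pd.Index
    adjacency: np.ndarray
    weighted: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        if not self.genes.is_unique:
            raise ValueError("gene symbols must be unique")
        A = np.asarray(self.adjacency, dtype=float)
        if A.shape != (len(self.genes), len(self.genes)):
            raise ValueError(
                f"adjacency shape {A.shape} does not match {len(self.genes)} genes"
            )
        if A.size and not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if A.size and A.min() < 0:
            raise ValueError("adjacency must be non-negative")
        np.fill_diagonal(A, 0.0)
        if not self.weighted and A.size:
            vals = np.unique(A)
            if not np.isin(vals, [0.0, 1.0]).all():
                raise ValueError("unweighted network entries must be 0/1")
        self.adjacency = A

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def degrees(self) -> np.ndarray:
        """Weighted degree (column sums) of every gene."""
        return self.adjacency.sum(axis=0)

    def subset(self, genes) -> "GeneNetwork":
        """Restrict the network to ``genes`` (kept in the given order).

        Edges between retained genes are kept as-is; nothing is re-estimated.
        """
        genes = pd.Index(genes)
        missing = genes.difference(self.genes)
        if len(missing):
            raise KeyError(f"genes not in network: {list(missing[:5])} ...")
        idx = self.genes.get_indexer(genes)
        return GeneNetwork(
            genes=genes,
            adjacency=self.adjacency[np.ix_(idx, idx)],
            weighted=self.weighted,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.adjacency, index=self.genes, columns=self.genes)

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle edge list (gene_a, gene_b[, weight])."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        df = pd.DataFrame(
            {"gene_a": self.genes[iu], "gene_b": self.genes[ju]}
        )
        if self.weighted:
            df["weight"] = self.adjacency[iu, ju]
        return df
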