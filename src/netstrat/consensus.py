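"""Consensus clustering of network-smoothed mutation profiles.

Each replicate subsamples 80% of the patients and 80% of the genes without
replacement, restricts the propagation network and the p-NN graph to the
sampled genes (edges kept as-is, nothing re-estimated), re-smooths the
subsampled mutation matrix, factorises it with netNMF and labels the
sampled patients with the netNMF_HC rule.  Replicates accumulate, for every
patient pair, how often the pair was co-sampled and how often it landed in
the same cluster; the consensus similarity is the ratio of the two.  The
final subtype labels come from average-linkage hierarchical clustering of
the distance ``1 - similarity`` cut into k groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .factorization import assign_argmax, assign_hc, netnmf_factorize
from .network import GeneNetwork
from .smoothing import degree_normalize, propagate, quantile_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "similarity_from_counts",
    "consensus_cluster",
    "ConsensusNetNMFHC",
]


@dataclass
class ConsensusResult:
    """Final labels plus the consensus evidence behind them."""

    k: int
    labels: np.ndarray
    similarity: np.ndarray
    cosample_counts: np.ndarray
    cocluster_counts: np.ndarray
    n_iterations: int
    subsample_fraction: float
    seed: int | None
    samples: pd.Index | None = None
    replicate_labels: list = field(default_factory=list)


def similarity_from_counts(cocluster: np.ndarray, cosample: np.ndarray) -> np.ndarray:
    """Elementwise ``cocluster / cosample`` with 0/0 -> 0 and unit diagonal."""
    cocluster = np.asarray(cocluster)
    cosample = np.asarray(cosample)
    if (cocluster > cosample).any():
        raise ValueError("cocluster counts exceed cosample counts")
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(cosample > 0, cocluster / np.maximum(cosample, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    return sim


class ConsensusNetNMFHC(ClusterMixin, BaseEstimator):
    """Consensus-wrapped smoothing + netNMF_HC subtype clusterer.

    Parameters
    ----------
    n_clusters : int
        Number of subtypes k (replicates and the final cut use the same k).
    network : GeneNetwork
        Propagation graph (SCN, or a prior interaction network).
    knn : GeneNetwork
        p-NN graph supplying the factorisation Laplacian; same gene order
        as ``network``.
    n_iter : int, default 100
        Number of subsampling replicates.
    subsample : float, default 0.8
        Fraction of patients and of genes drawn (without replacement) per
        replicate.
    alpha, smooth_tol, smooth_max_iter : propagation parameters.
    reg, nmf_tol, nmf_max_iter : factorisation parameters.
    assignment : {'hc', 'argmax'}, default 'hc'
        Replicate labelling rule.
    random_state : int
        Master seed; replicate r uses child seed ``random_state + r``.

    Attributes
    ----------
    labels_ : final 1..k labels per sample
    similarity_, cosample_counts_, cocluster_counts_
    result_ : :class:`ConsensusResult`
    """

    def __init__(self, n_clusters: int = 3, network: GeneNetwork | None = None,
                 knn: GeneNetwork | None = None, n_iter: int = 100,
                 subsample: float = 0.8, alpha: float = 0.7,
                 smooth_tol: float = 1e-7, smooth_max_iter: int = 1000,
                 reg: float = 200.0, nmf_tol: float = 1e-6,
                 nmf_max_iter: int = 1000, assignment: str = "hc",
                 random_state: int = 0, keep_replicates: bool = False):
        self.n_clusters = n_clusters
        self.network = network
        self.knn = knn
        self.n_iter = n_iter
        self.subsample = subsample
        self.alpha = alpha
        self.smooth_tol = smooth_tol
        self.smooth_max_iter = smooth_max_iter
        self.reg = reg
        self.nmf_tol = nmf_tol
        self.nmf_max_iter = nmf_max_iter
        self.assignment = assignment
        self.random_state = random_state
        self.keep_replicates = keep_replicates

    def fit(self, X, y=None):
        samples = None
        if isinstance(X, pd.DataFrame):
            if self.network is not None and not X.columns.equals(self.network.genes):
                raise ValueError("mutation matrix columns must match network genes")
            samples = X.index
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        n, g = X.shape
        if self.network is None or self.knn is None:
            raise ValueError("ConsensusNetNMFHC requires `network` and `knn`")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample fraction must be in (0, 1]")
        n_sub = max(int(round(self.subsample * n)), 1)
        g_sub = max(int(round(self.subsample * g)), 1)
        if n_sub < self.n_clusters:
            raise ValueError(
                f"subsample fraction {self.subsample} yields {n_sub} patients "
                f"< k={self.n_clusters}"
            )

        W_net = self.network.adjacency
        A_knn = self.knn.adjacency
        cosample = np.zeros((n, n), dtype=np.int64)
        cocluster = np.zeros((n, n), dtype=np.int64)
        replicate_labels = []
        n_nonconverged = 0

        for r in range(self.n_iter):
            rng = np.random.default_rng(self.random_state + r)
            s_idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            g_idx = np.sort(rng.choice(g, size=g_sub, replace=False))

            F0 = X[np.ix_(s_idx, g_idx)]
            Wn = degree_normalize(GeneNetwork(
                genes=self.network.genes[g_idx],
                adjacency=W_net[np.ix_(g_idx, g_idx)],
                weighted=self.network.weighted,
            ))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                F, _ = propagate(F0, Wn, self.alpha, self.smooth_tol,
                                 self.smooth_max_iter)
                if F.shape[0] > 1:
                    F = quantile_normalize(F)
                fac = netnmf_factorize(
                    F.T, A_knn[np.ix_(g_idx, g_idx)], self.n_clusters,
                    lam=self.reg, seed=int(self.random_state + r),
                    tol=self.nmf_tol, max_iter=self.nmf_max_iter,
                )
            if not fac.converged:
                n_nonconverged += 1
                logger.debug("consensus replicate %d: netNMF hit max_iter", r)
            if self.assignment == "hc":
                labels = assign_hc(fac, self.n_clusters)
            else:
                labels = assign_argmax(fac)

            cosample[np.ix_(s_idx, s_idx)] += 1
            for c in np.unique(labels):
                members = s_idx[labels == c]
                cocluster[np.ix_(members, members)] += 1
            if self.keep_replicates:
                replicate_labels.append((s_idx, labels))

        if n_nonconverged:
            logger.info(
                "%d/%d consensus replicates stopped at the netNMF iteration "
                "cap; labels from the last iterate are used", n_nonconverged,
                self.n_iter,
            )
        never = (cosample == 0) & ~np.eye(n, dtype=bool)
        if never.any():
            warnings.warn(
                f"{int(never.sum()) // 2} patient pairs were never co-sampled; "
                "their similarity is set to 0", stacklevel=2,
            )
        sim = similarity_from_counts(cocluster, cosample)

        Z = linkage(squareform(1.0 - sim, checks=False), method="average")
        final = fcluster(Z, t=self.n_clusters, criterion="maxclust")

        self.labels_ = final
        self.similarity_ = sim
        self.cosample_counts_ = cosample
        self.cocluster_counts_ = cocluster
        self.result_ = ConsensusResult(
            k=self.n_clusters, labels=final, similarity=sim,
            cosample_counts=cosample, cocluster_counts=cocluster,
            n_iterations=self.n_iter, subsample_fraction=self.subsample,
            seed=self.random_state, samples=samples,
            replicate_labels=replicate_labels,
        )
        return self


def consensus_cluster(
    F0: pd.DataFrame,
    net: GeneNetwork,
    knn: GeneNetwork,
    k: int,
    n_iter: int = 100,
    frac: float = 0.8,
    seed: int = 0,
    alpha: float = 0.7,
    lam: float = 200.0,
    assignment: str = "hc",
    **kwargs,
) -> ConsensusResult:
    """Functional wrapper over :class:`ConsensusNetNMFHC`."""
    est = ConsensusNetNMFHC(
        n_clusters=k, network=net, knn=knn, n_iter=n_iter, subsample=frac,
        alpha=alpha, reg=lam, assignment=assignment, random_state=seed,
        **kwargs,
    ).fit(F0)
    return est.result_
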