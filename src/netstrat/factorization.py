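"""Graph-regularised non-negative matrix factorisation (netNMF).

The smoothed genes x samples matrix F is factorised as F ~ W H with
W (genes x k) the non-negative "metagene" basis and H (k x samples) the
coefficient matrix, minimising

    ||F - W H||_F^2 + lambda * trace(W^T L W),

where L = D - A is the Laplacian of the p-nearest-neighbour graph of the
weighted co-expression network.  The penalty pulls the gene loadings of
each metagene to vary smoothly over the co-expression manifold.

Optimisation uses the standard multiplicative updates for this objective:

    H <- H * (W^T F)        / (W^T W H)
    W <- W * (F H^T + l A W) / (W H H^T + l D W)

which preserve non-negativity and do not increase the objective.

Sample labels come from H either by per-sample argmax (netNMF) or by
average-linkage hierarchical clustering of the H columns (netNMF_HC) —
the latter is more robust when a sample loads almost equally on two
metagenes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state

from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "Factorization",
    "netnmf_objective",
    "netnmf_factorize",
    "assign_argmax",
    "assign_hc",
    "NetNMF",
    "NetNMFCluster",
]

_EPS = 1e-12  # denominator floor in the multiplicative updates


@dataclass
class Factorization:
    """Result of one netNMF run on a genes x samples matrix."""

    W_basis: np.ndarray          # genes x k metagenes
    H_coeff: np.ndarray          # k x samples coefficients
    k: int
    lam: float
    objective_trace: np.ndarray
    seed: int | None
    converged: bool
    samples: pd.Index | None = None
    genes: pd.Index | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_iter(self) -> int:
        return len(self.objective_trace)


def netnmf_objective(F, W, H, L, lam: float) -> float:
    """``||F - WH||_F^2 + lam * trace(W^T L W)``."""
    F = np.asarray(F, dtype=float)
    if F.shape != (W.shape[0], H.shape[1]) or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"dimension mismatch: F{F.shape}, W{W.shape}, H{H.shape}"
        )
    resid = F - W @ H
    return float((resid**2).sum() + lam * np.trace(W.T @ L @ W))


def _init_factors(F, k, rng):
    """Uniform (0,1] entries scaled so W H starts on the scale of F."""
    scale = np.sqrt(max(F.mean(), _EPS) / k)
    W = scale * (1.0 - rng.random((F.shape[0], k)))
    H = scale * (1.0 - rng.random((k, F.shape[1])))
    return W, H


def netnmf_factorize(
    F,
    knn: GeneNetwork | np.ndarray | None,
    k: int,
    lam: float = 200.0,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> Factorization:
    """Run multiplicative updates until the relative objective change < tol.

    Parameters
    ----------
    F : array or DataFrame, genes x samples, non-negative.
    knn : GeneNetwork or adjacency array or None
        p-NN graph supplying the Laplacian ``L = D - A``; None means ``lam=0``
        (plain NMF).
    k : int
        Number of metagenes, normally in 2..8.
    lam : float, default 200
        Regularisation weight.

    Non-convergence at ``max_iter`` returns the result with
    ``converged=False`` (and a warning) rather than raising.
    """
    samples = genes = None
    if isinstance(F, pd.DataFrame):
        genes, samples = F.index, F.columns
        F = F.to_numpy(dtype=float)
    else:
        F = np.asarray(F, dtype=float)
    if F.min() < 0:
        raise ValueError("F must be non-negative")
    m, n = F.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k={k} out of range for {m}x{n} input")

    if knn is None:
        A = np.zeros((m, m))
        lam = 0.0
    else:
        A = knn.adjacency if isinstance(knn, GeneNetwork) else np.asarray(knn, float)
        if A.shape != (m, m):
            raise ValueError("knn adjacency does not match the gene dimension")
    d = A.sum(axis=0)
    L = np.diag(d) - A

    rng = check_random_state(seed)
    W, H = _init_factors(F, k, rng)

    trace = [netnmf_objective(F, W, H, L, lam)]
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ F) / np.maximum(W.T @ W @ H, _EPS)
        numer = F @ H.T + lam * (A @ W)
        denom = W @ (H @ H.T) + lam * (d[:, None] * W)
        W *= numer / np.maximum(denom, _EPS)
        obj = netnmf_objective(F, W, H, L, lam)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), _EPS):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"netNMF did not converge in {max_iter} iterations "
            f"(last objective {trace[-1]:.4g})", stacklevel=2,
        )
    return Factorization(
        W_basis=W, H_coeff=H, k=k, lam=lam,
        objective_trace=np.asarray(trace), seed=seed, converged=converged,
        samples=samples, genes=genes,
    )


def assign_argmax(fac: Factorization) -> np.ndarray:
    """Label each sample by its largest coefficient (ties -> smallest index).

    Labels are 1-based to match the subtype numbering used downstream.
    """
    return fac.H_coeff.argmax(axis=0) + 1


def assign_hc(fac: Factorization, k_clusters: int | None = None) -> np.ndarray:
    """Cluster samples by average-linkage HC of the H columns (netNMF_HC)."""
    k_clusters = fac.k if k_clusters is None else k_clusters
    n = fac.H_coeff.shape[1]
    if k_clusters > n:
        raise ValueError(f"k_clusters={k_clusters} exceeds {n} samples")
    Z = linkage(fac.H_coeff.T, method="average", metric="euclidean")
    return fcluster(Z, t=k_clusters, criterion="maxclust")


class NetNMF(BaseEstimator):
    """Graph-regularised NMF as a decomposition estimator.

    Accepts X with rows = samples and columns = genes (the usual estimator
    layout); internally the transposed genes x samples matrix is factorised
    so the graph penalty falls on the gene-side basis.

    Attributes
    ----------
    basis_ : ndarray, genes x k           metagene matrix W
    coefficients_ : ndarray, k x samples  coefficient matrix H
    embedding_ : ndarray, samples x k     H transposed (sample coordinates)
    objective_trace_, n_iter_, converged_
    """

    def __init__(self, n_components: int = 3, knn: GeneNetwork | None = None,
                 reg: float = 200.0, tol: float = 1e-6, max_iter: int = 1000,
                 random_state: int | None = None):
        self.n_components = n_components
        self.knn = knn
        self.reg = reg
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        F = X.T if isinstance(X, pd.DataFrame) else np.asarray(X, float).T
        fac = netnmf_factorize(
            F, self.knn, self.n_components, lam=self.reg,
            seed=self.random_state, tol=self.tol, max_iter=self.max_iter,
        )
        self.factorization_ = fac
        self.basis_ = fac.W_basis
        self.coefficients_ = fac.H_coeff
        self.embedding_ = fac.H_coeff.T
        self.objective_trace_ = fac.objective_trace
        self.n_iter_ = fac.n_iter
        self.converged_ = fac.converged
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


class NetNMFCluster(ClusterMixin, BaseEstimator):
    """Subtype assignment by netNMF followed by argmax or HC labelling.

    ``assignment='hc'`` is the netNMF_HC rule (average-linkage hierarchical
    clustering of the coefficient columns); ``'argmax'`` is the plain
    netNMF rule.
    """

    def __init__(self, n_clusters: int = 3, knn: GeneNetwork | None = None,
                 reg: float = 200.0, assignment: str = "hc", tol: float = 1e-6,
                 max_iter: int = 1000, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.knn = knn
        self.reg = reg
        self.assignment = assignment
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        nmf = NetNMF(
            n_components=self.n_clusters, knn=self.knn, reg=self.reg,
            tol=self.tol, max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(X)
        self.netnmf_ = nmf
        if self.assignment == "hc":
            self.labels_ = assign_hc(nmf.factorization_, self.n_clusters)
        elif self.assignment == "argmax":
            self.labels_ = assign_argmax(nmf.factorization_)
        else:
            raise ValueError(f"unknown assignment rule: {self.assignment!r}")
        return self
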