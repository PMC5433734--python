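"""Network propagation of binary mutation profiles.

Mutation indicators diffuse over a gene network by the iteration

    F_{t+1} = alpha * F_t W' + (1 - alpha) * F_0,

where ``W' = D^{-1/2} W D^{-1/2}`` is the degree-normalised adjacency and
``alpha`` in (0, 1) balances network influence against the original signal.
Because the spectral radius of W' is at most 1, the map is a contraction
with factor alpha and converges to the unique fixed point
``F = (1-alpha) F_0 (I - alpha W')^{-1}`` (available as
:func:`propagate_closed_form` for cross-checking).

After convergence each patient's profile is quantile-normalised to a common
reference distribution so that every patient follows the same smoothed
mutation value distribution; the result is finally transposed to
genes x samples for factorisation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "degree_normalize",
    "propagate",
    "propagate_closed_form",
    "quantile_normalize",
    "NetworkSmoother",
    "smooth_profiles",
]


def degree_normalize(net: GeneNetwork) -> np.ndarray:
    """Symmetric degree normalisation ``W' = D^{-1/2} W D^{-1/2}``.

    Isolated genes (degree 0) keep all-zero rows/columns, so under
    propagation their smoothed value converges to ``(1-alpha) * F0``.
    """
    W = net.adjacency
    d = W.sum(axis=0)
    isolated = d == 0
    if isolated.any():
        logger.info("degree_normalize: %d isolated genes kept with zero rows",
                    int(isolated.sum()))
    inv_sqrt = np.zeros_like(d)
    inv_sqrt[~isolated] = 1.0 / np.sqrt(d[~isolated])
    return W * inv_sqrt[:, None] * inv_sqrt[None, :]


def propagate(
    F0: np.ndarray,
    Wn: np.ndarray,
    alpha: float = 0.7,
    tol: float = 1e-7,
    max_iter: int = 1000,
):
    """Iterate the diffusion to its fixed point.

    Parameters
    ----------
    F0 : array, samples x genes
        Binary (or non-negative) seed profiles.
    Wn : array, genes x genes
        Degree-normalised adjacency.
    alpha : float in (0, 1)
        Diffusion strength; 0.7 is the operating default.
    tol : float
        Convergence threshold on the Frobenius norm of successive iterates.

    Returns
    -------
    (F, n_iter) : smoothed samples x genes array and iterations run.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    F0 = np.asarray(F0, dtype=float)
    F = F0.copy()
    for it in range(1, max_iter + 1):
        F_next = alpha * (F @ Wn) + (1.0 - alpha) * F0
        resid = np.linalg.norm(F_next - F)
        F = F_next
        if resid < tol:
            return F, it
    raise RuntimeError(
        f"propagation did not converge in {max_iter} iterations "
        f"(last residual {resid:.3e})"
    )


def propagate_closed_form(F0: np.ndarray, Wn: np.ndarray, alpha: float) -> np.ndarray:
    """Exact fixed point ``(1-alpha) F0 (I - alpha W')^{-1}`` via linear solve."""
    F0 = np.asarray(F0, dtype=float)
    g = Wn.shape[0]
    A = np.eye(g) - alpha * Wn  # symmetric positive definite for alpha<1
    return (1.0 - alpha) * np.linalg.solve(A, F0.T).T


def quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Force every row (sample) onto the common order-statistic distribution.

    The reference distribution is the mean of the sorted rows; entry with
    mid-rank spanning positions i..j receives the mean of the reference
    values at those positions, so tied values stay tied and every row's
    sorted vector becomes identical (up to tie collapsing).
    """
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    if n == 1:
        warnings.warn("quantile_normalize with a single sample is the identity",
                      stacklevel=2)
        return X.copy()
    reference = np.sort(X, axis=1).mean(axis=0)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    rmin = stats.rankdata(X, method="min", axis=1).astype(int)
    rmax = stats.rankdata(X, method="max", axis=1).astype(int)
    # mean of reference values over the positions a tie group spans
    return (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)


class NetworkSmoother(TransformerMixin, BaseEstimator):
    """Transformer that network-smooths binary mutation profiles.

    Parameters
    ----------
    network : GeneNetwork
        Propagation graph (typically the SCN); gene order must match the
        columns of the matrices passed to :meth:`transform`.
    alpha : float, default 0.7
        Diffusion strength.
    tol : float, default 1e-7
        Frobenius-norm convergence threshold.
    max_iter : int, default 1000
        Iteration cap; exceeding it raises.
    quantile : bool, default True
        Apply per-sample quantile normalisation after propagation.

    Attributes
    ----------
    normalized_adjacency_ : ndarray
        ``D^{-1/2} W D^{-1/2}`` of the network.
    n_iter_ : int
        Iterations used by the last :meth:`transform`.
    """

    def __init__(self, network: GeneNetwork | None = None, alpha: float = 0.7,
                 tol: float = 1e-7, max_iter: int = 1000, quantile: bool = True):
        self.network = network
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.quantile = quantile

    def fit(self, X=None, y=None):
        if self.network is None:
            raise ValueError("NetworkSmoother requires a network")
        self.normalized_adjacency_ = degree_normalize(self.network)
        return self

    def transform(self, X):
        if not hasattr(self, "normalized_adjacency_"):
            self.fit(X)
        columns = index = None
        if isinstance(X, pd.DataFrame):
            if not X.columns.equals(self.network.genes):
                raise ValueError("mutation matrix columns must match network genes")
            columns, index = X.columns, X.index
            X = X.to_numpy()
        F, self.n_iter_ = propagate(
            X, self.normalized_adjacency_, self.alpha, self.tol, self.max_iter
        )
        if self.quantile and F.shape[0] > 1:
            F = quantile_normalize(F)
        if columns is not None:
            F = pd.DataFrame(F, index=index, columns=columns)
        return F


def smooth_profiles(
    F0: pd.DataFrame,
    net: GeneNetwork,
    alpha: float = 0.7,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Smooth, quantile-normalise and transpose to the genes x samples layout."""
    smoother = NetworkSmoother(network=net, alpha=alpha, tol=tol,
                               max_iter=max_iter).fit()
    return smoother.transform(F0).T
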