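"""Differentially mutated genes per subtype.

Each subtype is compared one-vs-rest on the network-smoothed mutation
values with a standardised two-sample Wilcoxon rank-sum statistic
(mid-ranks, tie-corrected variance).  False discovery rates follow the
permutation recipe of significance analysis of microarrays (SAM): subtype
labels are permuted, and for every candidate threshold the FDR is the
median across permutations of the null exceedance count divided by the
observed exceedance count; a gene's q-value is the smallest such FDR over
thresholds at or below its own |statistic|, capped at 1 and made monotone
in |statistic|.

Ranks are scale-free, so no exchangeability fudge factor is needed on top
of the rank statistic.  The test is two-sided: a subtype may be either
hyper- or hypo-mutated in a gene's network neighbourhood.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "wilcoxon_statistic",
    "sam_qvalues",
    "select_differential",
    "subtype_overlap",
]


@dataclass
class DifferentialResult:
    """Per-gene one-vs-rest statistics and q-values for one subtype."""

    subtype: object
    genes: pd.Index
    statistic: np.ndarray
    qvalues: np.ndarray
    n_permutations: int
    seed: int | None

    @property
    def significant(self) -> list:
        return select_differential(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"statistic": self.statistic, "q": self.qvalues}, index=self.genes
        ).sort_values(["q", "statistic"], ascending=[True, False])


def _rank_sum_moments(ranks: np.ndarray, n1: int):
    """Mean and tie-corrected SD of the in-group rank sum, per gene.

    ``ranks`` is genes x samples of mid-ranks.  With N samples and n1 in
    the group, mu = n1(N+1)/2 and
    var = n1*n2/12 * (N+1 - sum(t^3-t)/(N(N-1))) over tie groups of size t.
    """
    g, N = ranks.shape
    n2 = N - n1
    mu = n1 * (N + 1) / 2.0
    sorted_r = np.sort(ranks, axis=1)
    # tie sizes per gene: run lengths of equal consecutive mid-ranks
    tie_term = np.zeros(g)
    for i in range(g):
        _, counts = np.unique(sorted_r[i], return_counts=True)
        tie_term[i] = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    return mu, np.sqrt(np.maximum(var, 0.0))


def wilcoxon_statistic(values_in, values_out) -> float:
    """Standardised rank-sum z for one gene: (R - mu_R) / sigma_R.

    Mid-ranks for ties, tie-corrected variance; all-tied input gives 0.
    """
    values_in = np.asarray(values_in, dtype=float)
    values_out = np.asarray(values_out, dtype=float)
    if values_in.size == 0 or values_out.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([values_in, values_out])[None, :]
    ranks = stats.rankdata(pooled, axis=1)
    mu, sd = _rank_sum_moments(ranks, len(values_in))
    R = ranks[0, : len(values_in)].sum()
    return float((R - mu) / sd[0]) if sd[0] > 0 else 0.0


def _statistics_for_mask(ranks, mu, sd, mask):
    """Vectorised per-gene z for a boolean in-group mask over samples."""
    R = ranks[:, mask].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (R - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def sam_qvalues(
    F: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    target,
    n_perm: int = 1000,
    seed: int | None = None,
) -> DifferentialResult:
    """Permutation q-values for one subtype vs the rest.

    Parameters
    ----------
    F : DataFrame, genes x samples
        Network-smoothed (or raw binary) mutation values.
    labels : per-sample subtype labels aligned to the columns of F.
    target : the subtype compared against all remaining samples.
    n_perm : number of label permutations (>= 100).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for stable q-values")
    if isinstance(labels, pd.Series):
        labels = labels.reindex(F.columns).to_numpy()
    else:
        labels = np.asarray(labels)
    mask = labels == target
    n1 = int(mask.sum())
    if n1 < 2:
        raise ValueError(f"target subtype {target!r} has {n1} samples (< 2)")
    if n1 == len(labels):
        raise ValueError("all samples carry the target label; no comparison group")

    values = F.to_numpy(dtype=float)
    ranks = stats.rankdata(values, axis=1)
    mu, sd = _rank_sum_moments(ranks, n1)
    observed = _statistics_for_mask(ranks, mu, sd, mask)
    abs_obs = np.abs(observed)

    rng = np.random.default_rng(seed)
    null_sorted = np.empty((n_perm, len(abs_obs)))
    for b in range(n_perm):
        perm_mask = np.zeros(len(labels), dtype=bool)
        perm_mask[rng.choice(len(labels), size=n1, replace=False)] = True
        null_sorted[b] = np.sort(
            np.abs(_statistics_for_mask(ranks, mu, sd, perm_mask))
        )

    # thresholds = the observed |z| values, descending
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    obs_counts = np.arange(1, len(thresholds) + 1)  # #(|z_obs| >= thr)
    # per permutation, #(null |z| >= thr) via searchsorted on the sorted nulls
    null_counts = null_sorted.shape[1] - np.stack(
        [np.searchsorted(null_sorted[b], thresholds, side="left")
         for b in range(n_perm)]
    )
    fdr = np.median(null_counts, axis=0) / obs_counts
    # q = min FDR over thresholds at or below the gene's |z|  (i.e. at the
    # gene's own position or later in the descending order), then monotone
    q_sorted = np.minimum(np.minimum.accumulate(fdr[::-1])[::-1], 1.0)
    qvalues = np.empty_like(q_sorted)
    qvalues[order] = q_sorted

    return DifferentialResult(
        subtype=target, genes=pd.Index(F.index), statistic=observed,
        qvalues=qvalues, n_permutations=n_perm, seed=seed,
    )


def select_differential(result: DifferentialResult, q_cut: float = 0.05) -> list:
    """Genes with q strictly below ``q_cut``, sorted by (q, symbol)."""
    keep = result.qvalues < q_cut
    pairs = sorted(zip(result.qvalues[keep], result.genes[keep]))
    return [g for _, g in pairs]


def subtype_overlap(gene_sets: dict) -> pd.DataFrame:
    """Pairwise intersection sizes of per-subtype significant gene sets."""
    if len(gene_sets) < 2:
        raise ValueError("need >= 2 gene sets")
    keys = list(gene_sets)
    rows = []
    for a, b in itertools.combinations(keys, 2):
        rows.append({
            "subtype_a": a, "subtype_b": b,
            "overlap": len(set(gene_sets[a]) & set(gene_sets[b])),
        })
    total = len(set.intersection(*(set(v) for v in gene_sets.values())))
    out = pd.DataFrame(rows)
    out.attrs["total_intersection"] = total
    return out
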