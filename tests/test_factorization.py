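import numpy as np
import pandas as pd
import pytest

from conftest import random_graph
from netstrat import (Factorization, NetNMF, NetNMFCluster, assign_argmax,
                      assign_hc, graph_laplacian, knn_graph, netnmf_factorize,
                      netnmf_objective)


def _fac(H, k=None):
    H = np.asarray(H, float)
    k = k or H.shape[0]
    return Factorization(W_basis=np.ones((3, k)), H_coeff=H, k=k, lam=0.0,
                         objective_trace=np.zeros(1), seed=0, converged=True)


class TestObjective:
    def test_zero_factors_give_squared_norm(self, rng):
        F = rng.random((6, 4))
        W, H = np.zeros((6, 2)), np.zeros((2, 4))
        L = np.zeros((6, 6))
        assert netnmf_objective(F, W, H, L, 200.0) == pytest.approx(
            (F**2).sum())

    def test_exact_factorization_zero_without_penalty(self, rng):
        W, H = rng.random((5, 2)), rng.random((2, 4))
        assert netnmf_objective(W @ H, W, H, np.eye(5), 0.0) == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self, rng):
        F, W, H = rng.random((5, 4)), rng.random((5, 2)), rng.random((2, 4))
        net = random_graph(rng, 5, density=0.5)
        L = graph_laplacian(net)
        resid = sum(
            (F[i, j] - sum(W[i, a] * H[a, j] for a in range(2))) ** 2
            for i in range(5) for j in range(4)
        )
        pen = sum(
            W[i, a] * L[i, j] * W[j, a]
            for a in range(2) for i in range(5) for j in range(5)
        )
        assert netnmf_objective(F, W, H, L, 7.0) == pytest.approx(
            resid + 7.0 * pen)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            netnmf_objective(rng.random((5, 4)), rng.random((5, 2)),
                             rng.random((3, 4)), np.eye(5), 0.0)


class TestFactorize:
    def test_noiseless_rank3_recovery_without_penalty(self, rng):
        W0, H0 = rng.random((40, 3)), rng.random((3, 25))
        F = W0 @ H0
        fac = netnmf_factorize(F, None, k=3, lam=0.0, seed=5, tol=1e-10,
                               max_iter=3000)
        rel = np.linalg.norm(F - fac.W_basis @ fac.H_coeff) / np.linalg.norm(F)
        assert rel < 1e-3

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_non_increasing(self, seed, rng):
        F = np.random.default_rng(seed).random((50, 30))
        knn = knn_graph(random_graph(np.random.default_rng(seed), 50,
                                     density=0.5, weighted=True), p=5)
        fac = netnmf_factorize(F, knn, k=4, lam=200.0, seed=seed, max_iter=150)
        assert (np.diff(fac.objective_trace) <= 1e-9).all()
        assert (fac.W_basis >= 0).all() and (fac.H_coeff >= 0).all()

    def test_larger_k_fits_at_least_as_well(self, rng):
        F = rng.random((20, 8))
        errs = []
        for k in (2, 8):
            fac = netnmf_factorize(F, None, k=k, lam=0.0, seed=1, tol=1e-12,
                                   max_iter=4000)
            errs.append(np.linalg.norm(F - fac.W_basis @ fac.H_coeff))
        assert errs[1] <= errs[0]

    def test_penalty_monotone_in_lambda(self, rng):
        F = rng.random((30, 20))
        knn = knn_graph(random_graph(rng, 30, density=0.5, weighted=True), p=4)
        L = graph_laplacian(knn)
        penalties = []
        for lam in (0.0, 20.0, 200.0, 2000.0):
            fac = netnmf_factorize(F, knn, k=3, lam=lam, seed=2, max_iter=400)
            penalties.append(np.trace(fac.W_basis.T @ L @ fac.W_basis))
        assert (np.diff(penalties) <= 1e-9).all()

    def test_matches_sklearn_nmf_without_penalty(self, rng):
        # independent multiplicative-update implementation as cross-check
        from sklearn.decomposition import NMF

        F = rng.random((25, 15))
        fac = netnmf_factorize(F, None, k=3, lam=0.0, seed=7, tol=1e-12,
                               max_iter=3000)
        ref = NMF(n_components=3, solver="mu", init="random", random_state=7,
                  tol=1e-10, max_iter=5000).fit(F)
        ours = np.linalg.norm(F - fac.W_basis @ fac.H_coeff)
        assert ours == pytest.approx(ref.reconstruction_err_, rel=0.01)

    def test_negative_input_rejected(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            netnmf_factorize(-rng.random((5, 4)), None, k=2)


class TestAssignment:
    def test_argmax_basic_and_tie_break(self):
        labels = assign_argmax(_fac([[0.9, 0.5, 0.2], [0.1, 0.5, 0.8]]))
        assert list(labels) == [1, 1, 2]  # tie -> smallest index

    def test_argmax_row_permutation_equivariance(self, rng):
        H = rng.random((4, 10))
        base = assign_argmax(_fac(H))
        perm = np.array([2, 0, 3, 1])
        permuted = assign_argmax(_fac(H[perm]))
        assert (perm[permuted - 1] + 1 == base).all()

    def test_hc_recovers_separated_groups(self, rng):
        H = np.zeros((2, 10))
        H[0, :5] = 1.0
        H[1, 5:] = 1.0
        H += 0.01 * rng.random((2, 10))
        fac = _fac(H)
        hc = assign_hc(fac, 2)
        am = assign_argmax(fac)
        assert len(set(zip(hc, am))) == 2  # identical partitions

    def test_hc_groups_near_tied_samples_argmax_splits(self):
        # two samples nearly tied between metagenes but mutually close:
        # argmax separates them, HC keeps them together
        H = np.array([
            [1.00, 0.02, 0.51, 0.49],
            [0.02, 1.00, 0.49, 0.51],
        ])
        fac = _fac(H)
        am = assign_argmax(fac)
        hc = assign_hc(fac, 2)
        assert am[2] != am[3]
        assert hc[2] == hc[3]

    def test_hc_singletons_when_k_equals_n(self, rng):
        fac = _fac(rng.random((2, 4)))
        assert sorted(assign_hc(fac, 4)) == [1, 2, 3, 4]

    def test_hc_k_beyond_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            assign_hc(_fac(rng.random((2, 3))), 5)


class TestEstimators:
    def test_netnmf_estimator_shapes(self, rng):
        X = rng.random((12, 30))  # samples x genes
        est = NetNMF(n_components=4, knn=None, reg=0.0, random_state=0,
                     max_iter=100).fit(X)
        assert est.basis_.shape == (30, 4)
        assert est.coefficients_.shape == (4, 12)
        assert est.embedding_.shape == (12, 4)
        assert est.fit_transform(X).shape == (12, 4)

    def test_cluster_estimator_labels(self, rng):
        X = rng.random((10, 20))
        knn = knn_graph(random_graph(rng, 20, density=0.5, weighted=True), p=3)
        est = NetNMFCluster(n_clusters=2, knn=knn, assignment="hc",
                            random_state=0, max_iter=100).fit(X)
        assert set(est.labels_) <= {1, 2} and len(est.labels_) == 10

    def test_unknown_assignment_rejected(self, rng):
        with pytest.raises(ValueError, match="assignment"):
            NetNMFCluster(assignment="kmeans", max_iter=50).fit(
                rng.random((6, 8)))
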