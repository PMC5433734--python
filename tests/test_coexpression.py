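import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import random_graph
from netstrat import (CorrelationResult, build_cn, build_scn, graph_laplacian,
                      knn_graph, spearman_all_pairs)


def _expr(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values, columns=[f"g{j}" for j in range(values.shape[1])])


class TestSpearmanAllPairs:
    def test_perfect_monotone_pairs(self):
        E = _expr(np.c_[[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        res = spearman_all_pairs(E)
        assert res.rho[0, 1] == pytest.approx(1.0)
        assert res.rho[0, 2] == pytest.approx(-1.0)
        assert res.pvalues[0, 1] == 0.0  # |rho| = 1 maps to p = 0

    def test_ties_match_midrank_then_pearson_oracle(self):
        x, y = [1, 2, 3, 3, 4], [3, 1, 2, 4, 4]
        res = spearman_all_pairs(_expr(np.c_[x, y]))
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_matches_per_pair_scipy_oracle(self, rng):
        E = _expr(rng.integers(0, 6, size=(15, 20)))  # integers force ties
        res = spearman_all_pairs(E)
        for i in range(20):
            for j in range(i + 1, 20):
                rho, p = stats.spearmanr(E.iloc[:, i], E.iloc[:, j])
                assert res.rho[i, j] == pytest.approx(rho, abs=1e-12)
                assert res.pvalues[i, j] == pytest.approx(p, abs=1e-9)

    def test_constant_gene_gets_zero_rho_unit_p(self, rng):
        E = _expr(np.c_[np.ones(6), rng.random(6)])
        res = spearman_all_pairs(E)
        assert res.rho[0, 1] == 0.0 and res.pvalues[0, 1] == 1.0
        assert res.rho[0, 0] == 1.0  # diagonal convention survives

    def test_too_few_samples_error(self, rng):
        with pytest.raises(ValueError, match=">= 4 samples"):
            spearman_all_pairs(_expr(rng.random((3, 5))))

    def test_blocked_equals_unblocked(self, rng):
        E = _expr(rng.random((20, 30)))
        full = spearman_all_pairs(E, block_size=1024)
        blocked = spearman_all_pairs(E, block_size=7)
        assert np.allclose(full.rho, blocked.rho)


def _corr(rho, pvalues, n=100):
    rho = np.asarray(rho, float)
    return CorrelationResult(
        genes=pd.Index([f"g{i}" for i in range(len(rho))]),
        rho=rho, pvalues=np.asarray(pvalues, float), n_samples=n,
    )


class TestNetworks:
    def test_cn_uses_absolute_rho_with_zero_diagonal(self):
        res = _corr([[1, -0.8], [-0.8, 1]], [[0, 0.01], [0.01, 0]])
        cn = build_cn(res)
        assert cn.adjacency[0, 1] == pytest.approx(0.8)
        assert np.diag(cn.adjacency).sum() == 0

    def test_scn_bonferroni_arithmetic(self):
        # g=3 genes -> m=3 tested pairs; q = p*m
        p = np.zeros((3, 3))
        p[0, 1] = p[1, 0] = 0.01   # q=0.03 < 0.05 -> edge
        p[0, 2] = p[2, 0] = 0.02   # q=0.06 >= 0.05 -> no edge
        p[1, 2] = p[2, 1] = 0.5
        scn = build_scn(_corr(np.eye(3), p))
        assert scn.adjacency[0, 1] == 1
        assert scn.adjacency[0, 2] == 0 and scn.adjacency[1, 2] == 0

    def test_scn_monotone_in_alpha(self, rng):
        E = pd.DataFrame(rng.random((30, 15)),
                         columns=[f"g{j}" for j in range(15)])
        res = spearman_all_pairs(E)
        strict = build_scn(res, alpha_level=0.01).adjacency
        loose = build_scn(res, alpha_level=0.05).adjacency
        assert (loose >= strict).all()  # edge set is nested


class TestKnnGraph:
    def test_small_p_covers_all_with_few_genes(self, rng):
        cn = random_graph(rng, 3, density=1.0, weighted=True)
        assert (knn_graph(cn, p=2).adjacency == cn.adjacency.astype(bool)).all()

    def test_star_weighting_with_or_rule(self):
        # gene 0 carries the top weight to everyone; p=1 keeps the star
        W = np.full((4, 4), 0.1)
        W[0, :] = W[:, 0] = 0.9
        np.fill_diagonal(W, 0)
        cn = random_graph(np.random.default_rng(0), 4, weighted=True)
        cn.adjacency = W
        A = knn_graph(cn, p=1).adjacency
        expected = np.zeros((4, 4))
        expected[0, 1:] = expected[1:, 0] = 1
        assert (A == expected).all()

    def test_symmetric_for_random_weights(self, rng):
        for _ in range(5):
            cn = random_graph(rng, 12, density=0.6, weighted=True)
            A = knn_graph(cn, p=3).adjacency
            assert (A == A.T).all() and np.diag(A).sum() == 0

    def test_p_at_least_n_warns_complete(self, rng):
        cn = random_graph(rng, 4, density=1.0, weighted=True)
        with pytest.warns(UserWarning, match="complete"):
            A = knn_graph(cn, p=10).adjacency
        assert (A == (np.ones((4, 4)) - np.eye(4))).all()

    def test_p_equal_n_minus_1_equals_cn_support(self, rng):
        cn = random_graph(rng, 10, density=0.5, weighted=True)
        A = knn_graph(cn, p=9).adjacency
        assert (A == (cn.adjacency > 0)).all()

    def test_tie_break_prefers_lower_gene_index(self):
        # gene 0 ties between genes 2 and 3; nobody else selects gene 0,
        # so the resulting edge reveals the tie-break
        W = np.array([
            [0.0, 0.40, 0.50, 0.50],
            [0.40, 0.0, 0.45, 0.00],
            [0.50, 0.45, 0.0, 0.90],
            [0.50, 0.00, 0.90, 0.0],
        ])
        cn = random_graph(np.random.default_rng(0), 4, weighted=True)
        cn.adjacency = W
        A = knn_graph(cn, p=1).adjacency
        assert A[0, 2] == 1  # ascending-index tie-break picks gene 2
        assert A[0, 3] == 0


class TestLaplacian:
    def test_path_graph_textbook_form(self, path_graph):
        L = graph_laplacian(path_graph)
        assert (L == [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]).all()

    def test_empty_graph_zero_matrix(self):
        from netstrat import GeneNetwork
        net = GeneNetwork(genes=pd.Index(["a", "b"]),
                          adjacency=np.zeros((2, 2)), weighted=False)
        assert (graph_laplacian(net) == 0).all()

    def test_quadratic_form_matches_pairwise_oracle(self, rng):
        net = random_graph(rng, 15, density=0.3)
        L, w = graph_laplacian(net), net.adjacency
        for _ in range(20):
            x = rng.standard_normal(15)
            oracle = 0.5 * (w * (x[:, None] - x[None, :]) ** 2).sum()
            assert x @ L @ x == pytest.approx(oracle, rel=1e-9, abs=1e-9)
            assert x @ L @ x >= -1e-9  # PSD

    def test_row_sums_zero(self, rng):
        L = graph_laplacian(random_graph(rng, 20, density=0.4))
        assert np.allclose(L.sum(axis=1), 0.0)
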