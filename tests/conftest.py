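import numpy as np
import pandas as pd
import pytest

from netstrat import GeneNetwork, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Strong-signal cohort small enough for fast module tests."""
    cfg = SyntheticConfig(
        n_samples=60, n_genes=90, n_subtypes=3, module_sizes=(15, 15, 15),
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def path_graph():
    """a - b - c chain."""
    A = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return GeneNetwork(genes=pd.Index(["a", "b", "c"]), adjacency=A,
                       weighted=False)


def random_graph(rng, n, density=0.2, weighted=False):
    """Random symmetric zero-diagonal adjacency helper."""
    A = (rng.random((n, n)) < density).astype(float)
    if weighted:
        A *= rng.random((n, n))
    A = np.triu(A, 1)
    A = A + A.T
    return GeneNetwork(
        genes=pd.Index([f"g{i}" for i in range(n)]), adjacency=A,
        weighted=weighted,
    )
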