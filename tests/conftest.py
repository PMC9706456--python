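import numpy as np
import pandas as pd
import pytest

import cohealth as ch


@pytest.fixture
def toy_adjacency():
    """3-gene adjacency with a12=0.8, a13=0.5, a23=0.4 (hand-checkable)."""
    a = np.array([[1.0, 0.8, 0.5],
                  [0.8, 1.0, 0.4],
                  [0.5, 0.4, 1.0]])
    genes = ["gene1", "gene2", "gene3"]
    return pd.DataFrame(a, index=genes, columns=genes)


@pytest.fixture(scope="session")
def default_collection():
    """The default two-species, four-experiment synthetic collection."""
    cfg = ch.SimulationConfig(seed=11)
    experiments, truth, ortholog = ch.generate_collection(cfg)
    return cfg, experiments, truth, ch.OrthologMap(ortholog)


def random_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric matrix with entries in [0, 1] and unit diagonal."""
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop evaluation of the unsigned TOM formula."""
    n = a.shape[0]
    k = np.array([sum(a[i, j] for j in range(n) if j != i) for i in range(n)])
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom
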