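import numpy as np
import pytest

import pathgcn as pg


@pytest.fixture(scope="session")
def small_single_dataset():
    """60-molecule 2-class planted-motif set, fully separable."""
    spec = pg.SyntheticSpec(
        n_molecules=60, n_classes=2, multi_label_fraction=0.0, seed=11
    )
    return pg.generate(spec)


@pytest.fixture(scope="session")
def small_multi_dataset():
    """120-molecule 4-class set with mixed-membership compounds."""
    spec = pg.SyntheticSpec(
        n_molecules=120, n_classes=4, multi_label_fraction=0.15, seed=12
    )
    return pg.generate(spec)


@pytest.fixture(scope="session")
def tiny_hyperparams():
    return pg.GCNHyperparams(dim=12, layers=2, radius=1, epochs=25, seed=5)


@pytest.fixture(scope="session")
def tiny_model(small_single_dataset, tiny_hyperparams):
    """A small trained softmax model shared across read-only tests."""
    return pg.train(small_single_dataset, tiny_hyperparams)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_molecular_graph(rng, max_nodes=8):
    """Random connected atom-labeled graph with bond multiplicities."""
    n = int(rng.integers(1, max_nodes + 1))
    labels = tuple(rng.choice(["C", "N", "O", "S"]) for _ in range(n))
    A = np.zeros((n, n), dtype=np.int64)
    # random spanning tree keeps the graph connected
    for i in range(1, n):
        j = int(rng.integers(0, i))
        A[i, j] = A[j, i] = int(rng.integers(1, 4))
    # a few extra edges
    for _ in range(int(rng.integers(0, n))):
        i, j = rng.integers(0, n, size=2)
        if i != j and A[i, j] == 0:
            A[i, j] = A[j, i] = int(rng.integers(1, 4))
    return pg.MolecularGraph(atom_labels=labels, adjacency=A)
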