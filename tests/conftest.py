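"""Shared fixtures: tiny hand-built networks and random instances."""

import numpy as np
import pytest

from adrlink import BipartiteNetwork, SimilarityMatrix


@pytest.fixture
def tiny_net() -> BipartiteNetwork:
    """d1-{a1,a2}, d2-{a2,a3}: the classic two-drug overlap example."""
    Y = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
    return BipartiteNetwork(("d1", "d2"), ("a1", "a2", "a3"), Y)


def random_network(rng: np.random.Generator, n: int, m: int, p: float = 0.4) -> BipartiteNetwork:
    Y = (rng.random((n, m)) < p).astype(float)
    # keep at least one edge so degree-based features are non-degenerate
    if Y.sum() == 0:
        Y[rng.integers(n), rng.integers(m)] = 1.0
    drugs = tuple(f"d{i}" for i in range(n))
    adrs = tuple(f"a{j}" for j in range(m))
    return BipartiteNetwork(drugs, adrs, Y)


def random_similarity(rng: np.random.Generator, ids: tuple, side: str) -> SimilarityMatrix:
    k = len(ids)
    A = rng.random((k, k))
    S = (A + A.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(side, "blended", ids, S)


@pytest.fixture(scope="session")
def default_synthetic():
    """The default synthetic study conditions (shared across tests)."""
    from adrlink import SyntheticSpec, generate

    return generate(SyntheticSpec())
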