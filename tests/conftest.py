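import numpy as np
import pytest

from coexgraph import CoExpressionGraph


def complete_graph(n: int, weight: float = 1.0) -> CoExpressionGraph:
    A = np.full((n, n), weight, dtype=float)
    np.fill_diagonal(A, 0.0)
    return CoExpressionGraph([f"G{i}" for i in range(n)], A)


def random_graph(rng: np.random.Generator, n: int = 10) -> CoExpressionGraph:
    """Random weighted graph: symmetric uniform weights in [0, 1], zero diagonal."""
    upper = rng.uniform(0.0, 1.0, size=(n, n))
    A = np.triu(upper, k=1)
    A = A + A.T
    return CoExpressionGraph([f"G{i}" for i in range(n)], A)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2025)


@pytest.fixture
def unit_k3() -> CoExpressionGraph:
    return complete_graph(3, 1.0)
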