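import numpy as np
import pytest

from graphimpute import ExpressionMatrix, generate_reference, make_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts():
    """4 cells x 3 genes integer count matrix with one sparse gene."""
    values = np.array(
        [
            [4, 0, 1],
            [2, 1, 0],
            [0, 3, 0],
            [5, 2, 2],
        ],
        dtype=float,
    )
    return ExpressionMatrix(values, ("g1", "g2", "g3"), ("c1", "c2", "c3", "c4"))


@pytest.fixture
def random_expression(rng):
    """10 cells x 5 genes nonnegative float matrix."""
    values = rng.gamma(2.0, 1.5, size=(10, 5))
    return ExpressionMatrix(
        values,
        tuple(f"g{j}" for j in range(5)),
        tuple(f"c{i}" for i in range(10)),
    )


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small planted-module benchmark shared by pipeline-level tests."""
    ds = generate_reference(
        m=40, n=300, n_blocks=4, within_block_strength=0.9, seed=42
    )
    return make_benchmark(ds, p_mask=0.8, seed=43)
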