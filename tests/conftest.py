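import numpy as np
import pytest

from colodiff import BackgroundParams, CountMatrix, ExpressionMatrix, log_normalize


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_counts():
    """5 genes x 4 cells with assorted sparsity."""
    vals = np.array(
        [
            [5, 0, 1, 2],
            [0, 3, 0, 0],
            [1, 1, 1, 1],
            [0, 0, 0, 4],
            [2, 0, 3, 0],
        ]
    )
    return CountMatrix(vals, [f"g{i}" for i in range(5)], [f"c{j}" for j in range(4)], "demo")


@pytest.fixture()
def random_expr(rng):
    """A moderately sized random log-normalized matrix (60 genes x 80 cells)."""
    counts = rng.poisson(1.2, size=(60, 80))
    counts[0] += 1  # ensure no zero-total cells
    cm = CountMatrix(counts, [f"g{i:02d}" for i in range(60)], [f"c{j:02d}" for j in range(80)])
    return log_normalize(cm)


def make_expression(values, prefix="g") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"c{j}" for j in range(values.shape[1])],
    )


@pytest.fixture()
def tiny_background():
    return BackgroundParams(n_genes=150, n_cells=120)
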