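import numpy as np
import pandas as pd
import pytest

from scdnet import ExpressionMatrix, StateAssignment


def expression_from_array(values, gene_ids=None, cell_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    G, K = values.shape
    genes = gene_ids or [f"g{i}" for i in range(G)]
    cells = cell_ids or [f"c{k}" for k in range(K)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells))


def two_state_labels(E: ExpressionMatrix, n_state0: int) -> StateAssignment:
    """First n_state0 cells -> state 'A' (0), the rest -> 'B' (1)."""
    lab = ["A"] * n_state0 + ["B"] * (E.n_cells - n_state0)
    return StateAssignment.from_series(pd.Series(lab, index=E.cell_ids))


def sparse_lognormal_matrix(rng, G=12, K=40, sparsity=0.3) -> ExpressionMatrix:
    """Positive lognormal counts with uniformly planted zeros."""
    values = 10.0 * np.exp(0.5 * rng.standard_normal((G, K)))
    values[rng.random((G, K)) < sparsity] = 0.0
    return expression_from_array(values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_matrix(rng):
    return sparse_lognormal_matrix(rng, G=12, K=40, sparsity=0.3)


@pytest.fixture
def small_states(small_matrix):
    return two_state_labels(small_matrix, n_state0=20)
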