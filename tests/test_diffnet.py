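"""Exact |X|-|Y| null, differential calling, hubs and DE overlap."""

import numpy as np
import pandas as pd
import pytest

from scdnet import (
    StateAssignment,
    ValidationError,
    call_differential,
    compare_with_de,
    delta_cdf,
    delta_interaction,
    delta_pvalue,
    fisher_interaction,
    hub_table,
)
from scdnet.corrcore import StateCorrelation
from scdnet.diffnet import DifferentialNetwork

from conftest import expression_from_array, two_state_labels


# ---------------------------------------------------------------------------
# the exact null of |X| - |Y|
# ---------------------------------------------------------------------------


def test_delta_interaction_arithmetic():
    assert delta_interaction(-2.0, 2.0) == 0.0
    assert delta_interaction(1.0, 3.0) == 2.0
    assert delta_interaction(3.0, 1.0) == -2.0  # loss of interaction in state 1


def test_delta_cdf_values_and_symmetry():
    assert delta_cdf(0.0) == 0.5
    # closed form 1/2 + erf(0.5) - erf(0.5)^2 / 2
    assert delta_cdf(1.0) == pytest.approx(0.8850398164113483, abs=1e-15)
    grid = np.linspace(-4, 4, 33)
    np.testing.assert_allclose(delta_cdf(grid) + delta_cdf(-grid), 1.0, atol=1e-15)
    assert np.all(np.diff(delta_cdf(grid)) > 0)


def test_delta_cdf_against_monte_carlo_small():
    r = np.random.default_rng(5)
    draws = np.abs(r.standard_normal(10**6)) - np.abs(r.standard_normal(10**6))
    draws.sort()
    for d in (-2.0, -0.5, 0.7, 1.0, 2.5):
        emp = np.searchsorted(draws, d, side="right") / draws.size
        assert delta_cdf(d) == pytest.approx(emp, abs=2e-3)


def test_delta_pvalue_tails_and_identity():
    assert delta_pvalue(0.0) == 1.0
    grid = np.linspace(-5, 5, 41)
    for d in grid:
        two = delta_pvalue(d)
        assert two == pytest.approx(
            2 * min(delta_pvalue(d, "gain"), delta_pvalue(d, "loss")), rel=1e-12
        )
        assert 0 < two <= 1
    # F(d) = 0.975 -> two-sided p = 0.05
    from scipy.optimize import brentq

    d975 = brentq(lambda d: delta_cdf(d) - 0.975, 0, 10)
    assert delta_pvalue(d975) == pytest.approx(0.05, rel=1e-9)
    # far tail stays positive (no underflow to exactly 0 at representable d)
    assert delta_pvalue(50.0) > 0.0


def test_delta_pvalue_uniform_under_global_null():
    """Two uncorrelated states: interaction scores are independent standard
    normals, so the two-sided p of their |.|-difference is uniform."""
    r = np.random.default_rng(99)
    I0, I1 = r.standard_normal(10_000), r.standard_normal(10_000)
    p = delta_pvalue(delta_interaction(I0, I1))
    for alpha in (0.01, 0.05, 0.2):
        frac = (p < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / 10_000)
        assert abs(frac - alpha) < 4 * se


# ---------------------------------------------------------------------------
# differential calling
# ---------------------------------------------------------------------------


def _state_corr(I: np.ndarray, S: int, state: int, genes) -> StateCorrelation:
    G = I.shape[0]
    C = np.tanh(np.where(np.isfinite(I), I, 0.0) / np.sqrt(S - 3))
    C[~np.isfinite(I)] = np.nan
    np.fill_diagonal(C, np.nan)
    Sm = np.full((G, G), S, dtype=np.int64)
    np.fill_diagonal(Sm, 0)
    return StateCorrelation(
        state=state, gene_ids=pd.Index(genes), C=C, S=Sm, I=I,
        s_min=10, n_cells=S,
    )


def _toy_states(I0, I1, genes):
    I0, I1 = np.asarray(I0, float), np.asarray(I1, float)
    np.fill_diagonal(I0, np.nan)
    np.fill_diagonal(I1, np.nan)
    return _state_corr(I0, 50, 0, genes), _state_corr(I1, 50, 1, genes)


def test_identical_states_give_no_edges(rng):
    G = 6
    I = rng.standard_normal((G, G))
    I = (I + I.T) / 2
    s0, s1 = _toy_states(I.copy(), I.copy(), [f"g{i}" for i in range(G)])
    net = call_differential(s0, s1, alpha=0.999)
    assert net.n_edges == 0
    assert net.n_tested == G * (G - 1) // 2


def test_single_planted_differential_pair():
    genes = list("abcde")
    G = len(genes)
    I0 = np.zeros((G, G))
    I1 = np.zeros((G, G))
    # pair (a, b): rho = 0.95 at n = 50 in state 1 only
    I1[0, 1] = I1[1, 0] = fisher_interaction(0.95, 50)
    s0, s1 = _toy_states(I0, I1, genes)
    net = call_differential(s0, s1, alpha=0.05)
    assert [(e.gene_i, e.gene_j) for e in net.edges] == [("a", "b")]
    e = net.edges[0]
    assert e.specific_state == 1 and e.delta > 0
    assert e.p_adj == pytest.approx(min(1.0, e.p * net.n_tested))
    assert net.degree == {"a": 1, "b": 1}


def test_state_swap_flips_specificity():
    genes = list("abcd")
    I0 = np.zeros((4, 4))
    I0[2, 3] = I0[3, 2] = 8.0  # strong only in state 0
    I1 = np.zeros((4, 4))
    s0, s1 = _toy_states(I0, I1, genes)
    net = call_differential(s0, s1)
    assert net.edges[0].specific_state == 0 and net.edges[0].delta < 0
    swapped = call_differential(s1, s0)
    assert swapped.edges[0].specific_state == 1
    assert swapped.edges[0].p == net.edges[0].p


def test_star_network_degrees_and_hub_table():
    genes = list("abcd")
    I0 = np.zeros((4, 4))
    I1 = np.zeros((4, 4))
    for j in (1, 2, 3):  # edges ab, ac, ad
        I1[0, j] = I1[j, 0] = 9.0
    s0, s1 = _toy_states(I0, I1, genes)
    net = call_differential(s0, s1)
    assert net.degree == {"a": 3, "b": 1, "c": 1, "d": 1}
    assert sum(net.degree.values()) == 2 * net.n_edges
    assert hub_table(net, 2) == [("a", 3), ("b", 1)]  # tie broken lexicographically
    assert hub_table(net, 100) == [("a", 3), ("b", 1), ("c", 1), ("d", 1)]
    assert net.mean_degree == pytest.approx(2 * 3 / 4)


def test_mean_degree_hand_count(rng):
    # complete graph on 5 genes: 10 edges, mean degree 2*10/5 = 4 by hand
    G = 5
    I1 = np.full((G, G), 9.0)
    s0, s1 = _toy_states(np.zeros((G, G)), I1, [f"g{i}" for i in range(G)])
    net = call_differential(s0, s1)
    assert net.n_edges == 10
    assert net.mean_degree == pytest.approx(4.0)


def test_p_adjust_is_monotone_and_edges_below_threshold(rng):
    G = 8
    I0 = rng.standard_normal((G, G)) * 2
    I0 = (I0 + I0.T) / 2
    I1 = rng.standard_normal((G, G)) * 2
    I1 = (I1 + I1.T) / 2
    s0, s1 = _toy_states(I0, I1, [f"g{i}" for i in range(G)])
    net = call_differential(s0, s1, alpha=0.5)
    ps = [e.p for e in net.edges]
    padj = [e.p_adj for e in net.edges]
    assert padj == sorted(padj)  # monotone in p (edges sorted by p)
    assert all(a <= 1 and a >= p for p, a in zip(ps, padj))
    assert all(a < 0.5 for a in padj)


def test_missing_pairs_are_excluded_from_m():
    genes = list("abc")
    I0 = np.zeros((3, 3))
    I1 = np.zeros((3, 3))
    I0[0, 2] = I0[2, 0] = np.nan  # pair (a, c) unavailable in state 0
    s0, s1 = _toy_states(I0, I1, genes)
    net = call_differential(s0, s1)
    assert net.n_tested == 2
    with pytest.warns(RuntimeWarning):
        empty = call_differential(
            _toy_states(np.full((3, 3), np.nan), I1, genes)[0],
            _toy_states(I0, I1, genes)[1],
        )
    assert empty.n_edges == 0 and empty.n_tested == 0


# ---------------------------------------------------------------------------
# DE overlap
# ---------------------------------------------------------------------------


def test_compare_with_de_overlap_fraction(rng):
    # 20 genes, the network involves g0..g9; g0 and g1 get a strong mean
    # shift in state B, every other gene is identical across states
    half = rng.random((20, 30)) + 1.0
    values = np.hstack([half, half.copy()])
    values[0, 30:] += 5.0
    values[1, 30:] += 5.0
    E = expression_from_array(values)
    states = two_state_labels(E, 30)
    net = DifferentialNetwork(
        nodes=[f"g{i}" for i in range(10)],
        edges=[],
        degree={f"g{i}": 1 for i in range(10)},
        n_tested=45,
        threshold=0.05,
    )
    summary = compare_with_de(net, E, states)
    assert summary.overlap == 2
    assert summary.overlap_fraction == pytest.approx(0.2)
    assert summary.network_only == 8
    assert summary.de_only == 0


def test_compare_with_de_skips_flat_genes(rng):
    values = rng.random((4, 20)) + 1.0
    values[2, :] = 3.0  # zero variance in both groups
    values = np.hstack([values, values.copy()])
    E = expression_from_array(values)
    states = two_state_labels(E, 20)
    net = DifferentialNetwork(
        nodes=["g2", "g3"], edges=[], degree={"g2": 1, "g3": 1},
        n_tested=6, threshold=0.05,
    )
    summary = compare_with_de(net, E, states)
    assert summary.overlap_fraction == 0.0  # identical states: nothing DE
    empty = DifferentialNetwork(nodes=[], edges=[], degree={}, n_tested=0, threshold=0.05)
    with pytest.raises(ValidationError):
        compare_with_de(empty, E, states)
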