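"""Inter-state differential network analysis.

The change in interaction strength of a gene pair between two cellular
states is

    delta = |I1| - |I0|,

the difference of the absolute Fisher interaction scores.  Under the null
(no true correlation in either state) I0 and I1 are independent standard
normals, so delta is distributed as |X| - |Y| with X, Y ~ N(0, 1), whose
CDF has the exact closed form

    F(d) = 1/2 + erf(d/2) - 1/2 * sgn(d) * erf(d/2)^2.

P-values therefore come straight from F with no permutation or simulation.
Pairs significant after Bonferroni control are merged into a differential
network whose node degrees rank hub genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import erf, erfc

from .corrcore import StateCorrelation
from .preprocess import ExpressionMatrix, StateAssignment, ValidationError

_TINY = 5e-324

EDGE_COLUMNS = [
    "gene_i",
    "gene_j",
    "I0",
    "I1",
    "S0",
    "S1",
    "delta",
    "p",
    "p_adj",
    "specific_state",
]


# ---------------------------------------------------------------------------
# The exact null of |X| - |Y|
# ---------------------------------------------------------------------------


def delta_interaction(I0, I1):
    """Change of interaction strength |I1| - |I0| (positive = gain in state 1)."""
    return np.abs(I1) - np.abs(I0)


def delta_cdf(d):
    """Exact CDF of |X| - |Y| for independent standard normal X, Y.

    F(d) = 1/2 + erf(d/2) - 1/2 * sgn(d) * erf(d/2)^2.
    """
    d = np.asarray(d, dtype=float)
    e = erf(d / 2.0)
    out = 0.5 + e - 0.5 * np.sign(d) * e * e
    return out if out.ndim else float(out)


def _upper_tail(d):
    """P(|X| - |Y| > d), numerically stable in the far right tail.

    For d >= 0 the identity 1 - F(d) = erfc(d/2)^2 / 2 avoids the
    catastrophic cancellation of computing 1 - F directly.
    """
    d = np.asarray(d, dtype=float)
    pos = 0.5 * erfc(d / 2.0) ** 2
    e = erf(d / 2.0)  # negative branch: plain formula is already stable
    neg = 0.5 - e - 0.5 * e * e
    return np.where(d >= 0, pos, neg)


def _lower_tail(d):
    """P(|X| - |Y| <= d), stable in the far left tail (mirror of the upper)."""
    d = np.asarray(d, dtype=float)
    neg = 0.5 * erfc(-d / 2.0) ** 2
    e = erf(d / 2.0)
    pos = 0.5 + e - 0.5 * e * e
    return np.where(d <= 0, neg, pos)


def delta_pvalue(d, tail: str = "two_sided"):
    """P-value for an interaction change under the exact |X| - |Y| null.

    ``two_sided``: 2 * min(F(d), 1 - F(d)) = erfc(|d|/2)^2;
    ``gain``: 1 - F(d) (specific to state 1); ``loss``: F(d).
    Always in (0, 1].
    """
    d = np.asarray(d, dtype=float)
    if tail == "two_sided":
        p = erfc(np.abs(d) / 2.0) ** 2
    elif tail == "gain":
        p = _upper_tail(d)
    elif tail == "loss":
        p = _lower_tail(d)
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    p = np.clip(p, _TINY, 1.0)
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# Network containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentialPair:
    """One gene pair with a significant inter-state interaction change."""

    gene_i: str
    gene_j: str
    I0: float
    I1: float
    S0: int
    S1: int
    delta: float
    p: float
    p_adj: float
    specific_state: int  # state with the larger |I|


@dataclass
class DifferentialNetwork:
    """Merged network of all differential pairs.

    ``nodes`` are the genes incident to at least one edge; ``degree`` counts
    incident differential pairs per gene.  ``n_tested`` is the Bonferroni
    denominator m (pairs defined in both states).
    """

    nodes: list[str]
    edges: list[DifferentialPair]
    degree: dict[str, int]
    n_tested: int
    threshold: float
    tail: str = "two_sided"
    params: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        """Average number of partners per involved gene: 2|E| / |V|."""
        if not self.nodes:
            return float("nan")
        return 2.0 * len(self.edges) / len(self.nodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {c: getattr(e, c) for c in EDGE_COLUMNS}
                for e in self.edges
            ],
            columns=EDGE_COLUMNS,
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.gene_i,
                e.gene_j,
                delta=float(e.delta),
                p=float(e.p),
                p_adj=float(e.p_adj),
                I0=float(e.I0),
                I1=float(e.I1),
                S0=int(e.S0),
                S1=int(e.S1),
                specific_state=int(e.specific_state),
            )
        return g

    # -- exports -------------------------------------------------------------

    def write_edges_tsv(self, path: str | Path, header_lines: list[str] | None = None):
        path = Path(path)
        with path.open("w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def write_sif(self, path: str | Path) -> None:
        """Cytoscape-readable SIF: ``geneA<TAB>diff<TAB>geneB``."""
        with Path(path).open("w") as fh:
            for e in self.edges:
                fh.write(f"{e.gene_i}\tdiff\t{e.gene_j}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_nodes(self, path: str | Path) -> None:
        """Plain gene list for external annotation tools."""
        Path(path).write_text("\n".join(self.nodes) + ("\n" if self.nodes else ""))


# ---------------------------------------------------------------------------
# Differential calling
# ---------------------------------------------------------------------------


def call_differential(
    state0: StateCorrelation,
    state1: StateCorrelation,
    alpha: float = 0.05,
    adjusted_p_cut: float | None = None,
    tail: str = "two_sided",
) -> DifferentialNetwork:
    """Test every pair defined in both states and assemble the network.

    The Bonferroni denominator m is the number of pairs actually tested
    (interaction score available in both states).  An edge is a pair with
    adjusted p = min(1, p * m) below ``adjusted_p_cut`` (default: ``alpha``).
    Edges are ordered by (p, gene_i, gene_j).
    """
    if not state0.gene_ids.equals(state1.gene_ids):
        raise ValidationError("state correlations have different gene indexing")
    genes = state0.gene_ids
    testable = state0.defined() & state1.defined()
    iu = np.triu_indices(len(genes), k=1)
    sel = testable[iu]
    m = int(sel.sum())
    cut = alpha if adjusted_p_cut is None else adjusted_p_cut
    if m == 0:
        warnings.warn("no gene pair is testable in both states", RuntimeWarning)
        return DifferentialNetwork(
            nodes=[], edges=[], degree={}, n_tested=0, threshold=cut, tail=tail
        )

    ii, jj = iu[0][sel], iu[1][sel]
    I0 = state0.I[ii, jj]
    I1 = state1.I[ii, jj]
    d = delta_interaction(I0, I1)
    p = np.asarray(delta_pvalue(d, tail=tail))
    p_adj = np.minimum(1.0, p * m)

    hit = p_adj < cut
    edges = []
    for k in np.flatnonzero(hit):
        gi, gj = str(genes[ii[k]]), str(genes[jj[k]])
        edges.append(
            DifferentialPair(
                gene_i=gi,
                gene_j=gj,
                I0=float(I0[k]),
                I1=float(I1[k]),
                S0=int(state0.S[ii[k], jj[k]]),
                S1=int(state1.S[ii[k], jj[k]]),
                delta=float(d[k]),
                p=float(p[k]),
                p_adj=float(p_adj[k]),
                specific_state=1 if d[k] > 0 else 0,
            )
        )
    edges.sort(key=lambda e: (e.p, e.gene_i, e.gene_j))
    degree: dict[str, int] = {}
    for e in edges:
        degree[e.gene_i] = degree.get(e.gene_i, 0) + 1
        degree[e.gene_j] = degree.get(e.gene_j, 0) + 1
    nodes = sorted(degree)
    return DifferentialNetwork(
        nodes=nodes,
        edges=edges,
        degree=degree,
        n_tested=m,
        threshold=cut,
        tail=tail,
        params={"alpha": alpha, "adjusted_p_cut": adjusted_p_cut},
    )


def hub_table(net: DifferentialNetwork, top_k: int) -> list[tuple[str, int]]:
    """Top hub genes, ranked by degree (ties broken lexicographically)."""
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    ranked = sorted(net.degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


@dataclass(frozen=True)
class OverlapSummary:
    """Overlap between differential-network genes and differentially expressed genes."""

    network_only: int
    de_only: int
    overlap: int
    overlap_fraction: float
    de_alpha: float


def compare_with_de(
    net: DifferentialNetwork,
    E: ExpressionMatrix,
    states: StateAssignment,
    de_alpha: float = 0.05,
) -> OverlapSummary:
    """Contrast network membership with per-gene differential expression.

    Each gene gets a Welch two-sample t-test between the states on its
    normalized counts (zeros included).  The overlap fraction is the share
    of network genes that are also DE at ``de_alpha`` — in the intended use
    a small value, showing the network captures rewiring of co-expression
    rather than shifts in mean expression.
    """
    if not net.nodes:
        raise ValidationError("network is empty; nothing to compare")
    states.check_compatible(E)
    idx0 = states.cells_of_state(E, 0)
    idx1 = states.cells_of_state(E, 1)
    values = E.values
    de_genes: set[str] = set()
    net_genes = set(net.nodes)
    for g, gene in enumerate(E.gene_ids):
        a, b = values[g, idx0], values[g, idx1]
        if a.std() == 0.0 and b.std() == 0.0:
            continue  # untestable; a network member counts as network-only
        t = stats.ttest_ind(a, b, equal_var=False)
        if t.pvalue < de_alpha:
            de_genes.add(str(gene))
    overlap = len(net_genes & de_genes)
    return OverlapSummary(
        network_only=len(net_genes - de_genes),
        de_only=len(de_genes - net_genes),
        overlap=overlap,
        overlap_fraction=overlap / len(net_genes),
        de_alpha=de_alpha,
    )
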