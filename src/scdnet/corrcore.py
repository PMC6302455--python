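"""Intra-state masked correlation and sample-size-adjusted Fisher scoring.

For a cellular state n, correlation between genes i and j is computed only
over the pair's *support*: the cells of the state where neither gene is a
dropout (exact zero in the normalized counts).  Because every pair has its
own support, each pair also has its own sample size, which the Fisher
transformation folds into a sample-size-free interaction score

    I(i, j) = sqrt(S(i, j) - 3) / 2 * ln((1 + C(i, j)) / (1 - C(i, j)))
            = sqrt(S - 3) * atanh(C).

Under the no-correlation null, I is standard normal, so intra-state
significance is a plain two-sided normal test and inter-state differences
of |I| have the exact closed-form null handled in :mod:`scdnet.diffnet`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import (
    ExpressionMatrix,
    StateAssignment,
    ValidationError,
    ZScoredMatrix,
)

logger = logging.getLogger(__name__)

#: correlations within this distance of +-1 are considered degenerate ...
_CLAMP_TOL = 1e-12
#: ... and replaced by +-(1 - _CLAMP_VALUE) so the Fisher score stays finite.
_CLAMP_VALUE = 1e-7

#: smallest positive double; p-values are floored here, never exactly 0
_TINY = 5e-324


@dataclass(frozen=True)
class PairSupport:
    """Support set of one gene pair in one state."""

    i: str
    j: str
    state: int
    cells: pd.Index  # cell ids, in matrix column order

    @property
    def size(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class StateCorrelation:
    """Per-state correlation (C), sample-size (S) and interaction (I) matrices.

    All three are G x G and symmetric; missing entries (support below
    ``s_min``, zero variance on the support, or the diagonal) are NaN in C
    and I.  ``S`` always holds the support size, with 0 on the diagonal.
    """

    state: int
    gene_ids: pd.Index
    C: np.ndarray
    S: np.ndarray
    I: np.ndarray
    s_min: int
    n_cells: int
    n_clamped: int = 0

    def defined(self) -> np.ndarray:
        """Boolean G x G array where the interaction score is available."""
        return np.isfinite(self.I)

    def write_tsv(self, outdir: str | Path, prefix: str = "") -> list[Path]:
        """Export C/S/I as gene x gene TSVs; missing values written as NA."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, mat in (("C", self.C), ("S", self.S), ("I", self.I)):
            path = outdir / f"{prefix}{name}_state{self.state}.tsv"
            pd.DataFrame(mat, index=self.gene_ids, columns=self.gene_ids).to_csv(
                path, sep="\t", na_rep="NA"
            )
            written.append(path)
        return written


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def fisher_interaction(r, n):
    """Sample-size-adjusted Fisher score sqrt(n - 3) * atanh(r).

    ``r`` and ``n`` broadcast; ``n`` must be >= 4 everywhere (the adjustment
    needs n - 3 >= 1).  Correlations within 1e-12 of +-1 are clamped to
    +-(1 - 1e-7) so the score stays finite.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n)
    if np.any(n < 4):
        raise ValidationError("fisher_interaction requires n >= 4")
    clamped = np.abs(r) >= 1.0 - _CLAMP_TOL
    n_clamped = int(np.count_nonzero(clamped & np.isfinite(r)))
    if n_clamped:
        logger.info("clamped %d correlation(s) at |r| ~ 1", n_clamped)
        r = np.where(clamped, np.sign(r) * (1.0 - _CLAMP_VALUE), r)
    out = np.sqrt(np.asarray(n, dtype=float) - 3.0) * np.arctanh(r)
    return out if out.ndim else float(out)


def intra_state_pvalue(I_value):
    """Two-sided p-value of an interaction score under the N(0, 1) null.

    p = 2 * (1 - Phi(|I|)), floored at the smallest positive double so the
    result is always in (0, 1].
    """
    I_value = np.asarray(I_value, dtype=float)
    p = np.minimum(2.0 * stats.norm.sf(np.abs(I_value)), 1.0)
    p = np.maximum(p, _TINY)
    return p if p.ndim else float(p)


def pair_support(
    E: ExpressionMatrix,
    mask: np.ndarray,
    states: StateAssignment,
    state: int,
    i: str | int,
    j: str | int,
) -> PairSupport:
    """Cells of ``state`` where neither gene ``i`` nor ``j`` is a dropout.

    ``mask`` is the dropout mask (True = zero count).  Genes may be given as
    ids or row indices.  The support preserves matrix column order.
    """

    def _row(g):
        return g if isinstance(g, (int, np.integer)) else E.gene_ids.get_loc(g)

    ri, rj = _row(i), _row(j)
    if ri == rj:
        raise ValidationError("pair_support requires two distinct genes")
    cols = states.cells_of_state(E, state)
    keep = ~mask[ri, cols] & ~mask[rj, cols]
    return PairSupport(
        i=str(E.gene_ids[ri]),
        j=str(E.gene_ids[rj]),
        state=state,
        cells=E.cell_ids[cols[keep]],
    )


# ---------------------------------------------------------------------------
# Full per-state computation
# ---------------------------------------------------------------------------


def _resolve_inputs(matrix, mask):
    if isinstance(matrix, ZScoredMatrix):
        values = matrix.values.to_numpy(dtype=float)
        gene_ids, cell_ids = matrix.gene_ids, matrix.cell_ids
        if mask is None:
            mask = matrix.dropout_mask
    elif isinstance(matrix, ExpressionMatrix):
        values = matrix.values
        gene_ids, cell_ids = matrix.gene_ids, matrix.cell_ids
        if mask is None:
            mask = matrix.dropout_mask
    else:
        raise TypeError("matrix must be an ExpressionMatrix or ZScoredMatrix")
    return values, np.asarray(mask, dtype=bool), gene_ids, cell_ids


def state_correlation(
    matrix,
    states: StateAssignment,
    state: int,
    s_min: int = 10,
    mask: np.ndarray | None = None,
    engine: str = "blocked",
) -> StateCorrelation:
    """Masked correlation, support-size and Fisher matrices for one state.

    Parameters
    ----------
    matrix
        :class:`ExpressionMatrix` or :class:`ZScoredMatrix`.  Pearson
        correlation is affine-invariant per gene, so both give identical C.
    states, state
        The two-state assignment and which state (0/1) to compute.
    s_min
        Minimum support size for a pair to receive an interaction score.
        Must be >= 4; pairs below it keep their C (if computable) but have
        NaN in I.
    mask
        Dropout mask overriding the one derived from the matrix.
    engine
        ``"blocked"`` (matrix products over the whole state, default) or
        ``"pairwise"`` (straight per-pair loop; reference path for tests).
    """
    if s_min < 4:
        raise ValidationError(f"s_min must be >= 4 (got {s_min})")
    values, mask, gene_ids, cell_ids = _resolve_inputs(matrix, mask)
    if state not in (0, 1):
        raise ValidationError("state must be 0 or 1")
    if isinstance(matrix, ZScoredMatrix):
        # cells_of_state needs an ExpressionMatrix-shaped object only for ids
        coded = states.labels.loc[cell_ids].to_numpy()
        cols = np.flatnonzero(coded == state)
    else:
        cols = states.cells_of_state(matrix, state)
    X = values[:, cols]
    M = (~mask[:, cols]).astype(float)
    G = X.shape[0]

    if engine == "blocked":
        C, S = _masked_corr_blocked(X, M)
    elif engine == "pairwise":
        C, S = _masked_corr_pairwise(X, M)
    else:
        raise ValidationError(f"unknown engine {engine!r}")

    np.fill_diagonal(C, np.nan)
    np.fill_diagonal(S, 0)

    I = np.full((G, G), np.nan)
    ok = np.isfinite(C) & (S >= s_min)
    n_clamped = int(np.count_nonzero(np.abs(C[ok]) >= 1.0 - _CLAMP_TOL))
    if ok.any():
        I[ok] = fisher_interaction(C[ok], S[ok])
    return StateCorrelation(
        state=state,
        gene_ids=gene_ids,
        C=C,
        S=S.astype(np.int64),
        I=I,
        s_min=s_min,
        n_cells=len(cols),
        n_clamped=n_clamped,
    )


def _masked_corr_blocked(X: np.ndarray, M: np.ndarray):
    """All-pairs masked Pearson correlation via three matrix products.

    With A = X * M (dropouts zeroed) the per-pair sums over the joint support
    are plain inner products:  S = M M^T,  sum x_i = A M^T,  sum x_i x_j =
    A A^T,  sum x_i^2 = (A*A) M^T.  The correlation follows from the usual
    product-moment identity; entries with support < 2 or a (numerically)
    constant gene on the support are NaN.

    Genes are pre-centered (a per-gene shift leaves Pearson r unchanged) so
    the identity does not cancel catastrophically at raw-count scale.
    """
    X = X - X.mean(axis=1, keepdims=True)
    A = X * M
    S = M @ M.T
    Sx = A @ M.T            # Sx[i, j] = sum of x_i over support(i, j)
    Sxy = A @ A.T
    Sxx = (A * A) @ M.T
    cov = S * Sxy - Sx * Sx.T
    varx = S * Sxx - Sx**2  # var of gene i over support(i, j), times S^2
    vary = varx.T
    # relative guard: exact-constant supports cancel to ~0 but roundoff can
    # leave a tiny residue of either sign
    tol = 1e-13 * np.maximum(S * Sxx, 1.0)
    ok = (S >= 2) & (varx > tol) & (vary > tol.T)
    C = np.full(S.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        C[ok] = cov[ok] / np.sqrt(varx[ok] * vary[ok])
    np.clip(C, -1.0, 1.0, out=C)
    # two points with non-degenerate coordinates have r = +-1 exactly
    two = ok & (S == 2)
    C[two] = np.sign(cov[two])
    return C, S.astype(np.int64)


def _masked_corr_pairwise(X: np.ndarray, M: np.ndarray):
    """Per-pair loop over explicit support sets (reference path)."""
    X = X - X.mean(axis=1, keepdims=True)
    G = X.shape[0]
    C = np.full((G, G), np.nan)
    S = np.zeros((G, G), dtype=np.int64)
    Mb = M.astype(bool)
    for i in range(G):
        for j in range(i + 1, G):
            sup = Mb[i] & Mb[j]
            n = int(sup.sum())
            S[i, j] = S[j, i] = n
            if n < 2:
                continue
            x, y = X[i, sup], X[j, sup]
            sx, sy = x.sum(), y.sum()
            sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
            vx, vy = n * sxx - sx * sx, n * syy - sy * sy
            tol_x = 1e-13 * max(n * sxx, 1.0)
            tol_y = 1e-13 * max(n * syy, 1.0)
            if vx <= tol_x or vy <= tol_y:
                continue
            if n == 2:  # exactly +-1 for two non-degenerate points
                r = float(np.sign(n * sxy - sx * sy))
            else:
                r = (n * sxy - sx * sy) / np.sqrt(vx * vy)
            C[i, j] = C[j, i] = min(1.0, max(-1.0, r))
    return C, S
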