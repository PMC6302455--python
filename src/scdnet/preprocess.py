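"""Loading, validation and preprocessing of normalized expression matrices.

The pipeline operates on a genes x cells matrix of normalized, non-negative
read counts.  Exact zeros are dropouts: transcripts that failed to be
captured.  They are recorded in a boolean mask *before* any transformation
and downstream correlation is computed only over cells where both genes of a
pair are non-zero.

Preprocessing steps, in pipeline order:

1. :func:`read_matrix` — dense TSV/CSV or sparse MatrixMarket input.
2. :func:`median_of_ratios_normalize` — optional size-factor normalization
   (median-of-ratios; a light convenience, not a DESeq2 reimplementation).
3. :func:`filter_low_cv` — drop genes whose coefficient of variation is
   below a threshold in either cell state (non-informative genes).
4. :func:`z_transform` — per-gene standardization across all retained cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Raised when an input matrix, label file or configuration is invalid."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x cells matrix of normalized, non-negative read counts.

    Parameters
    ----------
    data
        DataFrame indexed by unique gene ids (rows) and unique cell ids
        (columns).  All values must be finite and >= 0.  Exact zeros are
        meaningful (dropouts) and are preserved as 0.0, never as NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(
                f"expression matrix must be at least 2x2, got {df.shape[0]}x{df.shape[1]}"
            )
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell ids: {dups[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric entries")
        if not np.isfinite(values).all():
            g, k = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {df.index[g]!r}, cell {df.columns[k]!r}"
            )
        if (values < 0).any():
            g, k = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at gene {df.index[g]!r}, cell {df.columns[k]!r}"
            )

    # -- convenience views ---------------------------------------------------

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    @property
    def dropout_mask(self) -> np.ndarray:
        """Boolean genes x cells array, True where the count is exactly zero."""
        return self.values == 0.0

    @property
    def sparsity(self) -> float:
        """Fraction of entries that are exact zeros."""
        return float(self.dropout_mask.mean())


@dataclass(frozen=True)
class StateAssignment:
    """Assignment of every cell to one of two cellular states (0 or 1).

    ``labels`` maps cell id -> state index; ``state_names`` maps the state
    index back to the user-facing label string.
    """

    labels: pd.Series
    state_names: dict = field(default_factory=lambda: {0: "state0", 1: "state1"})

    def __post_init__(self) -> None:
        vals = set(self.labels.unique().tolist())
        if not vals <= {0, 1}:
            raise ValidationError(f"state labels must be 0/1, got {sorted(vals)}")
        if vals != {0, 1}:
            raise ValidationError("both states must be non-empty")
        if self.labels.index.has_duplicates:
            dups = self.labels.index[self.labels.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell ids in labels: {dups[:5]}")

    @classmethod
    def from_series(
        cls,
        labels: pd.Series,
        state0: str | None = None,
        state1: str | None = None,
    ) -> "StateAssignment":
        """Build from a cell -> label-string series.

        Exactly two distinct label strings are required.  They are mapped to
        {0, 1} lexicographically unless ``state0``/``state1`` override it.
        """
        uniq = sorted(map(str, pd.unique(labels.astype(str))))
        if len(uniq) != 2:
            raise ValidationError(
                f"expected exactly two distinct state labels, got {uniq}"
            )
        if state0 is not None or state1 is not None:
            if state0 is None or state1 is None:
                raise ValidationError("state0 and state1 must be given together")
            if sorted([state0, state1]) != uniq:
                raise ValidationError(
                    f"state overrides {state0!r}/{state1!r} do not match labels {uniq}"
                )
            names = {0: state0, 1: state1}
        else:
            names = {0: uniq[0], 1: uniq[1]}
        inverse = {names[0]: 0, names[1]: 1}
        coded = labels.astype(str).map(inverse).astype(np.int8)
        return cls(labels=coded, state_names=names)

    @classmethod
    def from_tsv(
        cls, path: str | Path, state0: str | None = None, state1: str | None = None
    ) -> "StateAssignment":
        """Read a two-column ``cell_id<TAB>state_label`` file (no header)."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] != 2:
            raise ValidationError(
                f"label file {path} must have two columns, got {df.shape[1]}"
            )
        series = pd.Series(df[1].values, index=pd.Index(df[0], name="cell_id"))
        return cls.from_series(series, state0=state0, state1=state1)

    def check_compatible(self, E: ExpressionMatrix) -> None:
        """Every cell of ``E`` must carry exactly one label."""
        missing = E.cell_ids.difference(self.labels.index)
        if len(missing):
            raise ValidationError(f"no state label for cell(s): {missing.tolist()[:5]}")
        for n in (0, 1):
            if not (self.labels.loc[E.cell_ids] == n).any():
                raise ValidationError(
                    f"state {self.state_names[n]!r} has no cells in the matrix"
                )

    def cells_of_state(self, E: ExpressionMatrix, state: int) -> np.ndarray:
        """Column indices (in matrix order) of the cells in ``state``."""
        coded = self.labels.loc[E.cell_ids].to_numpy()
        return np.flatnonzero(coded == state)

    def swapped(self) -> "StateAssignment":
        """Return the assignment with states 0 and 1 exchanged."""
        return StateAssignment(
            labels=(1 - self.labels).astype(np.int8),
            state_names={0: self.state_names[1], 1: self.state_names[0]},
        )


@dataclass(frozen=True)
class ZScoredMatrix:
    """Per-gene standardized expression with the dropout mask of the source.

    Each row of ``values`` has mean 0 and standard deviation 1 across all
    retained cells.  ``dropout_mask`` marks entries that were exactly zero in
    the *normalized counts*; those entries are never treated as signal even
    though they now carry a (negative) z-score.
    """

    values: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    dropout_mask: np.ndarray
    ddof: int = 1

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SEPARATORS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix == "csv":
        return "csv"
    if suffix == "mtx":
        return "mtx"
    raise ValidationError(f"cannot infer matrix format from {path.name!r}")


def read_matrix(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Dense ``tsv``/``csv``: first column gene ids, header row of cell ids.
    Sparse ``mtx``: MatrixMarket coordinate file with companion one-id-per-line
    ``genes.txt`` and ``cells.txt`` in the same directory.  Entries omitted
    from the triplet file read as exact zeros (dropouts).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        genes_file = path.parent / "genes.txt"
        cells_file = path.parent / "cells.txt"
        for companion in (genes_file, cells_file):
            if not companion.exists():
                raise FileNotFoundError(
                    f"MTX input requires companion file {companion}"
                )
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = genes_file.read_text().split()
        cells = cells_file.read_text().split()
        if mat.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match id files "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
        return ExpressionMatrix(df)
    if fmt not in _SEPARATORS:
        raise ValidationError(f"unknown matrix format {fmt!r}")
    try:
        df = pd.read_csv(
            path, sep=_SEPARATORS[fmt], index_col=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:  # message carries the line number
        raise ValidationError(f"malformed {fmt.upper()} file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no cell columns parsed")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        g, k = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {df.iat[g, k]!r} at gene "
            f"{df.index[g]!r}, cell {df.columns[k]!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(coerced.astype(float))


def write_matrix(E: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write an expression matrix; inverse of :func:`read_matrix`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(E.values))
        (path.parent / "genes.txt").write_text("\n".join(E.gene_ids) + "\n")
        (path.parent / "cells.txt").write_text("\n".join(E.cell_ids) + "\n")
        return
    if fmt not in _SEPARATORS:
        raise ValidationError(f"unknown matrix format {fmt!r}")
    E.data.to_csv(path, sep=_SEPARATORS[fmt])


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------


def median_of_ratios_normalize(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios size-factor normalization of raw counts.

    For every gene with all-positive counts, compute count / geometric mean of
    that gene; each cell's size factor is the median of those ratios and the
    cell's column is divided by it.  This is the classical size-factor recipe
    and intentionally nothing more (no dispersion modelling).
    """
    counts = raw.values
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "no gene has all-positive counts; size factors are undefined — "
            "provide pre-normalized input instead"
        )
    ref = counts[all_positive]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_geomean)
    size_factors = np.median(ratios, axis=0)
    if (size_factors <= 0).any():
        raise ValidationError("non-positive size factor encountered")
    return ExpressionMatrix(
        pd.DataFrame(
            counts / size_factors, index=raw.gene_ids, columns=raw.cell_ids
        )
    )


def per_state_cv(
    E: ExpressionMatrix, states: StateAssignment, ddof: int = 1
) -> pd.DataFrame:
    """Coefficient of variation (std/mean) of every gene within each state.

    Computed on the normalized counts with zeros included.  Genes with zero
    mean in a state get CV = NaN.
    """
    states.check_compatible(E)
    out = {}
    for n in (0, 1):
        idx = states.cells_of_state(E, n)
        sub = E.values[:, idx]
        mean = sub.mean(axis=1)
        std = sub.std(axis=1, ddof=ddof)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, std / mean, np.nan)
        out[n] = cv
    return pd.DataFrame(out, index=E.gene_ids)


def filter_low_cv(
    E: ExpressionMatrix,
    states: StateAssignment,
    cv_threshold: float = 0.25,
    ddof: int = 1,
) -> ExpressionMatrix:
    """Remove non-informative genes by per-state coefficient of variation.

    A gene is retained only if its CV is >= ``cv_threshold`` in *both* states;
    a gene falling below the threshold in either state, or with zero mean in a
    state, is removed.  Gene order is preserved.
    """
    if cv_threshold < 0:
        raise ValidationError("cv_threshold must be >= 0")
    cv = per_state_cv(E, states, ddof=ddof)
    keep = (cv.notna() & (cv >= cv_threshold)).all(axis=1)
    if int(keep.sum()) < 2:
        raise ValidationError(
            f"too few informative genes: {int(keep.sum())} of {E.n_genes} pass "
            f"CV >= {cv_threshold} in both states"
        )
    return ExpressionMatrix(E.data.loc[keep.to_numpy()])


def z_transform(E: ExpressionMatrix, ddof: int = 1) -> ZScoredMatrix:
    """Standardize each gene to mean 0 / std 1 across all retained cells.

    The dropout mask (entries that are exactly zero in the normalized counts)
    is captured here, before standardization, so downstream support sets are
    defined on the counts and never on z-scores.
    """
    values = E.values
    mu = values.mean(axis=1)
    sigma = values.std(axis=1, ddof=ddof)
    if (sigma <= 0).any():
        g = int(np.argmax(sigma <= 0))
        raise ValidationError(f"gene {E.gene_ids[g]!r} has zero variance")
    z = (values - mu[:, None]) / sigma[:, None]
    return ZScoredMatrix(
        values=pd.DataFrame(z, index=E.gene_ids, columns=E.cell_ids),
        mu=pd.Series(mu, index=E.gene_ids, name="mu"),
        sigma=pd.Series(sigma, index=E.gene_ids, name="sigma"),
        dropout_mask=E.dropout_mask,
        ddof=ddof,
    )
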