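"""Expression-matrix containers, readers/writers, normalization and reference filters.

The canonical in-memory orientation is **cells x genes** (``n`` cells, ``m``
genes), matching the convention that a gene's expression across cells is a
column vector.  On-disk MatrixMarket defaults to genes-in-rows (the 10x
convention); an orientation flag overrides this for every format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "MatrixFormatError",
    "FilterError",
    "read_matrix",
    "write_matrix",
    "library_size_normalize",
    "filter_reference",
]

Format = Literal["mtx", "dense", "hdf5"]
Orientation = Literal["genes-in-rows", "cells-in-rows"]


class MatrixFormatError(ValueError):
    """A file does not parse as the declared expression-matrix format."""


class FilterError(ValueError):
    """A reference filter removed every cell or every gene."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative expression values for ``n_cells`` x ``n_genes``.

    ``values`` is always a dense float64 array in cells x genes orientation.
    Labels are stored as tuples so instances are hashable and immutable.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if np.any(values < 0):
            raise ValueError("expression values must be nonnegative")
        gene_ids = tuple(str(g) for g in self.gene_ids)
        cell_ids = tuple(str(c) for c in self.cell_ids)
        if len(gene_ids) != values.shape[1]:
            raise ValueError(
                f"{len(gene_ids)} gene labels for {values.shape[1]} gene columns"
            )
        if len(cell_ids) != values.shape[0]:
            raise ValueError(
                f"{len(cell_ids)} cell labels for {values.shape[0]} cell rows"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene labels must be unique")
        if len(set(cell_ids)) != len(cell_ids):
            raise ValueError("cell labels must be unique")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "cell_ids", cell_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def is_count(self) -> bool:
        """True iff every value is a nonnegative integer."""
        return bool(np.all(self.values == np.round(self.values)))

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same labels, new values (must keep the shape)."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the shape")
        return ExpressionMatrix(values, self.gene_ids, self.cell_ids)

    def cell_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def gene_means(self) -> np.ndarray:
        return self.values.mean(axis=0)


def _companion_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_genes.txt"), Path(f"{stem}_cells.txt")


def _read_labels(path: Path) -> list[str]:
    if not path.exists():
        raise MatrixFormatError(f"companion label file missing: {path}")
    return [line.rstrip("\n") for line in path.read_text().splitlines() if line.strip()]


def _dense_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    format: Format = "mtx",
    orientation: Orientation = "genes-in-rows",
) -> ExpressionMatrix:
    """Read an expression matrix, returning it in cells x genes orientation.

    ``mtx``: MatrixMarket coordinate file with companion one-label-per-line
    ``<stem>_genes.txt`` and ``<stem>_cells.txt`` files.  ``dense``: delimited
    text with a header row of column labels and a first column of row labels
    (tab-separated unless the suffix is ``.csv``).  ``hdf5``: datasets
    ``values``, ``gene_ids``, ``cell_ids``.

    ``orientation`` states which axis the *rows on disk* represent.
    MatrixMarket 1-based indices are converted to 0-based internally by scipy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        try:
            mat = spio.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad triplets
            raise MatrixFormatError(f"malformed MatrixMarket file {path}: {exc}") from exc
        values = np.asarray(
            mat.toarray() if sparse.issparse(mat) else mat, dtype=np.float64
        )
        genes_path, cells_path = _companion_paths(path)
        gene_ids = _read_labels(genes_path)
        cell_ids = _read_labels(cells_path)
        row_ids, col_ids = (
            (gene_ids, cell_ids) if orientation == "genes-in-rows" else (cell_ids, gene_ids)
        )
        if values.shape != (len(row_ids), len(col_ids)):
            raise MatrixFormatError(
                f"{path}: matrix is {values.shape} but labels imply "
                f"({len(row_ids)}, {len(col_ids)}) under orientation={orientation!r}"
            )
    elif format == "dense":
        try:
            df = pd.read_csv(path, sep=_dense_sep(path), index_col=0)
        except Exception as exc:
            raise MatrixFormatError(f"malformed delimited file {path}: {exc}") from exc
        values = df.to_numpy(dtype=np.float64)
        if orientation == "genes-in-rows":
            gene_ids, cell_ids = list(df.index), list(df.columns)
        else:
            cell_ids, gene_ids = list(df.index), list(df.columns)
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            values = np.asarray(f["values"], dtype=np.float64)
            gene_ids = [g.decode() if isinstance(g, bytes) else str(g) for g in f["gene_ids"][()]]
            cell_ids = [c.decode() if isinstance(c, bytes) else str(c) for c in f["cell_ids"][()]]
    else:
        raise ValueError(f"unknown format {format!r}")

    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise MatrixFormatError(
            f"{path}: negative value at on-disk position {tuple(bad)}"
        )
    if orientation == "genes-in-rows":
        values = values.T
    return ExpressionMatrix(values, tuple(gene_ids), tuple(cell_ids))


def write_matrix(
    X: ExpressionMatrix,
    path: str | Path,
    format: Format = "mtx",
    orientation: Orientation = "genes-in-rows",
) -> Path:
    """Write ``X`` so that ``read_matrix`` round-trips values and labels.

    MatrixMarket output stores only nonzero entries (integer field when the
    matrix is count-valued) plus the two companion label files.
    """
    path = Path(path)
    values = X.values.T if orientation == "genes-in-rows" else X.values
    if format == "mtx":
        out = values.astype(np.int64) if X.is_count else values
        spio.mmwrite(path, sparse.coo_matrix(out))
        genes_path, cells_path = _companion_paths(path)
        genes_path.write_text("".join(f"{g}\n" for g in X.gene_ids))
        cells_path.write_text("".join(f"{c}\n" for c in X.cell_ids))
    elif format == "dense":
        if orientation == "genes-in-rows":
            df = pd.DataFrame(values, index=list(X.gene_ids), columns=list(X.cell_ids))
        else:
            df = pd.DataFrame(values, index=list(X.cell_ids), columns=list(X.gene_ids))
        df.to_csv(path, sep=_dense_sep(path))
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=values)
            f.create_dataset("gene_ids", data=np.array(X.gene_ids, dtype="S"))
            f.create_dataset("cell_ids", data=np.array(X.cell_ids, dtype="S"))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def library_size_normalize(
    X: ExpressionMatrix, target: float | Literal["median"] = "median"
) -> ExpressionMatrix:
    """Scale each cell so its total equals ``target``.

    ``target="median"`` uses the median of the observed cell totals, a
    scale-free and outlier-robust choice.  Cells with zero total are an error:
    they must be filtered out first rather than silently dropped.
    """
    totals = X.cell_totals()
    if np.any(totals <= 0):
        zero = [X.cell_ids[i] for i in np.flatnonzero(totals <= 0)[:5]]
        raise ValueError(
            f"{int(np.sum(totals <= 0))} cell(s) have zero total counts "
            f"(e.g. {zero}); remove them with filter_reference before normalizing"
        )
    t = float(np.median(totals)) if target == "median" else float(target)
    if t <= 0:
        raise ValueError("normalization target must be positive")
    return X.with_values(X.values * (t / totals)[:, None])


def filter_reference(
    X: ExpressionMatrix, min_cell_total: float, min_gene_frac: float
) -> ExpressionMatrix:
    """Keep high-depth cells, then widely detected genes.

    Cells with total count strictly greater than ``min_cell_total`` are kept
    first; then genes with a nonzero fraction strictly greater than
    ``min_gene_frac``, computed on the retained cells.  This is the standard
    recipe for building a high-quality reference subset before down-sampling
    experiments.  Idempotent for fixed thresholds.
    """
    if not 0 <= min_gene_frac <= 1:
        raise ValueError("min_gene_frac must lie in [0, 1]")
    keep_cells = X.cell_totals() > min_cell_total
    n_cells_kept = int(keep_cells.sum())
    if n_cells_kept == 0:
        raise FilterError(
            f"cell filter (total > {min_cell_total}) removed all {X.n_cells} cells"
        )
    sub = X.values[keep_cells]
    nz_frac = (sub > 0).mean(axis=0)
    keep_genes = nz_frac > min_gene_frac
    if not keep_genes.any():
        raise FilterError(
            f"gene filter (nonzero fraction > {min_gene_frac}) removed all "
            f"{X.n_genes} genes after keeping {n_cells_kept}/{X.n_cells} cells"
        )
    return ExpressionMatrix(
        sub[:, keep_genes],
        tuple(g for g, k in zip(X.gene_ids, keep_genes) if k),
        tuple(c for c, k in zip(X.cell_ids, keep_cells) if k),
    )
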