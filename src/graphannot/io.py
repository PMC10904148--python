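"""Data containers and file I/O.

Expression matrices are cells x genes throughout the package.  Delimited text
(TSV/CSV, auto-detected by extension) and Matrix Market sparse files with
row/column name sidecars are supported.  Label tables are delimited text with
``cell_id`` and ``type`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ParameterError, ParseError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "LabelTable",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "select_variable_genes",
]

UNLABELED = -1


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with unique cell and gene identifiers."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 2 or n < 1:
            raise ValidationError(
                f"need at least 2 cells and 1 gene, got {m} cells x {n} genes"
            )
        if len(self.cell_ids) != m:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {m} rows"
            )
        if len(self.gene_ids) != n:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n} columns"
            )
        if len(set(self.cell_ids)) != m:
            raise ValidationError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != n:
            raise ValidationError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at cell row {bad[0]}, gene column {bad[1]}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelTable:
    """Cell-type assignments aligned to an expression matrix's cell order.

    ``codes[i]`` is the index into ``type_names`` for cell ``i``, or ``-1``
    when the cell is unannotated.
    """

    cell_ids: np.ndarray
    type_names: list[str]
    codes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=int)
        if len(self.codes) != len(self.cell_ids):
            raise ValidationError("codes and cell_ids differ in length")
        if np.any(self.codes >= len(self.type_names)) or np.any(self.codes < UNLABELED):
            raise ValidationError("label code out of range")
        if len(set(self.type_names)) != len(self.type_names):
            raise ValidationError("duplicate type names")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.codes != UNLABELED

    @property
    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labeled_mask)

    @property
    def unlabeled_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.labeled_mask)

    def onehot(self, subset: np.ndarray | None = None) -> np.ndarray:
        """One-hot indication matrix for ``subset`` (default: labeled cells)."""
        if subset is None:
            subset = self.labeled_indices
        codes = self.codes[subset]
        if np.any(codes == UNLABELED):
            raise ValidationError("one-hot coding requested for unlabeled cells")
        out = np.zeros((len(subset), self.n_types))
        out[np.arange(len(subset)), codes] = 1.0
        return out

    def subset_labels(self, indices: np.ndarray) -> "LabelTable":
        """A copy where only ``indices`` keep their labels (the rest unlabeled)."""
        codes = np.full(self.n_cells, UNLABELED, dtype=int)
        codes[indices] = self.codes[indices]
        return LabelTable(self.cell_ids, list(self.type_names), codes)


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    format: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from delimited text or Matrix Market format.

    Delimited files carry gene ids in the header row and cell ids in the first
    column.  Matrix Market files require ``<path>.rows`` / ``<path>.cols``
    sidecars with one identifier per line.  ``transpose`` accepts files stored
    genes x cells.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    if format is None:
        format = "mtx" if path.suffix.lower() == ".mtx" else "delimited"
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy error text varies
            raise ParseError(f"could not parse Matrix Market file {path}: {exc}") from exc
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        rows = _read_names(Path(str(path) + ".rows"))
        cols = _read_names(Path(str(path) + ".cols"))
        if transpose:
            values, rows, cols = values.T, cols, rows
        if len(rows) != values.shape[0]:
            raise ValidationError(
                f"row sidecar lists {len(rows)} names for {values.shape[0]} rows"
            )
        if len(cols) != values.shape[1]:
            raise ValidationError(
                f"column sidecar lists {len(cols)} names for {values.shape[1]} columns"
            )
        return ExpressionMatrix(values, rows, cols)
    if format != "delimited":
        raise ParameterError(f"unknown expression format: {format!r}")
    sep = _delimiter_for(path)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy() & frame[col].notna().to_numpy())
        if frame[col].isna().any():
            row = int(np.flatnonzero(frame[col].isna().to_numpy())[0])
            raise ParseError(
                f"{path}: missing value at data row {row + 1}, column {col!r}"
            )
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric entry {frame[col].iloc[bad[0]]!r} "
                f"at data row {bad[0] + 1}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    cell_ids = frame.index.astype(str).to_numpy()
    gene_ids = frame.columns.astype(str).to_numpy()
    if transpose:
        values, cell_ids, gene_ids = values.T, gene_ids, cell_ids
    return ExpressionMatrix(values, cell_ids, gene_ids)


def _read_names(path: Path) -> np.ndarray:
    if not path.exists():
        raise ParseError(f"missing name sidecar: {path}")
    names = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return np.asarray(names, dtype=object)


def write_expression(X: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix.lower() == ".mtx" else "delimited"
    if format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(X.values))
        Path(str(path) + ".rows").write_text("\n".join(map(str, X.cell_ids)) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(map(str, X.gene_ids)) + "\n")
        return
    frame = pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids)
    frame.to_csv(path, sep=_delimiter_for(path))


def read_labels(path: str | Path, cell_ids: np.ndarray) -> LabelTable:
    """Read a label table and align it to ``cell_ids``; absent cells are unlabeled."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=_delimiter_for(path))
    except Exception as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if "cell_id" not in frame.columns or "type" not in frame.columns:
        raise ParseError(f"{path}: label table needs 'cell_id' and 'type' columns")
    if frame["cell_id"].duplicated().any():
        dup = frame.loc[frame["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"duplicate label entry for cell {dup!r}")
    known = set(map(str, cell_ids))
    unknown = [c for c in frame["cell_id"].astype(str) if c not in known]
    if unknown:
        raise ValidationError(f"label table names unknown cell {unknown[0]!r}")
    type_names = sorted(frame["type"].astype(str).unique())
    lookup = {t: i for i, t in enumerate(type_names)}
    by_cell = dict(zip(frame["cell_id"].astype(str), frame["type"].astype(str)))
    codes = np.array(
        [lookup[by_cell[str(c)]] if str(c) in by_cell else UNLABELED for c in cell_ids]
    )
    return LabelTable(np.asarray(cell_ids, dtype=object), type_names, codes)


def write_labels(labels: LabelTable, path: str | Path, provenance: np.ndarray | None = None) -> None:
    path = Path(path)
    mask = labels.labeled_mask
    data = {
        "cell_id": labels.cell_ids[mask],
        "type": [labels.type_names[c] for c in labels.codes[mask]],
    }
    if provenance is not None:
        data["provenance"] = np.asarray(provenance, dtype=object)[mask]
    pd.DataFrame(data).to_csv(path, sep=_delimiter_for(path), index=False)


def select_variable_genes(X: ExpressionMatrix, top_n: int) -> ExpressionMatrix:
    """Keep the ``top_n`` genes with the highest variance across cells.

    Ties are broken toward the lower gene index; the retained genes keep their
    original order.
    """
    if top_n < 1 or top_n > X.n_genes:
        raise ParameterError(
            f"top_n must be in [1, {X.n_genes}], got {top_n}"
        )
    variances = X.values.var(axis=0)
    order = np.argsort(-variances, kind="stable")[:top_n]
    keep = np.sort(order)
    return ExpressionMatrix(X.values[:, keep], X.cell_ids, X.gene_ids[keep])
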