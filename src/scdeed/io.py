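"""Matrix, label and result I/O.

All inputs and outputs are plain text: delimited matrices (comma default,
tab auto-detected), Matrix Market triplets with companion feature/barcode
files, and CSV result tables. Parsing is delegated to pandas and scipy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .config import ValidationError


class MatrixFormatError(ValueError):
    """Raised when an input file cannot be parsed as a matrix."""


@dataclass
class GeneCellMatrix:
    """A genes x cells expression matrix with row and column identifiers.

    Values are taken as supplied (typically normalized, log-transformed
    expression); no normalization is performed downstream.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2D genes x cells matrix")
        g, n = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene{i + 1}" for i in range(g)]
        if not self.cell_ids:
            self.cell_ids = [f"cell{j + 1}" for j in range(n)]
        self.gene_ids = [str(s) for s in self.gene_ids]
        self.cell_ids = [str(s) for s in self.cell_ids]
        if g < 1 or n < 4:
            raise ValidationError(
                f"matrix must have >= 1 gene and >= 4 cells, got {g} x {n}"
            )
        if len(self.gene_ids) != g or len(self.cell_ids) != n:
            raise ValidationError("id lengths do not match matrix shape")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains missing or non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = _sniff_sep(path)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    if frame.empty:
        raise MatrixFormatError(f"{path} contains no data rows")
    if not all(np.issubdtype(dt, np.number) for dt in frame.dtypes):
        bad = [c for c, dt in frame.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise MatrixFormatError(f"non-numeric columns in {path}: {bad[:5]}")
    return frame


def _read_mtx(path: Path) -> pd.DataFrame:
    """Matrix Market triplet read as genes x cells with companion id files.

    Companion files are looked up next to the .mtx file: ``features.tsv`` or
    ``genes.tsv`` for rows and ``barcodes.tsv`` for columns (first column of
    each is used as the identifier).
    """
    try:
        mat = mmread(path)
    except Exception as exc:
        raise MatrixFormatError(f"cannot parse Matrix Market file {path}: {exc}") from exc
    values = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
    folder = path.parent
    feat = folder / "features.tsv"
    if not feat.exists():
        feat = folder / "genes.tsv"
    barc = folder / "barcodes.tsv"
    for companion in (feat, barc):
        if not companion.exists():
            raise MatrixFormatError(f"missing companion id file {companion}")
    gene_ids = pd.read_csv(feat, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    cell_ids = pd.read_csv(barc, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if len(gene_ids) != values.shape[0] or len(cell_ids) != values.shape[1]:
        raise MatrixFormatError(
            f"id files do not match matrix shape {values.shape} "
            f"({len(gene_ids)} features, {len(cell_ids)} barcodes)"
        )
    return pd.DataFrame(values, index=gene_ids, columns=cell_ids)


def read_matrix(path: str | Path, layout: str = "genes_by_cells") -> GeneCellMatrix:
    """Read an expression matrix, returning it in genes x cells orientation.

    Parameters
    ----------
    path
        Delimited text file (first column holds row ids, header holds column
        ids) or a Matrix Market ``.mtx`` file with companion
        ``features.tsv``/``genes.tsv`` and ``barcodes.tsv`` files.
    layout
        On-disk orientation: ``"genes_by_cells"`` (default) or
        ``"cells_by_genes"`` (the matrix is transposed on read). Matrix
        Market input always follows the genes x cells convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in ("genes_by_cells", "cells_by_genes"):
        raise ValidationError(f"unknown layout {layout!r}")
    if path.suffix == ".mtx":
        frame = _read_mtx(path)
    else:
        frame = _read_delimited(path)
        if layout == "cells_by_genes":
            frame = frame.T
    return GeneCellMatrix(
        values=frame.to_numpy(dtype=float),
        gene_ids=[str(s) for s in frame.index],
        cell_ids=[str(s) for s in frame.columns],
    )


def write_matrix(matrix: GeneCellMatrix, path: str | Path) -> None:
    """Write a matrix as genes x cells CSV (gene ids in the first column)."""
    frame = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.cell_ids)
    frame.to_csv(path)


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column ``cell_id,label`` CSV into a Series indexed by cell."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise MatrixFormatError(f"{path} must have cell_id and label columns")
    series = pd.Series(
        frame.iloc[:, 1].astype(str).to_numpy(), index=frame.iloc[:, 0].astype(str)
    )
    if series.index.has_duplicates:
        raise ValidationError(f"duplicate cell ids in {path}")
    return series


def write_results(result, path: str | Path) -> None:
    """Write a per-cell score table or a hyperparameter grid table as CSV.

    Per-cell tables have columns ``cell_id, reliability_score, label``; cells
    with an undefined score get an empty score field and the label
    ``undefined``. Grid tables have one row per evaluated setting.
    """
    from .optimizer import OptimizationResult
    from .reliability import ReliabilityResult

    path = Path(path)
    if isinstance(result, ReliabilityResult):
        result.to_frame().to_csv(path, index=False)
    elif isinstance(result, OptimizationResult):
        result.to_frame().to_csv(path, index=False)
    else:
        raise TypeError(f"cannot write object of type {type(result).__name__}")


def read_pre_embedding(path: str | Path):
    """Read a cells x dims coordinate CSV (header row, cell ids in column 1)."""
    from .preembedding import PreEmbedding

    frame = _read_delimited(Path(path))
    return PreEmbedding(
        coords=frame.to_numpy(dtype=float),
        cell_ids=[str(s) for s in frame.index],
        source="user_supplied",
    )


def write_chosen_setting(result, path: str | Path) -> None:
    """Write the optimizer's chosen setting(s) as JSON."""
    payload = {
        "best_setting": result.best_setting.to_dict(),
        "n_dubious": int(result.min_dubious),
        "all_minimizers": [s.to_dict() for s in result.all_minimizers],
        "kneedle_setting": (
            result.kneedle_setting.to_dict() if result.kneedle_setting else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
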