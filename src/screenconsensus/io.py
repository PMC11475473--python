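"""Reading, validation and alignment of gene x cell-line screen matrices.

Dependency screens (CRISPR knockout, shRNA knockdown) and expression
profiles are all distributed as delimited text matrices with gene
identifiers on one axis and cell-line identifiers on the other.  This
module provides a thin validated container (:class:`ScreenMatrix`), a
tolerant reader for both orientations, and alignment of several matrices
onto a shared, lexicographically sorted gene / cell-line index.

Identifier matching is exact after stripping surrounding whitespace and
uppercasing; no gene-symbol alias resolution is attempted.  Missing
values are kept as NaN and handled per-operation downstream -- silent
imputation would bias the percentile labeling.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

KINDS = ("essentiality", "expression")

#: cell values treated as missing when parsing delimited text
_MISSING_TOKENS = {"", "na", "nan", "null"}


class MatrixParseError(ValueError):
    """Raised when a delimited matrix file cannot be parsed."""


def _canonical_index(ids: Iterable, axis_name: str) -> pd.Index:
    idx = pd.Index([str(x).strip().upper() for x in ids], name=axis_name)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {axis_name} identifiers: {dups[:5]}")
    if (idx == "").any():
        raise ValueError(f"empty {axis_name} identifier")
    return idx


@dataclasses.dataclass
class ScreenMatrix:
    """A gene x cell-line matrix of essentiality scores or expression.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as index and cell-line
        identifiers as columns.  Values are floats; NaN means missing.
    kind
        ``"essentiality"`` (more negative = stronger growth defect on
        perturbation) or ``"expression"`` (log2 TPM, non-negative).
    platform
        Free-text tag, e.g. ``"CRISPR"`` or ``"shRNA"``.
    """

    data: pd.DataFrame
    kind: str
    platform: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        df = self.data
        genes = _canonical_index(df.index, "gene")
        cells = _canonical_index(df.columns, "cell_line")
        df = pd.DataFrame(df.to_numpy(dtype=float), index=genes, columns=cells)
        if self.kind == "expression":
            vals = df.to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("expression values must be non-negative")
        self.data = df

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def cellline_ids(self) -> np.ndarray:
        return self.data.columns.to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select(self, genes: Sequence[str], cells: Sequence[str]) -> "ScreenMatrix":
        """Restrict and reorder to the given gene / cell-line identifiers."""
        return ScreenMatrix(self.data.loc[list(genes), list(cells)],
                            kind=self.kind, platform=self.platform)


@dataclasses.dataclass
class AlignedDataset:
    """Two platform score matrices plus expression on identical axes."""

    crispr: ScreenMatrix
    shrna: ScreenMatrix
    expression: ScreenMatrix

    def __post_init__(self) -> None:
        if self.crispr.kind != "essentiality" or self.shrna.kind != "essentiality":
            raise ValueError("crispr and shrna matrices must be kind='essentiality'")
        if self.expression.kind != "expression":
            raise ValueError("expression matrix must be kind='expression'")
        ref = self.crispr.data
        for other in (self.shrna.data, self.expression.data):
            if not ref.index.equals(other.index) or not ref.columns.equals(other.columns):
                raise ValueError("matrices of an AlignedDataset must share identical axes")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.crispr.gene_ids

    @property
    def cellline_ids(self) -> np.ndarray:
        return self.crispr.cellline_ids


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_matrix(path, kind: str, platform: str = "",
                transpose: bool = False) -> ScreenMatrix:
    """Read a delimited gene x cell-line matrix.

    The file must have one header row of cell-line identifiers and a
    first column of gene identifiers (or the transpose, selected by
    ``transpose``).  The delimiter is auto-detected between comma and
    tab from the header line.  Empty cells (and NA/NaN/null tokens)
    parse as missing; any other non-numeric cell is an error naming the
    offending row and column.
    """
    path = Path(path)
    sep = _detect_sep(path)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                          keep_default_na=False)
    except Exception as exc:  # malformed header / ragged rows
        raise MatrixParseError(f"{path}: cannot parse delimited matrix: {exc}") from exc
    if raw.columns.size == 0:
        raise MatrixParseError(f"{path}: header row defines no data columns")

    stripped = raw.apply(lambda col: col.str.strip())
    missing = stripped.apply(lambda col: col.str.lower().isin(_MISSING_TOKENS))
    numeric = stripped.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing.to_numpy()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"{path}: non-numeric value {stripped.iat[i, j]!r} at "
            f"row {raw.index[i]!r}, column {raw.columns[j]!r}")
    numeric = numeric.where(~missing)
    if transpose:
        numeric = numeric.T
    try:
        return ScreenMatrix(numeric, kind=kind, platform=platform)
    except ValueError as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc


def write_matrix(matrix: ScreenMatrix, path) -> None:
    """Write a :class:`ScreenMatrix` as CSV (missing -> empty field)."""
    matrix.data.to_csv(path, na_rep="")


def align_datasets(crispr: ScreenMatrix, shrna: ScreenMatrix,
                   expression: ScreenMatrix) -> AlignedDataset:
    """Restrict all three matrices to their common genes and cell lines.

    Both axes of the result are the set intersection of the inputs'
    axes, sorted lexicographically.  An empty intersection on either
    axis is an error.
    """
    genes = sorted(set(crispr.gene_ids) & set(shrna.gene_ids)
                   & set(expression.gene_ids))
    cells = sorted(set(crispr.cellline_ids) & set(shrna.cellline_ids)
                   & set(expression.cellline_ids))
    if not genes:
        raise ValueError("no genes shared by all three matrices")
    if not cells:
        raise ValueError("no cell lines shared by all three matrices")
    return AlignedDataset(crispr=crispr.select(genes, cells),
                          shrna=shrna.select(genes, cells),
                          expression=expression.select(genes, cells))
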