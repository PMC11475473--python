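"""Percentile tri-labeling and the gene-group bipartite graph.

Per cell line, genes are split into three classes by their essentiality
score rank: the ``floor(frac * m_valid)`` lowest-scoring genes are
essential (E), the same number of highest-scoring genes are
nonessential (NE), and the remaining scored genes are irrelevant (I).
Each cell line then contributes three group nodes -- (essential,
nonessential, irrelevant) -- and every scored gene links to exactly one
of them, giving an m x 3n bipartite adjacency.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ScreenMatrix

#: fixed class order used everywhere: columns of U/Q/Y, group offsets
CLASSES = ("E", "NE", "I")
_CODE = {"E": 0, "NE": 1, "I": 2}


@dataclasses.dataclass
class TriLabelMatrix:
    """Per-(gene, cell line) class labels in {E, NE, I}, NaN = missing."""

    data: pd.DataFrame  # object dtype: "E" / "NE" / "I" / NaN
    frac: float

    @property
    def gene_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def cellline_ids(self) -> np.ndarray:
        return self.data.columns.to_numpy()

    def codes(self) -> np.ndarray:
        """Labels as int8 codes (E=0, NE=1, I=2, missing=-1)."""
        out = np.full(self.data.shape, -1, dtype=np.int8)
        vals = self.data.to_numpy()
        for lab, code in _CODE.items():
            out[vals == lab] = code
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy long form: one row per labeled (gene, cell_line)."""
        long = self.data.stack().rename("label").reset_index()
        long.columns = ["gene", "cell_line", "label"]
        return long


@dataclasses.dataclass
class BipartiteGraph:
    """Gene-group bipartite graph with one-hot group labels.

    ``A`` is the m x v (v = 3n) 0/1 adjacency: gene i links to group
    3j + 0/1/2 when it is labeled E/NE/I in cell line j.  ``Y`` holds
    each group's one-hot class row in the order (E, NE, I) per cell
    line, so ``Y = tile(I_3, (n, 1))``.
    """

    A: sp.csr_matrix
    Y: np.ndarray
    gene_ids: np.ndarray
    cellline_ids: np.ndarray

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def v(self) -> int:
        return self.A.shape[1]

    @property
    def n(self) -> int:
        return len(self.cellline_ids)

    def link_counts(self) -> np.ndarray:
        """Number of labeled cell lines per gene (row sums of A)."""
        return np.asarray(self.A.sum(axis=1)).ravel()

    def group_sizes(self) -> np.ndarray:
        """Number of genes linked to each group (column sums of A)."""
        return np.asarray(self.A.sum(axis=0)).ravel()


def assign_labels(scores: ScreenMatrix, frac: float) -> TriLabelMatrix:
    """Tri-label every cell line of an essentiality matrix by score rank.

    Ties are broken by ascending gene identifier via a single stable
    ascending sort per cell line: the first ``k`` genes become E and the
    last ``k`` become NE (k = floor(frac * m_valid)), so at a fully tied
    boundary the lexicographically first genes fill the essential side
    and the last ones fill the nonessential side.

    Raises
    ------
    ValueError
        If ``frac`` is outside (0, 0.5) or any cell line has fewer than
        3 scored genes.
    """
    if not 0.0 < frac < 0.5:
        raise ValueError(f"frac must be in (0, 0.5), got {frac}")
    genes = scores.data.index.to_numpy()
    vals = scores.values
    m, n = vals.shape
    out = np.full((m, n), np.nan, dtype=object)
    for j, cell in enumerate(scores.cellline_ids):
        col = vals[:, j]
        valid = np.flatnonzero(~np.isnan(col))
        m_valid = valid.size
        if m_valid < 3:
            raise ValueError(
                f"cell line {cell!r} has only {m_valid} scored genes (< 3)")
        k = math.floor(frac * m_valid)
        # ascending by (score, gene id); lexsort's last key is primary
        order = valid[np.lexsort((genes[valid], col[valid]))]
        out[order, j] = "I"
        if k:
            out[order[:k], j] = "E"
            out[order[-k:], j] = "NE"
    df = pd.DataFrame(out, index=scores.data.index, columns=scores.data.columns)
    return TriLabelMatrix(data=df, frac=frac)


def build_bipartite(labels: TriLabelMatrix) -> BipartiteGraph:
    """Build the gene-group adjacency and one-hot group labels."""
    codes = labels.codes()
    m, n = codes.shape
    gi, cj = np.nonzero(codes >= 0)
    cols = 3 * cj + codes[gi, cj]
    A = sp.csr_matrix((np.ones(gi.size), (gi, cols)), shape=(m, 3 * n))
    Y = np.tile(np.eye(3), (n, 1))
    return BipartiteGraph(A=A, Y=Y, gene_ids=labels.gene_ids,
                          cellline_ids=labels.cellline_ids)
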