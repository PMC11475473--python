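"""Final per-cell-line essential / nonessential gene calls.

The consensus model yields one genome-wide ranking of common essential
(or nonessential) genes, but essentiality is cell-line specific.  The
final call set for a cell line is therefore the intersection of the
top x% most extreme experimentally scored genes in that cell line with
the top x% of the model-ranked common genes -- the experimental side
preserves cell-line specificity, the predicted side filters screening
false positives.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .consensus import ConsensusFit, rank_common
from .io import ScreenMatrix


@dataclasses.dataclass
class EssentialCallSet:
    """Per-cell-line called gene sets for one platform and class."""

    platform: str
    label_class: str  # "E" or "NE"
    x_frac: float
    calls: dict[str, frozenset[str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.platform, self.label_class, cl, g)
                for cl in self.calls for g in sorted(self.calls[cl])]
        return pd.DataFrame(rows, columns=["platform", "class", "cell_line", "gene"])


def call_final(scores: ScreenMatrix, fit_result: ConsensusFit,
               label_class: str, x_frac: float) -> EssentialCallSet:
    """Intersect experimental top-x% genes with predicted common genes.

    Per cell line, the experimental set holds the ``floor(x_frac *
    m_valid)`` lowest-scoring genes for class E (highest for NE, ties by
    ascending identifier, consistent with the tri-labeling rule); the
    predicted set is the top ``floor(x_frac * m)`` genes of the
    consensus ranking.  The call set is their intersection.
    """
    if label_class not in ("E", "NE"):
        raise ValueError("label_class must be 'E' or 'NE'")
    if not 0.0 < x_frac < 0.5:
        raise ValueError(f"x_frac must be in (0, 0.5), got {x_frac}")
    genes = scores.gene_ids
    if not np.array_equal(genes, np.asarray(fit_result.gene_ids)):
        raise ValueError("scores and fit must share the same gene index")
    m = genes.size
    predicted = frozenset(rank_common(fit_result, label_class,
                                      max(1, math.floor(x_frac * m))))
    vals = scores.values
    calls: dict[str, frozenset[str]] = {}
    for j, cell in enumerate(scores.cellline_ids):
        col = vals[:, j]
        valid = np.flatnonzero(~np.isnan(col))
        k = math.floor(x_frac * valid.size)
        order = valid[np.lexsort((genes[valid], col[valid]))]
        chosen = order[:k] if label_class == "E" else order[-k:] if k else order[:0]
        calls[cell] = frozenset(genes[chosen]) & predicted
    return EssentialCallSet(platform=scores.platform, label_class=label_class,
                            x_frac=x_frac, calls=calls)


def count_unique_and_overlap(calls: EssentialCallSet) -> tuple[int, int]:
    """(distinct genes across cell lines, total gene-cell-line pairs)."""
    sets = calls.calls.values()
    unique = len(set().union(*sets)) if calls.calls else 0
    with_overlap = sum(len(s) for s in sets)
    return unique, with_overlap
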