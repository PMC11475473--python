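"""Platform comparison statistics over expression strata.

Numeric summaries comparing how the knockout (CRISPR) and knockdown
(shRNA) platforms call essential genes across gene expression levels:
per-cell-line Pearson correlations, counts of calls within low/high
expression strata, the eight-way overlap classification of called
(gene, cell line) pairs, per-group expression summaries, kernel density
estimates of call expression, and per-gene essentiality profiles.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .calling import EssentialCallSet
from .io import ScreenMatrix
from .labeling import TriLabelMatrix

# Eight-way overlap groups for (CRISPR status, shRNA status); statuses
# are "E", "NE" or None (uncalled).  Pairs uncalled on both platforms
# belong to no group.
_GROUP8 = {
    ("E", "E"): 1,
    ("E", None): 2,
    (None, "E"): 3,
    ("E", "NE"): 4,
    ("NE", "E"): 5,
    ("NE", "NE"): 6,
    (None, "NE"): 7,
    ("NE", None): 8,
}


def per_cellline_correlation(
    x: ScreenMatrix, y: ScreenMatrix,
    subset: Mapping[str, frozenset[str]] | None = None,
) -> tuple[pd.Series, float]:
    """Pearson r between two matrices, per cell line, plus its mean.

    r is computed over pairwise-complete genes in each cell line
    (restricted to ``subset[cell_line]`` when given).  Cell lines with
    fewer than 3 paired values or zero variance on either side get NaN
    and are excluded from the unweighted mean.
    """
    if not x.data.index.equals(y.data.index) or \
            not x.data.columns.equals(y.data.columns):
        raise ValueError("matrices must share identical axes")
    genes = x.gene_ids
    out = {}
    for j, cell in enumerate(x.cellline_ids):
        a = x.values[:, j]
        b = y.values[:, j]
        mask = ~np.isnan(a) & ~np.isnan(b)
        if subset is not None:
            mask &= np.isin(genes, list(subset.get(cell, ())))
        a, b = a[mask], b[mask]
        if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            out[cell] = np.nan
            continue
        out[cell] = float(np.corrcoef(a, b)[0, 1])
    series = pd.Series(out, name="r")
    series.index.name = "cell_line"
    return series, float(series.mean())


def _stratum(expr_col: np.ndarray, genes: np.ndarray, p: float,
             side: str) -> frozenset[str]:
    valid = np.flatnonzero(~np.isnan(expr_col))
    k = int(np.floor(p * valid.size))
    order = valid[np.lexsort((genes[valid], expr_col[valid]))]
    chosen = order[:k] if side == "low" else order[-k:] if k else order[:0]
    return frozenset(genes[chosen])


def expression_strata_counts(
    calls_E: EssentialCallSet, calls_NE: EssentialCallSet,
    expression: ScreenMatrix, p: float, side: str,
) -> pd.DataFrame:
    """Count called genes inside each cell line's expression stratum.

    The stratum is the ``floor(p * m_valid)`` lowest- (``side="low"``)
    or highest- (``side="high"``) expressed genes of the cell line, ties
    by ascending identifier.  Returns tidy rows
    (cell_line, side, p, class, count).
    """
    if side not in ("low", "high"):
        raise ValueError("side must be 'low' or 'high'")
    if not 0.0 < p < 0.5:
        raise ValueError(f"p must be in (0, 0.5), got {p}")
    genes = expression.gene_ids
    rows = []
    for j, cell in enumerate(expression.cellline_ids):
        stratum = _stratum(expression.values[:, j], genes, p, side)
        for calls in (calls_E, calls_NE):
            count = len(calls.calls.get(cell, frozenset()) & stratum)
            rows.append((cell, side, p, calls.label_class, count))
    return pd.DataFrame(rows, columns=["cell_line", "side", "p", "class", "count"])


def group8_classify(crispr_E: EssentialCallSet, crispr_NE: EssentialCallSet,
                    shrna_E: EssentialCallSet, shrna_NE: EssentialCallSet,
                    ) -> pd.DataFrame:
    """Eight-way overlap classification of called (gene, cell line) pairs.

    Group semantics: 1 = essential on both platforms; 2/3 = essential on
    CRISPR/shRNA only; 4 = CRISPR-essential but shRNA-nonessential;
    5 = shRNA-essential but CRISPR-nonessential; 6 = nonessential on
    both; 7/8 = nonessential on shRNA/CRISPR only.  Pairs called by
    neither platform are omitted.  Returns tidy rows
    (gene, cell_line, group).
    """
    cells = set()
    for cs in (crispr_E, crispr_NE, shrna_E, shrna_NE):
        cells.update(cs.calls)
    rows = []
    for cell in sorted(cells):
        ce = crispr_E.calls.get(cell, frozenset())
        cn = crispr_NE.calls.get(cell, frozenset())
        se = shrna_E.calls.get(cell, frozenset())
        sn = shrna_NE.calls.get(cell, frozenset())
        if ce & cn or se & sn:
            raise ValueError(
                f"cell line {cell!r}: overlapping E and NE calls on one platform")
        for gene in sorted(ce | cn | se | sn):
            c_status = "E" if gene in ce else "NE" if gene in cn else None
            s_status = "E" if gene in se else "NE" if gene in sn else None
            rows.append((gene, cell, _GROUP8[(c_status, s_status)]))
    return pd.DataFrame(rows, columns=["gene", "cell_line", "group"])


def group_expression_summary(assignment: pd.DataFrame,
                             expression: ScreenMatrix) -> pd.DataFrame:
    """Five-number expression summary per overlap group.

    Quantiles are taken over the multiset of expression values of the
    (gene, cell line) member pairs of each group; empty groups yield
    NaN rows.
    """
    if assignment.empty:
        raise ValueError("assignment is empty")
    stats = ["min", "q1", "median", "q3", "max"]
    out = pd.DataFrame(np.nan, index=pd.Index(range(1, 9), name="group"),
                       columns=stats)
    expr = expression.data
    for group, members in assignment.groupby("group"):
        vals = np.array([expr.at[g, c]
                         for g, c in zip(members["gene"], members["cell_line"])])
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        out.loc[group] = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0])
    return out


@dataclasses.dataclass
class DensitySummary:
    """Gaussian KDE of a 1-D sample on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    peaks: np.ndarray  # grid locations of the density modes


def expression_density(values: Sequence[float], n_grid: int = 512,
                       min_prominence: float = 0.1) -> DensitySummary:
    """Gaussian kernel density estimate with Silverman's bandwidth.

    The bandwidth is ``0.9 * min(sd, IQR / 1.34) * n**(-1/5)`` and the
    grid spans ``[min - 3h, max + 3h]``.  Peaks are local maxima of the
    estimated density whose prominence is at least ``min_prominence``
    times the maximum density; at realistic sample sizes Silverman
    smoothing leaves small sampling wiggles on broad modes, and the
    prominence floor keeps mode counting robust to them (set it to 0 to
    recover every strict local maximum).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(v) == 0:
        raise ValueError(
            "all values identical: density is a point mass; report it directly")
    sd = float(v.std(ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * scale * v.size ** (-0.2)
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, n_grid)
    kde = gaussian_kde(v, bw_method=h / sd)
    density = kde(grid)
    idx, _ = find_peaks(density, prominence=min_prominence * density.max())
    return DensitySummary(grid=grid, density=density, bandwidth=h,
                          peaks=grid[idx])


def low_expression_report(calls: EssentialCallSet, expression: ScreenMatrix,
                          threshold: float = 1.8) -> tuple[int, int]:
    """Unique / with-overlap counts of calls expressed below threshold.

    A (gene, cell line) call pair is counted when its expression in that
    cell line is strictly below ``threshold`` (log2 TPM; default 1.8).
    """
    expr = expression.data
    kept_genes: set[str] = set()
    pairs = 0
    for cell, genes in calls.calls.items():
        for g in genes:
            val = expr.at[g, cell]
            if not np.isnan(val) and val < threshold:
                kept_genes.add(g)
                pairs += 1
    return len(kept_genes), pairs


def essentiality_profile(labels: TriLabelMatrix,
                         gene_order: Sequence[str]) -> pd.DataFrame:
    """Per-gene counts of cell lines labeled E and NE.

    Rows follow ``gene_order`` (typically the predicted top-k common
    genes) followed by all remaining genes in ascending identifier
    order.  Columns: gene, n_essential_lines, n_nonessential_lines.
    """
    codes = labels.codes()
    genes = labels.gene_ids
    n_e = (codes == 0).sum(axis=1)
    n_ne = (codes == 1).sum(axis=1)
    table = pd.DataFrame({"n_essential_lines": n_e,
                          "n_nonessential_lines": n_ne},
                         index=pd.Index(genes, name="gene"))
    ordered = list(gene_order)
    missing = [g for g in ordered if g not in table.index]
    if missing:
        raise ValueError(f"gene_order contains unknown genes: {missing[:5]}")
    rest = sorted(set(genes) - set(ordered))
    return table.loc[ordered + rest].reset_index()
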