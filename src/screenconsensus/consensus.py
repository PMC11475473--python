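"""Graph-based consensus model for common essential gene prediction.

The model estimates, for every gene, the probability of belonging to
each of the three classes (essential, nonessential, irrelevant) by
maximizing consensus over the gene-group bipartite graph.  With
``A`` the m x v adjacency, ``Y`` the v x 3 one-hot initial group
labels, ``U`` (m x 3) the gene class probabilities and ``Q`` (v x 3)
the group class probabilities, the objective is

    J(U, Q) = sum_z sum_i sum_k a_ik (u_iz - q_kz)^2
              + alpha * sum_z sum_k (q_kz - y_kz)^2

subject to each row of U and Q lying on the probability simplex.  The
first term pulls linked gene and group probabilities together; the
second keeps group probabilities close to their initial percentile
labels, with regularization weight ``alpha`` expressing confidence in
those labels.

Each block subproblem is an unconstrained strictly convex quadratic
whose minimizer happens to stay on the simplex (the update formulas
are convex averages of simplex rows), so alternating the two exact
closed-form updates

    q_kz = (sum_i a_ik u_iz + alpha y_kz) / (alpha + sum_i a_ik)
    u_iz = (sum_k a_ik q_kz) / (sum_k a_ik)

monotonically decreases J to its unique global minimum.  Genes with
partial cell-line coverage use their own link count in place of n in
the U update, which keeps U rows normalized.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .labeling import CLASSES, BipartiteGraph

_CLASS_COL = {c: i for i, c in enumerate(CLASSES)}


@dataclasses.dataclass
class ConsensusConfig:
    """Hyper-parameters of the consensus fit.

    alpha : float
        Regularization weight on group-label fidelity (default 1000, a
        strong prior on the initial percentile labels).
    epsilon : float
        Convergence tolerance on the Frobenius norm of successive U
        iterates (default 1e-4).
    max_iter : int
        Maximum number of full (Q then U) sweeps.
    """

    alpha: float = 1000.0
    epsilon: float = 1e-4
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclasses.dataclass
class ConsensusFit:
    """Result of a consensus fit.

    ``U`` rows are gene class probabilities in the order (E, NE, I);
    ``Q`` rows likewise for the 3n group nodes.  ``objective_trace``
    holds J at initialization and after every full sweep and is
    non-increasing.
    """

    U: np.ndarray
    Q: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    gene_ids: np.ndarray

    def u_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.U, index=pd.Index(self.gene_ids, name="gene"),
                            columns=[f"p_{c}" for c in CLASSES])

    def q_frame(self) -> pd.DataFrame:
        idx = pd.RangeIndex(self.Q.shape[0], name="group")
        return pd.DataFrame(self.Q, index=idx,
                            columns=[f"p_{c}" for c in CLASSES])


def _row_counts(graph: BipartiteGraph) -> np.ndarray:
    d = graph.link_counts()
    if (d == 0).any():
        bad = graph.gene_ids[d == 0][:5].tolist()
        raise ValueError(f"genes with no labeled cell line: {bad}")
    return d


def init_U(graph: BipartiteGraph) -> np.ndarray:
    """Label-frequency voting: one U update from Q = Y.

    ``u_iz`` is the fraction of the gene's labeled cell lines that
    assigned it class z.
    """
    d = _row_counts(graph)
    return (graph.A @ graph.Y) / d[:, None]


def update_Q(U: np.ndarray, graph: BipartiteGraph, alpha: float) -> np.ndarray:
    """Exact minimizer of J in Q for fixed U (rows stay on the simplex).

    A group with no linked genes keeps its initial one-hot label row.
    """
    sizes = graph.group_sizes()
    return (graph.A.T @ U + alpha * graph.Y) / (alpha + sizes)[:, None]


def update_U(Q: np.ndarray, graph: BipartiteGraph) -> np.ndarray:
    """Exact minimizer of J in U for fixed Q: mean of linked group rows."""
    d = _row_counts(graph)
    return (graph.A @ Q) / d[:, None]


def objective(U: np.ndarray, Q: np.ndarray, graph: BipartiteGraph,
              alpha: float) -> float:
    """Evaluate the consensus objective J(U, Q)."""
    d = graph.link_counts()
    sizes = graph.group_sizes()
    cross = float(np.sum((graph.A @ Q) * U))
    pair = float(d @ (U ** 2).sum(axis=1)) - 2.0 * cross \
        + float(sizes @ (Q ** 2).sum(axis=1))
    reg = alpha * float(((Q - graph.Y) ** 2).sum())
    return pair + reg


def fit(graph: BipartiteGraph, config: ConsensusConfig | None = None) -> ConsensusFit:
    """Alternate exact Q and U updates until U stabilizes.

    Starts from U = label-frequency voting and Q = Y; stops when
    ``||U_t - U_{t-1}||_F < epsilon`` or after ``max_iter`` sweeps.
    Non-convergence is reported via the ``converged`` flag, not raised.
    """
    if config is None:
        config = ConsensusConfig()
    U = init_U(graph)
    Q = graph.Y.copy()
    trace = [objective(U, Q, graph, config.alpha)]
    converged = False
    n_iter = 0
    for _ in range(config.max_iter):
        Q = update_Q(U, graph, config.alpha)
        U_new = update_U(Q, graph)
        n_iter += 1
        trace.append(objective(U_new, Q, graph, config.alpha))
        delta = float(np.linalg.norm(U_new - U))
        U = U_new
        if delta < config.epsilon:
            converged = True
            break
    return ConsensusFit(U=U, Q=Q, objective_trace=np.asarray(trace),
                        n_iter=n_iter, converged=converged,
                        gene_ids=graph.gene_ids)


def solve_exact(graph: BipartiteGraph, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Dense fixed-point solve of the consensus objective (test oracle).

    Eliminating U via its update gives, per class z,

        (diag(d + alpha) - A^T D^{-1} A) q_z = alpha y_z,

    with d the column sums of A and D = diag(row sums of A).  The
    objective is strictly jointly convex when every gene has at least
    one link and alpha > 0, so this is the unique global minimizer.
    Intended for small instances (v up to a few hundred).
    """
    d_row = _row_counts(graph)
    sizes = graph.group_sizes()
    A = graph.A.toarray()
    M = np.diag(sizes + alpha) - A.T @ (A / d_row[:, None])
    Q = np.linalg.solve(M, alpha * graph.Y)
    U = (A @ Q) / d_row[:, None]
    return U, Q


def rank_common(fit_result: ConsensusFit, label_class: str,
                k: int | float) -> list[str]:
    """Top genes by estimated probability of the given class.

    Genes are sorted by descending ``u_i,class`` with ties broken by
    ascending gene identifier.  ``k`` may be a positive integer count or
    a fraction in (0, 1), interpreted as ``floor(k * m)``.
    """
    if label_class not in ("E", "NE"):
        raise ValueError("label_class must be 'E' or 'NE'")
    genes = np.asarray(fit_result.gene_ids)
    m = genes.size
    if isinstance(k, float) and 0 < k < 1:
        k = math.floor(k * m)
    k = int(k)
    if not 0 < k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    p = fit_result.U[:, _CLASS_COL[label_class]]
    order = np.lexsort((genes, -p))
    return genes[order[:k]].tolist()
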