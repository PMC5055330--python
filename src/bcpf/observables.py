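"""Summary statistics and structural checks on states and runs.

The observable suite:

* ``D+`` / ``D-`` — mean opinion distance over positive / negative links
  (intra-clique diversity and inter-clique separation once balanced);
* ``F_unbal`` — fraction of unbalanced triads;
* ``N_op`` — number of distinct opinions, by single-linkage grouping at a
  tolerance;
* ``S_dif`` — absolute clique-size difference in percent of N;
* one-dimensional segregation (one clique's opinions all below the other's),
  exact linear separability of the two cliques' opinion sets for F >= 2, and
  the within-cluster collinearity (alignment) score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import (
    NotApplicableError,
    OpinionMatrix,
    SystemState,
    distance_matrix,
)


@dataclass(frozen=True)
class OpinionClustering:
    """Partition of agents into groups sharing one opinion (to tolerance)."""

    labels: np.ndarray
    clusters: list[np.ndarray]
    centroids: list[np.ndarray]

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _opinion_values(state_or_opinions) -> np.ndarray:
    if isinstance(state_or_opinions, SystemState):
        return state_or_opinions.opinions.values
    if isinstance(state_or_opinions, OpinionMatrix):
        return state_or_opinions.values
    return np.atleast_2d(np.asarray(state_or_opinions, dtype=float))


def diversity_measures(state: SystemState, metric: str = "chebyshev") -> tuple[float, float]:
    """(D+, D-): mean pairwise opinion distance over unordered positive and
    negative links.  A measure whose link class is empty is undefined and
    reported as NaN, not 0."""
    d = distance_matrix(state.opinions, metric)
    iu = np.triu_indices(state.n, k=1)
    signs = state.network.signs[iu]
    dists = d[iu]
    pos = signs == 1
    neg = signs == -1
    d_plus = float(dists[pos].mean()) if pos.any() else float("nan")
    d_minus = float(dists[neg].mean()) if neg.any() else float("nan")
    return d_plus, d_minus


def count_opinions(
    state_or_opinions, tol_cluster: float = 1e-6, metric: str = "chebyshev"
) -> tuple[int, OpinionClustering]:
    """N_op and the clustering behind it: single-linkage grouping of agents
    at opinion distance <= tol_cluster."""
    x = _opinion_values(state_or_opinions)
    d = distance_matrix(x, metric)
    adj = csr_matrix((d <= tol_cluster).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = [np.flatnonzero(labels == c) for c in range(n_comp)]
    # deterministic report order: by centroid, lexicographically over issues
    centroids = [x[c].mean(axis=0) for c in clusters]
    order = sorted(range(n_comp), key=lambda c: tuple(centroids[c]))
    clusters = [clusters[c] for c in order]
    centroids = [centroids[c] for c in order]
    relabel = np.empty(n_comp, dtype=int)
    relabel[order] = np.arange(n_comp)
    return n_comp, OpinionClustering(relabel[labels], clusters, centroids)


def clique_size_difference(partition: tuple[np.ndarray, np.ndarray]) -> float:
    """S_dif = |C1 - C2| / N * 100 (percent points); 100 when one clique is
    empty (all-friends)."""
    c1, c2 = partition
    n = len(c1) + len(c2)
    return abs(len(c1) - len(c2)) / n * 100.0


def check_segregation_1d(state: SystemState, partition: tuple[np.ndarray, np.ndarray]) -> bool:
    """True iff every opinion in one clique is strictly below every opinion in
    the other (ties violate).  Requires F = 1 and a genuine bipartition."""
    c1, c2 = partition
    if state.opinions.n_issues != 1:
        raise NotApplicableError("1-D segregation check requires F = 1")
    if len(c1) == 0 or len(c2) == 0:
        raise NotApplicableError("segregation check requires two non-empty cliques")
    x = state.opinions.values[:, 0]
    a, b = x[c1], x[c2]
    return bool(a.max() < b.min() or b.max() < a.min())


def check_hyperplane_separation(
    state_or_opinions, partition: tuple[np.ndarray, np.ndarray]
) -> bool:
    """Exact strict linear separability of the two cliques' opinion point
    sets (F >= 2), decided by a linear-feasibility problem.

    Strict separability of the finite sets A, B is equivalent to the
    feasibility of  w·a - b >= 1 for a in A  and  w·x - b <= -1 for x in B
    (the margin can always be scaled to 1 when the convex hulls are disjoint).
    A degenerate partition with an empty side is separable by convention
    (flagged with a warning).
    """
    x = _opinion_values(state_or_opinions)
    c1, c2 = partition
    if x.shape[1] < 2:
        raise NotApplicableError("hyperplane separation check requires F >= 2")
    if len(c1) == 0 or len(c2) == 0:
        warnings.warn("degenerate partition: one clique is empty; separable by convention")
        return True
    a, b = x[c1], x[c2]
    nf = x.shape[1]
    # variables: (w_1..w_F, b); constraints in A_ub z <= b_ub form
    a_ub = np.vstack([np.hstack([-a, np.ones((len(a), 1))]),
                      np.hstack([b, -np.ones((len(b), 1))])])
    b_ub = -np.ones(len(a) + len(b))
    res = linprog(np.zeros(nf + 1), A_ub=a_ub, b_ub=b_ub,
                  bounds=[(None, None)] * (nf + 1), method="highs")
    return bool(res.success)


def alignment_score(points: np.ndarray) -> float:
    """Collinearity of a set of opinion vectors: the leading eigenvalue of
    their (population) covariance divided by the eigenvalue sum.

    1.0 means perfectly collinear points; for F = 2 the floor 0.5 means
    isotropic scatter.  Undefined (NaN) when all points coincide.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise NotApplicableError("alignment score needs at least 2 points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    ev = np.linalg.eigvalsh(cov)
    total = ev.sum()
    if total <= 0:
        return float("nan")
    return float(ev[-1] / total)
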