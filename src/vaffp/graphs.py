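"""Strict and approximate ancestry graphs.

The *strict* ancestry graph of a VAF matrix ``F`` has an edge ``j -> k``
whenever mutation ``j`` is at least as frequent as ``k`` in every sample — the
ancestry condition implied by the infinite sites assumption. Clonal trees
consistent with ``F`` are exactly the spanning arborescences of this graph
that satisfy the sum condition.

The *approximate* ancestry graph replaces the hard frequency comparison with
a posterior probability. Modeling reads as binomial draws with a flat prior
on the VAF, the posterior VAF of mutation ``j`` in sample ``i`` with variant
count ``v`` and reference count ``r - v`` is ``Beta(v + 1, r - v + 1)``. The
weight of edge ``j -> k`` is the probability that ``j``'s VAF exceeds
``k``'s in the *least favorable* sample:

    Pr[j ancestral to k] = min_i Pr[X_ij >= X_ik].

The graph is complete, so relaxing the sum condition can recover trees whose
edges noise removed from the strict graph.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from scipy.special import betaln

from .model import ReadCountMatrix, VAFMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "build_strict_graph",
    "build_approximate_graph",
    "beta_ancestral_probability",
]


def _pr_beta_ge(a: int, b: int, c: int, d: int) -> float:
    """Exact ``Pr[X >= Y]`` for ``X ~ Beta(a, b)``, ``Y ~ Beta(c, d)``.

    All parameters are positive integers (flat-prior posteriors of integer
    read counts), so the probability has a finite-sum closed form

        Pr[X > Y] = sum_{j=0}^{a-1} B(c + j, d + b) / [(b + j) B(1 + j, b) B(c, d)]

    evaluated in log space. The tie event has probability zero for these
    continuous distributions. The shorter of the two complementary sums is
    used for speed.
    """
    if c < a:
        return 1.0 - _pr_beta_ge(c, d, a, b)
    j = np.arange(a)
    log_terms = (
        betaln(c + j, d + b) - np.log(b + j) - betaln(1 + j, b) - betaln(c, d)
    )
    return float(np.clip(np.exp(log_terms).sum(), 0.0, 1.0))


def beta_ancestral_probability(v_j, r_j, v_k, r_k) -> float:
    """Probability that mutation ``j`` is ancestral to mutation ``k``.

    Parameters are per-sample vectors of variant and *total* read counts for
    the two mutations. Returns ``min_i Pr[X_ij >= X_ik]`` with flat-prior
    beta posteriors ``X ~ Beta(v + 1, (r - v) + 1)``; accurate to 1e-6.
    """
    v_j = np.atleast_1d(np.asarray(v_j, dtype=np.int64))
    r_j = np.atleast_1d(np.asarray(r_j, dtype=np.int64))
    v_k = np.atleast_1d(np.asarray(v_k, dtype=np.int64))
    r_k = np.atleast_1d(np.asarray(r_k, dtype=np.int64))
    if not (v_j.shape == r_j.shape == v_k.shape == r_k.shape):
        raise ValueError("count vectors must have identical shapes")
    if np.any(v_j > r_j) or np.any(v_k > r_k) or min(v_j.min(), v_k.min()) < 0:
        raise ValueError("need 0 <= variant <= total in every sample")
    best = 1.0
    for i in range(v_j.shape[0]):
        p = _pr_beta_ge(
            int(v_j[i]) + 1,
            int(r_j[i] - v_j[i]) + 1,
            int(v_k[i]) + 1,
            int(r_k[i] - v_k[i]) + 1,
        )
        best = min(best, p)
    return best


# ---------------------------------------------------------------------------
# array-level builders (fast path shared with the experiment driver)
# ---------------------------------------------------------------------------

def strict_adjacency(values: np.ndarray) -> np.ndarray:
    """Boolean (n, n) adjacency of the strict graph: ``adj[j, k]`` iff
    ``F[i, j] >= F[i, k]`` in every sample ``i`` (no self loops)."""
    adj = np.all(values[:, :, None] >= values[:, None, :], axis=0)
    np.fill_diagonal(adj, False)
    return adj


def select_root(adj: np.ndarray, values: np.ndarray, warn: bool = False) -> int:
    """Designated root: the unique in-degree-0 node if one exists, otherwise
    the node maximizing the total frequency across samples (ties broken by
    column order). Ambiguity is common in noisy data; pass ``warn`` to log it."""
    indeg = adj.sum(axis=0)
    zeros = np.flatnonzero(indeg == 0)
    if len(zeros) == 1:
        return int(zeros[0])
    log = logger.warning if warn else logger.debug
    log("%s in-degree-0 nodes; falling back to max total-frequency root", len(zeros))
    return int(np.argmax(values.sum(axis=0)))


def ancestral_probability_matrix(
    variant: np.ndarray, total: np.ndarray, pairs: np.ndarray | None = None
) -> np.ndarray:
    """(n, n) matrix of ``Pr[j ancestral to k]`` from count arrays of shape
    (s, n). Diagonal is 0. ``pairs`` optionally restricts computation to the
    given (j, k) index pairs, leaving other entries 0."""
    n = variant.shape[1]
    W = np.zeros((n, n))
    if pairs is None:
        pairs = np.array([(j, k) for j in range(n) for k in range(n) if j != k])
    for j, k in pairs:
        W[j, k] = beta_ancestral_probability(
            variant[:, j], total[:, j], variant[:, k], total[:, k]
        )
    return W


# ---------------------------------------------------------------------------
# public graph builders
# ---------------------------------------------------------------------------

def _wrap(adj, labels, root_idx, kind, weights=None) -> nx.DiGraph:
    G = nx.DiGraph(kind=kind, designated_root=labels[root_idx])
    G.add_nodes_from(labels)
    n = len(labels)
    for j in range(n):
        for k in range(n):
            if j != k and adj[j, k]:
                if weights is None:
                    G.add_edge(labels[j], labels[k])
                else:
                    G.add_edge(labels[j], labels[k], weight=float(weights[j, k]))
    return G


def build_strict_graph(F: VAFMatrix) -> nx.DiGraph:
    """Strict ancestry graph of ``F`` as a ``networkx.DiGraph``.

    Graph attributes carry ``kind='strict'`` and ``designated_root``. Exact
    frequency ties produce edges in both directions, so the result is not
    guaranteed to be acyclic.
    """
    adj = strict_adjacency(F.values)
    root = select_root(adj, F.values, warn=True)
    return _wrap(adj, F.mutation_ids, root, "strict")


def build_approximate_graph(R: ReadCountMatrix) -> nx.DiGraph:
    """Complete, probability-weighted ancestry graph from read counts."""
    W = ancestral_probability_matrix(R.variant, R.total)
    values = R.vaf_matrix().values
    n = R.n_mutations
    adj = ~np.eye(n, dtype=bool)
    root = select_root(strict_adjacency(values), values, warn=True)
    return _wrap(adj, R.mutation_ids, root, "approximate", weights=W)
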