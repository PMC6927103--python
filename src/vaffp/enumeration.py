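"""Enumeration, counting, ranking and selection of valid clonal trees.

A *valid* tree is a spanning arborescence of an ancestry graph, rooted at the
graph's designated root, whose frequencies satisfy the (possibly relaxed) sum
condition. The enumerator is a Gabow-Myers-style structured DFS that prunes
any partial tree already violating the condition; on a DAG the number of
unconstrained arborescences is the product of the non-root in-degrees, which
upper-bounds the number of valid trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import _fast
from .model import SUM_CONDITION_SLACK, ClonalTree, VAFMatrix

__all__ = [
    "SolutionSet",
    "enumerate_valid_trees",
    "count_spanning_trees",
    "min_epsilon_search",
    "rank_trees_by_weight",
]

DEFAULT_CAP = 10**6


@dataclass
class SolutionSet:
    """The result of an enumeration: candidate clonal trees for one dataset."""

    trees: list[ClonalTree]
    weights: list[float] | None = None
    epsilon_used: float = 0.0
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# graph -> array plumbing
# ---------------------------------------------------------------------------

def graph_arrays(
    G: nx.DiGraph, labels: list, weighted: bool = False
) -> tuple[np.ndarray, int, np.ndarray | None]:
    """Adjacency (and optional weight matrix) of ``G`` in ``labels`` order,
    plus the index of the designated root."""
    if set(G.nodes) != set(labels):
        raise ValueError("graph nodes do not match the expected label set")
    index = {v: i for i, v in enumerate(labels)}
    n = len(labels)
    adj = np.zeros((n, n), dtype=bool)
    W = np.zeros((n, n)) if weighted else None
    for u, v, data in G.edges(data=True):
        adj[index[u], index[v]] = True
        if weighted:
            W[index[u], index[v]] = data.get("weight", 1.0)
    root = G.graph.get("designated_root")
    if root is None:
        indeg = adj.sum(axis=0)
        zeros = np.flatnonzero(indeg == 0)
        root = labels[int(zeros[0])] if len(zeros) else labels[0]
    return adj, index[root], W


def compile_search(adj: np.ndarray, root: int):
    """Assignment order and flattened candidate-parent lists for the DFS.

    Non-root vertices are processed in ascending index order and parent
    candidates are tried in ascending index order, which fixes the output
    order of the enumeration.
    """
    n = adj.shape[0]
    order = np.array([v for v in range(n) if v != root], dtype=np.int64)
    cand_start = np.zeros(len(order) + 1, dtype=np.int64)
    flat: list[int] = []
    for i, v in enumerate(order):
        parents = np.flatnonzero(adj[:, v])
        flat.extend(int(p) for p in parents)
        cand_start[i + 1] = len(flat)
    return order, np.array(flat, dtype=np.int64), cand_start


_DUMMY_ANC = np.zeros(1, dtype=np.int64)
_DUMMY_OUT = np.zeros((1, 1), dtype=np.int16)


def run_dfs(
    adj: np.ndarray,
    root: int,
    F: np.ndarray,
    epsilon: float,
    mode: int,
    cap: int = DEFAULT_CAP,
    truth_anc: np.ndarray | None = None,
    out_parents: np.ndarray | None = None,
) -> np.ndarray:
    """Array-level entry point to the jitted search (see ``_fast``)."""
    order, cand_flat, cand_start = compile_search(adj, root)
    return _fast.enumerate_arborescences(
        order,
        cand_flat,
        cand_start,
        np.ascontiguousarray(F, dtype=np.float64),
        float(epsilon),
        SUM_CONDITION_SLACK,
        mode,
        float(cap),
        truth_anc if truth_anc is not None else _DUMMY_ANC,
        out_parents if out_parents is not None else _DUMMY_OUT,
    )


def materialize_valid(
    adj: np.ndarray, root: int, F: np.ndarray, epsilon: float, cap: int = DEFAULT_CAP
) -> tuple[np.ndarray, bool]:
    """All valid trees as an (count, n) array of parent indices (-1 = root)."""
    n = adj.shape[0]
    if n == 1:
        return np.full((1, 1), -1, dtype=np.int16), False
    indeg = adj.sum(axis=0)
    bound = 1.0
    for v in range(n):
        if v != root:
            bound *= max(int(indeg[v]), 1)
    rows = int(min(float(cap), bound))
    out = np.zeros((max(rows, 1), n), dtype=np.int16)
    res = run_dfs(adj, root, F, epsilon, _fast.MODE_MATERIALIZE, cap=rows, out_parents=out)
    count = int(res[_fast.R_COUNT])
    return out[:count], bool(res[_fast.R_TRUNCATED])


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def enumerate_valid_trees(
    G: nx.DiGraph,
    F: VAFMatrix,
    epsilon: float = 0.0,
    cap: int | None = DEFAULT_CAP,
) -> SolutionSet:
    """All spanning arborescences of ``G`` (rooted at its designated root)
    that satisfy the sum condition relaxed by ``epsilon``.

    Enumeration stops after ``cap`` trees, flagged by ``truncated``.
    """
    cap = cap or DEFAULT_CAP
    adj, root, _ = graph_arrays(G, F.mutation_ids)
    parents, truncated = materialize_valid(adj, root, F.values, epsilon, cap)
    trees = [
        ClonalTree.from_parent_array(row, F.mutation_ids) for row in parents
    ]
    return SolutionSet(trees, epsilon_used=float(epsilon), truncated=truncated)


def count_spanning_trees(G: nx.DiGraph) -> int:
    """Number of spanning arborescences of a rooted DAG: the product of the
    in-degrees of its non-root nodes (the sum condition is ignored).

    Raises if ``G`` has a directed cycle or its designated root has incoming
    edges, in which case the product formula does not apply.
    """
    if not nx.is_directed_acyclic_graph(G):
        raise ValueError("spanning-tree count formula requires a DAG")
    root = G.graph.get("designated_root")
    if root is None:
        sources = [v for v in G.nodes if G.in_degree(v) == 0]
        if len(sources) != 1:
            raise ValueError("graph must designate a root")
        root = sources[0]
    if G.in_degree(root) != 0:
        raise ValueError("designated root has incoming edges")
    count = 1
    for v in G.nodes:
        if v != root:
            count *= G.in_degree(v)
    return count


def min_epsilon_search(G: nx.DiGraph, F: VAFMatrix, tol: float = 0.0) -> float:
    """Smallest relaxation ``epsilon`` admitting one valid spanning tree.

    Equals the minimum over spanning arborescences of the maximal sum-
    condition overflow, clamped below at 0. Computed exactly by branch and
    bound (partial overflows only grow as children are added), so ``tol`` is
    honored trivially.
    """
    adj, root, _ = graph_arrays(G, F.mutation_ids)
    vals = F.values
    s, n = vals.shape
    order = [v for v in range(n) if v != root]
    cands = [np.flatnonzero(adj[:, v]) for v in order]
    childsum = np.zeros((s, n))
    parent = np.full(n, -1, dtype=int)
    best = np.inf

    def creates_cycle(p: int, v: int) -> bool:
        w = p
        while w >= 0:
            if w == v:
                return True
            w = parent[w]
        return False

    def rec(pos: int, overflow: float) -> None:
        nonlocal best
        if overflow >= best:
            return
        if pos == len(order):
            best = overflow
            return
        v = order[pos]
        for p in cands[pos]:
            if creates_cycle(int(p), v):
                continue
            childsum[:, p] += vals[:, v]
            parent[v] = p
            new_over = max(overflow, float((childsum[:, p] - vals[:, p]).max()))
            if new_over < best:
                rec(pos + 1, new_over)
            childsum[:, p] -= vals[:, v]
            parent[v] = -1

    rec(0, -np.inf)
    if not np.isfinite(best):
        raise ValueError("graph has no spanning arborescence")
    return max(0.0, float(best))


def rank_trees_by_weight(
    G: nx.DiGraph,
    F: VAFMatrix,
    k: int,
    epsilon: float = 0.0,
    cap: int = DEFAULT_CAP,
) -> SolutionSet:
    """Up to ``k`` valid spanning trees of a weighted (approximate) ancestry
    graph, in nonincreasing order of tree weight.

    Tree weight is the product of its edge probabilities; rank 1 is the
    max-weight valid tree. The full valid set is enumerated (feasible at the
    problem sizes this package targets) and sorted by weight, with
    equal-weight ties broken by lexicographic parent-vector order.
    """
    adj, root, W = graph_arrays(G, F.mutation_ids, weighted=True)
    parents, truncated = materialize_valid(adj, root, F.values, epsilon, cap)
    if len(parents) == 0:
        return SolutionSet([], weights=[], epsilon_used=float(epsilon), truncated=truncated)
    logw = tree_log_weights(parents, W)
    idx = sorted(range(len(parents)), key=lambda t: (-logw[t], tuple(parents[t])))[:k]
    trees = [ClonalTree.from_parent_array(parents[t], F.mutation_ids) for t in idx]
    weights = [float(np.exp(logw[t])) for t in idx]
    return SolutionSet(trees, weights=weights, epsilon_used=float(epsilon), truncated=truncated)


def tree_log_weights(parents: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Log product-of-edge-probability weight for each parent-vector row."""
    n = parents.shape[1]
    with np.errstate(divide="ignore"):
        logW = np.log(W)
    total = np.zeros(len(parents))
    for v in range(n):
        p = parents[:, v].astype(np.int64)
        m = p >= 0
        total[m] += logW[p[m], v]
    return total
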