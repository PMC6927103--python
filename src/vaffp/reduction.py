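"""Transitive reduction and k-partial transitive reduction of ancestry graphs.

An edge ``(u, v)`` of a DAG is *k-transitive* when the transitive reduction
``R`` contains a ``u -> v`` path of length ``k``. The k-PTR removes every
edge whose endpoints are at distance >= k in ``R`` (distances computed with
one BFS per node), shrinking the spanning-tree space while preserving
reachability: ``R`` itself is a subgraph of every k-PTR, and the 2-PTR is
exactly the classical transitive reduction.
"""

from __future__ import annotations

import networkx as nx

__all__ = ["transitive_reduction", "k_partial_transitive_reduction"]


def _check_dag(G: nx.DiGraph) -> None:
    if nx.is_directed_acyclic_graph(G):
        return
    cycle = nx.find_cycle(G)
    u, v = cycle[0][0], cycle[0][1]
    raise ValueError(
        f"graph has a directed cycle (e.g. through edge {u!r} -> {v!r}); "
        "frequency ties can create such 2-cycles — perturb the tied "
        "frequencies or merge the tied mutations into one cluster"
    )


def _copy_attrs(src: nx.DiGraph, dst: nx.DiGraph) -> nx.DiGraph:
    dst.graph.update(src.graph)
    for u, v in dst.edges:
        dst.edges[u, v].update(src.edges[u, v])
    return dst


def transitive_reduction(G: nx.DiGraph) -> nx.DiGraph:
    """Unique minimal subgraph of a DAG with the same reachability relation."""
    _check_dag(G)
    return _copy_attrs(G, nx.transitive_reduction(G))


def k_partial_transitive_reduction(G: nx.DiGraph, k: int = 2) -> nx.DiGraph:
    """Remove every >=k-transitive edge of a DAG.

    Edges ``(u, v)`` with shortest-path distance >= k from ``u`` to ``v`` in
    the transitive reduction are dropped; reduction edges (distance 1) are
    never removed, and ``k=2`` reproduces the transitive reduction itself.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    R = transitive_reduction(G)
    dist = {u: nx.single_source_shortest_path_length(R, u) for u in R.nodes}
    H = G.copy()
    H.remove_edges_from(
        [(u, v) for u, v in G.edges if dist[u].get(v, 0) >= k]
    )
    return H
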