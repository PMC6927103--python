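"""Independent brute-force oracles used to validate the enumeration engine.

These deliberately avoid the pruned DFS used by the package: arborescences
are generated by exhaustive parent-choice products and validated with
networkx, and trees are filtered afterwards with the public sum-condition
check. Only practical for a handful of nodes.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from vaffp.model import ClonalTree, VAFMatrix, check_sum_condition


def all_arborescences(G: nx.DiGraph, root) -> list[ClonalTree]:
    """Every spanning arborescence of ``G`` rooted at ``root``, by exhaustive
    choice of one in-edge per non-root node plus an explicit networkx check."""
    nodes = list(G.nodes)
    others = [v for v in nodes if v != root]
    choices = [[u for u in G.predecessors(v)] for v in others]
    out = []
    if any(len(c) == 0 for c in choices):
        return out
    for combo in itertools.product(*choices):
        T = nx.DiGraph()
        T.add_nodes_from(nodes)
        T.add_edges_from(zip(combo, others))
        if nx.is_arborescence(T) and T.in_degree(root) == 0:
            parent = {v: None for v in nodes}
            for u, v in T.edges:
                parent[v] = u
            out.append(ClonalTree(parent))
    return out


def valid_trees_oracle(G: nx.DiGraph, F: VAFMatrix, epsilon: float) -> set:
    """Valid-tree set as frozen parent maps, via exhaustive enumeration."""
    root = G.graph["designated_root"]
    return {
        frozenset(t.parent.items())
        for t in all_arborescences(G, root)
        if check_sum_condition(t, F, epsilon)[0]
    }


def min_epsilon_oracle(G: nx.DiGraph, F: VAFMatrix) -> float:
    root = G.graph["designated_root"]
    trees = all_arborescences(G, root)
    if not trees:
        raise ValueError("no arborescence")
    return max(0.0, min(check_sum_condition(t, F, 0.0)[1] for t in trees))


def random_strict_instance(rng: np.random.Generator, n: int, s: int = 2):
    """A random VAF matrix and its strict ancestry graph (may be any DAG)."""
    from vaffp.graphs import build_strict_graph

    F = VAFMatrix(
        rng.random((s, n)) * 0.5, mutation_ids=[f"m{j + 1}" for j in range(n)]
    )
    return F, build_strict_graph(F)


def mc_beta_ge(a, b, c, d, rng, draws=200_000):
    """Monte-Carlo estimate and standard error of Pr[Beta(a,b) >= Beta(c,d)]."""
    x = rng.beta(a, b, draws)
    y = rng.beta(c, d, draws)
    p = float(np.mean(x >= y))
    se = max(np.sqrt(p * (1 - p) / draws), 1.0 / draws)
    return p, se
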