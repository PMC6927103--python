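"""Scoring reconstructed clonal trees against a reference tree.

Clonal trees carry internal node labels, so classical phylogenetic distances
(Robinson-Foulds and relatives) do not apply. Instead trees are compared by
their ancestor-descendant (A-D) relations: the distance between two trees on
the same label set is the size of the symmetric difference of their sets of
ordered (ancestor, descendant) pairs. The headline quality score, *A-D
improvement*, is the proportional decrease in mean A-D distance of a
solution set relative to an equal number of random uniform-attachment trees:

    (AD(random) - AD(solutions)) / AD(random)

0 means no better than random, 1 means the solution set is exactly the
reference tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _fast
from .enumeration import SolutionSet
from .model import ClonalTree

__all__ = [
    "TopologyMetrics",
    "ad_pairs",
    "ad_distance",
    "ad_improvement",
    "topology_metrics",
]

#: baseline sample cap: above this many solutions the random-tree mean is
#: estimated from this many draws instead of one draw per solution
BASELINE_CAP = 10**4


def ad_pairs(tree: ClonalTree) -> set[tuple]:
    """Ordered pairs ``(a, b)`` with ``a`` a proper ancestor of ``b``."""
    pairs = set()
    for v in tree.nodes:
        w = tree.parent[v]
        while w is not None:
            pairs.add((w, v))
            w = tree.parent[w]
    return pairs


def ad_distance(t1: ClonalTree, t2: ClonalTree) -> int:
    """Symmetric-difference count of ancestor-descendant pairs."""
    if set(t1.parent) != set(t2.parent):
        raise ValueError("trees must share the same node label set")
    return len(ad_pairs(t1) ^ ad_pairs(t2))


def random_parent_batch(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """``m`` random recursive trees over ``n`` labels as full parent arrays.

    Each tree inserts the labels in a uniformly random order and attaches
    every insertion to a uniformly chosen earlier node, so the root label is
    itself random — the baseline carries no information about which mutation
    founded the tumor.
    """
    canon = rng.integers(0, np.arange(1, n), size=(m, n - 1))
    perm = np.argsort(rng.random((m, n)), axis=1)
    parents = np.empty((m, n), dtype=np.int64)
    rows = np.arange(m)[:, None]
    src = np.concatenate(
        [np.full((m, 1), -1), np.take_along_axis(perm, canon, axis=1)], axis=1
    )
    parents[rows, perm] = src
    return parents


def random_baseline_ad(
    truth_anc: np.ndarray, n: int, m: int, rng: np.random.Generator
) -> float:
    """Mean A-D distance to the reference of ``m`` randomly labeled
    uniform-attachment trees (the denominator of the A-D improvement)."""
    m = int(min(m, BASELINE_CAP))
    if n < 2 or m < 1:
        raise ValueError("baseline undefined for degenerate inputs")
    batch = random_parent_batch(n, m, rng)
    total = _fast.batch_ad_sum(np.ascontiguousarray(batch), truth_anc)
    return float(total) / m


def mean_ad_to_truth(trees: list[ClonalTree], truth: ClonalTree) -> float:
    order = truth.nodes
    truth_anc = _fast.ancestor_mask_array(truth.to_parent_array(order))
    dists = [
        np.bitwise_count(
            _fast.ancestor_mask_array(t.to_parent_array(order)) ^ truth_anc
        ).sum()
        for t in trees
    ]
    return float(np.mean(dists))


def ad_improvement(
    solutions: SolutionSet | list[ClonalTree],
    truth: ClonalTree,
    rng: np.random.Generator,
) -> float:
    """A-D improvement of a solution set over a random-tree baseline of equal
    size (capped at ``BASELINE_CAP`` draws)."""
    trees = solutions.trees if isinstance(solutions, SolutionSet) else list(solutions)
    if not trees:
        raise ValueError("solution set is empty")
    n = truth.n_nodes
    if n < 2:
        raise ValueError("A-D improvement undefined for single-node trees")
    truth_anc = _fast.ancestor_mask_array(truth.to_parent_array(truth.nodes))
    ad_random = random_baseline_ad(truth_anc, n, len(trees), rng)
    if ad_random == 0:
        raise ValueError("random baseline distance is zero")
    return (ad_random - mean_ad_to_truth(trees, truth)) / ad_random


@dataclass
class TopologyMetrics:
    """Shape descriptors of a clonal tree.

    height: edge count of the longest root-leaf path; leaf_count: nodes with
    no children; single_child_fraction: nodes with exactly one child, over
    all nodes; mean_subtree_height: mean over nodes of the height of the
    subtree rooted there. Branching topologies are wide and shallow (many
    leaves, small heights), linear ones the opposite.
    """

    height: int
    leaf_count: int
    single_child_fraction: float
    mean_subtree_height: float


def topology_metrics(tree: ClonalTree) -> TopologyMetrics:
    n = tree.n_nodes
    depths = {v: tree.depth(v) for v in tree.nodes}
    subtree_height = {v: 0 for v in tree.nodes}
    for v in tree.nodes:
        d_v = depths[v]
        w = tree.parent[v]
        while w is not None:
            subtree_height[w] = max(subtree_height[w], d_v - depths[w])
            w = tree.parent[w]
    leaf_count = sum(1 for v in tree.nodes if not tree.children[v])
    single = sum(1 for v in tree.nodes if len(tree.children[v]) == 1)
    return TopologyMetrics(
        height=max(depths.values()),
        leaf_count=leaf_count,
        single_child_fraction=single / n,
        mean_subtree_height=float(np.mean(list(subtree_height.values()))),
    )
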