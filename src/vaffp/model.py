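"""Core data model for VAF factorization phylogenies.

The central objects are the s x n variant allele frequency (VAF) matrix ``F``,
rooted clonal trees over the n mutations, the binary clonal matrix ``B`` (one
row per tumor cell population, listing the mutations it carries), and the
usage matrix ``U`` of population mixing proportions per sample. Under the
infinite sites assumption a clonal tree and its usage matrix factorize the
frequencies as ``F = (1/2) U B`` — the 1/2 because mutations are modeled as
heterozygous SNVs in diploid regions.

A tree is consistent with ``F`` when, in every sample, the frequencies of the
children of any node sum to at most the node's own frequency (the *sum
condition*); equivalently, when ``U`` derived from the tree is nonnegative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: absolute slack added on top of epsilon in floating-point sum-condition tests
SUM_CONDITION_SLACK = 1e-12

Node = Hashable


def _as_id_list(ids: Iterable) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("identifiers must be unique")
    return ids


@dataclass
class VAFMatrix:
    """Observed variant allele frequencies, one row per sample.

    ``values[i, j]`` is the fraction of reads from sample ``i`` that carry
    mutation ``j``. Entries must be finite and lie in [0, 1].
    """

    values: np.ndarray
    sample_ids: list = field(default_factory=list)
    mutation_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (samples x mutations) array")
        s, n = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(s)]
        if not self.mutation_ids:
            self.mutation_ids = [f"m{j + 1}" for j in range(n)]
        self.sample_ids = _as_id_list(self.sample_ids)
        self.mutation_ids = _as_id_list(self.mutation_ids)
        if len(self.sample_ids) != s or len(self.mutation_ids) != n:
            raise ValueError("label lists inconsistent with matrix shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VAF entries must be finite")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("VAF entries must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_mutations(self) -> int:
        return self.values.shape[1]

    def column(self, mutation: Node) -> np.ndarray:
        return self.values[:, self.mutation_ids.index(mutation)]


@dataclass
class ReadCountMatrix:
    """Per-sample, per-mutation variant and *total* read counts.

    ``total`` stores sequencing depth; the reference count used in beta
    posteriors is ``total - variant``.
    """

    variant: np.ndarray
    total: np.ndarray
    sample_ids: list = field(default_factory=list)
    mutation_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variant = np.asarray(self.variant, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.variant.shape != self.total.shape or self.variant.ndim != 2:
            raise ValueError("variant/total must be 2-D arrays of equal shape")
        s, n = self.variant.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(s)]
        if not self.mutation_ids:
            self.mutation_ids = [f"m{j + 1}" for j in range(n)]
        self.sample_ids = _as_id_list(self.sample_ids)
        self.mutation_ids = _as_id_list(self.mutation_ids)
        if len(self.sample_ids) != s or len(self.mutation_ids) != n:
            raise ValueError("label lists inconsistent with matrix shape")
        if self.variant.min(initial=0) < 0:
            raise ValueError("variant counts must be nonnegative")
        if np.any(self.variant > self.total):
            raise ValueError("variant counts cannot exceed total counts")

    @property
    def n_samples(self) -> int:
        return self.variant.shape[0]

    @property
    def n_mutations(self) -> int:
        return self.variant.shape[1]

    def vaf_matrix(self) -> VAFMatrix:
        """Observed VAFs ``v / total``; zero-depth sites are set to 0."""
        zero = self.total == 0
        if np.any(zero):
            logger.warning(
                "%d zero-depth site(s); their VAF is reported as 0", int(zero.sum())
            )
        denom = np.where(zero, 1, self.total)
        return VAFMatrix(
            self.variant / denom,
            list(self.sample_ids),
            list(self.mutation_ids),
        )


class ClonalTree:
    """A rooted tree whose nodes are mutations (or mutation clusters).

    Parameters
    ----------
    parent
        Mapping node -> parent node; exactly one node (the root) maps to
        ``None``. Alternatively pass an edge iterable via :meth:`from_edges`.
    node_mutations
        Optional mapping node -> iterable of mutation labels, for trees whose
        nodes represent clusters of mutations. Each node is treated as a unit.
    """

    def __init__(
        self,
        parent: Mapping[Node, Node | None],
        node_mutations: Mapping[Node, Sequence] | None = None,
    ) -> None:
        self.parent: dict[Node, Node | None] = dict(parent)
        roots = [v for v, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root: Node = roots[0]
        for v, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"parent {p!r} of {v!r} is not a node")
        self.children: dict[Node, list[Node]] = {v: [] for v in self.parent}
        for v, p in self.parent.items():
            if p is not None:
                self.children[p].append(v)
        # reachability doubles as the acyclicity check
        seen = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            seen.add(v)
            stack.extend(self.children[v])
        if seen != set(self.parent):
            raise ValueError("all nodes must be reachable from the root")
        self.node_mutations = (
            {v: list(ms) for v, ms in node_mutations.items()}
            if node_mutations is not None
            else None
        )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[Node, Node]], root: Node | None = None
    ) -> "ClonalTree":
        parent: dict[Node, Node | None] = {}
        for p, c in edges:
            parent.setdefault(p, None)
            if c in parent and parent[c] is not None:
                raise ValueError(f"node {c!r} has two parents")
            parent[c] = p
        if root is not None:
            parent.setdefault(root, None)
        return cls(parent)

    @classmethod
    def from_parent_array(
        cls, parents: Sequence[int], labels: Sequence[Node] | None = None
    ) -> "ClonalTree":
        """Build from an integer array where ``parents[v] == -1`` marks the root."""
        n = len(parents)
        labels = list(labels) if labels is not None else list(range(n))
        return cls(
            {
                labels[v]: (None if parents[v] < 0 else labels[parents[v]])
                for v in range(n)
            }
        )

    # -- views ------------------------------------------------------------
    @property
    def nodes(self) -> list[Node]:
        return list(self.parent)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def edges(self) -> list[tuple[Node, Node]]:
        return [(p, v) for v, p in self.parent.items() if p is not None]

    def to_parent_array(self, order: Sequence[Node]) -> np.ndarray:
        order = list(order)
        if set(order) != set(self.parent):
            raise ValueError("order must be a permutation of the tree's nodes")
        index = {v: i for i, v in enumerate(order)}
        out = np.full(len(order), -1, dtype=np.int64)
        for v, p in self.parent.items():
            if p is not None:
                out[index[v]] = index[p]
        return out

    def depth(self, v: Node) -> int:
        d = 0
        while self.parent[v] is not None:
            v = self.parent[v]
            d += 1
        return d

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ClonalTree) and self.parent == other.parent

    def __hash__(self) -> int:
        return hash(frozenset(self.parent.items()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ClonalTree(root={self.root!r}, edges={sorted(map(str, self.edges()))})"


@dataclass
class ClonalMatrix:
    """Binary population x mutation membership matrix of a clonal tree."""

    B: np.ndarray
    node_ids: list

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B)
        if self.B.ndim != 2 or self.B.shape[0] != self.B.shape[1]:
            raise ValueError("B must be square")
        self.node_ids = _as_id_list(self.node_ids)
        if len(self.node_ids) != self.B.shape[0]:
            raise ValueError("node_ids inconsistent with B")


@dataclass
class UsageMatrix:
    """Sample x population mixing proportions; negative entries flag
    sum-condition violations of the generating tree."""

    U: np.ndarray
    sample_ids: list
    node_ids: list


def clonal_matrix_from_tree(
    tree: ClonalTree, order: Sequence[Node] | None = None
) -> ClonalMatrix:
    """Binary matrix with ``B[l, j] = 1`` iff mutation ``j`` lies on the
    root-to-``l`` path (both endpoints included)."""
    order = list(order) if order is not None else tree.nodes
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    B = np.zeros((n, n), dtype=np.int8)
    for v in order:
        w: Node | None = v
        while w is not None:
            B[index[v], index[w]] = 1
            w = tree.parent[w]
    return ClonalMatrix(B, order)


def _aligned_F(tree: ClonalTree, F: VAFMatrix) -> tuple[np.ndarray, list[Node]]:
    order = tree.nodes
    missing = [v for v in order if v not in F.mutation_ids]
    if missing:
        raise ValueError(f"tree nodes absent from VAF matrix: {missing!r}")
    cols = [F.mutation_ids.index(v) for v in order]
    return F.values[:, cols], order


def check_sum_condition(
    tree: ClonalTree, F: VAFMatrix, epsilon: float = 0.0
) -> tuple[bool, float]:
    """Test the (relaxed) sum condition and report the worst overflow.

    Returns ``(ok, max_overflow)`` where ``max_overflow`` is the largest value
    of ``sum(children VAF) - parent VAF`` over all samples and nodes (negative
    when the condition holds with room to spare). ``ok`` is True iff the
    overflow is at most ``epsilon`` (plus a tiny representation slack).
    """
    vals, order = _aligned_F(tree, F)
    index = {v: i for i, v in enumerate(order)}
    max_overflow = -np.inf
    for v in order:
        kids = tree.children[v]
        child_sum = (
            vals[:, [index[c] for c in kids]].sum(axis=1) if kids else 0.0
        )
        overflow = child_sum - vals[:, index[v]]
        max_overflow = max(max_overflow, float(np.max(overflow)))
    return max_overflow <= epsilon + SUM_CONDITION_SLACK, max_overflow


def usage_from_tree(tree: ClonalTree, F: VAFMatrix) -> UsageMatrix:
    """Population proportions ``U[i, j] = 2 (F[i, j] - sum of children F)``.

    Entries may be negative; nonnegativity of ``U`` is equivalent to the
    sum condition holding at ``epsilon = 0``.
    """
    vals, order = _aligned_F(tree, F)
    index = {v: i for i, v in enumerate(order)}
    U = 2.0 * vals.copy()
    for v in order:
        for c in tree.children[v]:
            U[:, index[v]] -= 2.0 * vals[:, index[c]]
    return UsageMatrix(U, list(F.sample_ids), order)


def reconstruct_F(U: UsageMatrix, B: ClonalMatrix) -> VAFMatrix:
    """Recompose frequencies as ``F = (1/2) U B``."""
    if U.U.shape[1] != B.B.shape[0]:
        raise ValueError("shape mismatch between U and B")
    if U.node_ids != B.node_ids:
        raise ValueError("U and B must share the same node order")
    values = 0.5 * U.U @ B.B
    return VAFMatrix(np.clip(values, 0.0, 1.0), list(U.sample_ids), list(B.node_ids))
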