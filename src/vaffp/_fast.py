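"""Jit-compiled depth-first enumeration of sum-condition spanning arborescences.

Every non-root vertex of an ancestry graph must pick exactly one incoming
edge; on a DAG any such choice is automatically a spanning arborescence
(which is why the arborescence count is the product of non-root in-degrees),
and on general digraphs an incremental cycle check suffices. The search
assigns parents in ascending vertex order and prunes a branch as soon as the
children already placed under some node overflow its frequency by more than
``epsilon`` in any sample — child sums only grow, so pruning is sound.

Modes:
  0  existence: stop at the first valid tree
  1  count valid trees
  2  count + accumulate ancestor-descendant distance to a reference tree,
     leaf counts and heights of the valid trees
  3  count + materialize parent vectors into a preallocated array
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_EXISTS = 0
MODE_COUNT = 1
MODE_SCORE = 2
MODE_MATERIALIZE = 3

R_COUNT, R_TRUNCATED, R_AD_SUM, R_LEAF_SUM, R_HEIGHT_SUM = 0, 1, 2, 3, 4


@njit(cache=True)
def _popcount(x):
    c = 0
    while x:
        x &= x - 1
        c += 1
    return c


@njit(cache=True)
def _ancestor_masks(parent, anc, done, chain):
    """Fill ``anc[v]`` = bitmask of proper ancestors of ``v`` (parent array
    with -1 at the root)."""
    n = parent.shape[0]
    for v in range(n):
        done[v] = False
    for v in range(n):
        if parent[v] < 0:
            anc[v] = 0
            done[v] = True
    for v in range(n):
        w = v
        top = 0
        while not done[w]:
            chain[top] = w
            top += 1
            w = parent[w]
        while top > 0:
            top -= 1
            x = chain[top]
            p = parent[x]
            anc[x] = anc[p] | (np.int64(1) << p)
            done[x] = True


@njit(cache=True)
def enumerate_arborescences(
    order, cand_flat, cand_start, F, eps, slack, mode, cap, truth_anc, out_parents
):
    """Core DFS. See module docstring for the contract.

    Returns a float64[5] result vector: count, truncated flag, and (mode 2)
    summed A-D distance, leaf count and height of all valid trees.
    """
    s, n = F.shape
    m = order.shape[0]
    res = np.zeros(5, dtype=np.float64)
    parent = np.full(n, -1, dtype=np.int64)
    childsum = np.zeros((s, n), dtype=np.float64)
    ci = np.zeros(m, dtype=np.int64)
    anc = np.zeros(n, dtype=np.int64)
    done = np.zeros(n, dtype=np.bool_)
    chain = np.zeros(n, dtype=np.int64)
    has_child = np.zeros(n, dtype=np.bool_)

    if m == 0:  # single-node graph: exactly one (empty) tree
        res[R_COUNT] = 1.0
        if mode == MODE_SCORE:
            res[R_LEAF_SUM] = 1.0
        return res

    pos = 0
    while pos >= 0:
        v = order[pos]
        advanced = False
        lo = cand_start[pos]
        hi = cand_start[pos + 1]
        while lo + ci[pos] < hi:
            p = cand_flat[lo + ci[pos]]
            ci[pos] += 1
            # cycle check: would p -> v close a directed cycle?
            w = p
            bad = False
            while w >= 0:
                if w == v:
                    bad = True
                    break
                w = parent[w]
            if bad:
                continue
            # sum condition: children of p must not overflow its frequency
            for i in range(s):
                if childsum[i, p] + F[i, v] > F[i, p] + eps + slack:
                    bad = True
                    break
            if bad:
                continue
            if pos == m - 1:
                # complete valid tree
                parent[v] = p
                res[R_COUNT] += 1.0
                if mode == MODE_EXISTS:
                    return res
                if mode == MODE_SCORE:
                    _ancestor_masks(parent, anc, done, chain)
                    ad = 0
                    height = 0
                    for u in range(n):
                        ad += _popcount(anc[u] ^ truth_anc[u])
                        d = _popcount(anc[u])
                        if d > height:
                            height = d
                    res[R_AD_SUM] += ad
                    res[R_HEIGHT_SUM] += height
                    for u in range(n):
                        has_child[u] = False
                    for u in range(n):
                        if parent[u] >= 0:
                            has_child[parent[u]] = True
                    leaves = 0
                    for u in range(n):
                        if not has_child[u]:
                            leaves += 1
                    res[R_LEAF_SUM] += leaves
                elif mode == MODE_MATERIALIZE:
                    row = int(res[R_COUNT]) - 1
                    for u in range(n):
                        out_parents[row, u] = parent[u]
                parent[v] = -1
                if res[R_COUNT] >= cap:
                    res[R_TRUNCATED] = 1.0
                    return res
                continue
            # commit and descend
            parent[v] = p
            for i in range(s):
                childsum[i, p] += F[i, v]
            pos += 1
            advanced = True
            break
        if not advanced:
            ci[pos] = 0
            pos -= 1
            if pos >= 0:
                u = order[pos]
                q = parent[u]
                parent[u] = -1
                for i in range(s):
                    childsum[i, q] -= F[i, u]
    return res


@njit(cache=True)
def batch_ad_sum(parents_batch, truth_anc):
    """Sum of A-D distances to the reference over a batch of full parent
    arrays (one tree per row, -1 marking each tree's root)."""
    m, n = parents_batch.shape
    anc = np.zeros(n, dtype=np.int64)
    done = np.zeros(n, dtype=np.bool_)
    chain = np.zeros(n, dtype=np.int64)
    total = 0.0
    for t in range(m):
        _ancestor_masks(parents_batch[t], anc, done, chain)
        ad = 0
        for u in range(n):
            ad += _popcount(anc[u] ^ truth_anc[u])
        total += ad
    return total


def ancestor_mask_array(parent: np.ndarray) -> np.ndarray:
    """Ancestor bitmasks for a single parent array (root marked -1)."""
    n = parent.shape[0]
    anc = np.zeros(n, dtype=np.int64)
    done = np.zeros(n, dtype=np.bool_)
    chain = np.zeros(n, dtype=np.int64)
    _ancestor_masks(np.asarray(parent, dtype=np.int64), anc, done, chain)
    return anc
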