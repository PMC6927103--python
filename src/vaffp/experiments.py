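"""Simulation-study drivers: parameter sweeps, rank analyses, PTR analyses.

Each trial simulates a dataset, builds the strict ancestry graph of the
observed VAFs, optionally prunes transitive edges, enumerates the valid
spanning trees and scores them against the underlying tree. A trial is
*solvable* when at least one valid tree exists at the epsilon in force.
Trials are independently seeded (trial ``t`` of grid point ``g`` uses the
stream ``[seed, g, t]``), so aggregates are reproducible and order-independent.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fast
from .enumeration import DEFAULT_CAP, materialize_valid, run_dfs, tree_log_weights
from .evaluate import random_baseline_ad
from .graphs import ancestral_probability_matrix, select_root, strict_adjacency
from .simulate import GroundTruth, SimulationConfig, simulate_trial

__all__ = ["SweepResult", "RankResult", "run_sweep", "rank_analysis", "ptr_analysis"]


# ---------------------------------------------------------------------------
# array-level helpers for strict ancestry graphs
# ---------------------------------------------------------------------------

def has_tie_cycle(adj: np.ndarray) -> bool:
    """Directed cycles in a strict ancestry graph arise exactly from mutual
    frequency ties, so acyclicity reduces to checking for 2-cycles."""
    return bool(np.any(adj & adj.T))


def closed_dag_reduction(adj: np.ndarray) -> np.ndarray:
    """Transitive reduction of a transitively closed DAG: drop every edge
    bypassed by a 2-path. (The strict ancestry relation is transitive, so
    its graph is always closed.)"""
    two_path = (adj.astype(np.uint8) @ adj.astype(np.uint8)) > 0
    return adj & ~two_path


def closed_dag_ptr(adj: np.ndarray, k: int) -> np.ndarray:
    """k-PTR of a transitively closed DAG: remove edges at distance >= k in
    the transitive reduction (distances by BFS per node)."""
    R = closed_dag_reduction(adj)
    n = adj.shape[0]
    out = adj.copy()
    succ = [np.flatnonzero(R[u]) for u in range(n)]
    for u in range(n):
        dist = np.full(n, -1)
        dist[u] = 0
        q = deque([u])
        while q:
            w = q.popleft()
            for x in succ[w]:
                if dist[x] < 0:
                    dist[x] = dist[w] + 1
                    q.append(x)
        drop = (dist >= k) & adj[u]
        out[u, drop] = False
    return out


def truth_anc_masks(gt: GroundTruth) -> np.ndarray:
    return _fast.ancestor_mask_array(
        gt.tree.to_parent_array(gt.F.mutation_ids)
    )


def spanning_count(adj: np.ndarray, root: int) -> int:
    """Product of non-root in-degrees (arborescence count of a rooted DAG)."""
    indeg = adj.sum(axis=0)
    count = 1
    for v in range(adj.shape[0]):
        if v != root:
            count *= int(indeg[v])
    return count


def _trial_rng(seed: int, point: int, t: int) -> np.random.Generator:
    return np.random.default_rng([seed, point, t])


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Aggregates of a one-parameter sweep, one row per grid value."""

    varying: str
    grid: list
    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


_CFG_PARAMS = {"n", "s", "coverage", "rho"}


def run_sweep(
    varying: str,
    grid,
    trials: int,
    defaults: SimulationConfig | None = None,
    mode: str = "strict",
    epsilon: float = 0.0,
    ptr_k: int | None = None,
    seed: int = 0,
    quality: bool = True,
    count_trees: bool = False,
    cap: int = DEFAULT_CAP,
) -> SweepResult:
    """Sweep one parameter, running ``trials`` independent simulate ->
    graph -> (optional k-PTR) -> enumerate -> evaluate pipelines per value.

    ``varying`` is one of n / s / coverage / rho (simulation parameters) or
    ``epsilon`` (enumeration relaxation). With ``quality`` the valid trees of
    every solvable trial are enumerated and scored (A-D improvement against
    an equal number of random trees, plus solution topology); otherwise only
    existence is tested, which is much cheaper. ``count_trees`` additionally
    reports mean/max valid-tree counts over solvable trials.
    """
    if varying not in _CFG_PARAMS | {"epsilon"}:
        raise ValueError(f"cannot vary {varying!r}")
    defaults = defaults or SimulationConfig()
    result = SweepResult(varying, list(grid))
    for g, value in enumerate(result.grid):
        cfg_kwargs = {
            p: getattr(defaults, p) for p in _CFG_PARAMS
        }
        eps = epsilon
        if varying == "epsilon":
            eps = float(value)
        else:
            cfg_kwargs[varying] = value
        cfg = SimulationConfig(seed=defaults.seed, **cfg_kwargs)
        row = _run_point(
            cfg, trials, seed, g, eps, ptr_k, quality, count_trees, cap, mode
        )
        row[varying] = value
        result.rows.append(row)
    return result


def _run_point(
    cfg: SimulationConfig,
    trials: int,
    seed: int,
    point: int,
    epsilon: float,
    ptr_k: int | None,
    quality: bool,
    count_trees: bool,
    cap: int,
    mode: str = "strict",
) -> dict:
    if mode not in ("strict", "approx"):
        raise ValueError("mode must be 'strict' or 'approx'")
    solvable = 0
    skipped = 0
    improvements: list[float] = []
    counts: list[float] = []
    sol_leaves: list[float] = []
    sol_heights: list[float] = []
    truth_heights: list[float] = []
    truth_leaves: list[float] = []
    for t in range(trials):
        rng = _trial_rng(seed, point, t)
        gt = simulate_trial(cfg, rng)
        adj = strict_adjacency(gt.F.values)
        root = select_root(adj, gt.F.values)
        if mode == "approx":
            # complete ancestry graph: the relaxed sum condition alone decides
            adj = ~np.eye(cfg.n, dtype=bool)
        if ptr_k is not None and ptr_k >= 2:
            if has_tie_cycle(adj):
                skipped += 1
                continue
            adj = closed_dag_ptr(adj, ptr_k)
        truth_anc = truth_anc_masks(gt)
        truth_heights.append(np.bitwise_count(truth_anc).max())
        truth_leaves.append(
            cfg.n - len(set(int(p) for p in gt.tree.to_parent_array(gt.F.mutation_ids) if p >= 0))
        )
        if quality:
            res = run_dfs(
                adj, root, gt.F.values, epsilon, _fast.MODE_SCORE,
                cap=cap, truth_anc=truth_anc,
            )
            cnt = res[_fast.R_COUNT]
            if cnt == 0:
                continue
            solvable += 1
            counts.append(float(cnt))
            mean_ad = res[_fast.R_AD_SUM] / cnt
            ad_rand = random_baseline_ad(truth_anc, cfg.n, int(cnt), rng)
            if ad_rand > 0:  # degenerate only for tiny n
                improvements.append((ad_rand - mean_ad) / ad_rand)
            sol_leaves.append(res[_fast.R_LEAF_SUM] / cnt)
            sol_heights.append(res[_fast.R_HEIGHT_SUM] / cnt)
        elif count_trees:
            res = run_dfs(adj, root, gt.F.values, epsilon, _fast.MODE_COUNT, cap=cap)
            cnt = res[_fast.R_COUNT]
            if cnt > 0:
                solvable += 1
                counts.append(float(cnt))
        else:
            res = run_dfs(adj, root, gt.F.values, epsilon, _fast.MODE_EXISTS, cap=cap)
            if res[_fast.R_COUNT] > 0:
                solvable += 1
    row = {
        "trials": trials,
        "skipped": skipped,
        "solvable": solvable,
        "solvable_fraction": solvable / trials if trials else float("nan"),
        "mean_ad_improvement": float(np.mean(improvements)) if improvements else float("nan"),
        "mean_truth_height": float(np.mean(truth_heights)) if truth_heights else float("nan"),
        "mean_truth_leaves": float(np.mean(truth_leaves)) if truth_leaves else float("nan"),
    }
    if counts:
        row["mean_tree_count"] = float(np.mean(counts))
        row["max_tree_count"] = int(max(counts))
    elif quality or count_trees:
        row["mean_tree_count"] = float("nan")
        row["max_tree_count"] = 0
    if sol_leaves:
        row["mean_solution_leaves"] = float(np.mean(sol_leaves))
        row["mean_solution_height"] = float(np.mean(sol_heights))
    return row


# ---------------------------------------------------------------------------
# rank analysis on the approximate ancestry graph
# ---------------------------------------------------------------------------

@dataclass
class RankResult:
    """Per-rank aggregates over trials with enough valid spanning trees."""

    ranks: np.ndarray
    mean_ad: np.ndarray
    mean_height: np.ndarray
    mean_leaves: np.ndarray
    mean_single_child_fraction: np.ndarray
    mean_subtree_height: np.ndarray
    n_qualifying: int
    n_trials: int
    mean_underlying_height: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "mean_ad": self.mean_ad,
                "mean_height": self.mean_height,
                "mean_leaves": self.mean_leaves,
                "mean_single_child_fraction": self.mean_single_child_fraction,
                "mean_subtree_height": self.mean_subtree_height,
            }
        )


def _row_topology(parent: np.ndarray, n: int) -> tuple[int, int, float, float]:
    anc = _fast.ancestor_mask_array(parent.astype(np.int64))
    depths = np.bitwise_count(anc)
    nkids = np.bincount(parent[parent >= 0], minlength=n)
    sub_h = np.zeros(n)
    for u in range(n):
        desc = (anc >> u) & 1 == 1
        if desc.any():
            sub_h[u] = (depths[desc] - depths[u]).max()
    return (
        int(depths.max()),
        int((nkids == 0).sum()),
        float((nkids == 1).sum() / n),
        float(sub_h.mean()),
    )


def rank_analysis(
    trials: int,
    min_trees: int = 100,
    top_k: int = 100,
    defaults: SimulationConfig | None = None,
    seed: int = 0,
    epsilon: float = 0.0,
    cap: int = DEFAULT_CAP,
) -> RankResult:
    """Relate tree weight rank in the approximate ancestry graph to quality.

    Keeps trials with at least ``min_trees`` valid spanning trees, sorts each
    trial's valid trees by descending product-of-edge-probability weight
    (rank 1 = max weight) and aggregates mean A-D distance to the underlying
    tree plus topology metrics per rank. At ``epsilon = 0`` the valid trees
    of the complete approximate graph coincide with those of the strict
    graph, so enumeration runs on the strict graph and only the beta edge
    weights of its edges are computed.
    """
    if min_trees < top_k:
        raise ValueError("min_trees must be at least top_k")
    defaults = defaults or SimulationConfig()
    n = defaults.n
    ad_sum = np.zeros(top_k)
    h_sum = np.zeros(top_k)
    l_sum = np.zeros(top_k)
    sc_sum = np.zeros(top_k)
    sh_sum = np.zeros(top_k)
    under_h = []
    qualifying = 0
    for t in range(trials):
        rng = _trial_rng(seed, 0, t)
        gt = simulate_trial(defaults, rng)
        adj = strict_adjacency(gt.F.values)
        root = select_root(adj, gt.F.values)
        parents, _ = materialize_valid(adj, root, gt.F.values, epsilon, cap)
        if len(parents) < min_trees:
            continue
        qualifying += 1
        pairs = np.argwhere(adj)
        W = ancestral_probability_matrix(gt.reads.variant, gt.reads.total, pairs)
        logw = tree_log_weights(parents, W)
        top = np.lexsort((np.arange(len(parents)), -logw))[:top_k]
        truth_anc = truth_anc_masks(gt)
        under_h.append(int(np.bitwise_count(truth_anc).max()))
        for r, idx in enumerate(top):
            parent = parents[idx].astype(np.int64)
            anc = _fast.ancestor_mask_array(parent)
            ad_sum[r] += int(np.bitwise_count(anc ^ truth_anc).sum())
            hh, ll, sc, sh = _row_topology(parent, n)
            h_sum[r] += hh
            l_sum[r] += ll
            sc_sum[r] += sc
            sh_sum[r] += sh
    if qualifying == 0:
        raise ValueError("no trial reached the min_trees threshold")
    q = qualifying
    return RankResult(
        ranks=np.arange(1, top_k + 1),
        mean_ad=ad_sum / q,
        mean_height=h_sum / q,
        mean_leaves=l_sum / q,
        mean_single_child_fraction=sc_sum / q,
        mean_subtree_height=sh_sum / q,
        n_qualifying=q,
        n_trials=trials,
        mean_underlying_height=float(np.mean(under_h)),
    )


# ---------------------------------------------------------------------------
# partial transitive reduction analysis
# ---------------------------------------------------------------------------

def ptr_analysis(
    trials: int,
    ks,
    defaults: SimulationConfig | None = None,
    seed: int = 0,
    epsilon: float = 0.0,
    quality: bool = True,
    cap: int = DEFAULT_CAP,
) -> pd.DataFrame:
    """Effect of k-PTR pruning on the strict-graph pipeline.

    For each trial the same simulated dataset is analyzed unpruned and after
    every requested k-PTR. Reports, per k (``None`` = unpruned): the solvable
    fraction, mean A-D improvement over solvable trials, mean/max spanning-
    arborescence counts (in-degree product) and mean solution topology.
    Trials whose strict graph has tie-induced cycles are skipped and counted.
    """
    defaults = defaults or SimulationConfig()
    ks = list(ks)
    levels: list[int | None] = [None] + ks
    acc = {
        k: {
            "solvable": 0,
            "improvements": [],
            "span_counts": [],
            "span_counts_solvable": [],
            "sol_leaves": [],
            "sol_heights": [],
        }
        for k in levels
    }
    skipped = 0
    used = 0
    for t in range(trials):
        rng = _trial_rng(seed, 0, t)
        gt = simulate_trial(defaults, rng)
        adj = strict_adjacency(gt.F.values)
        if has_tie_cycle(adj):
            skipped += 1
            continue
        used += 1
        root = select_root(adj, gt.F.values)
        truth_anc = truth_anc_masks(gt)
        for k in levels:
            a = adj if k is None else closed_dag_ptr(adj, k)
            st = acc[k]
            span = spanning_count(a, root)
            st["span_counts"].append(span)
            if quality:
                res = run_dfs(
                    a, root, gt.F.values, epsilon, _fast.MODE_SCORE,
                    cap=cap, truth_anc=truth_anc,
                )
                cnt = res[_fast.R_COUNT]
                if cnt > 0:
                    st["solvable"] += 1
                    st["span_counts_solvable"].append(span)
                    mean_ad = res[_fast.R_AD_SUM] / cnt
                    ad_rand = random_baseline_ad(truth_anc, defaults.n, int(cnt), rng)
                    if ad_rand > 0:
                        st["improvements"].append((ad_rand - mean_ad) / ad_rand)
                    st["sol_leaves"].append(res[_fast.R_LEAF_SUM] / cnt)
                    st["sol_heights"].append(res[_fast.R_HEIGHT_SUM] / cnt)
            else:
                res = run_dfs(a, root, gt.F.values, epsilon, _fast.MODE_EXISTS, cap=cap)
                if res[_fast.R_COUNT] > 0:
                    st["solvable"] += 1
                    st["span_counts_solvable"].append(span)
    rows = []
    for k in levels:
        st = acc[k]
        rows.append(
            {
                "k": "none" if k is None else k,
                "trials": trials,
                "skipped": skipped,
                "used": used,
                "solvable": st["solvable"],
                "solvable_fraction": st["solvable"] / used if used else float("nan"),
                "mean_ad_improvement": float(np.mean(st["improvements"]))
                if st["improvements"]
                else float("nan"),
                "mean_spanning_count": float(np.mean(st["span_counts"]))
                if st["span_counts"]
                else float("nan"),
                "max_spanning_count": int(max(st["span_counts"]))
                if st["span_counts"]
                else 0,
                # counts conditioned on that k's own solvable trials, which is
                # how pruning effectiveness is reported downstream
                "mean_spanning_count_solvable": float(np.mean(st["span_counts_solvable"]))
                if st["span_counts_solvable"]
                else float("nan"),
                "max_spanning_count_solvable": int(max(st["span_counts_solvable"]))
                if st["span_counts_solvable"]
                else 0,
                "mean_solution_leaves": float(np.mean(st["sol_leaves"]))
                if st["sol_leaves"]
                else float("nan"),
                "mean_solution_height": float(np.mean(st["sol_heights"]))
                if st["sol_heights"]
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
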