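"""File formats, filtering and cluster aggregation.

All tabular formats are tab-separated text with a header row; trees travel
as edge-list TSV, JSON (round-trippable, carrying node labels and optional
weights) or DOT for rendering. Read counts use a long table with columns
``mutation_id``, ``sample_id``, ``variant_reads``, ``total_reads``; VAF
matrices are wide tables with one row per sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enumeration import SolutionSet
from .model import ClonalTree, ReadCountMatrix, VAFMatrix

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_vaf_tsv",
    "write_vaf_tsv",
    "read_tree_tsv",
    "write_tree_tsv",
    "tree_to_dict",
    "tree_from_dict",
    "write_solutions_json",
    "read_solutions_json",
    "tree_to_dot",
    "graph_to_dot",
    "write_graph_tsv",
    "filter_high_vaf",
    "aggregate_clusters",
    "read_cluster_tsv",
]


# -- read counts ------------------------------------------------------------

def read_counts_tsv(path) -> ReadCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str, "sample_id": str})
    required = {"mutation_id", "sample_id", "variant_reads", "total_reads"}
    if not required <= set(df.columns):
        raise ValueError(f"counts TSV needs columns {sorted(required)}")
    muts = list(dict.fromkeys(df["mutation_id"]))
    samples = list(dict.fromkeys(df["sample_id"]))
    v = df.pivot(index="sample_id", columns="mutation_id", values="variant_reads")
    r = df.pivot(index="sample_id", columns="mutation_id", values="total_reads")
    v = v.loc[samples, muts]
    r = r.loc[samples, muts]
    if v.isna().any().any() or r.isna().any().any():
        raise ValueError("counts TSV must cover every (sample, mutation) pair")
    return ReadCountMatrix(v.to_numpy(), r.to_numpy(), samples, muts)


def write_counts_tsv(R: ReadCountMatrix, path) -> None:
    rows = [
        {
            "mutation_id": m,
            "sample_id": s,
            "variant_reads": int(R.variant[i, j]),
            "total_reads": int(R.total[i, j]),
        }
        for j, m in enumerate(R.mutation_ids)
        for i, s in enumerate(R.sample_ids)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- VAF matrices -----------------------------------------------------------

def read_vaf_tsv(path) -> VAFMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return VAFMatrix(df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns])


def write_vaf_tsv(F: VAFMatrix, path) -> None:
    pd.DataFrame(F.values, index=F.sample_ids, columns=F.mutation_ids).rename_axis(
        "sample_id"
    ).to_csv(path, sep="\t")


# -- trees ------------------------------------------------------------------

def write_tree_tsv(tree: ClonalTree, path) -> None:
    pd.DataFrame(tree.edges(), columns=["parent", "child"]).to_csv(
        path, sep="\t", index=False
    )


def read_tree_tsv(path) -> ClonalTree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ClonalTree.from_edges(df[["parent", "child"]].itertuples(index=False))


def tree_to_dict(tree: ClonalTree, weight: float | None = None) -> dict:
    d = {
        "root": tree.root,
        "edges": [[p, c] for p, c in tree.edges()],
    }
    if tree.node_mutations is not None:
        d["node_labels"] = {str(v): list(ms) for v, ms in tree.node_mutations.items()}
    if weight is not None:
        d["weight"] = weight
    return d


def tree_from_dict(d: dict) -> ClonalTree:
    tree = ClonalTree.from_edges([tuple(e) for e in d["edges"]], root=d["root"])
    if "node_labels" in d:
        tree.node_mutations = {v: list(ms) for v, ms in d["node_labels"].items()}
    return tree


def write_solutions_json(solutions: SolutionSet, path) -> None:
    weights = solutions.weights or [None] * len(solutions.trees)
    payload = {
        "epsilon": solutions.epsilon_used,
        "truncated": solutions.truncated,
        "n_trees": len(solutions.trees),
        "trees": [tree_to_dict(t, w) for t, w in zip(solutions.trees, weights)],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_solutions_json(path) -> SolutionSet:
    payload = json.loads(Path(path).read_text())
    trees = [tree_from_dict(d) for d in payload["trees"]]
    weights = [d.get("weight") for d in payload["trees"]]
    return SolutionSet(
        trees,
        weights=None if any(w is None for w in weights) else weights,
        epsilon_used=payload.get("epsilon", 0.0),
        truncated=payload.get("truncated", False),
    )


# -- DOT / graph exports ----------------------------------------------------

def _dot_id(v) -> str:
    return '"' + str(v).replace('"', r"\"") + '"'


def tree_to_dot(tree: ClonalTree, weights: dict | None = None) -> str:
    lines = ["digraph clonal_tree {"]
    for v in tree.nodes:
        lines.append(f"  {_dot_id(v)};")
    for p, c in tree.edges():
        label = ""
        if weights and (p, c) in weights:
            label = f' [label="{weights[(p, c)]:.3f}"]'
        lines.append(f"  {_dot_id(p)} -> {_dot_id(c)}{label};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def graph_to_dot(G: nx.DiGraph) -> str:
    lines = ["digraph ancestry_graph {"]
    for v in G.nodes:
        lines.append(f"  {_dot_id(v)};")
    for u, v, data in G.edges(data=True):
        label = f' [label="{data["weight"]:.3f}"]' if "weight" in data else ""
        lines.append(f"  {_dot_id(u)} -> {_dot_id(v)}{label};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_graph_tsv(G: nx.DiGraph, path) -> None:
    rows = [
        {"src": u, "dst": v, "weight": data.get("weight", "")}
        for u, v, data in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["src", "dst", "weight"]).to_csv(path, sep="\t", index=False)


# -- filtering and clustering ----------------------------------------------

def filter_high_vaf(matrix, threshold: float = 0.5):
    """Drop every mutation whose VAF *exceeds* ``threshold`` in any sample
    (sites above 0.5 are suspect for copy-number distortion; exactly 0.5 is
    kept). Returns the filtered matrix and the removed mutation ids."""
    if isinstance(matrix, ReadCountMatrix):
        vafs = matrix.vaf_matrix().values
    elif isinstance(matrix, VAFMatrix):
        vafs = matrix.values
    else:
        raise TypeError("expected a ReadCountMatrix or VAFMatrix")
    keep = ~(vafs > threshold).any(axis=0)
    removed = [m for m, k in zip(matrix.mutation_ids, keep) if not k]
    if not keep.any():
        raise ValueError("filtering removed every mutation")
    kept_ids = [m for m, k in zip(matrix.mutation_ids, keep) if k]
    if isinstance(matrix, ReadCountMatrix):
        out = ReadCountMatrix(
            matrix.variant[:, keep], matrix.total[:, keep],
            list(matrix.sample_ids), kept_ids,
        )
    else:
        out = VAFMatrix(vafs[:, keep], list(matrix.sample_ids), kept_ids)
    return out, removed


def read_cluster_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mutation_id", "cluster_id"} <= set(df.columns):
        raise ValueError("cluster TSV needs columns mutation_id, cluster_id")
    return dict(zip(df["mutation_id"], df["cluster_id"]))


def aggregate_clusters(R: ReadCountMatrix, assign: dict) -> ReadCountMatrix:
    """Pool read counts of co-clustered mutations (summing variant and total
    counts per sample, so the cluster VAF is the depth-weighted mean). The
    assignment must cover every mutation; cluster order follows the first
    appearance of each cluster among the mutations."""
    unknown = set(assign) - set(R.mutation_ids)
    if unknown:
        raise ValueError(f"unknown mutation ids in assignment: {sorted(unknown)}")
    missing = [m for m in R.mutation_ids if m not in assign]
    if missing:
        raise ValueError(f"mutations without a cluster: {missing}")
    clusters = list(dict.fromkeys(assign[m] for m in R.mutation_ids))
    if not clusters:
        raise ValueError("empty cluster assignment")
    v = np.zeros((R.n_samples, len(clusters)), dtype=np.int64)
    r = np.zeros_like(v)
    col = {c: i for i, c in enumerate(clusters)}
    for j, m in enumerate(R.mutation_ids):
        v[:, col[assign[m]]] += R.variant[:, j]
        r[:, col[assign[m]]] += R.total[:, j]
    return ReadCountMatrix(v, r, list(R.sample_ids), clusters)
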