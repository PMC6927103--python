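"""Enumerate the clonal trees consistent with a tiny hand-written VAF matrix.

Three mutations observed in two samples: mutation m1 looks clonal (VAF 0.5
everywhere) while m2 and m3 swap order between samples, so neither can be
ancestral to the other. Only trees satisfying the sum condition survive.
"""

from vaffp import (
    VAFMatrix,
    build_strict_graph,
    check_sum_condition,
    enumerate_valid_trees,
    min_epsilon_search,
    usage_from_tree,
)

F = VAFMatrix(
    [[0.50, 0.28, 0.18],
     [0.50, 0.20, 0.27]],
    sample_ids=["biopsy_a", "biopsy_b"],
    mutation_ids=["m1", "m2", "m3"],
)

G = build_strict_graph(F)
print("ancestry graph edges:", sorted(G.edges), "root:", G.graph["designated_root"])

sols = enumerate_valid_trees(G, F, epsilon=0.0)
print(f"{len(sols)} valid clonal tree(s) at epsilon=0")
for t in sols.trees:
    ok, overflow = check_sum_condition(t, F)
    print("  edges:", t.edges(), " worst child-sum overflow:", round(overflow, 3))
    U = usage_from_tree(t, F)
    print("  population proportions per sample:", U.U.round(3).tolist())

print("smallest epsilon admitting a tree:", min_epsilon_search(G, F))
# The star m1 -> {m2, m3} is the only topology compatible with both samples:
# each population proportion row is nonnegative and sums to at most 1.
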