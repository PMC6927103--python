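# vaffp — clonal tree enumeration from bulk SNV frequencies

`vaffp` reconstructs candidate tumor evolutionary histories from
multi-sample bulk DNA sequencing of single-nucleotide variants, and
quantifies when such reconstruction is possible at all. It is aimed at
cancer genomicists and method developers who want to see the *whole space*
of phylogenies consistent with their variant allele frequencies (VAFs)
rather than a single point estimate, and at anyone designing sequencing
experiments (how much coverage? how many samples?) for downstream phylogeny
inference.

## The model

A tumor's history is a *clonal tree* `T`: a rooted tree whose nodes are cell
populations, each introducing one new mutation, with each population
carrying all mutations on its root path. Under the infinite sites
assumption (ISA), the observed `s x n` VAF matrix `F` factorizes as

```
F = ½ U B
```

where `B` is the binary population × mutation membership matrix of `T` and
`U` holds the per-sample population mixing proportions (the ½ because
mutations are heterozygous SNVs). A tree is consistent with `F` exactly
when it spans the **ancestry graph** — which has an edge `j → k` whenever
`F_ij ≥ F_ik` in every sample — and satisfies the **sum condition**

```
Σ_{k ∈ children(j)} F_ik  ≤  F_ij        for every sample i,
```

equivalently when `U = 2(F − F·children)` is nonnegative. The package:

- enumerates all such trees with a sum-condition-pruned Gabow–Myers-style
  search (with the in-degree-product formula as an upper bound on the
  arborescence count);
- relaxes the sum condition by an error threshold `ε` (`… ≤ F_ij + ε`) and
  finds the smallest feasible `ε` for noisy data;
- builds the **approximate ancestry graph**, the complete digraph whose edge
  `j → k` is weighted by `min_i Pr[X_ij ≥ X_ik]` with flat-prior beta
  posteriors `X_ij ~ Beta(v_ij + 1, r_ij − v_ij + 1)` on read counts, and
  ranks valid trees by their product-of-edge-probability weight;
- prunes `≥k`-transitive edges (the *k-partial transitive reduction*) to
  shrink the search space while preserving reachability;
- simulates ground-truth tumors (uniform-attachment random trees, uniform
  simplex clone proportions, Poisson depths, beta-binomial reads with
  overdispersion `ρ`) and scores reconstructions by ancestor–descendant
  (A-D) distance and the A-D improvement over a random-tree baseline.

## Worked example

`examples/01_enumerate_trees.py` builds a three-mutation, two-biopsy VAF
matrix in which `m1` looks clonal and `m2`/`m3` swap order between samples:

```
ancestry graph edges: [('m1', 'm2'), ('m1', 'm3')] root: m1
1 valid clonal tree(s) at epsilon=0
  edges: [('m1', 'm2'), ('m1', 'm3')]  worst child-sum overflow: -0.03
  population proportions per sample: [[0.08, 0.56, 0.36], [0.06, 0.4, 0.54]]
smallest epsilon admitting a tree: 0.0
```

Because `m2` and `m3` are incomparable across samples, the only consistent
topology is the branching tree `m1 → {m2, m3}`; the recovered `U` rows are
nonnegative, confirming the sum condition, and give the fraction of cells
in each biopsy belonging to each clone. The other example scripts cover
noisy-trial recovery (`02`), minimum-ε relaxation with weight-ranked trees
(`03`), transitive-edge pruning (`04`) and a coverage sweep (`05`); each
prints a short interpretation of its numbers. A thin CLI mirrors the
library (`vaffp simulate | enumerate | evaluate | sweep | ptr | rank`).

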