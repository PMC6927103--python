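# Methods

## Problem setting

Bulk sequencing of `s` tumor samples yields, for each of `n` SNVs, variant
and total read counts `v_ij`, `r_ij` and hence observed VAFs
`F_ij = v_ij / r_ij`. Assuming heterozygous SNVs in diploid regions and the
infinite sites assumption (ISA), every clonal tree `T` consistent with the
data factorizes `F = ½ U B` with `U ≥ 0`. The package enumerates the full
set of consistent trees — spanning arborescences of the ancestry graph that
satisfy the sum condition — rather than reporting one tree, because that
set is typically far from a singleton and its size and composition are
themselves the scientifically interesting output.

## Enumeration

Every non-root node of an ancestry graph must select exactly one incoming
edge. On a DAG any such selection is automatically a spanning arborescence
(hence the count of arborescences is the product of non-root in-degrees);
on graphs with 2-cycles (possible under exact VAF ties, since the ancestry
condition uses `≥`) an incremental walk-up cycle check rejects the bad
selections. The enumerator assigns parents in ascending node order, keeps a
running per-(parent, sample) child-frequency sum, and abandons a branch as
soon as any sum exceeds `F_ij + ε + 1e-12`; since child sums only grow,
this pruning is sound and the search visits exactly the valid trees. The
inner search is compiled with numba; ancestor sets are maintained as
bitmasks (`n ≤ 62`), which makes per-tree ancestor–descendant scoring a
handful of XOR/popcount operations. A cap (default 10⁶ trees, flagged via
`truncated`) bounds enumeration on adversarial inputs, whose arborescence
counts grow super-exponentially.

`min_epsilon_search` finds the smallest `ε` admitting one valid tree by
branch-and-bound over the same space: the partial maximum overflow is
monotone along a branch, so branches at or above the incumbent are cut.
The result is exact (no bisection), so the `tol` argument is honored
trivially.

Ranked enumeration on the probability-weighted complete graph materializes
the valid set and sorts by total log edge weight (log-space products avoid
underflow; equal weights are broken by lexicographic parent-vector order so
results are reproducible). At the problem sizes this package targets
(n ≤ 12) full enumeration is faster and simpler than a k-best arborescence
scheme.

## Edge probabilities

The approximate ancestry graph weights edge `j → k` by
`min_i Pr[X_ij ≥ X_ik]`, `X_ij ~ Beta(v_ij + 1, r_ij − v_ij + 1)` (flat
prior). With integer parameters the tail probability has an exact finite
sum, evaluated in log space with `betaln`; the shorter of the two
complementary sums is used. Accuracy is limited only by floating point
(validated at ~1e-13 against quadrature, and against Monte Carlo in the
tests), comfortably inside the 1e-6 contract.

## Partial transitive reduction

An edge `(u, v)` is pruned by the k-PTR when the shortest `u → v` path in
the transitive reduction `R` has length ≥ k; distances come from one BFS
per node on `R`. This operational rule (rather than "some path of length
≥ k exists in G") is the one that makes 2-PTR coincide exactly with the
classical transitive reduction and yields the nesting
`R ⊆ k-PTR ⊆ (k+1)-PTR ⊆ G`. The general implementation delegates the
reduction itself to networkx; the experiment driver uses an array fast
path valid for strict ancestry graphs, which are transitively closed
(`F_j ≥ F_k ≥ F_l` pointwise implies `F_j ≥ F_l`), and the two are
cross-checked in the tests. Strict graphs with tie-induced 2-cycles are not
DAGs; such trials are counted and skipped in PTR analyses, and the API
raises with a suggestion to perturb or merge the tied mutations.

## Simulator

A trial draws (1) a uniform-attachment random tree — clone `t` attaches to
a uniform earlier clone, one new mutation per clone, so `n` clones equal
`n` mutations; (2) clone proportions `u` uniform on the simplex
(Dirichlet(1,…,1)); (3) mutation frequencies `f = ½ u B`, so the founder
mutation sits at exactly 0.5 and `f` satisfies the sum condition with zero
slack (the generator itself always respects the ISA — every downstream
violation is noise-induced); (4) per sample and site, depth
`r ~ Poisson(c)` and variant reads `v ~ Binomial(r, p)` with `p = f_j` when
`ρ = 0`, otherwise a fresh `p ~ Beta(f_j(1−ρ)/ρ, (1−f_j)(1−ρ)/ρ)` per
(sample, site) — the standard per-observation beta-binomial reading, since
sharing one draw across samples would correlate samples beyond what a
"completely mixed tumor" model intends. Degenerate `f ∈ {0, 1}` stays a
point mass. Zero-depth sites report VAF 0 with a logged warning; they are
rare at the coverages studied and any constant convention only perturbs
tie-breaking. Defaults (n=10, s=5, c=60, ρ=0) are the study's default
conditions. Each trial owns the RNG stream `[seed, grid-point, trial]`, so
sweeps are reproducible and order-independent.

What the simulator deliberately omits: regional/sample-specific clone
mixtures, copy-number events, driver/passenger structure, and mutation
clustering error. Passing tests therefore demonstrate correct behavior
under ISA-respecting, completely mixed, heterozygous-SNV data — not
robustness to real tumors' full complexity.

## Evaluation

Trees with identical label sets are compared by the ancestor–descendant
distance: the size of the symmetric difference of their
(ancestor, descendant) pair sets, unnormalized. The A-D improvement of a
solution set is `(AD(random) − AD(solutions)) / AD(random)` where the
baseline is an equal number (capped at 10⁴, estimating by sampling beyond)
of uniform-attachment trees built over a uniformly random insertion order
of the labels. The random order matters: the simulator's truth trees root
at the first label by construction, and a baseline sharing that root would
already encode the founder mutation and roughly quarter the measured
improvement. Topology metrics (height, leaf count, single-child fraction
over all nodes, mean subtree height) characterize branching versus linear
shapes; any fixed single-child denominator preserves the monotone trends
the analyses rely on.

## Experiment drivers and problem sizes

`run_sweep` varies one parameter (n, s, coverage, ρ, or the relaxation ε)
and aggregates solvability, conditional A-D improvement, and valid-tree
counts; relaxed-ε experiments run on the complete (approximate) graph,
where the relaxation can actually admit new topologies. `rank_analysis`
keeps trials with ≥ 100 valid trees, ranks by weight and aggregates
per-rank distance and topology; since the valid sets at ε=0 coincide
between the strict and complete graphs, it enumerates the strict graph and
computes beta weights only for its edges. `ptr_analysis` reruns the strict
pipeline per pruning level on identical trials, reporting per-k solvability
and spanning counts both unconditioned and conditioned on that k's solvable
trials (the conditional versions are what pruning-effectiveness summaries
use, as unsolvable trials never pay the enumeration cost being saved).

`scripts/acceptance.py` runs every experiment at 10000 trials (a few
minutes total on one CPU thanks to the compiled kernel); the test suite
uses 1000–8000 trials per check with tolerances widened by a 3σ binomial
margin for the reduced replication. Heavy-tailed statistics (mean and
especially max tree counts) get proportionally wider bands.

## Known limitations

- The in-degree-product count and the PTR machinery require DAGs; exact VAF
  ties are handled in enumeration but excluded from counting/pruning.
- Root choice on noisy graphs (unique source, else maximum total VAF) is a
  heuristic; with very high noise the designated root can differ from the
  truth and the valid set may be empty even at large ε.
- Tree weights are ancestry probabilities used as parent-edge weights, so
  high-weight trees are systematically biased toward wide, shallow
  topologies; the rank analyses quantify rather than correct this.
- No copy-number-aware or multi-allelic modeling; mutations above VAF 0.5
  should be filtered out (`filter_high_vaf`) before analysis.
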