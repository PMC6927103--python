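"""Simulation of ground-truth clonal trees and noisy multi-sample read counts.

A trial proceeds in four steps: (1) grow a uniform-attachment random tree —
each new clone becomes the child of a uniformly chosen existing clone, and
carries exactly one new somatic mutation, so clones and mutations coincide;
(2) draw the clone proportions ``u`` uniformly from the simplex; (3) derive
the mutation frequencies ``f = (1/2) u B`` (the root mutation always sits at
frequency 1/2); (4) per sample and site, draw a Poisson depth at the mean
coverage and binomial variant reads at success probability ``f_j`` — or, with
overdispersion ``rho > 0``, at a fresh beta-distributed probability with mean
``f_j`` and shape ``alpha = f_j (1 - rho) / rho``, ``beta = (1 - f_j)
(1 - rho) / rho``, inflating the read-count variance beyond binomial.

The tumor is modeled as completely mixed: every sample shares the same
expected composition, so all variation across samples comes from read
sampling and overdispersion. The generated frequencies always satisfy the
sum condition exactly, i.e. the simulation itself respects the infinite
sites assumption; violations observed downstream are purely noise-induced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ClonalMatrix, ClonalTree, ReadCountMatrix, VAFMatrix, clonal_matrix_from_tree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "random_tree",
    "sample_clone_frequencies",
    "mutation_frequencies",
    "simulate_reads",
    "simulate_trial",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    n: number of clones (= mutations); s: number of samples; coverage: mean
    sequencing depth per site; rho: beta-binomial overdispersion in [0, 1),
    with 0 meaning pure binomial sampling; seed: RNG seed.
    """

    n: int = 10
    s: int = 5
    coverage: float = 60.0
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.s < 1 or self.coverage < 0:
            raise ValueError("need n >= 1, s >= 1, coverage >= 0")
        if not 0 <= self.rho < 1:
            raise ValueError("overdispersion rho must lie in [0, 1)")


@dataclass
class GroundTruth:
    """One simulated trial: the underlying tree and everything derived from it."""

    tree: ClonalTree
    u: np.ndarray
    f: np.ndarray
    reads: ReadCountMatrix
    F: VAFMatrix


def random_parent_array(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-attachment recursive tree as a parent-index array (root = -1)."""
    parents = np.full(n, -1, dtype=np.int64)
    if n > 1:
        # vertex t (1-based t+1) picks its parent uniformly among 0..t-1
        parents[1:] = rng.integers(0, np.arange(1, n))
    return parents


def random_tree(n: int, rng: np.random.Generator, labels=None) -> ClonalTree:
    """Random recursive tree on ``n`` nodes: node t attaches to a parent
    chosen uniformly among the t-1 earlier nodes; node 1 is the root."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return ClonalTree.from_parent_array(
        random_parent_array(n, rng),
        labels if labels is not None else [f"m{j + 1}" for j in range(n)],
    )


def sample_clone_frequencies(n: int, rng: np.random.Generator) -> np.ndarray:
    """Clone proportions drawn uniformly from the (n-1)-simplex."""
    return rng.dirichlet(np.ones(n))


def mutation_frequencies(u: np.ndarray, B: ClonalMatrix) -> np.ndarray:
    """Expected VAFs ``f = (1/2) u B``; the root mutation is always 1/2."""
    u = np.asarray(u, dtype=float)
    if abs(u.sum() - 1.0) > 1e-9:
        raise ValueError("clone frequencies must sum to 1")
    return 0.5 * u @ B.B


def simulate_reads(
    f: np.ndarray,
    s: int,
    coverage: float,
    rho: float,
    rng: np.random.Generator,
    sample_ids=None,
    mutation_ids=None,
) -> tuple[ReadCountMatrix, VAFMatrix]:
    """Draw read counts for ``s`` samples at the given mutation frequencies.

    Depth is Poisson(coverage) per site; variant reads are binomial with
    success probability ``f_j`` (``rho = 0``) or a fresh Beta draw with mean
    ``f_j`` per (sample, site) pair (``rho > 0``). Degenerate frequencies 0
    and 1 are kept as point masses.
    """
    f = np.asarray(f, dtype=float)
    n = f.shape[0]
    if f.size and (f.min() < 0 or f.max() > 1):
        raise ValueError("mutation frequencies must lie in [0, 1]")
    total = rng.poisson(coverage, size=(s, n))
    if rho > 0:
        scale = (1.0 - rho) / rho
        p = np.broadcast_to(f, (s, n)).astype(float).copy()
        interior = (f > 0) & (f < 1)
        if interior.any():
            alpha = scale * f[interior]
            beta = scale * (1.0 - f[interior])
            p[:, interior] = rng.beta(alpha, beta, size=(s, int(interior.sum())))
    else:
        p = np.broadcast_to(f, (s, n))
    variant = rng.binomial(total, p)
    reads = ReadCountMatrix(variant, total, sample_ids or [], mutation_ids or [])
    return reads, reads.vaf_matrix()


def simulate_trial(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Run the full four-step generator; reproducible from ``cfg.seed``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = [f"m{j + 1}" for j in range(cfg.n)]
    tree = random_tree(cfg.n, rng, labels)
    B = clonal_matrix_from_tree(tree, labels)
    u = sample_clone_frequencies(cfg.n, rng)
    f = mutation_frequencies(u, B)
    reads, F = simulate_reads(
        f, cfg.s, cfg.coverage, cfg.rho, rng, mutation_ids=labels
    )
    return GroundTruth(tree=tree, u=u, f=f, reads=reads, F=F)
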