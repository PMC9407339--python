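"""Continuous-time random walks, Markov stability, and the multiscale
Laplacian score.

A continuous-time random walker on the cell graph follows
``P(t) = exp(-t L_rw)``; small Markov times t probe local neighbourhoods,
large t global structure.  Markov stability scores a partition by the
probability that a stationary walker stays inside its community over time
t, minus the chance co-occurrence of two independent walkers; maximizing
it (Louvain) at a grid of times yields partitions at every scale, and
local minima of the mean pairwise variation of information across
repeated optimizations mark the robust scales.  The multiscale Laplacian
score (MLS) of a gene g at resolution t,

    MLS(g, t) = sum_{u,v} d_u P(t)_uv (g(u) - g(v))^2 / (2 Var_G(g)),

is the expected squared change in g seen by a stationary walker over time
t, normalized by the graph variance: the Laplacian score generalized from
a single step to a diffusion scale (it is 0 at t = 0 and tends to 1 as
t -> infinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._louvain import louvain_dense, partition_quality
from .graph import (
    CellGraph,
    ConstantSignalError,
    GeneSignalSet,
    GraphTopologyError,
    laplacian,
)

__all__ = [
    "TransitionKernel",
    "Partition",
    "StabilityProfile",
    "MLSMatrix",
    "HeatKernel",
    "stationary_distribution",
    "heat_kernel",
    "markov_stability",
    "optimize_partition",
    "variation_of_information",
    "scan_scales",
    "default_time_grid",
    "mls",
]

#: numerical slack below which negative kernel entries are clipped to zero
_KERNEL_SLACK = 1e-12

#: relative depth a VI plateau must sit below the global VI maximum
_VI_DEPTH = 0.01


def stationary_distribution(G: CellGraph) -> np.ndarray:
    """Stationary distribution ``pi_v = d_v / sum_u d_u`` of the walk.

    Unique only on connected graphs; disconnected graphs are rejected
    (apply per component instead).
    """
    if not G.is_connected():
        raise GraphTopologyError(
            "stationary distribution is not unique on a disconnected graph; "
            "apply per connected component"
        )
    return G.degrees / G.total_weight


class HeatKernel:
    """Factory for ``P(t) = exp(-t L_rw)``, sharing one eigendecomposition.

    ``L_rw`` is conjugate to the symmetric normalized Laplacian via
    ``D^{1/2}``, so a single symmetric eigendecomposition serves every
    Markov time: ``P(t) = D^{-1/2} U e^{-t Lambda} U^T D^{1/2}``.
    """

    def __init__(self, G: CellGraph):
        self.graph = G
        self.degrees = G.degrees
        self.pi = G.degrees / G.total_weight
        self._sqrt_d = np.sqrt(G.degrees)
        Lsym = laplacian(G, "normalized").toarray()
        lam, U = np.linalg.eigh(Lsym)
        self._lam = np.maximum(lam, 0.0)
        self._U = U

    def matrix(self, t: float) -> np.ndarray:
        """Dense row-stochastic transition matrix P(t)."""
        if t < 0:
            raise ValueError(f"Markov time must be non-negative, got {t}")
        decay = np.exp(-t * self._lam)
        left = (self._U * decay[None, :]) / self._sqrt_d[:, None]
        P = left @ (self._U.T * self._sqrt_d[None, :])
        P[(P < 0) & (P > -_KERNEL_SLACK)] = 0.0
        np.maximum(P, 0.0, out=P)
        return P

    def quality_matrix(self, t: float) -> np.ndarray:
        """Symmetrized Markov-stability quality matrix
        ``B = sym(diag(pi) P(t)) - pi pi^T``."""
        M = self.pi[:, None] * self.matrix(t)
        B = (M + M.T) * 0.5
        B -= np.outer(self.pi, self.pi)
        return B


@dataclass
class TransitionKernel:
    """Row-stochastic continuous-time transition matrix at one Markov time."""

    time: float
    matrix: np.ndarray

    def __post_init__(self):
        rows = self.matrix.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-8:
            raise ValueError("transition matrix rows do not sum to 1")
        if self.matrix.min() < -_KERNEL_SLACK:
            raise ValueError("transition matrix has negative entries")


def heat_kernel(G: CellGraph, t: float) -> TransitionKernel:
    """Transition kernel ``P(t) = exp(-t L_rw)`` of the walk on ``G``."""
    return TransitionKernel(time=float(t), matrix=HeatKernel(G).matrix(t))


@dataclass
class Partition:
    """Partition of the nodes into non-empty communities (labels 0..k-1)."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D integer array")
        uniq = np.unique(self.labels)
        if uniq[0] < 0:
            raise ValueError("labels must be non-negative")
        # compact labels so every community 0..k-1 is non-empty
        self.labels = np.searchsorted(uniq, self.labels)

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)

    def canonical(self) -> np.ndarray:
        """Labels renumbered by first occurrence (permutation-invariant form)."""
        _, first = np.unique(self.labels, return_index=True)
        order = np.argsort(np.argsort(first))
        return order[self.labels]

    def same_as(self, other: "Partition") -> bool:
        """Equality up to permutation of community labels."""
        if self.n_nodes != other.n_nodes:
            return False
        return bool(np.array_equal(self.canonical(), other.canonical()))


def markov_stability(G: CellGraph, partition: Partition, t: float,
                     kernel: HeatKernel | None = None) -> float:
    """Continuous Markov stability
    ``sum_{u,v} (pi_u P(t)_uv - pi_u pi_v) delta(c_u, c_v)`` in (-1/2, 1]."""
    if partition.n_nodes != G.n_nodes:
        raise ValueError("partition does not cover the graph's nodes")
    kernel = kernel if kernel is not None else HeatKernel(G)
    return partition_quality(kernel.quality_matrix(t), partition.labels)


def optimize_partition(G: CellGraph, t: float, runs: int = 20, seed: int = 0,
                       kernel: HeatKernel | None = None):
    """Louvain maximization of Markov stability at time ``t``.

    Runs ``runs`` independent seeded restarts (random node orders) and
    returns a list of ``(Partition, stability)`` pairs, one per run, each a
    local maximum under single-node moves.  Deterministic for fixed seed.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    kernel = kernel if kernel is not None else HeatKernel(G)
    B = kernel.quality_matrix(t)
    out = []
    for r in range(runs):
        rng = np.random.default_rng([seed, r])
        labels = louvain_dense(B, rng)
        out.append((Partition(labels), partition_quality(B, labels)))
    return out


def variation_of_information(P: Partition, Q: Partition) -> float:
    """Variation of information between two partitions, in bits.

    ``VI = 2 H(P, Q) - H(P) - H(Q)`` with base-2 entropies of the community
    occupancy distributions.  A metric: symmetric, zero iff the partitions
    agree up to relabeling, and satisfying the triangle inequality.
    """
    if P.n_nodes != Q.n_nodes:
        raise ValueError(
            f"partitions cover different node sets ({P.n_nodes} vs {Q.n_nodes})"
        )
    n = P.n_nodes

    def entropy(counts):
        p = counts / n
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    joint = np.unique(
        P.labels.astype(np.int64) * (Q.labels.max() + 1) + Q.labels,
        return_counts=True,
    )[1]
    vi = 2.0 * entropy(joint) - entropy(np.bincount(P.labels)) - entropy(
        np.bincount(Q.labels)
    )
    return max(vi, 0.0)


def default_time_grid(t_min: float = 1e-2, t_max: float = 1e2,
                      n_times: int = 100) -> np.ndarray:
    """Logarithmically spaced Markov-time grid (default 100 times over
    [1e-2, 1e2])."""
    return np.logspace(np.log10(t_min), np.log10(t_max), n_times)


@dataclass
class StabilityProfile:
    """Result of a Markov-stability scale scan.

    Per Markov time: the best (max-stability) partition over the repeated
    Louvain runs, its stability, its community count, and the mean pairwise
    VI across the runs.  ``selected_indices`` are the interior local minima
    of the VI curve (plateau midpoints); ``successive_vi[i]`` is the
    diagnostic VI between the best partitions at times i and i+1.
    """

    times: np.ndarray
    partitions: list = field(repr=False)
    stabilities: np.ndarray
    n_communities: np.ndarray
    mean_vi: np.ndarray
    successive_vi: np.ndarray = field(repr=False)
    selected_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def selected_scales(self) -> np.ndarray:
        return self.times[self.selected_indices]

    def selected_partitions(self):
        return [self.partitions[i] for i in self.selected_indices]


def _select_vi_minima(vi: np.ndarray, n_communities: np.ndarray,
                      tol: float = 1e-9, min_width: int = 3) -> np.ndarray:
    """Indices of plateau midpoints at local minima of the VI curve.

    A plateau is a maximal run of times with equal VI (within ``tol``) and
    an unchanged community count of the best partition.  It is selected
    when (a) neither neighbouring value outside the run is smaller (grid
    boundaries count as satisfied; an adjacent plateau at the same minimal
    VI but a different community count is a distinct robust scale and does
    not disqualify it), (b) its value sits below ``(1 - 0.01) * max(VI)``,
    and (c) it persists for at least ``min_width`` grid points -- robust
    scales occupy intervals of the Markov-time axis, whereas transition
    states between scales are short-lived.  A plateau spanning the whole
    grid (globally flat curve with one stable partition, e.g. a complete
    graph) yields the largest time.
    """
    m = len(vi)
    vmax = float(vi.max())
    thresh = vmax * (1.0 - _VI_DEPTH) if vmax > tol else tol
    selected = []
    start = 0
    while start < m:
        end = start
        while (end + 1 < m and abs(vi[end + 1] - vi[start]) <= tol
               and n_communities[end + 1] == n_communities[start]):
            end += 1
        val = vi[start]
        whole_grid = start == 0 and end == m - 1
        left_ok = start == 0 or vi[start - 1] >= val - tol
        right_ok = end == m - 1 or vi[end + 1] >= val - tol
        wide_enough = (end - start + 1) >= min(min_width, m)
        if left_ok and right_ok and wide_enough and not whole_grid and val <= thresh:
            selected.append((start + end) // 2)
        start = end + 1
    if not selected:
        return np.array([m - 1], dtype=int)
    return np.asarray(selected, dtype=int)


def scan_scales(G: CellGraph, times=None, runs: int = 20,
                seed: int = 0) -> StabilityProfile:
    """Scan Markov times for robust partition scales.

    At each time the quality matrix is optimized by ``runs`` seeded Louvain
    restarts; the max-stability partition is retained and the mean pairwise
    VI across runs measures the robustness of the scale.  Scales are the
    local minima of the VI curve.
    """
    if runs < 2:
        raise ValueError("runs must be >= 2 (pairwise VI is undefined otherwise)")
    times = default_time_grid() if times is None else np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a non-empty strictly ascending grid")
    kernel = HeatKernel(G)
    best_parts, stabilities, n_comms, mean_vi = [], [], [], []
    for ti, t in enumerate(times):
        results = optimize_partition(G, t, runs=runs, seed=seed + ti, kernel=kernel)
        values = [v for _, v in results]
        best = int(np.argmax(values))
        best_parts.append(results[best][0])
        stabilities.append(values[best])
        n_comms.append(results[best][0].n_communities)
        pair_vi = [
            variation_of_information(results[a][0], results[b][0])
            for a in range(runs)
            for b in range(a + 1, runs)
        ]
        mean_vi.append(float(np.mean(pair_vi)))
    successive = np.array(
        [
            variation_of_information(best_parts[i], best_parts[i + 1])
            for i in range(len(times) - 1)
        ]
    )
    mean_vi = np.asarray(mean_vi)
    return StabilityProfile(
        times=times,
        partitions=best_parts,
        stabilities=np.asarray(stabilities),
        n_communities=np.asarray(n_comms, dtype=int),
        mean_vi=mean_vi,
        successive_vi=successive,
        selected_indices=_select_vi_minima(mean_vi, np.asarray(n_comms)),
    )


@dataclass
class MLSMatrix:
    """Multiscale Laplacian scores: genes x selected Markov times."""

    gene_ids: np.ndarray
    times: np.ndarray
    scores: np.ndarray


def mls(signals: GeneSignalSet, G: CellGraph, times,
        kernel: HeatKernel | None = None) -> MLSMatrix:
    """Multiscale Laplacian score of every gene at every requested time.

    Uses the identity ``sum_{u,v} d_u P(t)_uv (g_u - g_v)^2 =
    2 (g' D g - g' W(t) g)`` with ``W(t) = diag(d) P(t)`` (symmetric by
    detailed balance), so each time costs one dense matrix product.
    """
    signals.check_matches(G)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("Markov times must be non-negative")
    kernel = kernel if kernel is not None else HeatKernel(G)
    V = signals.values
    d = G.degrees
    mu = (V @ d) / G.total_weight
    var = ((V - mu[:, None]) ** 2) @ d
    zero = var <= 0
    if np.any(zero):
        raise ConstantSignalError(
            "MLS undefined for constant signals: "
            f"{signals.gene_ids[np.flatnonzero(zero)[:10]].tolist()}"
        )
    term_d = (V**2) @ d
    scores = np.empty((signals.n_genes, len(times)))
    for j, t in enumerate(times):
        W = d[:, None] * kernel.matrix(t)
        cross = np.einsum("gi,gi->g", V, V @ W.T)
        scores[:, j] = np.maximum(term_d - cross, 0.0) / var
    return MLSMatrix(gene_ids=signals.gene_ids.copy(), times=times, scores=scores)
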