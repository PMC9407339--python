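"""Weighted cell-similarity graphs and single-scale signal scores.

A cell similarity graph is an undirected, non-negatively weighted graph whose
nodes are cells and whose edge weights encode transcriptional similarity
(typically a k-nearest-neighbour graph built from a reduced expression
matrix).  A gene is a *graph signal*: a real-valued function on the nodes.
This module provides the graph container (:class:`CellGraph`), the signal
container (:class:`GeneSignalSet`), k-nn graph construction with several
weighting kernels, the three graph Laplacians, degree-weighted signal
moments, Rayleigh quotients, and the Laplacian score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CellGraph",
    "GeneSignalSet",
    "GraphConstructionError",
    "GraphTopologyError",
    "ConstantSignalError",
    "ZeroSignalError",
    "build_knn_graph",
    "laplacian",
    "signal_moments",
    "rayleigh_quotient",
    "laplacian_score",
    "laplacian_scores",
]

#: relative tolerance for symmetry / row-sum consistency checks
SYMMETRY_RTOL = 1e-8

METRICS = ("euclidean", "cosine", "pearson-correlation-distance")
WEIGHTINGS = ("fuzzy-local-kernel", "gaussian-kernel", "unit")


class GraphConstructionError(ValueError):
    """Invalid parameters or degenerate inputs during graph construction."""


class GraphTopologyError(ValueError):
    """Operation undefined for the graph's topology (e.g. isolated nodes)."""


class ConstantSignalError(ValueError):
    """The Laplacian score (and MLS) are undefined for constant signals."""


class ZeroSignalError(ValueError):
    """Quotients of the zero signal are undefined."""


@dataclass
class CellGraph:
    """Undirected weighted graph over cells.

    Parameters
    ----------
    node_ids
        Ordered cell identifiers (strings).
    adjacency
        Symmetric non-negative weight matrix with zero diagonal (CSR).
    degrees
        Weighted degree vector, ``d_v = sum_u A_uv``.
    """

    node_ids: np.ndarray
    adjacency: sp.csr_matrix
    degrees: np.ndarray = field(repr=False)

    @classmethod
    def from_adjacency(cls, adjacency, node_ids=None, *, allow_isolated=False):
        """Validate a weight matrix and wrap it as a :class:`CellGraph`.

        ``allow_isolated`` relaxes the positive-degree invariant; it exists
        for induced subgraphs of a filtration, which may legitimately be
        edgeless.
        """
        A = sp.csr_matrix(adjacency, dtype=float)
        n = A.shape[0]
        if A.shape[0] != A.shape[1]:
            raise GraphConstructionError(f"adjacency must be square, got {A.shape}")
        scale = max(abs(A).max() if A.nnz else 0.0, 1e-300)
        asym = abs(A - A.T)
        if asym.nnz and asym.max() > SYMMETRY_RTOL * scale:
            raise GraphConstructionError("adjacency is not symmetric")
        diag = A.diagonal()
        if np.abs(diag).max(initial=0.0) > SYMMETRY_RTOL * scale:
            raise GraphConstructionError("adjacency has non-zero diagonal (self-loops)")
        if diag.any():
            A.setdiag(0.0)
            A.eliminate_zeros()
        if A.nnz and A.data.min() < -SYMMETRY_RTOL * scale:
            raise GraphConstructionError("adjacency has negative weights")
        A.data[A.data < 0] = 0.0
        A = (A + A.T) * 0.5  # exact symmetry for downstream solvers
        A = sp.csr_matrix(A)
        degrees = np.asarray(A.sum(axis=1)).ravel()
        if not allow_isolated and np.any(degrees <= 0):
            bad = np.flatnonzero(degrees <= 0)[:10]
            raise GraphConstructionError(
                f"graph has isolated nodes (zero degree) at indices {bad.tolist()}"
            )
        if node_ids is None:
            node_ids = np.array([f"cell{i}" for i in range(n)], dtype=object)
        else:
            node_ids = np.asarray(node_ids, dtype=object)
            if node_ids.shape[0] != n:
                raise GraphConstructionError(
                    f"{node_ids.shape[0]} node ids for {n} nodes"
                )
        return cls(node_ids=node_ids, adjacency=A, degrees=degrees)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def total_weight(self) -> float:
        """Sum of degrees (twice the total edge weight)."""
        return float(self.degrees.sum())

    def n_components(self) -> int:
        return connected_components(self.adjacency, directed=False)[0]

    def component_labels(self) -> np.ndarray:
        return connected_components(self.adjacency, directed=False)[1]

    def is_connected(self) -> bool:
        return self.n_components() == 1

    def subgraph(self, indices) -> "CellGraph":
        """Induced subgraph on ``indices`` (order preserved, isolated allowed)."""
        idx = np.asarray(indices, dtype=int)
        A = self.adjacency[idx][:, idx]
        return CellGraph.from_adjacency(A, self.node_ids[idx], allow_isolated=True)


@dataclass
class GeneSignalSet:
    """Named real-valued signals (genes) over the nodes (cells) of a graph.

    ``values`` has one row per gene and one column per cell, in the node
    order of the graph the signals live on.
    """

    gene_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.gene_ids.shape[0] != self.values.shape[0]:
            raise ValueError(
                f"{self.gene_ids.shape[0]} gene ids for {self.values.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.unique(np.nonzero(~np.isfinite(self.values))[0])[:10]
            raise ValueError(f"non-finite values in genes {self.gene_ids[bad].tolist()}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def check_matches(self, G: CellGraph) -> None:
        if self.n_cells != G.n_nodes:
            raise ValueError(
                f"signals have {self.n_cells} cells but graph has {G.n_nodes} nodes"
            )

    def subset(self, gene_indices) -> "GeneSignalSet":
        idx = np.asarray(gene_indices, dtype=int)
        return GeneSignalSet(self.gene_ids[idx], self.values[idx])

    def restrict_cells(self, cell_indices) -> "GeneSignalSet":
        idx = np.asarray(cell_indices, dtype=int)
        return GeneSignalSet(self.gene_ids.copy(), self.values[:, idx])


# ---------------------------------------------------------------------------
# k-nn graph construction
# ---------------------------------------------------------------------------


def _knn_arrays(points, k, metric):
    """Directed k-nn neighbour/distance arrays, self excluded."""
    sk_metric = {
        "euclidean": "euclidean",
        "cosine": "cosine",
        "pearson-correlation-distance": "correlation",
    }[metric]
    nn = NearestNeighbors(n_neighbors=min(k + 1, points.shape[0]), metric=sk_metric)
    nn.fit(points)
    dist, idx = nn.kneighbors(points)
    n = points.shape[0]
    out_idx = np.empty((n, k), dtype=int)
    out_dist = np.empty((n, k), dtype=float)
    rows = np.arange(n)
    for u in rows:
        mask = idx[u] != u
        if mask.sum() == idx.shape[1]:  # self not returned (duplicates)
            mask[-1] = False
        out_idx[u] = idx[u][mask][:k]
        out_dist[u] = dist[u][mask][:k]
    return out_dist, out_idx


def _smooth_knn_scales(dist, n_iter=64):
    """Per-node (rho, sigma) for the fuzzy local kernel.

    rho_u is the distance to the nearest neighbour; sigma_u is calibrated by
    bisection so that sum_j exp(-max(0, d_uj - rho_u)/sigma_u) = log2(k),
    the smooth-nearest-neighbour calibration used by fuzzy simplicial-set
    graph builders.
    """
    n, k = dist.shape
    rho = dist[:, 0].copy()
    target = np.log2(max(k, 2))
    sigma = np.ones(n)
    lo = np.full(n, 0.0)
    hi = np.full(n, np.inf)
    shifted = np.maximum(dist - rho[:, None], 0.0)
    mean_d = max(shifted.mean(), 1e-12)
    for _ in range(n_iter):
        val = np.exp(-shifted / np.maximum(sigma[:, None], 1e-300)).sum(axis=1)
        too_big = val > target
        hi = np.where(too_big, sigma, hi)
        lo = np.where(too_big, lo, sigma)
        sigma = np.where(np.isinf(hi), sigma * 2.0, (lo + hi) / 2.0)
    return rho, np.maximum(sigma, 1e-3 * mean_d)


def build_knn_graph(points, k, metric="euclidean", weighting="fuzzy-local-kernel",
                    node_ids=None) -> CellGraph:
    """Build a symmetric weighted k-nearest-neighbour graph on cells.

    An edge is present whenever either endpoint lists the other among its k
    nearest neighbours (union symmetrization).  Weighting schemes:

    ``unit``
        every edge has weight 1;
    ``gaussian-kernel``
        locally scaled heat kernel ``exp(-d^2 / (sigma_u sigma_v))`` with
        ``sigma_u`` the distance from u to its k-th neighbour;
    ``fuzzy-local-kernel``
        locally scaled exponential membership
        ``w_uv = exp(-max(0, d - rho_u)/sigma_u)`` combined by the fuzzy
        union ``w_uv + w_vu - w_uv w_vu`` (an approximation of the fuzzy
        simplicial-set weights produced by UMAP).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise GraphConstructionError("points must be a 2-D array with >= 2 rows")
    n = pts.shape[0]
    if not (1 <= k < n):
        raise GraphConstructionError(f"k must satisfy 1 <= k < n_cells; got k={k}, n={n}")
    if metric not in METRICS:
        raise GraphConstructionError(f"unknown metric {metric!r}; choose from {METRICS}")
    if weighting not in WEIGHTINGS:
        raise GraphConstructionError(
            f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}"
        )
    if metric == "pearson-correlation-distance":
        sd = pts.std(axis=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)[:10]
            raise GraphConstructionError(
                "pearson-correlation-distance undefined for zero-variance "
                f"rows {bad.tolist()}"
            )

    dist, idx = _knn_arrays(pts, k, metric)
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()

    if weighting == "unit":
        w = np.ones(rows.shape[0])
        W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
        A = W.maximum(W.T)
    elif weighting == "gaussian-kernel":
        sigma = dist[:, -1].copy()
        pos = sigma[sigma > 0]
        floor = pos.min() * 1e-3 if pos.size else 1.0
        sigma = np.maximum(sigma, floor)
        w = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
        W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
        A = W.maximum(W.T)
    else:  # fuzzy-local-kernel
        rho, sigma = _smooth_knn_scales(dist)
        w = np.exp(-np.maximum(dist.ravel() - rho[rows], 0.0) / sigma[rows])
        W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
        # fuzzy union: w_uv + w_vu - w_uv * w_vu
        A = W + W.T - W.multiply(W.T)

    A = sp.csr_matrix(A)
    A.setdiag(0.0)
    A.eliminate_zeros()
    return CellGraph.from_adjacency(A, node_ids)


# ---------------------------------------------------------------------------
# Laplacians and scores
# ---------------------------------------------------------------------------


def laplacian(G: CellGraph, kind="combinatorial") -> sp.csr_matrix:
    """Graph Laplacian of ``G``.

    ``combinatorial``: ``L = D - A``; ``normalized``:
    ``D^{-1/2} L D^{-1/2}``; ``random-walk``: ``D^{-1} L``.  The normalized
    and random-walk forms require strictly positive degrees.
    """
    A = G.adjacency
    d = G.degrees
    D = sp.diags(d)
    if kind == "combinatorial":
        return sp.csr_matrix(D - A)
    if np.any(d <= 0):
        raise GraphTopologyError(f"{kind} Laplacian undefined with isolated nodes")
    if kind == "normalized":
        inv_sqrt = sp.diags(1.0 / np.sqrt(d))
        return sp.csr_matrix(inv_sqrt @ (D - A) @ inv_sqrt)
    if kind == "random-walk":
        return sp.csr_matrix(sp.diags(1.0 / d) @ (D - A))
    raise ValueError(f"unknown Laplacian kind {kind!r}")


def _as_signal(g, G: CellGraph) -> np.ndarray:
    g = np.asarray(g, dtype=float).ravel()
    if g.shape[0] != G.n_nodes:
        raise ValueError(f"signal has {g.shape[0]} entries for {G.n_nodes} nodes")
    if not np.all(np.isfinite(g)):
        raise ValueError("signal has non-finite entries")
    return g


def signal_moments(g, G: CellGraph):
    """Degree-weighted graph mean and variance of a signal.

    ``mu_G(g) = (sum_v g(v) d_v) / (sum_u d_u)`` and
    ``Var_G(g) = sum_v d_v (g(v) - mu_G)^2``.
    """
    g = _as_signal(g, G)
    d = G.degrees
    mu = float(g @ d) / G.total_weight
    var = float(d @ (g - mu) ** 2)
    return mu, max(var, 0.0)


def rayleigh_quotient(g, G: CellGraph, normalized=False) -> float:
    """Rayleigh quotient ``sum_{u~v} A_uv (g(u)-g(v))^2 / <g,g>``.

    With ``normalized=True`` the denominator is the degree-weighted norm
    ``sum_u g(u)^2 d_u`` (the quotient of ``D^{1/2}g`` under the normalized
    Laplacian), whose value lies in ``[0, 2]``.
    """
    g = _as_signal(g, G)
    if not np.any(g):
        raise ZeroSignalError("Rayleigh quotient undefined for the zero signal")
    L = laplacian(G, "combinatorial")
    num = float(g @ (L @ g))
    den = float(g @ (G.degrees * g)) if normalized else float(g @ g)
    if den <= 0:
        raise ZeroSignalError("zero denominator in Rayleigh quotient")
    return max(num, 0.0) / den


def laplacian_score(g, G: CellGraph) -> float:
    """Laplacian score ``LS(g) = sum_{u~v} A_uv (g(u)-g(v))^2 / Var_G(g)``.

    The degree-normalized Rayleigh quotient of the graph-mean-centred
    signal; invariant under affine maps ``g -> a g + b`` (a != 0), and
    undefined for constant signals.
    """
    g = _as_signal(g, G)
    mu, var = signal_moments(g, G)
    scale = float(np.max(np.abs(g), initial=0.0))
    if var <= 1e-24 * max(scale, 1.0) ** 2 * G.total_weight:
        raise ConstantSignalError("Laplacian score undefined for constant signals")
    L = laplacian(G, "combinatorial")
    return max(float(g @ (L @ g)), 0.0) / var


def laplacian_scores(signals: GeneSignalSet, G: CellGraph) -> np.ndarray:
    """Vectorized Laplacian score for every gene in ``signals``."""
    signals.check_matches(G)
    V = signals.values
    d = G.degrees
    mu = (V @ d) / G.total_weight
    centred = V - mu[:, None]
    var = (centred**2) @ d
    zero = var <= 0
    if np.any(zero):
        raise ConstantSignalError(
            "Laplacian score undefined for constant signals: "
            f"{signals.gene_ids[np.flatnonzero(zero)[:10]].tolist()}"
        )
    L = laplacian(G, "combinatorial")
    num = np.einsum("gi,gi->g", V, (L @ V.T).T)
    return np.maximum(num, 0.0) / var
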