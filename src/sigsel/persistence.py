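"""Filtrations, Kron reduction (persistent Laplacian), and the persistent
Rayleigh quotient.

An integer filtration ``f`` on the nodes induces nested sublevel subgraphs
``G[alpha(i)]``, ``alpha(i) = {v : f(v) <= i}``.  For developmental data the
useful direction is *reverse time* (``f = t_max - t``), so the latest cells
enter first and branches appear before they merge through their parent.

The (i, j)-persistent Laplacian is the Schur complement (Kron reduction) of
the Laplacian of ``G[alpha(j)]`` onto the nodes ``alpha(i)``: it eliminates
the intermediate nodes while preserving effective connectivity, and its
nullity equals the persistent Betti-0 number of the inclusion
``G[alpha(i)] <= G[alpha(j)]``.  The persistent Rayleigh quotient (PRQ) of a
gene is the Rayleigh quotient under this operator; comparing the persistent
quotient with the full one separates genes by their role in a bifurcation
(parent-plus-one-daughter genes fall above the diagonal, both-daughters-only
genes below, single-daughter genes on it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .graph import CellGraph, GeneSignalSet, ZeroSignalError, laplacian

__all__ = [
    "Filtration",
    "ReducedLaplacian",
    "FiltrationRangeError",
    "SingularBlockError",
    "filtered_subgraph",
    "kron_reduce",
    "persistent_laplacian",
    "persistent_betti0",
    "prq",
    "prq_map",
]

logger = logging.getLogger(__name__)

#: eigenvalues below this fraction of the largest count as numerically zero
NULLITY_RTOL = 1e-8

#: positive off-diagonal entries below this (relative) size are clipped
_OFFDIAG_SLACK = 1e-10


class FiltrationRangeError(ValueError):
    """A sublevel set is empty at the requested filtration index."""


class SingularBlockError(ValueError):
    """The eliminated block is singular: some connected component lies
    entirely outside the kept node set."""


@dataclass
class Filtration:
    """Integer filtration value per node (same order as the graph)."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values)
        if not np.issubdtype(vals.dtype, np.integer):
            rounded = np.rint(np.asarray(vals, dtype=float))
            if np.max(np.abs(vals - rounded), initial=0.0) > 1e-9:
                raise ValueError("filtration values must be integers")
            vals = rounded.astype(np.int64)
        self.values = vals.astype(np.int64)

    @classmethod
    def from_times(cls, times, t_max=None) -> "Filtration":
        """Reverse-time filtration ``f = t_max - t`` from a time column."""
        t = np.asarray(times)
        t_max = int(np.max(t)) if t_max is None else int(t_max)
        return cls(t_max - np.asarray(t, dtype=np.int64))

    @property
    def min(self) -> int:
        return int(self.values.min())

    @property
    def max(self) -> int:
        return int(self.values.max())

    def sublevel(self, i: int) -> np.ndarray:
        """Indices of the sublevel node set ``alpha(i)`` (ascending)."""
        return np.flatnonzero(self.values <= i)


def filtered_subgraph(G: CellGraph, f: Filtration, i: int):
    """Sublevel node indices ``alpha(i)`` and the induced subgraph.

    The induced subgraph keeps every edge with both endpoints in
    ``alpha(i)`` and may contain isolated nodes.
    """
    if f.values.shape[0] != G.n_nodes:
        raise ValueError("filtration does not cover the graph's nodes")
    alpha = f.sublevel(i)
    if alpha.size == 0:
        raise FiltrationRangeError(
            f"sublevel set alpha({i}) is empty (filtration range "
            f"[{f.min}, {f.max}])"
        )
    return alpha, G.subgraph(alpha)


@dataclass
class ReducedLaplacian:
    """Kron-reduced Laplacian on a kept node subset.

    ``matrix`` is symmetric with zero row sums and non-positive
    off-diagonals (a Laplacian of some weighted graph on ``kept_nodes``);
    ``source`` records the (i, j) filtration indices when produced as a
    persistent Laplacian.
    """

    kept_nodes: np.ndarray
    matrix: np.ndarray
    source: tuple | None = None

    @property
    def degrees(self) -> np.ndarray:
        """Degree vector of the reduced graph (diagonal of the matrix)."""
        return np.diag(self.matrix).copy()

    def adjacency(self) -> np.ndarray:
        A = -self.matrix.copy()
        np.fill_diagonal(A, 0.0)
        return A

    def nullity(self, rtol: float = NULLITY_RTOL) -> int:
        """Number of numerically zero eigenvalues (scale-free cutoff)."""
        lam = np.linalg.eigvalsh(self.matrix)
        cutoff = rtol * max(lam[-1], 1e-300)
        return int(np.sum(lam < cutoff))


def _component_check(L: np.ndarray, keep: np.ndarray):
    """Raise if some connected component of L's graph avoids ``keep``."""
    off = -L.copy()
    np.fill_diagonal(off, 0.0)
    off[np.abs(off) <= _OFFDIAG_SLACK * max(np.abs(L).max(), 1e-300)] = 0.0
    n_comp, labels = connected_components(sp.csr_matrix(off != 0), directed=False)
    kept_comps = set(labels[keep].tolist())
    missing = [c for c in range(n_comp) if c not in kept_comps]
    if missing:
        nodes = np.flatnonzero(np.isin(labels, missing)).tolist()
        raise SingularBlockError(
            "eliminated block is singular: connected component(s) with nodes "
            f"{nodes[:20]} contain no kept node"
        )


def kron_reduce(L, keep, *, laplacian_kind="combinatorial",
                node_ids=None) -> ReducedLaplacian:
    """Schur complement of a Laplacian onto the node subset ``keep``.

    ``L_keep = L[a,a] - L[a,c] L[c,c]^{-1} L[c,a]`` with ``c`` the
    complement of ``a = keep``.  For a combinatorial Laplacian the result
    is again a Laplacian (symmetric, zero row sums, non-positive
    off-diagonals); tiny positive off-diagonals from floating point are
    clipped and the diagonal rebalanced.  Applies identically to
    normalized Laplacians (``laplacian_kind="normalized"`` skips the
    Laplacian-specific clean-up).
    """
    L = np.asarray(L.toarray() if sp.issparse(L) else L, dtype=float)
    n = L.shape[0]
    keep = np.asarray(keep, dtype=int)
    if keep.size == 0:
        raise ValueError("keep must be a non-empty node subset")
    comp = np.setdiff1d(np.arange(n), keep)
    ids = (
        np.asarray(node_ids, dtype=object)[keep]
        if node_ids is not None
        else keep.astype(object)
    )
    if comp.size == 0:
        return ReducedLaplacian(kept_nodes=ids, matrix=L[np.ix_(keep, keep)].copy())
    _component_check(L, keep)
    Laa = L[np.ix_(keep, keep)]
    Lac = L[np.ix_(keep, comp)]
    Lcc = L[np.ix_(comp, comp)]
    X = np.linalg.solve(Lcc, Lac.T)
    red = Laa - Lac @ X
    red = (red + red.T) * 0.5
    if laplacian_kind == "combinatorial":
        scale = max(np.abs(red).max(), 1e-300)
        off = red - np.diag(np.diag(red))
        n_clip = int(np.sum(off > 0))
        if n_clip:
            if np.max(off) > _OFFDIAG_SLACK * scale:
                logger.warning(
                    "clipping %d positive off-diagonal entries up to %.3e",
                    n_clip,
                    float(np.max(off)),
                )
            off = np.minimum(off, 0.0)
        red = off + np.diag(-off.sum(axis=1))  # exact zero row sums
    return ReducedLaplacian(kept_nodes=ids, matrix=red)


def persistent_laplacian(G: CellGraph, f: Filtration, i: int, j: int,
                         normalized=False) -> ReducedLaplacian:
    """(i, j)-persistent Laplacian: the Laplacian of ``G[alpha(j)]``
    Kron-reduced onto ``alpha(i)``.

    For ``i = j`` this is the plain (combinatorial or normalized)
    Laplacian of ``G[alpha(i)]``.
    """
    if i > j:
        raise ValueError(f"filtration indices must satisfy i <= j, got ({i}, {j})")
    alpha_j, sub_j = filtered_subgraph(G, f, j)
    keep = np.flatnonzero(f.values[alpha_j] <= i)
    if keep.size == 0:
        raise FiltrationRangeError(f"sublevel set alpha({i}) is empty")
    kind = "normalized" if normalized else "combinatorial"
    Lj = laplacian(sub_j, kind)
    red = kron_reduce(Lj, keep, laplacian_kind=kind, node_ids=sub_j.node_ids)
    red.source = (i, j)
    return red


def persistent_betti0(G: CellGraph, f: Filtration, i: int, j: int) -> int:
    """Persistent Betti-0 number of ``G[alpha(i)] <= G[alpha(j)]``.

    The number of connected components of ``G[alpha(j)]`` that contain at
    least one node of ``alpha(i)`` -- equivalently the number of
    components of ``G[alpha(i)]`` still disconnected from each other in
    ``G[alpha(j)]``.  Equals the nullity of the (i, j)-persistent
    Laplacian.
    """
    if i > j:
        raise ValueError(f"filtration indices must satisfy i <= j, got ({i}, {j})")
    alpha_j, sub_j = filtered_subgraph(G, f, j)
    _, labels = connected_components(sub_j.adjacency, directed=False)
    keep = f.values[alpha_j] <= i
    if not np.any(keep):
        raise FiltrationRangeError(f"sublevel set alpha({i}) is empty")
    return int(np.unique(labels[keep]).size)


def _prq_values(signals: GeneSignalSet, red: ReducedLaplacian,
                alpha_idx: np.ndarray, normalized: bool):
    """Per-gene quotients plus a list of (gene_id, message) failures."""
    restricted = signals.values[:, alpha_idx]
    M = red.matrix
    deg = red.degrees
    values = np.full(signals.n_genes, np.nan)
    failures = []
    for gi in range(signals.n_genes):
        g = restricted[gi]
        if not np.any(g):
            failures.append(
                (str(signals.gene_ids[gi]), "signal restricted to alpha(i) is zero")
            )
            continue
        den = float(g @ (deg * g)) if normalized else float(g @ g)
        if den <= 0:
            failures.append(
                (
                    str(signals.gene_ids[gi]),
                    "restricted signal supported only on zero-degree reduced nodes",
                )
            )
            continue
        values[gi] = max(float(g @ (M @ g)), 0.0) / den
    return values, failures


def prq(signals: GeneSignalSet, G: CellGraph, f: Filtration, i: int, j: int,
        normalized=True) -> np.ndarray:
    """Persistent Rayleigh quotient of each gene for the pair (i, j).

    ``PRQ(i,j)(g) = <g, L^{ij} g> / <g, g>`` with ``g`` implicitly
    restricted to ``alpha(i)``; the normalized form divides by
    ``<g, D^{ij} g>`` with ``D^{ij}`` the degree matrix of the reduced
    graph.  Undefined (error) when the restricted signal is zero, or, in
    the normalized form, supported only on zero-degree reduced nodes.
    """
    signals.check_matches(G)
    red = persistent_laplacian(G, f, i, j, normalized=False)
    alpha_idx = f.sublevel(i)
    values, failures = _prq_values(signals, red, alpha_idx, normalized)
    if failures:
        gene, msg = failures[0]
        raise ZeroSignalError(f"PRQ undefined for gene {gene!r}: {msg}")
    return values


def classify_bifurcation_role(full, persistent, band: float = 0.05,
                              low: float = 0.1) -> np.ndarray:
    """Classify genes by their position in the persistent-vs-full PRQ plane.

    ``constant``: both quotients below ``low`` (housekeeping-like);
    ``parent+one-daughter``: persistent exceeds full by more than ``band``
    (above the diagonal); ``both-daughters``: full exceeds persistent by
    more than ``band`` (below); ``single-daughter``: within the diagonal
    band.
    """
    full = np.asarray(full, dtype=float)
    persistent = np.asarray(persistent, dtype=float)
    out = np.where(
        persistent - full > band,
        "parent+one-daughter",
        np.where(full - persistent > band, "both-daughters", "single-daughter"),
    ).astype(object)
    out[(full < low) & (persistent < low)] = "constant"
    return out


def prq_map(signals: GeneSignalSet, G: CellGraph, f: Filtration, pairs):
    """Batch PRQ evaluation over filtration pairs.

    Returns ``(table, report)``: a genes-by-pairs DataFrame with columns
    ``prq_i_j`` (normalized PRQ; undefined entries are NaN, genes are never
    dropped) and a list of per-gene failure records
    ``{"gene_id", "pair", "error"}``.
    """
    signals.check_matches(G)
    pairs = [(int(i), int(j)) for i, j in pairs]
    for i, j in pairs:
        if i > j:
            raise ValueError(f"invalid pair ({i}, {j}): need i <= j")
    table = pd.DataFrame(index=pd.Index(signals.gene_ids.astype(str), name="gene_id"))
    report = []
    cache = {}
    for i, j in pairs:
        col = f"prq_{i}_{j}"
        if (i, j) not in cache:
            red = persistent_laplacian(G, f, i, j, normalized=False)
            alpha_idx = f.sublevel(i)
            cache[(i, j)] = _prq_values(signals, red, alpha_idx, normalized=True)
        values, failures = cache[(i, j)]
        table[col] = values
        for gene, msg in failures:
            report.append({"gene_id": gene, "pair": (i, j), "error": msg})
    return table, report
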