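"""Low-frequency spectral basis and eigenscores.

The normalized Laplacian of a cell similarity graph admits an orthonormal
eigenbasis ``e_0, ..., e_{n-1}`` with eigenvalues ``0 = lambda_0 <= ... <=
lambda_{n-1}``; small eigenvalues correspond to smooth, large-scale
patterns.  The *i-th eigenscore* of a gene signal g,

    eig_i(g) = <D^{1/2} g, e_i> / ||D^{1/2} g||,

is the cosine between the degree-lifted signal and the i-th eigenvector: a
per-frequency decomposition of the Rayleigh quotient, since
``RQ(D^{1/2}g) = sum_i lambda_i eig_i(g)^2`` and ``sum_i eig_i(g)^2 = 1``
over a complete basis.  Ranking genes by the Euclidean norm of their
low-frequency eigenscores selects signals aligned with the graph's
dominant intrinsic patterns; noise plots near the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla

from .graph import CellGraph, GeneSignalSet, ZeroSignalError, laplacian

__all__ = [
    "SpectralBasis",
    "EigenscoreMatrix",
    "spectral_basis",
    "eigenscores",
    "rank_by_eigenscore_norm",
    "eigenscore_embedding_matrix",
]

#: default low-frequency cut-off for the eigenvalue selector
DEFAULT_MAX_EIGENVALUE = 0.1

#: graphs up to this size are decomposed densely (deterministic LAPACK path)
_DENSE_LIMIT = 4096


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


@dataclass
class SpectralBasis:
    """Ascending eigenpairs of the normalized Laplacian.

    ``eigenvectors`` has one orthonormal column per eigenvalue; for a
    connected graph ``e_0`` is ``D^{1/2} 1`` normalized to unit length.
    ``n_trivial`` counts zero eigenvalues (one per connected component);
    the corresponding eigenvectors carry no intra-component structure and
    are excluded from rankings by default.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    degree_sqrt: np.ndarray
    n_trivial: int = 1

    @property
    def n_vectors(self) -> int:
        return self.eigenvalues.shape[0]

    def nontrivial_dims(self):
        return range(self.n_trivial, self.n_vectors)


def spectral_basis(G: CellGraph, count=None, max_eigenvalue=None) -> SpectralBasis:
    """Low-frequency eigenpairs of the normalized Laplacian of ``G``.

    Exactly one selector applies: ``count`` returns the ``k`` smallest
    eigenpairs; ``max_eigenvalue`` returns all pairs with
    ``lambda_i < max_eigenvalue`` plus the trivial pair(s).  With neither,
    ``max_eigenvalue`` defaults to 0.1.  Eigenvector signs are fixed so the
    largest-magnitude entry of each vector is positive.
    """
    n = G.n_nodes
    if count is not None and max_eigenvalue is not None:
        raise ValueError("give either count or max_eigenvalue, not both")
    if count is None and max_eigenvalue is None:
        max_eigenvalue = DEFAULT_MAX_EIGENVALUE
    if count is not None and not (1 <= count <= n):
        raise ValueError(f"count must be in [1, {n}], got {count}")
    if max_eigenvalue is not None and max_eigenvalue <= 0:
        raise ValueError("max_eigenvalue must be positive")

    L = laplacian(G, "normalized")
    if n <= _DENSE_LIMIT:
        lam, vec = np.linalg.eigh(L.toarray())
    else:
        k = count if count is not None else min(n - 1, 64)
        while True:
            try:
                lam, vec = spla.eigsh(L, k=k, which="SA")
            except spla.ArpackNoConvergence as err:  # pragma: no cover
                raise RuntimeError(
                    f"eigensolver failed to converge ({err})"
                ) from err
            order = np.argsort(lam)
            lam, vec = lam[order], vec[:, order]
            if count is not None or lam[-1] >= max_eigenvalue or k >= n - 1:
                break
            k = min(2 * k, n - 1)
    lam = np.maximum(lam, 0.0)
    tol = 1e-10 * max(lam[-1], 1.0)
    n_trivial = int(np.sum(lam <= tol))
    if n_trivial > 1:
        warnings.warn(
            f"graph is disconnected: eigenvalue 0 has multiplicity {n_trivial}",
            stacklevel=2,
        )
    if count is not None:
        keep = count
    else:
        keep = max(int(np.sum(lam < max_eigenvalue)), n_trivial)
    lam, vec = lam[:keep], _fix_signs(vec[:, :keep])
    return SpectralBasis(
        eigenvalues=lam,
        eigenvectors=vec,
        degree_sqrt=np.sqrt(G.degrees),
        n_trivial=min(n_trivial, keep),
    )


@dataclass
class EigenscoreMatrix:
    """Per-gene eigenscores: ``scores[g, i] = eig_i(gene g)`` in [-1, 1]."""

    gene_ids: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    n_trivial: int = 1

    def norms(self, dims) -> np.ndarray:
        dims = list(dims)
        return np.linalg.norm(self.scores[:, dims], axis=1)


def eigenscores(signals: GeneSignalSet, basis: SpectralBasis) -> EigenscoreMatrix:
    """Cosine alignment of each degree-lifted gene signal with each basis vector."""
    if signals.n_cells != basis.degree_sqrt.shape[0]:
        raise ValueError(
            f"signals have {signals.n_cells} cells but basis has "
            f"{basis.degree_sqrt.shape[0]} nodes"
        )
    lifted = signals.values * basis.degree_sqrt[None, :]
    norms = np.linalg.norm(lifted, axis=1)
    zero = norms <= 0
    if np.any(zero):
        raise ZeroSignalError(
            "eigenscores undefined for all-zero signals: "
            f"{signals.gene_ids[np.flatnonzero(zero)[:10]].tolist()}"
        )
    scores = (lifted @ basis.eigenvectors) / norms[:, None]
    np.clip(scores, -1.0, 1.0, out=scores)
    return EigenscoreMatrix(
        gene_ids=signals.gene_ids.copy(),
        scores=scores,
        eigenvalues=basis.eigenvalues.copy(),
        n_trivial=basis.n_trivial,
    )


def _validate_dims(E: EigenscoreMatrix, dims, exclude_trivial: bool):
    dims = list(dims)
    if not dims:
        raise ValueError("dims must be non-empty")
    for d in dims:
        if not (0 <= d < E.scores.shape[1]):
            raise ValueError(f"dimension {d} outside basis range 0..{E.scores.shape[1]-1}")
        if exclude_trivial and d < E.n_trivial:
            raise ValueError(
                f"dimension {d} indexes a trivial (lambda=0) eigenvector; "
                "rankings use non-trivial dimensions only"
            )
    return dims


def rank_by_eigenscore_norm(E: EigenscoreMatrix, dims=None) -> pd.DataFrame:
    """Genes sorted by descending Euclidean norm over the selected dimensions.

    ``dims`` defaults to every non-trivial dimension.  Ties are broken by
    gene id (lexicographic), so the ranking is invariant to eigenvector
    sign flips and stable under reordering of the input genes.
    """
    if dims is None:
        dims = range(E.n_trivial, E.scores.shape[1])
    dims = _validate_dims(E, dims, exclude_trivial=True)
    df = pd.DataFrame({"gene_id": E.gene_ids.astype(str), "norm": E.norms(dims)})
    df = df.sort_values(["norm", "gene_id"], ascending=[False, True], kind="mergesort")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def eigenscore_embedding_matrix(E: EigenscoreMatrix, dims=None) -> np.ndarray:
    """Selected eigenscore columns as a genes-by-|dims| coordinate matrix.

    No further transformation is applied; the result feeds any external
    2-D embedding or plotting tool.
    """
    if dims is None:
        dims = range(E.n_trivial, E.scores.shape[1])
    dims = list(dims)
    if E.scores.shape[0] == 0:
        return np.empty((0, len(dims)))
    if dims:
        _validate_dims(E, dims, exclude_trivial=False)
    return E.scores[:, dims].copy()
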