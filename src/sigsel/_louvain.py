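"""Louvain-style optimizer for a dense quality (stability) matrix.

Markov stability of a partition is ``sum_{c_u = c_v} B_uv`` for the
symmetrized quality matrix ``B_uv = (pi_u P(t)_uv + pi_v P(t)_vu)/2 -
pi_u pi_v``.  The optimizer is the classic two-phase Louvain scheme --
greedy single-node label moves followed by community aggregation --
applied to B directly, which accommodates the dense, possibly negative
entries produced by the heat kernel at arbitrary Markov times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GAIN_TOL = 1e-12


@njit(cache=True)
def _local_moves(B, labels, order):
    """Greedy label moves until no single-node move improves the quality.

    Ties in gain are broken toward the lowest community index (the scan is
    in ascending index order with a strict improvement test); a node stays
    put unless the gain is strictly positive.
    """
    n = B.shape[0]
    improved = False
    while True:
        moved = 0
        for oi in range(n):
            v = order[oi]
            cv = labels[v]
            comm_w = np.zeros(n)
            for u in range(n):
                if u != v:
                    comm_w[labels[u]] += B[v, u]
            base = comm_w[cv]
            best_c = cv
            best_gain = _GAIN_TOL
            for c in range(n):
                if c == cv:
                    continue
                gain = comm_w[c] - base
                if gain > best_gain:
                    best_gain = gain
                    best_c = c
            if best_c != cv:
                labels[v] = best_c
                moved += 1
                improved = True
        if moved == 0:
            return improved


def _compact(labels):
    _, out = np.unique(labels, return_inverse=True)
    return out.astype(np.int64)


def _aggregate(B, labels):
    k = labels.max() + 1
    C = np.zeros((B.shape[0], k))
    C[np.arange(B.shape[0]), labels] = 1.0
    return C.T @ B @ C


def louvain_dense(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Maximize ``sum_{c_u=c_v} B_uv`` over partitions; returns node labels.

    Deterministic given the generator state: the only randomness is the
    node visiting order drawn per level.
    """
    n = B.shape[0]
    node_labels = np.arange(n, dtype=np.int64)
    Bcur = np.ascontiguousarray(B, dtype=np.float64)
    while True:
        m = Bcur.shape[0]
        labels = np.arange(m, dtype=np.int64)
        order = rng.permutation(m)
        improved = _local_moves(Bcur, labels, order)
        labels = _compact(labels)
        node_labels = labels[node_labels]
        if not improved or labels.max() + 1 == m:
            return _compact(node_labels)
        Bcur = _aggregate(Bcur, labels)


def partition_quality(B: np.ndarray, labels: np.ndarray) -> float:
    """Quality ``sum_{c_u = c_v} B_uv`` (diagonal included)."""
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())
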