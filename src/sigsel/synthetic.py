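"""Seeded synthetic fixtures: point clouds, planted-partition graphs, the
three-node bifurcation, and a Y-shaped bifurcating expression simulator.

Each generator returns a :class:`SyntheticBundle` holding the generated
points and/or graph, a named signal set, and the planted ground truth
(labels, partitions, filtrations, archetypes).  All randomness flows from
a single seed through one generator stream per bundle, so regeneration
with the same seed is bit-identical.  These fixtures exercise the
graph-signal machinery; they do not emulate scRNA-seq count noise
(no negative-binomial sampling or dropout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import CellGraph, GeneSignalSet, build_knn_graph

__all__ = [
    "SyntheticBundle",
    "four_balls",
    "hierarchical_graph",
    "three_community_graph",
    "toy_bifurcation",
    "bifurcating_expression",
]


@dataclass
class SyntheticBundle:
    """A generated fixture: data, signals, and planted truth."""

    points: np.ndarray | None
    graph: CellGraph | None
    signals: GeneSignalSet
    truth: dict = field(default_factory=dict)
    seed: int | None = None


def four_balls(points_per_ball: int = 100, dim: int = 30, seed: int = 0,
               k: int = 15) -> SyntheticBundle:
    """Four touching clusters at the corners of a planar square.

    ``points_per_ball`` points per cluster, drawn as isotropic Gaussian
    clouds (sd 0.35 of the half-spacing) around centres at (+-1, +-1) in
    the first two of ``dim`` dimensions.  Gaussian tails make adjacent
    clusters genuinely touch in the k-nn sense -- uniform hard balls in
    high dimension would leave the graph disconnected and no pair of
    low-frequency eigenvectors could separate the cluster pairs.  The
    bundle carries a k-nn graph (k=15 by default), per-ball 0/1 indicator
    signals, the two +-1 ball-pair signals (left/right and bottom/top,
    which align or anti-align with the two leading eigenvectors), and an
    i.i.d. noise signal.
    """
    if points_per_ball < 2:
        raise ValueError("points_per_ball must be >= 2")
    rng = np.random.default_rng(seed)
    centres = np.zeros((4, dim))
    # order: 0=(-1,-1) 1=(+1,-1) 2=(-1,+1) 3=(+1,+1)
    centres[:, 0] = [-1.0, 1.0, -1.0, 1.0]
    centres[:, 1] = [-1.0, -1.0, 1.0, 1.0]
    blocks = [
        centres[b] + rng.normal(scale=0.35, size=(points_per_ball, dim))
        for b in range(4)
    ]
    points = np.vstack(blocks)
    labels = np.repeat(np.arange(4), points_per_ball)
    n = points.shape[0]
    graph = build_knn_graph(points, k=k, metric="euclidean",
                            weighting="fuzzy-local-kernel")
    names, rows = [], []
    for b in range(4):
        names.append(f"ball_{b}")
        rows.append((labels == b).astype(float))
    names += ["pair_left", "pair_bottom", "noise"]
    rows.append(np.where(np.isin(labels, [0, 2]), 1.0, -1.0))  # x = -1 balls
    rows.append(np.where(np.isin(labels, [0, 1]), 1.0, -1.0))  # y = -1 balls
    rows.append(rng.standard_normal(n))
    signals = GeneSignalSet(np.array(names, dtype=object), np.vstack(rows))
    truth = {
        "ball_labels": labels,
        "pair_left_balls": np.array([0, 2]),
        "pair_bottom_balls": np.array([0, 1]),
    }
    return SyntheticBundle(points=points, graph=graph, signals=signals,
                           truth=truth, seed=seed)


def hierarchical_graph(branching: int = 4, depth: int = 4, leaf_size: int = 4,
                       weight_decay: float = 0.1, seed: int = 0) -> SyntheticBundle:
    """Balanced hierarchical benchmark graph with geometric coupling decay.

    A complete weighted graph on ``branching**depth`` leaf groups of
    ``leaf_size`` nodes (defaults: 256 groups, 1024 nodes).  The weight
    between two nodes is ``weight_decay**(depth - s)`` (up to a small
    seeded jitter) where ``s`` is the deepest hierarchy level at which
    they share a community (same leaf group: weight 1; related only
    through the root: ``weight_decay**depth``).  Truth holds the planted
    partition at every
    level, with community counts ``branching, branching**2, ...,
    branching**depth`` (defaults 4, 16, 64, 256).  This is a
    planted-structure stand-in whose scales, not edge statistics, realize
    the classic multiscale community benchmark.
    """
    if branching < 2 or depth < 2:
        raise ValueError("branching and depth must both be >= 2")
    if not (0 < weight_decay < 1):
        raise ValueError("weight_decay must lie in (0, 1)")
    n_groups = branching**depth
    n = n_groups * leaf_size
    # community label of each node at each level 1..depth
    level_labels = {}
    for level in range(1, depth + 1):
        block = n // branching**level
        level_labels[level] = np.arange(n) // block
    # deepest shared level per pair (0 = root only)
    shared = np.zeros((n, n), dtype=np.int64)
    for level in range(1, depth + 1):
        lab = level_labels[level]
        shared[lab[:, None] == lab[None, :]] = level
    rng = np.random.default_rng(seed)
    A = weight_decay ** (depth - shared).astype(float)
    # +-3% multiplicative jitter: enough to break exact symmetry (no
    # tie-break artifacts), small enough that sibling merges stay nearly
    # simultaneous and the planted scales dominate the time axis
    jitter = rng.uniform(0.97, 1.03, size=A.shape)
    A *= np.tril(jitter, -1) + np.tril(jitter, -1).T
    np.fill_diagonal(A, 0.0)
    graph = CellGraph.from_adjacency(sp.csr_matrix(A))
    signals = GeneSignalSet(
        np.array(["noise"], dtype=object), rng.standard_normal((1, n))
    )
    truth = {"level_partitions": level_labels,
             "level_counts": {lv: branching**lv for lv in range(1, depth + 1)}}
    return SyntheticBundle(points=None, graph=graph, signals=signals,
                           truth=truth, seed=seed)


def three_community_graph(sizes=(60, 30, 15), w_in: float = 1.0,
                          w_out: float = 0.05, seed: int = 0) -> SyntheticBundle:
    """Weighted planted-partition graph with three communities of distinct sizes.

    Every within-community pair is joined with weight ``w_in`` and every
    cross-community pair with ``w_out`` (``w_out = 0`` disconnects the
    communities).  Bundled signals (the classic four test signals): for
    each community an indicator that is 1 on the community and uniformly
    random elsewhere, plus one fully random signal.  Truth holds the
    3-way partition and the 2-way coarsening in which the two smallest
    communities are merged.
    """
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) != 3 or len(set(sizes)) != 3:
        raise ValueError(f"sizes must be three distinct integers, got {sizes}")
    if not (w_in > w_out >= 0):
        raise ValueError("weights must satisfy w_in > w_out >= 0")
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels3 = np.repeat(np.arange(3), sizes)
    A = np.where(labels3[:, None] == labels3[None, :], w_in, w_out)
    jitter = rng.uniform(0.8, 1.2, size=A.shape)  # break exact symmetry
    A *= np.tril(jitter, -1) + np.tril(jitter, -1).T
    np.fill_diagonal(A, 0.0)
    graph = CellGraph.from_adjacency(sp.csr_matrix(A),
                                     allow_isolated=(w_out == 0.0))
    order = np.argsort(sizes)  # ascending
    labels2 = np.where(np.isin(labels3, order[:2]), 1, 0)
    names, rows = [], []
    rank_names = ["largest", "middle", "smallest"]
    for rank, c in enumerate(np.argsort(sizes)[::-1]):  # largest first
        sig = rng.random(n)
        sig[labels3 == c] = 1.0
        names.append(f"indicator_{rank_names[rank]}")
        rows.append(sig)
    names.append("random")
    rows.append(rng.random(n))
    signals = GeneSignalSet(np.array(names, dtype=object), np.vstack(rows))
    truth = {"labels3": labels3, "labels2": labels2, "sizes": np.asarray(sizes)}
    return SyntheticBundle(points=None, graph=graph, signals=signals,
                           truth=truth, seed=seed)


def toy_bifurcation() -> SyntheticBundle:
    """The exact three-node bifurcation model (deterministic, no seed).

    Nodes a, b (daughters) and c (parent) with unit edges (a, c) and
    (b, c); binary signals g1=(1,1,1), g2=(1,0,1), g3=(1,1,0), g4=(0,1,0)
    over (a, b, c); reverse-time filtration f(a)=f(b)=0, f(c)=1.
    """
    A = np.array([[0.0, 0.0, 1.0],
                  [0.0, 0.0, 1.0],
                  [1.0, 1.0, 0.0]])
    graph = CellGraph.from_adjacency(sp.csr_matrix(A),
                                     node_ids=np.array(list("abc"), dtype=object))
    signals = GeneSignalSet(
        np.array(["g1", "g2", "g3", "g4"], dtype=object),
        np.array([[1.0, 1.0, 1.0],
                  [1.0, 0.0, 1.0],
                  [1.0, 1.0, 0.0],
                  [0.0, 1.0, 0.0]]),
    )
    truth = {"filtration": np.array([0, 0, 1]),
             "roles": {"g1": "constant", "g2": "parent+daughter",
                       "g3": "both-daughters", "g4": "single-daughter"}}
    return SyntheticBundle(points=None, graph=graph, signals=signals, truth=truth)


# --- bifurcating expression simulator -------------------------------------

#: archetype name -> class used for PRQ quadrant classification
ARCHETYPE_CLASSES = {
    "constant": "constant",
    "parent+daughter1": "parent+one-daughter",
    "parent+daughter2": "parent+one-daughter",
    "both-daughters": "both-daughters",
    "daughter1-only": "single-daughter",
    "daughter2-only": "single-daughter",
}

_N_STAGES = 7

#: log-scale expression level of an "on" gene (log1p units; an active
#: marker gene typically swings ~3 log-units from silent to expressed)
_ON_LEVEL = 3.0
_TRUNK_STAGES = (1, 2, 3, 4)
_BRANCH_STAGES = (5, 6, 7)


def _archetype_profile(archetype: str, stage: np.ndarray, branch: np.ndarray):
    """Noise-free expression of one archetype along the Y trajectory.

    ``branch`` is 0 on the trunk, 1/2 on the daughters.  Profiles are the
    binary expression programmes of the three-node bifurcation model,
    extended over the stages: the transition is a step at the branch
    point, which the per-stage cell placement turns into a one-stage ramp
    on the graph.
    """
    on_trunk = branch == 0
    on_b1 = branch == 1
    on_b2 = branch == 2
    x = np.zeros(stage.shape, dtype=float)
    if archetype == "constant":
        x[:] = _ON_LEVEL
    elif archetype in ("parent+daughter1", "parent+daughter2"):
        keep = on_b1 if archetype.endswith("1") else on_b2
        x[on_trunk | keep] = _ON_LEVEL
    elif archetype == "both-daughters":
        x[on_b1 | on_b2] = _ON_LEVEL
    elif archetype in ("daughter1-only", "daughter2-only"):
        keep = on_b1 if archetype.endswith("1") else on_b2
        x[keep] = _ON_LEVEL
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return x


def bifurcating_expression(n_cells_per_stage: int = 16,
                           n_genes_per_archetype: int = 20,
                           noise_sd: float = 0.1, seed: int = 0,
                           branch_coupling: float = 0.004) -> SyntheticBundle:
    """Y-shaped bifurcating expression: a trunk splitting into two branches.

    Cells occupy integer stages 1..7: the parental trunk spans stages 1-4,
    after which two daughter branches span stages 5-7.  The cell graph is
    the trajectory tree itself: consecutive trunk stages and the two
    branch-point attachments carry unit weight, while consecutive stages
    *within* a branch carry ``branch_coupling`` (default 0.004) -- newborn
    daughters still resemble the parent state and then diverge rapidly
    along their own branch.  This weak within-branch coupling keeps the
    Rayleigh quotients on the scale of the three-node bifurcation model
    instead of being diluted by branch volume.  With
    ``n_cells_per_stage > 1`` each stage becomes a block of cells and the
    couplings are split across the block pairs.  Genes follow archetypes
    -- constant, parent+daughter1, parent+daughter2, both-daughters-only,
    and single-daughter-only (one family per daughter) -- as step
    programmes at the branch point plus i.i.d. Gaussian noise of
    ``noise_sd``.  Truth records each cell's stage and branch, each
    gene's archetype, and the reverse-time filtration ``f = 7 - stage``.
    """
    if n_cells_per_stage < 1:
        raise ValueError("n_cells_per_stage must be positive")
    if n_genes_per_archetype < 1:
        raise ValueError("n_genes_per_archetype must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not (0 < branch_coupling <= 1):
        raise ValueError("branch_coupling must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    m = n_cells_per_stage
    stage_blocks = []  # (stage, branch, x, y)
    for s in _TRUNK_STAGES:
        stage_blocks.append((s, 0, float(s - 1), 0.0))
    for br, sign in ((1, 1.0), (2, -1.0)):
        for idx, s in enumerate(_BRANCH_STAGES):
            stage_blocks.append((s, br, 4.0 + idx * 0.7, sign * (1.0 + idx)))
    stage = np.repeat([b[0] for b in stage_blocks], m)
    branch = np.repeat([b[1] for b in stage_blocks], m)
    centres = np.repeat(np.array([[b[2], b[3]] for b in stage_blocks]), m, axis=0)
    points = centres + rng.normal(scale=0.1, size=centres.shape)

    n_blocks = len(stage_blocks)
    n = n_blocks * m
    A = np.zeros((n, n))

    def link(bi, bj, total_weight):
        # lineage coupling: cell l of one stage to cell l of the next,
        # forming m parallel strands whose quotients average (all-to-all
        # block coupling would instead create intra-stage effective edges
        # under Kron reduction, inflating reduced degrees)
        w = total_weight / m
        for ln in range(m):
            A[bi * m + ln, bj * m + ln] = w
            A[bj * m + ln, bi * m + ln] = w

    for bi in range(3):             # trunk chain 1-2-3-4
        link(bi, bi + 1, 1.0)
    link(3, 4, 1.0)                 # branch-point attachments
    link(3, 7, 1.0)
    for start in (4, 7):            # within-branch chains 5-6-7
        link(start, start + 1, branch_coupling)
        link(start + 1, start + 2, branch_coupling)
    if m > 1:                       # weak within-stage cohesion ties the strands
        for bi in range(n_blocks):
            blk = slice(bi * m, (bi + 1) * m)
            A[blk, blk] = branch_coupling / (100.0 * m)
    np.fill_diagonal(A, 0.0)

    graph = CellGraph.from_adjacency(sp.csr_matrix(A))

    names, rows, archetypes = [], [], []
    for archetype in ARCHETYPE_CLASSES:
        base = _archetype_profile(archetype, stage, branch)
        for g in range(n_genes_per_archetype):
            names.append(f"{archetype}_{g:03d}")
            archetypes.append(archetype)
            rows.append(base + rng.normal(scale=noise_sd, size=base.shape))
    signals = GeneSignalSet(np.array(names, dtype=object), np.vstack(rows))
    truth = {
        "stage": stage,
        "branch": branch,
        "archetype": np.array(archetypes, dtype=object),
        "archetype_class": np.array(
            [ARCHETYPE_CLASSES[a] for a in archetypes], dtype=object
        ),
        "filtration": _N_STAGES - stage,
    }
    return SyntheticBundle(points=points, graph=graph, signals=signals,
                           truth=truth, seed=seed)
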