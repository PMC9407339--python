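# Methods

This note records the models implemented in `sigsel`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations. Empirical statements here are the ones the
test suite and `scripts/acceptance.py` themselves compute.

## The cell graph and graph signals

A data set enters as a genes × cells matrix (Matrix Market triplet or
dense CSV/TSV; genes are rows throughout, the CellRanger convention) or
as a precomputed weighted edge list. The built-in preprocessing follows
the simple recipe: optional `log1p` or `tpm-log1p` normalization,
dispersion-ranked highly-variable-gene selection
(variance / (mean + 1e−8) of the normalized values), and optional PCA
(default 30 components) of the cells for graph building. Variance
stabilizing transforms are deliberately out of scope — users wanting one
supply a pre-normalized matrix. The scored signals are always the
retained normalized genes, never the principal components.

The k-nearest-neighbour graph (default k = 15) supports euclidean,
cosine, and Pearson-correlation distances and three weighting schemes:

* `unit` — every union-symmetrized k-nn edge has weight 1;
* `gaussian-kernel` — locally scaled heat kernel
  `exp(−d²/(σ_u σ_v))`, σ_u the distance from u to its k-th neighbour;
* `fuzzy-local-kernel` (default) — per-node membership
  `exp(−max(0, d − ρ_u)/σ_u)` with ρ_u the nearest-neighbour distance
  and σ_u calibrated by bisection so the memberships sum to log₂k,
  combined by the fuzzy union `w_uv + w_vu − w_uv·w_vu`. This
  approximates the fuzzy simplicial-set weights of UMAP without a UMAP
  dependency; exact UMAP weights can be supplied through the edge-list
  reader. The weights are used as-is (no renormalization) when building
  Laplacians.

`CellGraph` enforces symmetry, a zero diagonal, non-negative weights and
strictly positive degrees at 1e−8 relative tolerance. Induced subgraphs
of a filtration are the one sanctioned exception to the positive-degree
rule: a sublevel set may legitimately be edgeless (the bifurcation
example's first filtration step is), so `subgraph` permits isolated
nodes, and the normalized Laplacian refuses them explicitly.

## Single-scale scores

The combinatorial, normalized, and random-walk Laplacians are
`L = D − A`, `𝓛 = D^{−1/2} L D^{−1/2}`, and `L_rw = D^{−1} L`. The
Rayleigh quotient of a signal measures its roughness; the Laplacian
score divides by the degree-weighted graph variance
`Var_G(g) = Σ_v d_v (g(v) − μ_G(g))²`, making it affine-invariant and
undefined (an error, never a silent value) for constant signals.

## Eigenscores

`spectral_basis` computes the ascending eigenpairs of 𝓛, densely up to
4096 nodes (deterministic LAPACK path) and by restarted Lanczos above
that. Signs are fixed so each eigenvector's largest-magnitude entry is
positive; rankings are invariant to this choice, which exists purely for
reproducible output files. Zero eigenvalues (one per connected
component) are counted as "trivial" and excluded from rankings by
default. The default low-frequency selector keeps all eigenpairs with
λ < 0.1; within a degenerate eigenvalue cluster the per-coordinate
eigenscores refer to the solver's returned basis (norms over a dims
range spanning the whole cluster are rotation-invariant, individual
coordinates are not). Raw eigenscores are exported; any 2-D layout of
eigenscore space is delegated to external embedding tools.

## Markov stability and scale selection

The heat kernel `P(t) = exp(−t L_rw)` is evaluated through one symmetric
eigendecomposition of 𝓛 per graph, reused across all Markov times
(`P(t) = D^{−1/2} U e^{−tΛ} Uᵀ D^{1/2}`); entries below −1e−12 are
clipped to zero. Continuous Markov stability of a partition is
`Σ_{u,v} (π_u P(t)_{uv} − π_u π_v) δ(c_u, c_v)` with π = d/Σd, a value
in (−1/2, 1]. It is maximized per time by a Louvain scheme (greedy
single-node moves plus aggregation, numba-compiled) operating directly
on the dense symmetrized quality matrix — the matrix is dense for any
t > 0, so a sparse-graph Louvain would gain nothing. Node visiting order
is drawn per level from the seeded generator; gain ties break toward the
lowest community index; a node moves only on a strictly positive gain
(tolerance 1e−12). The linear small-t approximation of stability is not
implemented; the eigendecomposition route is exact and adequate at the
graph sizes this package targets (≲ a few thousand cells).

One mathematical consequence worth stating: on a complete graph all
non-trivial eigenvalues of L_rw coincide, so the stability of any
partition is `e^{−tλ}(1 − Σ_C π_C²)` and the singleton partition is the
exact maximizer at every finite time. "A complete graph has no
substructure" therefore manifests as a globally flat VI curve, not as an
all-in-one optimum.

`scan_scales` (default: 100 logarithmically spaced times in
[10⁻², 10²], 20 restarts per time) retains the best-stability partition
per time, the mean pairwise VI across the restarts (VI in bits,
`2H(P,Q) − H(P) − H(Q)`), and, as a diagnostic only, the VI between best
partitions at consecutive times. Scale selection operates on plateaus:

* a plateau is a maximal run of grid points with equal mean VI (1e−9
  tolerance) *and* an unchanged community count of the best partition —
  VI alone cannot distinguish two adjacent robust scales that are both
  perfectly reproducible (VI = 0);
* a plateau is selected when neither flanking VI value is smaller
  (boundaries count as satisfied; an adjacent equal-VI plateau with a
  different community count is a distinct scale, not a disqualifier),
  when its value lies below (1 − 0.01) × max VI, and when it persists
  for at least 3 grid points — robust scales occupy intervals of the
  Markov-time axis, transition states between scales are short-lived;
* a plateau spanning the entire grid (flat curve, single stable
  partition) yields the largest time;
* each selected plateau is reported by its midpoint time.

The MLS at the selected times is computed via
`MLS(g,t) = (gᵀDg − gᵀ diag(d) P(t) g)/Var_G(g)`, using detailed balance
(`diag(d)P(t)` is symmetric); it is 0 at t = 0, tends to 1 as t → ∞, and
reduces to the classic Laplacian score when P(t) is replaced by the
one-step matrix D^{−1}A. Exports include the classic score as a
comparison column.

## Persistence

A filtration is an integer label per cell; `Filtration.from_times`
implements the reverse-time convention f = t_max − t under which late
(differentiated) cells enter first and merge through their ancestors.
`kron_reduce` forms the Schur complement
`L[α,α] − L[α,αᶜ] L[αᶜ,αᶜ]^{−1} L[αᶜ,α]`; the eliminated block is
singular exactly when some connected component avoids α, which is
detected by component labelling first and reported as an error naming
the offending nodes. For combinatorial Laplacians the result is cleaned
to an exact Laplacian: floating-point positive off-diagonals (clipped at
1e−10 relative, larger ones logged) are zeroed and the diagonal
rebalanced so rows sum exactly to zero. Reductions of normalized
Laplacians skip this clean-up (their rows do not sum to zero).

Numerical nullity counts eigenvalues below 1e−8 × λ_max — a scale-free
cutoff — and equals the persistent Betti-0 number computed independently
from connected components; the test suite asserts this equality on 100
random filtered graphs. The normalized PRQ uses the degree matrix of the
*reduced* graph (the diagonal of L^{ij}); a restricted signal supported
only on zero-degree reduced nodes is an error, never a silent zero,
because silent zeros would corrupt rankings. `prq_map` evaluates batches
of (i, j) pairs, flags per-gene failures in a report instead of dropping
genes, and `classify_bifurcation_role` encodes the quadrant rule: above
the diagonal by more than 0.05 → parent plus one daughter, below →
both daughters only, within the ±0.05 band → single daughter, both
quotients under 0.1 → constant/housekeeping.

## Synthetic fixtures: what they plant, and what they do not show

All generators draw from a single `numpy` generator stream per bundle,
so the same seed is bit-identical. None of them emulate scRNA-seq count
noise (no negative-binomial sampling, no dropout): they plant the
geometric structures the scores are designed to detect, so passing tests
certify the graph-signal machinery, not robustness to count-level
technical noise.

**Four balls** (400 points, 30 dimensions). Four isotropic Gaussian
clouds (sd 0.35 of the half-spacing) at the corners of a planar square.
Gaussian tails are essential: uniform points in *touching hard balls* in
30 dimensions concentrate near the surfaces, the k = 15 graph comes out
with four connected components, and no pair of low-frequency
eigenvectors can separate the ball pairs. The ball-pair signals are
±1-valued because a 0/1 indicator of half the graph places ≈ 0.707 of
its norm on the trivial eigenvector, capping any other eigenscore at
≈ 0.707; centred signals reach |eig| > 0.97 on their matching
eigenvector.

**Hierarchical benchmark** (4-ary, depth 4, 4-node leaf groups, 1024
nodes). Complete weighted graph with weight `0.1^(depth − s)` for nodes
sharing their deepest community at level s, times a ±3% seeded jitter.
The jitter breaks exact symmetry (which would make Louvain's tie-break
deterministic and the VI curve uninformative) while keeping sibling
merges nearly simultaneous, so transition states live for less than one
grid step and the four planted scales — 256, 64, 16, 4 communities —
are the only surviving plateaus. A Bernoulli-edge realization was
rejected: quenched randomness in sparse realizations locks intermediate
merge states that 20 Louvain restarts reproduce exactly, creating
spurious robust scales.

**Three communities** (60/30/15 nodes, w_in = 1, w_out = 0.05, ±20%
jitter). The larger jitter makes Louvain runs disagree at transition
times (VI spikes) while the planted 3-way partition and its 2-way
coarsening (the two smallest communities merge) remain exactly
reproducible. Bundled signals: per-community indicators that are
uniformly random off-community, plus a fully random signal.

**Toy bifurcation.** The exact three-node graph, its four binary
signals, and the reverse-time filtration; deterministic.

**Bifurcating expression** (7 stages, 16 cells per stage, 160 cells,
120 genes). The cell graph is the trajectory tree itself: unit-weight
couplings along the trunk and at the two branch-point attachments,
weak couplings (0.004) between consecutive stages within a branch —
newborn daughters resemble the parent state and then diverge rapidly —
and stages coupled *per lineage strand* (cell i to cell i). Both
choices are load-bearing. Normalized Rayleigh quotients are
cut-over-volume ratios, so strong within-branch cohesion would dilute
every quotient toward zero and erase the quadrant geometry; and
all-to-all stage coupling would generate intra-stage effective edges
under Kron reduction that inflate reduced degrees and push branch-only
genes off the diagonal. With per-lineage strands, each strand reproduces
the toy model's quotients exactly and the per-gene quotient averages 16
nearly independent strand contributions, shrinking noise roughly as
1/√16. Gene programmes are steps at the branch point with "on" level
3.0 (a typical marker-gene swing in log1p units) plus i.i.d. Gaussian
noise. Quadrant classification of PRQ(2,6) against PRQ(6,6) recovers
the planted archetypes with mean accuracy 0.965 (minimum 0.95 over ten
seeds) at noise sd 0.1, and 0.998 at sd 0.05 — the numbers the test
suite recomputes.

## Problem sizes and determinism

The default benchmark scan (1024 nodes × 100 times × 20 restarts) runs
in a few minutes on one CPU: one 1024-dimensional eigendecomposition,
one dense matrix reconstruction per time, and 2000 numba-compiled
Louvain runs. Exhaustive stability enumeration uses 6-node graphs
(203 set partitions each). All randomness — generators, Louvain orders,
restarts — derives from explicit integer seeds; pipelines rerun with the
same configuration and seed produce byte-identical tables.

## Limitations

* Markov-stability optimization is a heuristic; the exhaustive check on
  6-node graphs requires ≥ 90% exact hits, not universal optimality.
* Scale selection reports plateau midpoints; on fixtures where VI is
  identically zero over long stretches the midpoint is a convention,
  not an estimate.
* Eigenscore coordinates within degenerate eigenvalue clusters depend on
  the solver's basis (norms over the cluster do not).
* The PRQ quadrant geometry is quantitative only at toy-like
  cut/volume scale; on dense k-nn graphs with large branches the same
  above/below/on-diagonal structure exists but compresses toward the
  origin, and the fixed ±0.05 band is then too wide an instrument.
* Higher-order persistent Laplacians (simplicial complexes), persistent
  homology barcodes, and pseudotime inference itself are out of scope.
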