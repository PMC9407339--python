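"""Readers, writers, preprocessing, and run configuration.

Canonical external formats (all plain text):

* expression matrices: Matrix Market triplet directory (``matrix.mtx`` +
  ``genes.tsv`` + ``barcodes.tsv``, genes as rows / cells as columns, the
  CellRanger convention) or dense CSV/TSV with gene ids in the first
  column and cell barcodes in the header;
* point clouds: dense CSV/TSV, first column cell id, header of feature
  names;
* graphs: undirected TSV edge lists ``node_u<TAB>node_v<TAB>weight``, one
  line per unordered pair;
* filtrations: TSV ``cell_id<TAB>integer_value``;
* partitions: TSV ``cell_id<TAB>community``;
* run configuration: TOML.

Floats are written with 10 significant digits so that writer output
round-trips through the matching reader.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .graph import CellGraph, GeneSignalSet

__all__ = [
    "FormatError",
    "RunConfig",
    "load_config",
    "save_config",
    "read_expression",
    "write_expression",
    "read_point_cloud",
    "write_point_cloud",
    "read_edge_list",
    "write_edge_list",
    "read_filtration",
    "write_filtration",
    "read_partition",
    "write_partition",
    "write_eigenscores",
    "write_profile",
    "preprocess",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

NORMALIZATIONS = ("none", "log1p", "tpm-log1p")


class FormatError(ValueError):
    """A file failed to parse or its pieces are dimensionally inconsistent."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _dedup_ids(ids):
    """Disambiguate duplicate identifiers by suffixing ``.1``, ``.2``, ..."""
    seen: dict = {}
    out = []
    for x in ids:
        if x in seen:
            seen[x] += 1
            out.append(f"{x}.{seen[x]}")
        else:
            seen[x] = 0
            out.append(x)
    return np.array(out, dtype=object)


def _read_sidecar(path: Path):
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def read_expression(path, fmt=None):
    """Read a genes-by-cells expression matrix.

    ``fmt`` is one of ``mtx-dir``, ``dense-csv``, ``dense-tsv``; when
    omitted it is inferred from the path (a directory implies ``mtx-dir``).
    Returns ``(GeneSignalSet, cell_ids)``.  Duplicate gene ids are
    suffixed; all-zero genes or cells are reported via logging but kept.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx-dir"
        elif path.suffix.lower() == ".csv":
            fmt = "dense-csv"
        else:
            fmt = "dense-tsv"
    if fmt == "mtx-dir":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        if not genes_f.exists():
            genes_f = path / "features.tsv"
        barcodes_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise FormatError(f"missing file {f}")
        try:
            M = scipy.io.mmread(mtx)
        except ValueError as err:
            raise FormatError(f"cannot parse {mtx}: {err}") from err
        M = sp.coo_matrix(M).toarray().astype(float)
        gene_ids = _read_sidecar(genes_f)
        cell_ids = _read_sidecar(barcodes_f)
        if M.shape[0] != len(gene_ids):
            raise FormatError(
                f"matrix has {M.shape[0]} rows but {genes_f} lists "
                f"{len(gene_ids)} genes"
            )
        if M.shape[1] != len(cell_ids):
            raise FormatError(
                f"matrix has {M.shape[1]} columns but {barcodes_f} lists "
                f"{len(cell_ids)} barcodes"
            )
    elif fmt in ("dense-csv", "dense-tsv"):
        sep = "," if fmt == "dense-csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
            M = df.to_numpy(dtype=float)
        except ValueError as err:
            raise FormatError(f"cannot parse {path}: {err}") from err
        gene_ids = df.index.to_numpy(dtype=object)
        cell_ids = df.columns.to_numpy(dtype=object)
    else:
        raise FormatError(f"unknown expression format {fmt!r}")
    if not np.all(np.isfinite(M)):
        raise FormatError(f"non-finite entries in {path}")
    gene_ids = _dedup_ids(gene_ids)
    empty_genes = int(np.sum(~M.any(axis=1)))
    empty_cells = int(np.sum(~M.any(axis=0)))
    if empty_genes or empty_cells:
        logger.info(
            "%s: %d all-zero genes, %d all-zero cells", path, empty_genes, empty_cells
        )
    return GeneSignalSet(gene_ids, M), np.asarray(cell_ids, dtype=object)


def write_expression(signals: GeneSignalSet, cell_ids, path, fmt="dense-tsv"):
    """Write a genes-by-cells matrix in ``mtx-dir`` or dense CSV/TSV form."""
    path = Path(path)
    cell_ids = np.asarray(cell_ids, dtype=object)
    if cell_ids.shape[0] != signals.n_cells:
        raise FormatError(
            f"{cell_ids.shape[0]} cell ids for {signals.n_cells} columns"
        )
    if fmt == "mtx-dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(signals.values))
        (path / "genes.tsv").write_text(
            "".join(f"{g}\n" for g in signals.gene_ids)
        )
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cell_ids))
    elif fmt in ("dense-csv", "dense-tsv"):
        sep = "," if fmt == "dense-csv" else "\t"
        df = pd.DataFrame(signals.values, index=signals.gene_ids.astype(str),
                          columns=cell_ids.astype(str))
        df.index.name = "gene_id"
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    else:
        raise FormatError(f"unknown expression format {fmt!r}")


# ---------------------------------------------------------------------------
# point clouds, graphs, filtrations, partitions
# ---------------------------------------------------------------------------


def read_point_cloud(path):
    """Dense cells-by-features table; returns ``(points, cell_ids)``."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), df.index.to_numpy(dtype=object)


def write_point_cloud(points, cell_ids, path):
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    points = np.asarray(points, dtype=float)
    df = pd.DataFrame(
        points,
        index=np.asarray(cell_ids, dtype=object).astype(str),
        columns=[f"f{i}" for i in range(points.shape[1])],
    )
    df.index.name = "cell_id"
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def write_edge_list(G: CellGraph, path):
    """Undirected TSV edge list, one line per unordered pair (u < v)."""
    coo = sp.triu(G.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        for u, v, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{G.node_ids[u]}\t{G.node_ids[v]}\t{_FLOAT_FMT % w}\n")


def read_edge_list(path, node_ids=None) -> CellGraph:
    """Read an undirected TSV edge list into a :class:`CellGraph`.

    ``node_ids`` fixes the node order; otherwise nodes appear in order of
    first occurrence.
    """
    us, vs, ws = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 tab-separated fields")
            try:
                w = float(parts[2])
            except ValueError as err:
                raise FormatError(f"{path}:{ln}: non-numeric weight") from err
            us.append(parts[0])
            vs.append(parts[1])
            ws.append(w)
    if node_ids is None:
        node_ids = list(dict.fromkeys(us + vs))
    node_ids = np.asarray(node_ids, dtype=object)
    index = {x: i for i, x in enumerate(node_ids)}
    try:
        rows = [index[u] for u in us]
        cols = [index[v] for v in vs]
    except KeyError as err:
        raise FormatError(f"{path}: unknown node id {err.args[0]!r}") from err
    n = len(node_ids)
    A = sp.coo_matrix((ws, (rows, cols)), shape=(n, n))
    A = A + A.T
    return CellGraph.from_adjacency(A, node_ids)


def write_filtration(node_ids, values, path):
    with open(path, "w") as fh:
        for nid, v in zip(node_ids, np.asarray(values, dtype=np.int64)):
            fh.write(f"{nid}\t{v}\n")


def read_filtration(path, node_ids=None):
    """TSV ``cell_id<TAB>integer``; returns values aligned to ``node_ids``
    (or file order, with the ids, when ``node_ids`` is None)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "value"],
                     dtype={"cell_id": str})
    if not np.issubdtype(df["value"].dtype, np.integer):
        raise FormatError(f"{path}: filtration values must be integers")
    if node_ids is None:
        return df["value"].to_numpy(), df["cell_id"].to_numpy(dtype=object)
    lookup = dict(zip(df["cell_id"], df["value"]))
    try:
        return np.array([lookup[str(n)] for n in node_ids], dtype=np.int64), np.asarray(
            node_ids, dtype=object
        )
    except KeyError as err:
        raise FormatError(f"{path}: missing filtration value for {err.args[0]!r}")


def write_partition(node_ids, labels, path):
    with open(path, "w") as fh:
        for nid, c in zip(node_ids, np.asarray(labels, dtype=np.int64)):
            fh.write(f"{nid}\t{c}\n")


def read_partition(path, node_ids=None):
    values, ids = read_filtration(path, node_ids)
    return values, ids


def write_eigenscores(E, path, dims=None):
    """TSV with columns ``gene_id, eig_1, ..., eig_k, norm`` plus a JSON
    metadata sidecar (eigenvalues and selector info) at ``<path>.meta.json``."""
    if dims is None:
        dims = list(range(E.n_trivial, E.scores.shape[1]))
    dims = list(dims)
    df = pd.DataFrame({"gene_id": E.gene_ids.astype(str)})
    for d in dims:
        df[f"eig_{d}"] = E.scores[:, d]
    df["norm"] = E.norms(dims)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = {
        "eigenvalues": [float(x) for x in E.eigenvalues],
        "n_trivial": int(E.n_trivial),
        "dims": [int(d) for d in dims],
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def write_profile(profile, path, partition_dir=None):
    """StabilityProfile to JSON; optionally one partition TSV per selected
    scale in ``partition_dir``."""
    payload = {
        "times": profile.times.tolist(),
        "stability": profile.stabilities.tolist(),
        "n_communities": profile.n_communities.tolist(),
        "mean_vi": profile.mean_vi.tolist(),
        "successive_vi": profile.successive_vi.tolist(),
        "selected_indices": profile.selected_indices.tolist(),
        "selected_scales": profile.selected_scales.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    if partition_dir is not None:
        partition_dir = Path(partition_dir)
        partition_dir.mkdir(parents=True, exist_ok=True)
        node_ids = getattr(profile, "node_ids", None)
        for idx in profile.selected_indices:
            part = profile.partitions[idx]
            ids = node_ids if node_ids is not None else np.arange(part.n_nodes)
            write_partition(
                ids, part.labels, partition_dir / f"partition_t{profile.times[idx]:g}.tsv"
            )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline configuration with serializable defaults.

    Defaults mirror the standard single-cell recipe: log1p normalization,
    dispersion-ranked highly variable genes, PCA to 30 components for
    graph building, and a k=15 fuzzy-weighted k-nn graph.
    """

    expression: str = ""
    edges: str = ""
    filtration: str = ""
    output_dir: str = "."
    normalization: str = "log1p"
    n_hvg: int = 10000
    n_pcs: int = 30
    subsample_cells: int = 0
    knn_k: int = 15
    metric: str = "euclidean"
    weighting: str = "fuzzy-local-kernel"
    max_eigenvalue: float = 0.1
    n_eigenvectors: int = 0
    t_min: float = 1e-2
    t_max: float = 1e2
    n_times: int = 100
    runs: int = 20
    seed: int = 0
    pairs: list = field(default_factory=list)

    def validate(self):
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {NORMALIZATIONS}, "
                f"got {self.normalization!r}"
            )
        for key in ("expression", "edges", "filtration"):
            val = getattr(self, key)
            if val and not Path(val).exists():
                raise ValueError(f"{key} path does not exist: {val}")
        return self


def _toml_value(v):
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def save_config(config: RunConfig, path):
    """Write a RunConfig as TOML (flat key = value lines)."""
    lines = [
        f"{f.name} = {_toml_value(getattr(config, f.name))}"
        for f in dataclasses.fields(config)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**data)
    if isinstance(cfg.pairs, list):
        cfg.pairs = [list(map(int, p)) for p in cfg.pairs]
    return cfg


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

_DISPERSION_EPS = 1e-8


def preprocess(raw: GeneSignalSet, normalization="log1p", n_hvg=10000, n_pcs=30,
               subsample_cells=0, seed=0):
    """Normalize, select highly variable genes, and build graph features.

    Normalization: ``none`` passes raw values through; ``log1p`` applies
    ``log(x+1)``; ``tpm-log1p`` scales each cell to a million total counts
    first.  Genes are ranked by dispersion (variance / (mean + 1e-8) of
    the normalized values) and the top ``n_hvg`` retained (clipped with a
    warning when fewer genes exist).  ``n_pcs > 0`` projects cells onto
    that many principal components for graph building; the scoring
    signals are always the retained normalized genes, never the PCs.

    Returns ``(features, retained, cell_idx)`` where ``features`` is
    cells x (PCs or retained genes), ``retained`` the GeneSignalSet to
    score, and ``cell_idx`` the (possibly subsampled) cell indices.
    """
    X = raw.values
    if normalization == "none":
        norm = X.copy()
    elif normalization == "log1p":
        norm = np.log1p(X)
    elif normalization == "tpm-log1p":
        totals = X.sum(axis=0)
        totals[totals == 0] = 1.0
        norm = np.log1p(X / totals[None, :] * 1e6)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    mean = norm.mean(axis=1)
    var = norm.var(axis=1)
    dispersion = var / (mean + _DISPERSION_EPS)
    if n_hvg > raw.n_genes:
        logger.warning("n_hvg=%d exceeds gene count %d; keeping all genes",
                       n_hvg, raw.n_genes)
        n_hvg = raw.n_genes
    order = np.argsort(-dispersion, kind="mergesort")[:n_hvg]
    order = np.sort(order)  # keep original gene order among the retained
    retained = GeneSignalSet(raw.gene_ids[order], norm[order])

    features = retained.values.T  # cells x genes
    cell_idx = np.arange(features.shape[0])
    if subsample_cells and subsample_cells < features.shape[0]:
        rng = np.random.default_rng(seed)
        cell_idx = np.sort(rng.choice(features.shape[0], subsample_cells,
                                      replace=False))
        features = features[cell_idx]
        retained = retained.restrict_cells(cell_idx)
    if n_pcs and n_pcs > 0:
        n_comp = min(n_pcs, features.shape[0] - 1, features.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
        features = pca.fit_transform(features)
    return features, retained, cell_idx
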