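"""Expression-matrix container and readers.

The package works on a light-weight dataset object rather than a full
AnnData: a counts matrix (cells x genes), optional log-transformed counts,
and — for simulated data — per-cell ground truth (simulation time and
branch identity) that benchmark metrics need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for n in names:
        if n in seen:
            dups.append(n)
        seen[n] = 1
    if dups:
        raise ValueError(f"duplicated {what}: {sorted(set(dups))}")


@dataclass
class ExpressionDataset:
    """Cells-by-genes expression matrix with optional ground truth.

    Attributes
    ----------
    counts
        Raw (or externally normalized) expression values, shape
        ``(n_cells, n_genes)``.
    cell_ids, gene_names
        Unique identifiers for rows and columns.
    log_counts
        Log-transformed normalized expression, same shape as ``counts``;
        ``None`` until :func:`treecap.preprocess.normalize_log` is applied.
    sim_time
        Per-cell ground-truth simulation time (synthetic data only).
    branch_label
        Per-cell ground-truth branch identity (synthetic data only).
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_names: list[str]
    log_counts: np.ndarray | None = None
    sim_time: np.ndarray | None = None
    branch_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_names = list(map(str, self.gene_names))
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        n, m = self.counts.shape
        if n != len(self.cell_ids) or m != len(self.gene_names):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cell ids x {len(self.gene_names)} gene names"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_names, "gene names")
        if self.log_counts is not None:
            self.log_counts = np.asarray(self.log_counts, dtype=float)
            if self.log_counts.shape != self.counts.shape:
                raise ValueError("log_counts shape must match counts")
        for attr in ("sim_time", "branch_label"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (n,):
                    raise ValueError(f"{attr} must have one entry per cell")
                setattr(self, attr, v)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            counts=self.counts[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_names=list(self.gene_names),
            log_counts=None if self.log_counts is None else self.log_counts[idx],
            sim_time=None if self.sim_time is None else self.sim_time[idx],
            branch_label=None if self.branch_label is None else self.branch_label[idx],
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_indices(genes)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            cell_ids=list(self.cell_ids),
            gene_names=[self.gene_names[i] for i in idx],
            log_counts=None if self.log_counts is None else self.log_counts[:, idx],
            sim_time=self.sim_time,
            branch_label=self.branch_label,
        )

    def with_(self, **kwargs) -> "ExpressionDataset":
        return replace(self, **kwargs)


@dataclass
class EmbeddingSpace:
    """PCA embedding: scores ``Z`` (cells x components) and loadings."""

    Z: np.ndarray
    explained_variance: np.ndarray
    components: np.ndarray  # (p, n_genes_used)
    genes: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.Z.shape[1]


@dataclass
class NeighborGraph:
    """Undirected weighted kNN graph on cells.

    Edges are the union ("mutualization") of the directed k-nearest-neighbor
    lists; weights are Euclidean distances in the embedding.
    """

    n_vertices: int
    edges: np.ndarray  # (n_edges, 2) int, i < j
    weights: np.ndarray  # (n_edges,) float
    k: int

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


def _read_table(path: Path, sep: str) -> ExpressionDataset:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as e:
        raise OSError(f"empty or unreadable file: {path}") from e
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise OSError(f"no data parsed from {path}")
    return ExpressionDataset(
        counts=df.to_numpy(dtype=float),
        cell_ids=list(df.index.astype(str)),
        gene_names=list(df.columns.astype(str)),
    )


def _read_mtx(path: Path, features_path=None, barcodes_path=None) -> ExpressionDataset:
    from scipy.io import mmread

    def _sibling(names):
        for n in names:
            p = path.parent / n
            if p.exists():
                return p
        return None

    features_path = Path(features_path) if features_path else _sibling(
        ["features.tsv", "genes.tsv", "features.txt", "genes.txt"]
    )
    barcodes_path = Path(barcodes_path) if barcodes_path else _sibling(
        ["barcodes.tsv", "barcodes.txt"]
    )
    if features_path is None or barcodes_path is None:
        raise OSError(
            f"MTX input {path} needs feature and barcode lists "
            "(features.tsv/genes.tsv and barcodes.tsv alongside, or explicit paths)"
        )
    try:
        mat = mmread(str(path))
    except Exception as e:  # scipy raises ValueError on malformed headers
        raise OSError(f"could not parse MatrixMarket file {path}: {e}") from e
    if hasattr(mat, "toarray"):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    genes = [l.split("\t")[0].strip() for l in features_path.read_text().splitlines() if l.strip()]
    cells = [l.strip() for l in barcodes_path.read_text().splitlines() if l.strip()]
    if mat.shape == (len(cells), len(genes)):
        pass
    elif mat.shape == (len(genes), len(cells)):
        mat = mat.T
    else:
        raise ValueError(
            f"MTX shape {mat.shape} matches neither {len(cells)} barcodes x "
            f"{len(genes)} features nor its transpose"
        )
    return ExpressionDataset(counts=mat, cell_ids=cells, gene_names=genes)


def _read_h5ad(path: Path) -> ExpressionDataset:
    import anndata as ad

    a = ad.read_h5ad(str(path))
    X = a.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    kwargs = {}
    if "sim_time" in a.obs:
        kwargs["sim_time"] = a.obs["sim_time"].to_numpy(dtype=float)
    if "branch_label" in a.obs:
        kwargs["branch_label"] = a.obs["branch_label"].to_numpy()
    if "log_counts" in a.layers:
        L = a.layers["log_counts"]
        kwargs["log_counts"] = L.toarray() if hasattr(L, "toarray") else np.asarray(L)
    return ExpressionDataset(
        counts=np.asarray(X, dtype=float),
        cell_ids=list(a.obs_names.astype(str)),
        gene_names=list(a.var_names.astype(str)),
        **kwargs,
    )


def load_counts(path, fmt: str | None = None, *, features_path=None, barcodes_path=None) -> ExpressionDataset:
    """Load a counts matrix from MTX, CSV/TSV, or h5ad.

    ``fmt`` is inferred from the file suffix when omitted. CSV/TSV files must
    have cells in rows (first column = cell ids, header = gene names); MTX
    orientation is resolved against the feature/barcode list lengths.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"file not found: {path}")
    if path.stat().st_size == 0:
        raise OSError(f"empty file: {path}")
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".h5ad": "h5ad"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    if fmt == "mtx":
        return _read_mtx(path, features_path, barcodes_path)
    if fmt == "csv":
        return _read_table(path, ",")
    if fmt == "tsv":
        return _read_table(path, "\t")
    if fmt == "h5ad":
        return _read_h5ad(path)
    raise ValueError(f"unknown format {fmt!r}")


def to_anndata(ds: ExpressionDataset):
    """Convert to an AnnData (counts in X, log_counts as a layer)."""
    import anndata as ad
    import pandas as pd

    obs = pd.DataFrame(index=pd.Index(ds.cell_ids, name="cell_id"))
    if ds.sim_time is not None:
        obs["sim_time"] = ds.sim_time
    if ds.branch_label is not None:
        obs["branch_label"] = ds.branch_label
    a = ad.AnnData(
        X=ds.counts.copy(),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(ds.gene_names, name="gene")),
    )
    if ds.log_counts is not None:
        a.layers["log_counts"] = ds.log_counts.copy()
    return a
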