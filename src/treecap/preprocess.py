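"""Filtering, normalization, feature selection, PCA, and the kNN cell graph.

Conventions follow common scRNA-seq practice: cells are filtered before
genes, library-size normalization targets the median per-cell total by
default, and highly variable genes are ranked by binned normalized
dispersion computed on de-logged expression.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .dataset import EmbeddingSpace, ExpressionDataset, NeighborGraph


def filter_cells_genes(
    ds: ExpressionDataset, min_genes: int = 200, min_cells: int = 3
) -> ExpressionDataset:
    """Keep cells expressing >= ``min_genes`` genes, then genes expressed in
    >= ``min_cells`` of the remaining cells (one pass each, cells first)."""
    expressed = ds.counts > 0
    keep_cells = np.flatnonzero(expressed.sum(axis=1) >= min_genes)
    if keep_cells.size == 0:
        raise ValueError("empty dataset after filtering")
    sub = ds.subset_cells(keep_cells)
    keep_genes = np.flatnonzero((sub.counts > 0).sum(axis=0) >= min_cells)
    if keep_genes.size == 0:
        raise ValueError("empty dataset after filtering")
    return sub.subset_genes([sub.gene_names[i] for i in keep_genes])


def normalize_log(ds: ExpressionDataset, target_sum: float | None = None) -> ExpressionDataset:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    ``target_sum=None`` uses the median of per-cell totals. The raw counts
    are kept; the result is stored in ``log_counts``.
    """
    if np.any(ds.counts < 0):
        raise ValueError("normalize_log requires non-negative counts")
    totals = ds.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = [ds.cell_ids[i] for i in zero[:10]]
        raise ValueError(f"cells with zero total counts cannot be normalized: {ids}")
    if target_sum is None:
        target_sum = float(np.median(totals))
    scaled = ds.counts * (target_sum / totals)[:, None]
    return ds.with_(log_counts=np.log1p(scaled))


def scale_min_max(ds: ExpressionDataset) -> ExpressionDataset:
    """Per-gene affine rescale of ``counts`` to [0, 1]; constant genes map to 0.

    Intended for externally normalized matrices that contain negative values.
    """
    lo = ds.counts.min(axis=0)
    hi = ds.counts.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = (ds.counts - lo) / safe
    scaled[:, span == 0] = 0.0
    return ds.with_(counts=scaled)


N_DISPERSION_BINS = 20


def normalized_dispersion(ds: ExpressionDataset, n_bins: int = N_DISPERSION_BINS) -> np.ndarray:
    """Per-gene normalized dispersion.

    Dispersion = variance/mean of ``expm1(log_counts)``, z-scored within
    equal-frequency bins of the gene means (genes sorted by mean, ties by
    index, split into ``n_bins`` near-equal groups). Bins with zero spread
    (or a single gene) yield 0.
    """
    if ds.log_counts is None:
        raise ValueError("log_counts required; run normalize_log first")
    X = np.expm1(ds.log_counts)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    order = np.lexsort((np.arange(len(mean)), mean))
    nd = np.zeros(len(mean))
    for bin_idx in np.array_split(order, min(n_bins, len(mean))):
        d = disp[bin_idx]
        mu, sd = d.mean(), d.std(ddof=0)
        nd[bin_idx] = (d - mu) / sd if sd > 0 else 0.0
    return nd


def select_hvg(
    ds: ExpressionDataset,
    n_top: int | None = None,
    dispersion_cutoff: float | None = None,
) -> list[str]:
    """Highly variable genes, by top-``n_top`` normalized dispersion or by a
    dispersion cutoff (exactly one of the two must be given)."""
    if (n_top is None) == (dispersion_cutoff is None):
        raise ValueError("give exactly one of n_top / dispersion_cutoff")
    nd = normalized_dispersion(ds)
    if n_top is not None:
        if n_top > ds.n_genes:
            raise ValueError(f"n_top={n_top} exceeds {ds.n_genes} genes")
        # stable rank: higher dispersion first, ties by gene order
        order = np.lexsort((np.arange(len(nd)), -nd))
        keep = sorted(order[:n_top])
    else:
        keep = np.flatnonzero(nd > dispersion_cutoff)
    return [ds.gene_names[i] for i in keep]


def pca(ds: ExpressionDataset, genes: list[str] | None = None, p: int = 50) -> EmbeddingSpace:
    """Exact PCA of the centered log-expression over ``genes``.

    Component signs are fixed so the largest-magnitude loading of each axis
    is positive, making the embedding deterministic.
    """
    if ds.log_counts is None:
        raise ValueError("log_counts required; run normalize_log first")
    if genes is None:
        genes = list(ds.gene_names)
    idx = ds.gene_indices(genes)
    X = ds.log_counts[:, idx]
    n, m = X.shape
    if p < 1:
        raise ValueError("p must be >= 1")
    if p > min(n, m):
        raise ValueError(f"p={p} exceeds min(n_cells, n_genes)={min(n, m)}")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :p], S[:p], Vt[:p]
    # deterministic sign: largest-|loading| entry of each axis positive
    for j in range(p):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    Z = U * S
    explained = S**2 / max(n - 1, 1)
    return EmbeddingSpace(Z=Z, explained_variance=explained, components=Vt, genes=list(genes))


def knn_graph(emb: EmbeddingSpace, k: int) -> NeighborGraph:
    """Union-mutualized k-nearest-neighbor graph with Euclidean weights.

    Distance ties are broken toward the lower cell index; self-loops are
    excluded.
    """
    Z = emb.Z
    n = Z.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells={n}")
    D = cdist(Z, Z)
    edge_set: set[tuple[int, int]] = set()
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf
        order = np.lexsort((np.arange(n), d))
        for j in order[:k]:
            edge_set.add((min(i, j), max(i, j)))
    edges = np.array(sorted(edge_set), dtype=int)
    weights = D[edges[:, 0], edges[:, 1]]
    return NeighborGraph(n_vertices=n, edges=edges, weights=weights, k=k)
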