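"""Single-cell alignment along matched cluster paths.

After tree alignment, cells of each root-to-leaf cluster path are ordered by
diffusion pseudotime (DPT) from a data-driven start cell, and the two
orderings are aligned with dynamic time warping (DTW). Per-gene kinetics
along the warped alignment are grouped by the sign of their regression
slopes.

The start cell is the expression-space diameter endpoint within the root
cluster: among root-cluster cells, the one whose largest distance to any
other cell in the dataset is maximal ("max-max"; the alternative "max-min"
reading is not used). DPT follows the accumulated-random-walk-transition
construction on a Gaussian-kernel kNN graph and is delegated to scanpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .dataset import ExpressionDataset
from .trajectory import Clustering


@dataclass
class PseudotimeOrdering:
    """Cells of one cluster path sorted by diffusion pseudotime."""

    cell_ids: list[str]
    pseudotime: np.ndarray  # non-decreasing, pseudotime[0] == 0
    start_cell: str
    path_clusters: list[int]
    cell_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __len__(self) -> int:
        return len(self.cell_ids)


@dataclass
class DTWAlignment:
    """Monotone warping path between two pseudotime orderings."""

    warping_path: list[tuple[int, int]]
    total_cost: float
    ordering_1: PseudotimeOrdering
    ordering_2: PseudotimeOrdering
    genes: list[str]

    def aligned_series(self, ds1: ExpressionDataset, ds2: ExpressionDataset, gene: str):
        """The two equal-length expression series of ``gene`` read off the
        warping path (log expression)."""
        g1 = ds1.gene_indices([gene])[0]
        g2 = ds2.gene_indices([gene])[0]
        e1 = ds1.log_counts[self.ordering_1.cell_indices, g1]
        e2 = ds2.log_counts[self.ordering_2.cell_indices, g2]
        i_idx = np.array([i for i, _ in self.warping_path])
        j_idx = np.array([j for _, j in self.warping_path])
        return e1[i_idx], e2[j_idx]


@dataclass
class GeneKinetics:
    gene: str
    slope_1: float
    slope_2: float
    group: str  # up_up | up_down | down_up | down_down | flat
    dtw_similarity: float


def select_start_cell(
    ds: ExpressionDataset, clustering: Clustering, root_cluster: int
) -> str:
    """Root-cluster cell with the longest distance (in log-expression space)
    to any other cell of the dataset; ties go to the lower cell index."""
    if ds.log_counts is None:
        raise ValueError("log_counts required")
    if ds.n_cells < 2:
        raise ValueError("need at least two cells to pick a start cell")
    members = clustering.members(root_cluster)
    if members.size == 0:
        raise ValueError(f"root cluster {root_cluster} is empty")
    D = cdist(ds.log_counts[members], ds.log_counts)
    far = D.max(axis=1)
    best = members[np.lexsort((members, -far))[0]]
    return ds.cell_ids[best]


def _knn_adjacency(X: np.ndarray, k: int) -> np.ndarray:
    n = X.shape[0]
    D = cdist(X, X)
    A = np.zeros((n, n), dtype=bool)
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf
        order = np.lexsort((np.arange(n), d))
        A[i, order[:k]] = True
    return A | A.T


def diffusion_pseudotime(
    ds: ExpressionDataset,
    path_cells: np.ndarray,
    start: str,
    k: int = 10,
    n_dcs: int = 10,
    path_clusters: list[int] | None = None,
    rep: np.ndarray | None = None,
    dense: bool = False,
) -> PseudotimeOrdering:
    """Diffusion pseudotime of ``path_cells`` from ``start``.

    A Gaussian-kernel transition matrix on the kNN graph of the path cells
    is spectrally decomposed; pseudotime is the accumulated-transition
    distance from the start cell over the top ``n_dcs`` non-stationary
    components (scanpy's DPT). The kNN subgraph must be connected.

    ``rep`` optionally supplies the coordinates used to build the neighbor
    graph (one row per cell of the full dataset, e.g. the PCA embedding);
    the default is the log-expression matrix. ``dense=True`` uses the full
    adaptive Gaussian kernel instead of truncating it to the kNN graph,
    which estimates pseudotime more stably on sparse cell populations.
    """
    import anndata as ad
    import scanpy as sc

    if ds.log_counts is None:
        raise ValueError("log_counts required")
    path_cells = np.asarray(path_cells, dtype=int)
    ids = [ds.cell_ids[i] for i in path_cells]
    if start not in ids:
        raise ValueError(f"start cell {start!r} is not among the path cells")
    n = len(path_cells)
    if n < 3:
        raise ValueError("need at least three cells for diffusion pseudotime")
    source = ds.log_counts if rep is None else np.asarray(rep, dtype=float)
    if source.shape[0] != ds.n_cells:
        raise ValueError("rep must have one row per cell of the dataset")
    X = source[path_cells]
    k_eff = min(k, n - 1)
    A = _knn_adjacency(X, k_eff)
    n_comp, labels = connected_components(A, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"kNN subgraph of the path cells is disconnected "
            f"({n_comp} components with sizes {sizes.tolist()})"
        )
    adata = ad.AnnData(X=X.copy())
    adata.obs_names = ids
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=k_eff, use_rep="X", method="gauss", knn=not dense)
        n_comps = int(min(n_dcs, n - 2))
        n_comps = max(n_comps, 2)
        sc.tl.diffmap(adata, n_comps=n_comps + 1)
        adata.uns["iroot"] = ids.index(start)
        sc.tl.dpt(adata, n_dcs=n_comps)
    pt = np.asarray(adata.obs["dpt_pseudotime"], dtype=float)
    order = np.lexsort((np.arange(n), pt))
    return PseudotimeOrdering(
        cell_ids=[ids[i] for i in order],
        pseudotime=pt[order],
        start_cell=start,
        path_clusters=list(path_clusters) if path_clusters is not None else [],
        cell_indices=path_cells[order],
    )


def dtw_core(local_dist: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    """Classical DTW on a precomputed local-distance matrix.

    Steps {(1,0),(0,1),(1,1)}, boundary-anchored; on ties the traceback
    prefers the diagonal step. Returns (total cost, warping path).
    """
    d = np.asarray(local_dist, dtype=float)
    n1, n2 = d.shape
    if n1 == 0 or n2 == 0:
        raise ValueError("empty series")
    C = np.full((n1, n2), np.inf)
    C[0, 0] = d[0, 0]
    for j in range(1, n2):
        C[0, j] = C[0, j - 1] + d[0, j]
    for i in range(1, n1):
        C[i, 0] = C[i - 1, 0] + d[i, 0]
        row_prev = C[i - 1]
        row = C[i]
        for j in range(1, n2):
            row[j] = d[i, j] + min(row_prev[j - 1], row_prev[j], row[j - 1])
    # traceback, diagonal preferred on ties
    path = [(n1 - 1, n2 - 1)]
    i, j = n1 - 1, n2 - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = C[i - 1, j - 1], C[i - 1, j], C[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return float(C[n1 - 1, n2 - 1]), path


def _spearman_cross(X1: np.ndarray, X2: np.ndarray, ids1, ids2) -> np.ndarray:
    """1 - Spearman correlation between every row of X1 and every row of X2."""
    R1 = np.apply_along_axis(rankdata, 1, X1)
    R2 = np.apply_along_axis(rankdata, 1, X2)
    for R, ids, side in ((R1, ids1, 1), (R2, ids2, 2)):
        sd = R.std(axis=1)
        if np.any(sd == 0):
            bad = [ids[i] for i in np.flatnonzero(sd == 0)[:5]]
            raise ValueError(
                f"cell(s) {bad} in series {side} have zero rank variance over "
                "the selected genes; Spearman correlation undefined"
            )
    A = R1 - R1.mean(axis=1, keepdims=True)
    B = R2 - R2.mean(axis=1, keepdims=True)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    return 1.0 - A @ B.T


def dtw_align(
    o1: PseudotimeOrdering,
    o2: PseudotimeOrdering,
    ds1: ExpressionDataset,
    ds2: ExpressionDataset,
    genes: list[str],
    metric: str = "spearman",
) -> DTWAlignment:
    """Dynamic time warping of two pseudotime-ordered cell series.

    The local distance between two cells is ``1 - Spearman`` of their log
    expression over ``genes`` (or Euclidean with ``metric='euclidean'``).
    """
    if len(o1) == 0 or len(o2) == 0:
        raise ValueError("empty pseudotime ordering")
    if not genes:
        raise ValueError("gene list is empty")
    X1 = ds1.log_counts[o1.cell_indices][:, ds1.gene_indices(genes)]
    X2 = ds2.log_counts[o2.cell_indices][:, ds2.gene_indices(genes)]
    if metric == "spearman":
        D = _spearman_cross(X1, X2, o1.cell_ids, o2.cell_ids)
    elif metric == "euclidean":
        D = cdist(X1, X2)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    cost, path = dtw_core(D)
    return DTWAlignment(
        warping_path=path, total_cost=cost, ordering_1=o1, ordering_2=o2, genes=list(genes)
    )


def _min_max(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    return (x - x.min()) / span if span > 0 else np.zeros_like(x)


def _classify(s1: float, s2: float) -> str:
    if s1 == 0 or s2 == 0:
        return "flat"
    if s1 > 0 and s2 > 0:
        return "up_up"
    if s1 > 0 and s2 < 0:
        return "up_down"
    if s1 < 0 and s2 > 0:
        return "down_up"
    return "down_down"


def gene_kinetics(
    al: DTWAlignment,
    ds1: ExpressionDataset,
    ds2: ExpressionDataset,
    dispersion_cutoff: float = 1.0,
) -> list[GeneKinetics]:
    """Per-gene kinetics along the aligned path.

    Genes with normalized dispersion above ``dispersion_cutoff`` in either
    dataset (computed on the path's cells) are kept. For each, the two
    aligned expression series are min-max scaled, a least-squares line is
    fitted against the normalized aligned position in [0, 1], and the gene
    is grouped by the slope signs. ``dtw_similarity`` is the per-gene DTW
    cost on the aligned series under absolute-difference local cost.
    """
    from .preprocess import normalized_dispersion

    sub1 = ds1.subset_cells(al.ordering_1.cell_indices)
    sub2 = ds2.subset_cells(al.ordering_2.cell_indices)
    shared = [g for g in ds1.gene_names if g in set(ds2.gene_names)]
    nd1 = dict(zip(sub1.gene_names, normalized_dispersion(sub1)))
    nd2 = dict(zip(sub2.gene_names, normalized_dispersion(sub2)))
    selected = [
        g
        for g in shared
        if nd1.get(g, -np.inf) > dispersion_cutoff or nd2.get(g, -np.inf) > dispersion_cutoff
    ]
    if not selected:
        warnings.warn("no genes pass the dispersion cutoff", stacklevel=2)
        return []
    L = len(al.warping_path)
    x = np.linspace(0.0, 1.0, L) if L > 1 else np.zeros(1)
    out: list[GeneKinetics] = []
    for g in selected:
        e1, e2 = al.aligned_series(ds1, ds2, g)
        s1n, s2n = _min_max(e1), _min_max(e2)
        slope1 = float(np.polyfit(x, s1n, 1)[0]) if L > 1 else 0.0
        slope2 = float(np.polyfit(x, s2n, 1)[0]) if L > 1 else 0.0
        sim, _ = dtw_core(np.abs(s1n[:, None] - s2n[None, :]))
        out.append(
            GeneKinetics(
                gene=g,
                slope_1=slope1,
                slope_2=slope2,
                group=_classify(slope1, slope2),
                dtw_similarity=sim,
            )
        )
    return out


def path_specific_genes(per_path_genes: dict[str, list[str]]) -> dict[str, list[str]]:
    """Set difference across aligned paths: genes selected for exactly one
    path, flagging potential cell-type-specific programs."""
    out: dict[str, list[str]] = {}
    for name, genes in per_path_genes.items():
        others = set()
        for other, g in per_path_genes.items():
            if other != name:
                others.update(g)
        out[name] = [g for g in genes if g not in others]
    return out
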