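"""End-to-end orchestration of the two-step alignment workflow.

``align_datasets`` runs: shared-gene intersection -> per-dataset filtering,
normalization, HVG selection, PCA, kNN graph, Leiden clustering, centroid
MST -> tree alignment -> per-lineage diffusion pseudotime (and optionally
DTW + gene kinetics) -> metrics. ``run_capital`` is the file-based wrapper
driven by a YAML config that the CLI uses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cell_align, metrics, preprocess, tree_align, trajectory
from .cell_align import DTWAlignment, GeneKinetics, PseudotimeOrdering, _knn_adjacency
from .dataset import ExpressionDataset
from .metrics import LineageConservation, NormalizedDistanceParams
from .synth import SimulationConfig, add_gaussian_noise, simulate_branching, split_dataset
from .trajectory import Clustering, TrajectoryTree
from .tree_align import AlignedTree, CostFunction


@dataclass
class LineageResult:
    """One aligned root-to-leaf path with its cell-level alignment."""

    path_1: list[int]
    path_2: list[int]
    ordering_1: PseudotimeOrdering
    ordering_2: PseudotimeOrdering
    conservation: LineageConservation | None = None
    dtw: DTWAlignment | None = None
    kinetics: list[GeneKinetics] | None = None

    @property
    def name(self) -> str:
        return f"{'-'.join(map(str, self.path_1))}|{'-'.join(map(str, self.path_2))}"


@dataclass
class CapitalResult:
    ds1: ExpressionDataset
    ds2: ExpressionDataset
    clustering1: Clustering
    clustering2: Clustering
    tree1: TrajectoryTree
    tree2: TrajectoryTree
    aligned: AlignedTree
    d_norm: float
    lineages: list[LineageResult]
    atc: float | None
    manifest: dict


def _prepare(
    ds: ExpressionDataset,
    *,
    min_genes: int,
    min_cells: int,
    target_sum: float | None,
) -> ExpressionDataset:
    if min_genes > 0 or min_cells > 0:
        ds = preprocess.filter_cells_genes(ds, min_genes=min_genes, min_cells=min_cells)
    if ds.log_counts is None:
        ds = preprocess.normalize_log(ds, target_sum=target_sum)
    # Spearman-based costs are undefined for cells with constant expression
    const = np.flatnonzero(np.ptp(ds.log_counts, axis=1) == 0)
    if const.size:
        warnings.warn(
            f"dropping {const.size} cell(s) with constant expression over the "
            "shared genes (Spearman undefined)",
            stacklevel=2,
        )
        keep = np.setdiff1d(np.arange(ds.n_cells), const)
        if keep.size == 0:
            raise ValueError("all cells constant over the shared genes")
        ds = ds.subset_cells(keep)
    return ds


def _auto_root(ds: ExpressionDataset, clustering: Clustering) -> int:
    """Fallback root cluster: by minimal median ground-truth simulation time
    when available, else the cluster holding the expression-space diameter
    endpoint."""
    if ds.sim_time is not None:
        med = [
            np.median(ds.sim_time[clustering.members(c)]) for c in range(clustering.n_clusters)
        ]
        return int(np.argmin(med))
    D_far = np.zeros(ds.n_cells)
    from scipy.spatial.distance import cdist

    D = cdist(ds.log_counts, ds.log_counts)
    D_far = D.max(axis=1)
    return int(clustering.labels[int(np.argmax(D_far))])


def _component_of_start(
    ds: ExpressionDataset, cells: np.ndarray, start_idx: int, k: int, rep=None
) -> np.ndarray:
    """Restrict path cells to the kNN connected component holding the start
    cell (warns when cells are dropped)."""
    from scipy.sparse.csgraph import connected_components

    X = (ds.log_counts if rep is None else np.asarray(rep))[cells]
    A = _knn_adjacency(X, min(k, len(cells) - 1))
    n_comp, labels = connected_components(A, directed=False)
    if n_comp == 1:
        return cells
    start_pos = int(np.flatnonzero(cells == start_idx)[0])
    keep = cells[labels == labels[start_pos]]
    warnings.warn(
        f"path cells split into {n_comp} kNN components; keeping the "
        f"{len(keep)}-cell component containing the start cell",
        stacklevel=2,
    )
    return keep


def align_datasets(
    ds1: ExpressionDataset,
    ds2: ExpressionDataset,
    *,
    min_genes: int = 0,
    min_cells: int = 0,
    target_sum: float | None = None,
    n_top_genes: int = 200,
    n_pcs: int = 50,
    n_neighbors: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
    root1: int | None = None,
    root2: int | None = None,
    delta: float = 1.0,
    alpha: float = 0.9,
    max_degree: int = 10,
    n_dcs: int = 10,
    dpt_neighbors: int = 30,
    compute_pseudotime: bool = True,
    compute_dtw: bool = False,
    dispersion_cutoff: float = 1.0,
) -> CapitalResult:
    """Run the full two-dataset trajectory alignment.

    The two datasets are first restricted to their shared gene namespace
    (orthologue renaming, if any, is the caller's responsibility). Roots may
    be given as cluster ids; ``None`` triggers the automatic fallback of
    :func:`_auto_root`.
    """
    shared = [g for g in ds1.gene_names if g in set(ds2.gene_names)]
    if not shared:
        raise ValueError("the two datasets share no genes")
    ds1 = ds1.subset_genes(shared)
    ds2 = ds2.subset_genes(shared)
    ds1 = _prepare(ds1, min_genes=min_genes, min_cells=min_cells, target_sum=target_sum)
    ds2 = _prepare(ds2, min_genes=min_genes, min_cells=min_cells, target_sum=target_sum)
    # re-intersect in case gene filtering diverged
    shared = [g for g in ds1.gene_names if g in set(ds2.gene_names)]
    if not shared:
        raise ValueError("no shared genes left after filtering")
    ds1, ds2 = ds1.subset_genes(shared), ds2.subset_genes(shared)

    sides = []
    hvgs = []
    for ds in (ds1, ds2):
        hvg = preprocess.select_hvg(ds, n_top=min(n_top_genes, ds.n_genes))
        p = min(n_pcs, len(hvg), ds.n_cells - 1)
        emb = preprocess.pca(ds, genes=hvg, p=p)
        graph = preprocess.knn_graph(emb, k=min(n_neighbors, ds.n_cells - 1))
        clust = trajectory.cluster_cells(graph, resolution=resolution, seed=seed)
        cents = trajectory.compute_centroids(ds, emb, clust)
        sides.append((emb, clust, cents))
        hvgs.append(hvg)
    (emb1, clust1, cents1), (emb2, clust2, cents2) = sides

    r1 = root1 if root1 is not None else _auto_root(ds1, clust1)
    r2 = root2 if root2 is not None else _auto_root(ds2, clust2)
    tree1 = trajectory.prune_or_flag_degree(trajectory.mst_trajectory(cents1, r1), max_degree)
    tree2 = trajectory.prune_or_flag_degree(trajectory.mst_trajectory(cents2, r2), max_degree)

    cost = CostFunction(delta=delta, shared_genes=shared)
    aligned = tree_align.align_trees(tree1, tree2, cost, max_degree=max_degree)
    d_norm = metrics.normalized_distance(aligned, NormalizedDistanceParams(alpha=alpha))

    dtw_genes = [g for g in hvgs[0] if g in set(hvgs[1])]
    if not dtw_genes:
        dtw_genes = sorted(set(hvgs[0]) | set(hvgs[1]))

    lineages: list[LineageResult] = []
    if compute_pseudotime:
        for p1, p2 in tree_align.aligned_paths(aligned):
            lr = _lineage(
                ds1, ds2, clust1, clust2, p1, p2,
                k=dpt_neighbors, n_dcs=n_dcs,
                compute_dtw=compute_dtw, dtw_genes=dtw_genes,
                dispersion_cutoff=dispersion_cutoff,
                rep1=emb1.Z, rep2=emb2.Z,
            )
            if lr is not None:
                lineages.append(lr)

    atc = None
    scored = [l for l in lineages if l.conservation is not None]
    if scored:
        atc = float(np.mean([l.conservation.score for l in scored]))

    manifest = {
        "n_cells": [ds1.n_cells, ds2.n_cells],
        "n_shared_genes": len(shared),
        "params": {
            "min_genes": min_genes, "min_cells": min_cells, "target_sum": target_sum,
            "n_top_genes": n_top_genes, "n_pcs": n_pcs, "n_neighbors": n_neighbors,
            "resolution": resolution, "seed": seed, "root1": r1, "root2": r2,
            "delta": delta, "alpha": alpha, "max_degree": max_degree, "n_dcs": n_dcs,
            "dispersion_cutoff": dispersion_cutoff,
        },
        "n_clusters": [clust1.n_clusters, clust2.n_clusters],
        "alignment": {
            "distance": aligned.distance,
            "matched_pairs": aligned.matched_pairs,
            "unmatched_pairs": aligned.unmatched_pairs,
            "d_norm": d_norm,
        },
        "atc": atc,
    }
    return CapitalResult(
        ds1=ds1, ds2=ds2, clustering1=clust1, clustering2=clust2,
        tree1=tree1, tree2=tree2, aligned=aligned, d_norm=d_norm,
        lineages=lineages, atc=atc, manifest=manifest,
    )


def _lineage(
    ds1, ds2, clust1, clust2, p1, p2, *, k, n_dcs, compute_dtw, dtw_genes,
    dispersion_cutoff, rep1=None, rep2=None,
) -> LineageResult | None:
    orderings = []
    for ds, clust, path, rep in ((ds1, clust1, p1, rep1), (ds2, clust2, p2, rep2)):
        cells = np.flatnonzero(np.isin(clust.labels, path))
        if len(cells) < 3:
            warnings.warn(f"path {path} has fewer than 3 cells; skipped", stacklevel=2)
            return None
        if ds.sim_time is not None:
            # benchmark protocol on ground-truthed data: anchor pseudotime at
            # the root-cluster cell of (near-)zero simulation time
            members = clust.members(path[0])
            start_idx = int(members[np.argmin(ds.sim_time[members])])
            start = ds.cell_ids[start_idx]
        else:
            start = cell_align.select_start_cell(ds, clust, path[0])
            start_idx = ds.cell_ids.index(start)
        cells = _component_of_start(ds, cells, start_idx, k, rep=rep)
        if len(cells) < 3 or start_idx not in cells:
            warnings.warn(f"path {path} unusable after connectivity pruning", stacklevel=2)
            return None
        orderings.append(
            cell_align.diffusion_pseudotime(
                ds, cells, start, k=k, n_dcs=n_dcs, path_clusters=list(path), rep=rep,
                dense=True,
            )
        )
    o1, o2 = orderings
    conservation = None
    if ds1.sim_time is not None and ds2.sim_time is not None:
        pairs = [
            (ds1.sim_time[o1.cell_indices], o1.pseudotime),
            (ds2.sim_time[o2.cell_indices], o2.pseudotime),
        ]
        name = f"{'-'.join(map(str, p1))}|{'-'.join(map(str, p2))}"
        conservation = metrics.lineage_conservation(name, pairs)
    dtw = kin = None
    if compute_dtw:
        dtw = cell_align.dtw_align(o1, o2, ds1, ds2, dtw_genes)
        kin = cell_align.gene_kinetics(dtw, ds1, ds2, dispersion_cutoff=dispersion_cutoff)
    return LineageResult(
        path_1=list(p1), path_2=list(p2), ordering_1=o1, ordering_2=o2,
        conservation=conservation, dtw=dtw, kinetics=kin,
    )


# ---------------------------------------------------------------------------
# benchmark protocol helpers (synthetic data with ground truth)
# ---------------------------------------------------------------------------

def split_benchmark(
    sim_cfg: SimulationConfig,
    *,
    split_seed: int = 0,
    noise_sd: float = 0.0,
    **align_kwargs,
) -> CapitalResult:
    """Simulate one dataset, split it into disjoint halves, optionally add
    Gaussian noise to each half's log counts, and align the halves.

    Roots default to the ground-truth choice (cluster of minimal median
    simulation time), mirroring the benchmark protocol of starting from a
    simulation-time-zero cell. Clustering resolution defaults to 2.0 here:
    split halves carry few cells per backbone segment, and a finer
    partition keeps branch-point clusters from mixing sibling branches.
    """
    align_kwargs.setdefault("resolution", 2.0)
    ds = simulate_branching(sim_cfg)
    h1, h2 = split_dataset(ds, seed=split_seed)
    h1 = preprocess.normalize_log(h1)
    h2 = preprocess.normalize_log(h2)
    if noise_sd > 0:
        h1 = add_gaussian_noise(h1, noise_sd, seed=split_seed * 2 + 1)
        h2 = add_gaussian_noise(h2, noise_sd, seed=split_seed * 2 + 2)
    return align_datasets(h1, h2, **align_kwargs)


# ---------------------------------------------------------------------------
# file-based run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    dataset1: str
    dataset2: str
    outdir: str
    root1: int | None = None
    root2: int | None = None
    format1: str | None = None
    format2: str | None = None
    min_genes: int = 200
    min_cells: int = 3
    target_sum: float | None = None
    n_top_genes: int = 200
    n_pcs: int = 50
    n_neighbors: int = 10
    resolution: float = 1.0
    seed: int = 0
    delta: float = 1.0
    alpha: float = 0.9
    max_degree: int = 10
    n_dcs: int = 10
    compute_dtw: bool = True
    dispersion_cutoff: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.dataset1, self.dataset2):
            if not Path(p).exists():
                raise ValueError(f"input file does not exist: {p}")
        if self.root1 is None or self.root2 is None:
            raise ValueError("root1 and root2 cluster ids are required in the run config")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"dataset1", "dataset2", "outdir"} - set(raw)
        if missing:
            raise ValueError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)


def run_capital(cfg: RunConfig) -> dict:
    """Execute the full workflow from a run config; returns the manifest.

    Outputs (all deterministic for fixed seeds): trajectory JSONs per
    dataset, the aligned-tree JSON, per-path DTW TSVs and gene-kinetics
    TSVs, a metrics JSON, and a manifest recording every parameter.
    """
    from .dataset import load_counts

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds1 = load_counts(cfg.dataset1, cfg.format1)
    ds2 = load_counts(cfg.dataset2, cfg.format2)
    res = align_datasets(
        ds1, ds2,
        min_genes=cfg.min_genes, min_cells=cfg.min_cells, target_sum=cfg.target_sum,
        n_top_genes=cfg.n_top_genes, n_pcs=cfg.n_pcs, n_neighbors=cfg.n_neighbors,
        resolution=cfg.resolution, seed=cfg.seed, root1=cfg.root1, root2=cfg.root2,
        delta=cfg.delta, alpha=cfg.alpha, max_degree=cfg.max_degree, n_dcs=cfg.n_dcs,
        compute_dtw=cfg.compute_dtw, dispersion_cutoff=cfg.dispersion_cutoff,
    )
    outputs: list[str] = []

    def emit(name: str, text: str) -> None:
        (outdir / name).write_text(text)
        outputs.append(name)

    emit("trajectory1.json", res.tree1.to_json())
    emit("trajectory2.json", res.tree2.to_json())
    emit("aligned_tree.json", res.aligned.to_json())
    emit(
        "metrics.json",
        json.dumps(
            {
                "d_norm": res.d_norm,
                "atc": res.atc,
                "distance": res.aligned.distance,
                "matched_pairs": res.aligned.matched_pairs,
                "unmatched_pairs": res.aligned.unmatched_pairs,
            },
            sort_keys=True,
        ),
    )
    for i, lin in enumerate(res.lineages):
        if lin.dtw is not None:
            rows = ["index_1\tcell_id_1\tpseudotime_1\tindex_2\tcell_id_2\tpseudotime_2"]
            for a, b in lin.dtw.warping_path:
                rows.append(
                    f"{a}\t{lin.ordering_1.cell_ids[a]}\t{lin.ordering_1.pseudotime[a]!r}"
                    f"\t{b}\t{lin.ordering_2.cell_ids[b]}\t{lin.ordering_2.pseudotime[b]!r}"
                )
            emit(f"path_{i}_alignment.tsv", "\n".join(rows) + "\n")
        if lin.kinetics:
            rows = ["gene\tslope_1\tslope_2\tgroup\tdtw_similarity"]
            for gk in lin.kinetics:
                rows.append(
                    f"{gk.gene}\t{gk.slope_1!r}\t{gk.slope_2!r}\t{gk.group}\t{gk.dtw_similarity!r}"
                )
            emit(f"path_{i}_kinetics.tsv", "\n".join(rows) + "\n")
    manifest = dict(res.manifest)
    manifest["config"] = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    manifest["outputs"] = outputs
    manifest["lineages"] = [
        {
            "path_1": lin.path_1,
            "path_2": lin.path_2,
            "n_cells": [len(lin.ordering_1), len(lin.ordering_2)],
        }
        for lin in res.lineages
    ]
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
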