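"""Ground-truthed branching scRNA-seq simulator and benchmark perturbations.

A transparent stand-in for a full gene-regulatory-network simulator: cells
are placed uniformly along the edges of a rooted backbone tree (default: a
stem followed by three binary branch points, i.e. four leaves), each edge
("branch") activates its own gene program as a smooth monotone ramp, and
counts are drawn from a Poisson-lognormal around the program mean with
optional dropout. Per-cell ground truth — simulation time (distance from
the root) and branch identity — is recorded so alignment benchmarks can
score themselves.

Perturbations mirror the benchmark protocols: random disjoint splitting of
one matrix into two, additive Gaussian noise on log counts of increasing
standard deviation, and node removals (leaf / internal / root) on inferred
trajectory trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset
from .trajectory import TrajectoryTree

#: binary tree with three branch points (root, B, C) and four leaves
DEFAULT_BACKBONE: list[tuple[str, str]] = [
    ("root", "B"),
    ("root", "C"),
    ("B", "leaf1"),
    ("B", "leaf2"),
    ("C", "leaf3"),
    ("C", "leaf4"),
]


@dataclass
class SimulationConfig:
    n_cells: int = 1000
    n_genes: int = 260
    backbone: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_BACKBONE))
    n_branch_genes: int = 30
    noise_sd_base: float = 0.3  # lognormal sd of the Poisson rate
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        children: dict[str, list[str]] = {}
        parents: dict[str, str] = {}
        for p, c in self.backbone:
            children.setdefault(p, []).append(c)
            if c in parents:
                raise ValueError(f"backbone node {c} has two parents")
            parents[c] = p
        roots = [p for p, _ in self.backbone if p not in parents]
        if len(set(roots)) != 1:
            raise ValueError("backbone must be a single rooted tree")
        self._root = roots[0]
        # reject cycles / disconnection
        nodes = {self._root} | set(parents)
        seen, stack = set(), [self._root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise ValueError("backbone contains a cycle")
            seen.add(v)
            stack.extend(children.get(v, []))
        if seen != nodes:
            raise ValueError("backbone is not connected")
        n_nodes = len(nodes)
        if self.n_cells < 2 * n_nodes:
            raise ValueError(f"n_cells must be >= {2 * n_nodes} (2x backbone nodes)")
        if self.n_genes < len(self.backbone) * self.n_branch_genes:
            raise ValueError(
                f"n_genes must cover {len(self.backbone)} branches x "
                f"{self.n_branch_genes} branch genes"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_sd_base < 0:
            raise ValueError("noise_sd_base must be >= 0")

    def depths(self) -> dict[str, float]:
        d = {self._root: 0.0}
        todo = list(self.backbone)
        while todo:
            rest = []
            for p, c in todo:
                if p in d:
                    d[c] = d[p] + 1.0
                else:
                    rest.append((p, c))
            todo = rest
        return d

    def descendant_edges(self) -> dict[tuple[str, str], set[tuple[str, str]]]:
        """For each edge, the set of edges strictly below its child node."""
        children: dict[str, list[tuple[str, str]]] = {}
        for p, c in self.backbone:
            children.setdefault(p, []).append((p, c))
        out: dict[tuple[str, str], set[tuple[str, str]]] = {}

        def below(node: str) -> set[tuple[str, str]]:
            acc: set[tuple[str, str]] = set()
            for e in children.get(node, []):
                acc.add(e)
                acc |= below(e[1])
            return acc

        for e in self.backbone:
            out[e] = below(e[1])
        return out


def simulate_branching(cfg: SimulationConfig) -> ExpressionDataset:
    """Simulate a branching differentiation process with known ground truth.

    Deterministic per seed. Branch genes ramp from a small baseline to their
    full amplitude along their own branch and stay activated in all
    descendant branches, so expression varies smoothly and monotonically
    along every root-to-leaf path.
    """
    rng = np.random.default_rng(cfg.seed)
    edges = list(cfg.backbone)
    n_edges = len(edges)
    depths = cfg.depths()
    desc = cfg.descendant_edges()

    # balanced deterministic edge assignment, random position on the edge
    edge_of = np.arange(cfg.n_cells) % n_edges
    pos = rng.uniform(0.0, 1.0, size=cfg.n_cells)
    sim_time = np.array([depths[edges[e][0]] for e in edge_of]) + pos
    branch_label = np.array([edges[e][1] for e in edge_of], dtype=object)

    n_branch_total = n_edges * cfg.n_branch_genes
    n_hk = cfg.n_genes - n_branch_total
    gene_names = [
        f"b_{edges[e][1]}_{k}" for e in range(n_edges) for k in range(cfg.n_branch_genes)
    ] + [f"hk_{k}" for k in range(n_hk)]

    base = 1.0
    amp = rng.uniform(8.0, 20.0, size=n_branch_total)
    hk_mean = rng.uniform(1.0, 4.0, size=n_hk)

    # activation of each branch program per cell
    mean = np.empty((cfg.n_cells, cfg.n_genes))
    for e_idx, e in enumerate(edges):
        act = np.zeros(cfg.n_cells)
        on_edge = edge_of == e_idx
        act[on_edge] = pos[on_edge]
        for d_idx, d in enumerate(edges):
            if d in desc[e]:
                act[edge_of == d_idx] = 1.0
        cols = slice(e_idx * cfg.n_branch_genes, (e_idx + 1) * cfg.n_branch_genes)
        mean[:, cols] = base + act[:, None] * amp[None, cols]
    mean[:, n_branch_total:] = hk_mean[None, :]

    rate = mean
    if cfg.noise_sd_base > 0:
        rate = mean * np.exp(rng.normal(0.0, cfg.noise_sd_base, size=mean.shape))
    counts = rng.poisson(rate).astype(float)
    if cfg.dropout_rate > 0:
        counts[rng.uniform(size=counts.shape) < cfg.dropout_rate] = 0.0

    width = len(str(cfg.n_cells))
    return ExpressionDataset(
        counts=counts,
        cell_ids=[f"cell_{i:0{width}d}" for i in range(cfg.n_cells)],
        gene_names=gene_names,
        sim_time=sim_time,
        branch_label=branch_label,
    )


def split_dataset(
    ds: ExpressionDataset, seed: int = 0, stratify_by_branch: bool = False
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Randomly partition cells into two disjoint halves sharing the gene
    set; ground-truth columns are carried along.

    With ``stratify_by_branch`` each branch label is split separately so
    both halves cover every branch.
    """
    n = ds.n_cells
    if n < 4:
        raise ValueError("need at least 4 cells to split")
    rng = np.random.default_rng(seed)
    if stratify_by_branch:
        if ds.branch_label is None:
            raise ValueError("stratified split requires branch labels")
        first: list[int] = []
        for lab in sorted(set(ds.branch_label)):
            idx = np.flatnonzero(ds.branch_label == lab)
            perm = rng.permutation(idx)
            first.extend(perm[: (len(idx) + 1) // 2])
        mask = np.zeros(n, dtype=bool)
        mask[np.array(first)] = True
        idx1, idx2 = np.flatnonzero(mask), np.flatnonzero(~mask)
    else:
        perm = rng.permutation(n)
        half = (n + 1) // 2
        idx1, idx2 = np.sort(perm[:half]), np.sort(perm[half:])
    return ds.subset_cells(idx1), ds.subset_cells(idx2)


def add_gaussian_noise(ds: ExpressionDataset, sd: float, seed: int = 0) -> ExpressionDataset:
    """Add independent N(0, sd^2) noise to every log-count entry.

    ``sd=0`` returns an identical copy; raw counts are untouched.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if ds.log_counts is None:
        raise ValueError("log_counts required; run normalize_log first")
    if sd == 0:
        return ds.with_(log_counts=ds.log_counts.copy())
    rng = np.random.default_rng(seed)
    return ds.with_(log_counts=ds.log_counts + rng.normal(0.0, sd, size=ds.log_counts.shape))


def perturb_tree(
    tree: TrajectoryTree,
    which: int,
    expect: str | None = None,
    expect_children: int | tuple[int, ...] | None = None,
) -> TrajectoryTree:
    """Remove node ``which`` from a trajectory tree.

    A removed leaf simply disappears; a removed internal node's children are
    reattached to its parent; removing the root promotes its lowest-id child
    to root and reattaches the other children beneath it. ``expect`` /
    ``expect_children`` optionally assert the node's category before
    removal.
    """
    if which not in tree.nodes:
        raise ValueError(f"node {which} not in tree")
    ch = tree.children_map()
    parents = tree.parent_map()
    n_children = len(ch[which])
    category = "root" if which == tree.root else ("leaf" if n_children == 0 else "internal")
    if expect is not None and expect != category:
        raise ValueError(f"node {which} is a {category}, not a {expect}")
    if expect_children is not None:
        allowed = (
            (expect_children,) if isinstance(expect_children, int) else tuple(expect_children)
        )
        if n_children not in allowed:
            raise ValueError(f"node {which} has {n_children} children, expected {allowed}")

    if category == "root":
        if len(tree.nodes) == 1:
            raise ValueError("cannot remove the root of a single-node tree")
        kids = ch[which]
        new_root = min(kids)
        edges = [(a, b) for a, b in tree.edges if a != which]
        edges += [(new_root, c) for c in kids if c != new_root]
        root = new_root
    else:
        parent = parents[which]
        edges = [(a, b) for a, b in tree.edges if a != which and b != which]
        edges += [(parent, c) for c in ch[which]]
        root = tree.root
    nodes = [v for v in tree.nodes if v != which]
    centroids = {k: v for k, v in tree.centroids.items() if k != which}
    return TrajectoryTree(nodes=nodes, edges=edges, root=root, centroids=centroids)
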