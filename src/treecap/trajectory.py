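"""Cluster-level trajectory inference.

Cells are partitioned by Leiden community detection on the kNN graph; each
cluster is summarized by a *centroid* (coordinate-wise medians in PC space
and in log-expression space); the trajectory is the minimum spanning tree
over centroids, rooted at a user-chosen cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataset import EmbeddingSpace, ExpressionDataset, NeighborGraph


@dataclass
class Clustering:
    labels: np.ndarray  # per-cell cluster id, contiguous 0..n_clusters-1
    n_clusters: int
    resolution: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        ids = np.unique(self.labels)
        if not np.array_equal(ids, np.arange(self.n_clusters)):
            raise ValueError("cluster ids must be contiguous 0..n_clusters-1 and non-empty")

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


@dataclass
class Centroid:
    cluster_id: int
    pc_median: np.ndarray
    expr_median: np.ndarray
    n_cells: int


@dataclass
class TrajectoryTree:
    """Rooted tree over cluster ids with centroid payloads.

    ``edges`` are (parent, child) pairs oriented away from ``root``. The
    empty tree (zero nodes, ``root=None``) is a valid value for alignment
    base cases.
    """

    nodes: list[int]
    edges: list[tuple[int, int]]
    root: int | None
    centroids: dict[int, Centroid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = [int(v) for v in self.nodes]
        self.edges = [(int(a), int(b)) for a, b in self.edges]
        if len(self.nodes) == 0:
            if self.root is not None or self.edges:
                raise ValueError("empty tree must have no root and no edges")
            return
        if self.root is None or self.root not in self.nodes:
            raise ValueError("root must be one of the nodes")
        if len(self.edges) != len(self.nodes) - 1:
            raise ValueError("a tree on |V| nodes must have |V|-1 edges")
        # reachability from root
        ch = self.children_map()
        seen = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise ValueError("cycle detected")
            seen.add(v)
            stack.extend(ch[v])
        if seen != set(self.nodes):
            raise ValueError("not all nodes reachable from root")

    @classmethod
    def empty(cls) -> "TrajectoryTree":
        return cls(nodes=[], edges=[], root=None)

    def __len__(self) -> int:
        return len(self.nodes)

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {v: [] for v in self.nodes}
        for a, b in self.edges:
            ch[a].append(b)
        for v in ch:
            ch[v] = sorted(ch[v])
        return ch

    def parent_map(self) -> dict[int, int]:
        return {b: a for a, b in self.edges}

    def leaves(self) -> list[int]:
        ch = self.children_map()
        return sorted(v for v in self.nodes if not ch[v])

    def subtree_nodes(self, v: int) -> list[int]:
        ch = self.children_map()
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(ch[u])
        return out

    def root_to_leaf_paths(self) -> list[list[int]]:
        ch = self.children_map()
        paths: list[list[int]] = []

        def walk(v: int, acc: list[int]) -> None:
            acc = acc + [v]
            if not ch[v]:
                paths.append(acc)
            for c in ch[v]:
                walk(c, acc)

        if self.nodes:
            walk(self.root, [])
        return paths

    def max_out_degree(self) -> int:
        ch = self.children_map()
        return max((len(c) for c in ch.values()), default=0)

    def to_json(self, path=None) -> str:
        payload = {
            "nodes": self.nodes,
            "edges": [list(e) for e in self.edges],
            "root": self.root,
            "centroids": {
                str(c.cluster_id): {
                    "n_cells": c.n_cells,
                    "pc_median": list(map(float, c.pc_median)),
                    "expr_median": list(map(float, c.expr_median)),
                }
                for c in self.centroids.values()
            },
        }
        s = json.dumps(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source: str) -> "TrajectoryTree":
        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                payload = json.load(fh)
        centroids = {
            int(k): Centroid(
                cluster_id=int(k),
                pc_median=np.array(v["pc_median"], dtype=float),
                expr_median=np.array(v["expr_median"], dtype=float),
                n_cells=int(v["n_cells"]),
            )
            for k, v in payload.get("centroids", {}).items()
        }
        return cls(
            nodes=payload["nodes"],
            edges=[tuple(e) for e in payload["edges"]],
            root=payload["root"],
            centroids=centroids,
        )

    def to_newick(self) -> str:
        ch = self.children_map()

        def fmt(v: int) -> str:
            if not ch[v]:
                return str(v)
            return "(" + ",".join(fmt(c) for c in ch[v]) + ")" + str(v)

        return fmt(self.root) + ";" if self.nodes else ";"


def cluster_cells(graph: NeighborGraph, resolution: float = 1.0, seed: int = 0) -> Clustering:
    """Leiden community detection on the (unweighted) kNN graph.

    Deterministic for a fixed seed; cluster ids are relabeled by order of
    first appearance so the numbering does not depend on leidenalg
    internals.
    """
    import igraph as ig
    import leidenalg

    if graph.n_vertices == 0:
        raise ValueError("empty graph")
    g = ig.Graph(n=graph.n_vertices, edges=[tuple(e) for e in graph.edges])
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.array(part.membership)
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return Clustering(labels=labels, n_clusters=len(remap), resolution=resolution, seed=seed)


def compute_centroids(
    ds: ExpressionDataset, emb: EmbeddingSpace, clustering: Clustering
) -> dict[int, Centroid]:
    """Per-cluster coordinate-wise medians in PC and log-expression space."""
    if ds.log_counts is None:
        raise ValueError("log_counts required")
    if len(clustering.labels) != ds.n_cells or emb.Z.shape[0] != ds.n_cells:
        raise ValueError("clustering/embedding do not cover the dataset")
    out: dict[int, Centroid] = {}
    for cid in range(clustering.n_clusters):
        idx = clustering.members(cid)
        out[cid] = Centroid(
            cluster_id=cid,
            pc_median=np.median(emb.Z[idx], axis=0),
            expr_median=np.median(ds.log_counts[idx], axis=0),
            n_cells=len(idx),
        )
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def mst_trajectory(centroids: dict[int, Centroid], root: int) -> TrajectoryTree:
    """Kruskal MST over the complete centroid graph (Euclidean distance
    between PC medians), oriented away from ``root``.

    Edge ties are broken lexicographically by (min id, max id).
    """
    ids = sorted(centroids)
    if root not in centroids:
        raise ValueError(f"root {root} is not a cluster id")
    if len(ids) == 1:
        return TrajectoryTree(nodes=ids, edges=[], root=root, centroids=dict(centroids))
    pos = {cid: i for i, cid in enumerate(ids)}
    cand = []
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1 :]:
            w = float(np.linalg.norm(centroids[a].pc_median - centroids[b].pc_median))
            cand.append((w, a, b))
    cand.sort()
    uf = _UnionFind(len(ids))
    undirected: dict[int, list[int]] = {v: [] for v in ids}
    n_edges = 0
    for w, a, b in cand:
        if uf.union(pos[a], pos[b]):
            undirected[a].append(b)
            undirected[b].append(a)
            n_edges += 1
            if n_edges == len(ids) - 1:
                break
    # orient away from root
    edges: list[tuple[int, int]] = []
    seen = {root}
    stack = [root]
    while stack:
        v = stack.pop()
        for u in sorted(undirected[v]):
            if u not in seen:
                seen.add(u)
                edges.append((v, u))
                stack.append(u)
    return TrajectoryTree(nodes=ids, edges=edges, root=root, centroids=dict(centroids))


def prune_or_flag_degree(tree: TrajectoryTree, max_degree: int = 10) -> TrajectoryTree:
    """Return the tree unchanged if every node has <= ``max_degree`` children;
    otherwise raise (the alignment DP enumerates child subsets, which is
    exponential in the degree)."""
    ch = tree.children_map()
    for v in tree.nodes:
        if len(ch[v]) > max_degree:
            raise ValueError(
                f"node {v} has {len(ch[v])} children, exceeding max_degree={max_degree}; "
                "re-cluster at lower resolution or raise max_degree"
            )
    return tree
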