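"""Optimal alignment of two rooted unordered trajectory trees.

An alignment overlays the two trees after inserting gap nodes (``#``) so
they become isomorphic; its cost is the sum over aligned node pairs of a
label cost: ``1 - Spearman(x_i, x_j)`` for two cluster expression vectors,
or a constant gap penalty ``delta`` when one side is a gap. The minimum
cost over all alignments (the alignment distance) is computed by dynamic
programming over subtrees and child-forest subsets, which is polynomial for
bounded node degree; the general unordered problem is MAX SNP-hard, so
degrees above ``max_degree`` are an error rather than an approximation.

The DP has three tree-level cases (match the two roots and align the child
forests; gap one root and align the whole opposite tree into one child) and
a forest-level recursion over subset pairs (peel a matched subtree pair, or
gap a subtree root and align its child forest against a subset of the other
side). Traceback is deterministic: case order as listed, then
lexicographically smallest expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, spearmanr

from .trajectory import TrajectoryTree

GAP = None  # gap label


@dataclass
class CostFunction:
    """Label-pair cost: Spearman distance between expression vectors, or the
    gap penalty ``delta`` when one label is a gap."""

    delta: float = 1.0
    shared_genes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


def gamma(label_i, label_j, cost: CostFunction) -> float:
    """Cost of pairing two labels (expression vectors or the gap ``None``)."""
    if label_i is GAP and label_j is GAP:
        raise ValueError("the pair (#, #) is excluded from the cost function domain")
    if label_i is GAP or label_j is GAP:
        return cost.delta
    x = np.asarray(label_i, dtype=float)
    y = np.asarray(label_j, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("expression labels must be equal-length vectors of length >= 2")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nan is handled below
        rho = spearmanr(x, y).statistic
    if np.isnan(rho):
        raise ValueError("Spearman correlation undefined (zero rank variance)")
    return float(1.0 - rho)


def _rank_rows(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, M)


def _gamma_matrix(expr1: np.ndarray, expr2: np.ndarray, ids1, ids2) -> np.ndarray:
    """1 - Spearman for every cluster pair, via Pearson on average ranks."""
    R1, R2 = _rank_rows(expr1), _rank_rows(expr2)
    for R, ids, side in ((R1, ids1, 1), (R2, ids2, 2)):
        sd = R.std(axis=1)
        if np.any(sd == 0):
            bad = [ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(
                f"zero rank variance for cluster(s) {bad} of tree {side}; "
                "Spearman correlation undefined"
            )
    A = R1 - R1.mean(axis=1, keepdims=True)
    B = R2 - R2.mean(axis=1, keepdims=True)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    return 1.0 - A @ B.T


@dataclass
class AlignedTree:
    """Overlay of two trajectory trees after optimal alignment.

    ``nodes[k]`` is a pair ``(a, b)`` of cluster ids, with ``None`` marking a
    gap on that side (never both). ``edges`` are (parent, child) indices into
    ``nodes``; node 0 is the root (preorder).
    """

    nodes: list[tuple[int | None, int | None]]
    edges: list[tuple[int, int]]
    distance: float
    matched_pairs: int
    unmatched_pairs: int
    d_matched: float
    d_unmatched: float
    delta: float = 1.0
    n_tree_states: int = 0  # DP diagnostics

    def project(self, side: int) -> TrajectoryTree:
        """Projection onto one input tree: drop gap nodes, contract edges."""
        if side not in (1, 2):
            raise ValueError("side must be 1 or 2")
        pick = (lambda pair: pair[0]) if side == 1 else (lambda pair: pair[1])
        children: dict[int, list[int]] = {i: [] for i in range(len(self.nodes))}
        for p, c in self.edges:
            children[p].append(c)

        def proj(k: int) -> list[tuple[int, list]]:
            sub = []
            for c in children[k]:
                sub.extend(proj(c))
            v = pick(self.nodes[k])
            return [(v, sub)] if v is not None else sub

        roots = proj(0) if self.nodes else []
        if not roots:
            return TrajectoryTree.empty()
        if len(roots) != 1:
            raise ValueError("projection is a forest; invalid aligned tree")
        nodes: list[int] = []
        edges: list[tuple[int, int]] = []

        def collect(item, parent):
            v, sub = item
            nodes.append(v)
            if parent is not None:
                edges.append((parent, v))
            for s in sub:
                collect(s, v)

        collect(roots[0], None)
        return TrajectoryTree(nodes=sorted(nodes), edges=edges, root=roots[0][0])

    def root_to_leaf_paths(self) -> list[list[int]]:
        children: dict[int, list[int]] = {i: [] for i in range(len(self.nodes))}
        for p, c in self.edges:
            children[p].append(c)
        paths: list[list[int]] = []

        def walk(k: int, acc: list[int]) -> None:
            acc = acc + [k]
            if not children[k]:
                paths.append(acc)
            for c in sorted(children[k]):
                walk(c, acc)

        if self.nodes:
            walk(0, [])
        return paths

    def to_json(self, path=None) -> str:
        import json

        payload = {
            "nodes": [list(p) for p in self.nodes],
            "edges": [list(e) for e in self.edges],
            "distance": self.distance,
            "matched_pairs": self.matched_pairs,
            "unmatched_pairs": self.unmatched_pairs,
            "d_matched": self.d_matched,
            "d_unmatched": self.d_unmatched,
            "delta": self.delta,
        }
        s = json.dumps(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source: str) -> "AlignedTree":
        import json
        from pathlib import Path

        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            payload = json.loads(Path(source).read_text())
        return cls(
            nodes=[tuple(p) for p in payload["nodes"]],
            edges=[tuple(e) for e in payload["edges"]],
            distance=payload["distance"],
            matched_pairs=payload["matched_pairs"],
            unmatched_pairs=payload["unmatched_pairs"],
            d_matched=payload["d_matched"],
            d_unmatched=payload["d_unmatched"],
            delta=payload.get("delta", 1.0),
        )


class _Node:
    __slots__ = ("a", "b", "children")

    def __init__(self, a, b, children):
        self.a, self.b, self.children = a, b, children


_EPS = 1e-9


class _Aligner:
    def __init__(self, t1: TrajectoryTree, t2: TrajectoryTree, cost: CostFunction):
        self.cost = cost
        self.delta = cost.delta
        self.t1, self.t2 = t1, t2
        self.ch1, self.ch2 = t1.children_map(), t2.children_map()
        self.size1 = {v: len(t1.subtree_nodes(v)) for v in t1.nodes}
        self.size2 = {v: len(t2.subtree_nodes(v)) for v in t2.nodes}
        ids1, ids2 = list(t1.nodes), list(t2.nodes)
        self.pos1 = {v: i for i, v in enumerate(ids1)}
        self.pos2 = {v: i for i, v in enumerate(ids2)}
        if ids1 and ids2:
            E1 = np.vstack([t1.centroids[v].expr_median for v in ids1])
            E2 = np.vstack([t2.centroids[v].expr_median for v in ids2])
            if E1.shape[1] != E2.shape[1]:
                raise ValueError("expression labels of the two trees differ in length")
            if E1.shape[1] < 2:
                raise ValueError("expression labels must have length >= 2")
            self.G = _gamma_matrix(E1, E2, ids1, ids2)
        self.memo_t: dict[tuple[int, int], float] = {}
        self.memo_f: dict[tuple[int, int, int, int], float] = {}

    # gap cost of a whole subtree / forest
    def gap1(self, v: int) -> float:
        return self.size1[v] * self.delta

    def gap2(self, v: int) -> float:
        return self.size2[v] * self.delta

    def g(self, i: int, j: int) -> float:
        return float(self.G[self.pos1[i], self.pos2[j]])

    def full_mask1(self, i: int) -> int:
        return (1 << len(self.ch1[i])) - 1

    def full_mask2(self, j: int) -> int:
        return (1 << len(self.ch2[j])) - 1

    def tree_dist(self, i: int, j: int) -> float:
        key = (i, j)
        if key in self.memo_t:
            return self.memo_t[key]
        best = self.forest_dist(i, j, self.full_mask1(i), self.full_mask2(j)) + self.g(i, j)
        for r in self.ch1[i]:
            best = min(best, self.gap1(i) + self.tree_dist(r, j) - self.gap1(r))
        for r in self.ch2[j]:
            best = min(best, self.gap2(j) + self.tree_dist(i, r) - self.gap2(r))
        self.memo_t[key] = best
        return best

    def forest_dist(self, i: int, j: int, maskA: int, maskB: int) -> float:
        """Alignment distance between subset ``maskA`` of i's child subtrees
        and subset ``maskB`` of j's child subtrees."""
        if maskA == 0 and maskB == 0:
            return 0.0
        if maskA == 0:
            return sum(self.gap2(c) for c in self._sel(self.ch2[j], maskB))
        if maskB == 0:
            return sum(self.gap1(c) for c in self._sel(self.ch1[i], maskA))
        key = (i, j, maskA, maskB)
        if key in self.memo_f:
            return self.memo_f[key]
        chA, chB = self.ch1[i], self.ch2[j]
        best = np.inf
        # case 1: match a subtree pair
        for p in range(len(chA)):
            if not maskA >> p & 1:
                continue
            for q in range(len(chB)):
                if not maskB >> q & 1:
                    continue
                v = self.forest_dist(i, j, maskA ^ (1 << p), maskB ^ (1 << q)) + self.tree_dist(
                    chA[p], chB[q]
                )
                best = min(best, v)
        # case 2: gap the root of one subtree of A; its child forest adopts
        # a subset of B
        for p in range(len(chA)):
            if not maskA >> p & 1:
                continue
            ip = chA[p]
            full_ip = self.full_mask1(ip)
            sub = maskB
            while True:
                v = (
                    self.forest_dist(ip, j, full_ip, sub)
                    + self.forest_dist(i, j, maskA ^ (1 << p), maskB ^ sub)
                    + self.delta
                )
                best = min(best, v)
                if sub == 0:
                    break
                sub = (sub - 1) & maskB
        # case 3: symmetric
        for q in range(len(chB)):
            if not maskB >> q & 1:
                continue
            jq = chB[q]
            full_jq = self.full_mask2(jq)
            sub = maskA
            while True:
                v = (
                    self.forest_dist(i, jq, sub, full_jq)
                    + self.forest_dist(i, j, maskA ^ sub, maskB ^ (1 << q))
                    + self.delta
                )
                best = min(best, v)
                if sub == 0:
                    break
                sub = (sub - 1) & maskA
        self.memo_f[key] = float(best)
        return float(best)

    @staticmethod
    def _sel(children: list[int], mask: int) -> list[int]:
        return [c for p, c in enumerate(children) if mask >> p & 1]

    # ----- traceback -----

    def _gap_tree1(self, v: int) -> _Node:
        return _Node(v, None, [self._gap_tree1(c) for c in self.ch1[v]])

    def _gap_tree2(self, v: int) -> _Node:
        return _Node(None, v, [self._gap_tree2(c) for c in self.ch2[v]])

    def tb_tree(self, i: int, j: int) -> _Node:
        target = self.tree_dist(i, j)
        v = self.forest_dist(i, j, self.full_mask1(i), self.full_mask2(j)) + self.g(i, j)
        if v <= target + _EPS:
            return _Node(i, j, self.tb_forest(i, j, self.full_mask1(i), self.full_mask2(j)))
        for r in self.ch1[i]:
            if self.gap1(i) + self.tree_dist(r, j) - self.gap1(r) <= target + _EPS:
                kids = [
                    self.tb_tree(r, j) if c == r else self._gap_tree1(c) for c in self.ch1[i]
                ]
                return _Node(i, None, kids)
        for r in self.ch2[j]:
            if self.gap2(j) + self.tree_dist(i, r) - self.gap2(r) <= target + _EPS:
                kids = [
                    self.tb_tree(i, r) if c == r else self._gap_tree2(c) for c in self.ch2[j]
                ]
                return _Node(None, j, kids)
        raise AssertionError("traceback failed to reproduce the DP optimum")

    def tb_forest(self, i: int, j: int, maskA: int, maskB: int) -> list[_Node]:
        if maskA == 0 and maskB == 0:
            return []
        chA, chB = self.ch1[i], self.ch2[j]
        if maskA == 0:
            return [self._gap_tree2(c) for c in self._sel(chB, maskB)]
        if maskB == 0:
            return [self._gap_tree1(c) for c in self._sel(chA, maskA)]
        target = self.forest_dist(i, j, maskA, maskB)
        for p in range(len(chA)):
            if not maskA >> p & 1:
                continue
            for q in range(len(chB)):
                if not maskB >> q & 1:
                    continue
                rest = maskA ^ (1 << p), maskB ^ (1 << q)
                if (
                    self.forest_dist(i, j, *rest) + self.tree_dist(chA[p], chB[q])
                    <= target + _EPS
                ):
                    return [self.tb_tree(chA[p], chB[q])] + self.tb_forest(i, j, *rest)
        for p in range(len(chA)):
            if not maskA >> p & 1:
                continue
            ip = chA[p]
            full_ip = self.full_mask1(ip)
            sub = maskB
            while True:
                if (
                    self.forest_dist(ip, j, full_ip, sub)
                    + self.forest_dist(i, j, maskA ^ (1 << p), maskB ^ sub)
                    + self.delta
                    <= target + _EPS
                ):
                    node = _Node(ip, None, self.tb_forest(ip, j, full_ip, sub))
                    return [node] + self.tb_forest(i, j, maskA ^ (1 << p), maskB ^ sub)
                if sub == 0:
                    break
                sub = (sub - 1) & maskB
        for q in range(len(chB)):
            if not maskB >> q & 1:
                continue
            jq = chB[q]
            full_jq = self.full_mask2(jq)
            sub = maskA
            while True:
                if (
                    self.forest_dist(i, jq, sub, full_jq)
                    + self.forest_dist(i, j, maskA ^ sub, maskB ^ (1 << q))
                    + self.delta
                    <= target + _EPS
                ):
                    node = _Node(None, jq, self.tb_forest(i, jq, sub, full_jq))
                    return [node] + self.tb_forest(i, j, maskA ^ sub, maskB ^ (1 << q))
                if sub == 0:
                    break
                sub = (sub - 1) & maskA
        raise AssertionError("forest traceback failed to reproduce the DP optimum")


def _flatten(root: _Node, aligner: _Aligner, distance: float, delta: float, n_states: int) -> AlignedTree:
    nodes: list[tuple[int | None, int | None]] = []
    edges: list[tuple[int, int]] = []

    def walk(n: _Node, parent: int | None) -> None:
        k = len(nodes)
        nodes.append((n.a, n.b))
        if parent is not None:
            edges.append((parent, k))
        for c in n.children:
            walk(c, k)

    walk(root, None)
    M = sum(1 for a, b in nodes if a is not None and b is not None)
    U = len(nodes) - M
    d_matched = sum(
        aligner.g(a, b) for a, b in nodes if a is not None and b is not None
    ) if aligner is not None else 0.0
    d_unmatched = U * delta
    return AlignedTree(
        nodes=nodes,
        edges=edges,
        distance=distance,
        matched_pairs=M,
        unmatched_pairs=U,
        d_matched=d_matched,
        d_unmatched=d_unmatched,
        delta=delta,
        n_tree_states=n_states,
    )


def _all_gap_alignment(tree: TrajectoryTree, side: int, delta: float) -> AlignedTree:
    nodes: list[tuple[int | None, int | None]] = []
    edges: list[tuple[int, int]] = []
    ch = tree.children_map()

    def walk(v: int, parent: int | None) -> None:
        k = len(nodes)
        nodes.append((v, None) if side == 1 else (None, v))
        if parent is not None:
            edges.append((parent, k))
        for c in ch[v]:
            walk(c, k)

    if tree.nodes:
        walk(tree.root, None)
    U = len(nodes)
    return AlignedTree(
        nodes=nodes,
        edges=edges,
        distance=U * delta,
        matched_pairs=0,
        unmatched_pairs=U,
        d_matched=0.0,
        d_unmatched=U * delta,
        delta=delta,
    )


def align_trees(
    t1: TrajectoryTree,
    t2: TrajectoryTree,
    cost: CostFunction | None = None,
    max_degree: int = 10,
) -> AlignedTree:
    """Optimal alignment of two rooted trajectory trees.

    Centroid ``expr_median`` vectors must live in the same (shared) gene
    space in both trees. An empty tree on either side yields the all-gap
    alignment of the other. Degrees above ``max_degree`` raise, since the
    forest DP enumerates child subsets.
    """
    from .trajectory import prune_or_flag_degree

    cost = cost or CostFunction()
    if len(t1) == 0 and len(t2) == 0:
        return AlignedTree(
            nodes=[], edges=[], distance=0.0, matched_pairs=0, unmatched_pairs=0,
            d_matched=0.0, d_unmatched=0.0, delta=cost.delta,
        )
    if len(t1) == 0:
        return _all_gap_alignment(t2, 2, cost.delta)
    if len(t2) == 0:
        return _all_gap_alignment(t1, 1, cost.delta)
    prune_or_flag_degree(t1, max_degree)
    prune_or_flag_degree(t2, max_degree)
    al = _Aligner(t1, t2, cost)
    dist = al.tree_dist(t1.root, t2.root)
    root = al.tb_tree(t1.root, t2.root)
    at = _flatten(root, al, float(dist), cost.delta, len(al.memo_t))
    return at


def forest_align(
    subtrees1: list[TrajectoryTree],
    subtrees2: list[TrajectoryTree],
    cost: CostFunction | None = None,
    max_degree: int = 10,
) -> float:
    """Alignment distance between two forests (lists of node-disjoint trees).

    Implemented by hanging each forest under a virtual root and querying the
    forest-level DP table at the full subset pair.
    """
    cost = cost or CostFunction()
    if not subtrees1 and not subtrees2:
        return 0.0

    def merge(forest: list[TrajectoryTree]) -> TrajectoryTree:
        if not forest:
            # a lone virtual root; never queried at forest level
            some = subtrees1 or subtrees2
            glen = len(next(iter(some[0].centroids.values())).expr_median)
            from .trajectory import Centroid

            vroot = -1
            return TrajectoryTree(
                nodes=[vroot], edges=[], root=vroot,
                centroids={vroot: Centroid(vroot, np.zeros(1), np.arange(glen, dtype=float), 1)},
            )
        from .trajectory import Centroid

        nodes, edges, centroids = [], [], {}
        vroot = -1
        for t in forest:
            if len(t) == 0:
                raise ValueError("forests may not contain empty trees")
            nodes.extend(t.nodes)
            edges.extend(t.edges)
            edges.append((vroot, t.root))
            centroids.update(t.centroids)
        if len(set(nodes)) != len(nodes):
            raise ValueError("forest subtrees must be node-disjoint")
        glen = len(next(iter(centroids.values())).expr_median)
        centroids[vroot] = Centroid(vroot, np.zeros(1), np.arange(glen, dtype=float), 1)
        return TrajectoryTree(nodes=[vroot] + nodes, edges=edges, root=vroot, centroids=centroids)

    v1, v2 = merge(subtrees1), merge(subtrees2)
    for t in (v1, v2):
        prune = t.max_out_degree()
        if prune > max_degree:
            raise ValueError(f"forest degree {prune} exceeds max_degree={max_degree}")
    al = _Aligner(v1, v2, cost)
    return al.forest_dist(v1.root, v2.root, al.full_mask1(v1.root), al.full_mask2(v2.root))


def aligned_paths(at: AlignedTree) -> list[tuple[list[int], list[int]]]:
    """Project every root-to-leaf path of the aligned tree onto the two
    cluster spaces, dropping gap entries; paths empty on either side are
    skipped."""
    if not at.nodes:
        raise ValueError("empty aligned tree")
    out: list[tuple[list[int], list[int]]] = []
    for path in at.root_to_leaf_paths():
        p1 = [at.nodes[k][0] for k in path if at.nodes[k][0] is not None]
        p2 = [at.nodes[k][1] for k in path if at.nodes[k][1] is not None]
        if p1 and p2:
            out.append((p1, p2))
    return out
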