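"""Independent brute-force oracles used to validate the dynamic programs.

Deliberately slow and structure-free: no memoization, independent data
representations (nested tuples for trees), exhaustive enumeration.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

# ---------------------------------------------------------------------------
# tree alignment: exhaustive enumeration over aligned-forest structures
# ---------------------------------------------------------------------------
# A tree is a nested tuple (label, (child, child, ...)). An aligned forest of
# two tuples-of-trees is enumerated by the fate of the first tree a0 of A:
#   1. a0's root is matched with the root of some tree b in B; their child
#      forests align, and the remaining forests align independently.
#   2. a0's root is gapped; the gap node adopts an arbitrary subset S of B,
#      which aligns against a0's child forest.
#   3. some tree b in B has its root paired with a gap node that adopts a
#      subset S of A containing a0; S aligns against b's child forest.
# Every legal space insertion/overlay reduces to one of these cases, since
# all content of a tree stays below the aligned node holding its root.


def tree_size(t) -> int:
    return 1 + sum(tree_size(c) for c in t[1])


def _subsets(items):
    for r in range(len(items) + 1):
        yield from combinations(items, r)


def brute_force_alignment_distance(A, B, g, delta: float) -> float:
    """Minimum alignment cost between forests A and B (tuples of trees).

    ``g(label1, label2)`` is the matched-pair cost; gaps cost ``delta``.
    """
    A, B = tuple(A), tuple(B)
    if not A and not B:
        return 0.0
    if not A:
        return delta * sum(tree_size(t) for t in B)
    if not B:
        return delta * sum(tree_size(t) for t in A)
    a0, rest = A[0], A[1:]
    best = np.inf
    # case 1: a0's root matched with some b's root
    for bi, b in enumerate(B):
        B_rest = B[:bi] + B[bi + 1 :]
        cost = (
            g(a0[0], b[0])
            + brute_force_alignment_distance(a0[1], b[1], g, delta)
            + brute_force_alignment_distance(rest, B_rest, g, delta)
        )
        best = min(best, cost)
    # case 2: a0's root gapped, adopting any subset of B
    for S in _subsets(range(len(B))):
        S_set = set(S)
        adopted = tuple(B[i] for i in S)
        left = tuple(B[i] for i in range(len(B)) if i not in S_set)
        cost = (
            delta
            + brute_force_alignment_distance(a0[1], adopted, g, delta)
            + brute_force_alignment_distance(rest, left, g, delta)
        )
        best = min(best, cost)
    # case 3: some b's root paired with a gap that adopts a subset of A
    # containing a0
    for bi, b in enumerate(B):
        B_rest = B[:bi] + B[bi + 1 :]
        for S in _subsets(range(1, len(A))):
            adopted = (a0,) + tuple(A[i] for i in S)
            left = tuple(A[i] for i in range(1, len(A)) if i not in set(S))
            cost = (
                delta
                + brute_force_alignment_distance(adopted, b[1], g, delta)
                + brute_force_alignment_distance(left, B_rest, g, delta)
            )
            best = min(best, cost)
    return float(best)


# ---------------------------------------------------------------------------
# DTW: exhaustive enumeration of monotone boundary-anchored paths
# ---------------------------------------------------------------------------

def brute_force_dtw_cost(D: np.ndarray) -> float:
    D = np.asarray(D, dtype=float)
    n1, n2 = D.shape

    def rec(i: int, j: int) -> float:
        if i == n1 - 1 and j == n2 - 1:
            return D[i, j]
        cands = []
        if i + 1 < n1:
            cands.append(rec(i + 1, j))
        if j + 1 < n2:
            cands.append(rec(i, j + 1))
        if i + 1 < n1 and j + 1 < n2:
            cands.append(rec(i + 1, j + 1))
        return D[i, j] + min(cands)

    return float(rec(0, 0))


# ---------------------------------------------------------------------------
# MST: enumeration of all labelled spanning trees via Pruefer sequences
# ---------------------------------------------------------------------------

def _pruefer_decode(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    for v in seq:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append((leaf, v))
                degree[leaf] -= 1
                degree[v] -= 1
                break
    u, w = [v for v in range(n) if degree[v] == 1]
    edges.append((u, w))
    return edges


def min_spanning_weight_enumerated(D: np.ndarray) -> float:
    """Minimum spanning-tree weight by enumerating all n^(n-2) labelled trees."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n == 1:
        return 0.0
    if n == 2:
        return float(D[0, 1])
    best = np.inf
    for seq in product(range(n), repeat=n - 2):
        w = sum(D[a, b] for a, b in _pruefer_decode(seq, n))
        best = min(best, w)
    return float(best)


# ---------------------------------------------------------------------------
# normalized dispersion: loop-based re-implementation
# ---------------------------------------------------------------------------

def normalized_dispersion_loops(log_counts: np.ndarray, n_bins: int = 20) -> np.ndarray:
    X = np.expm1(log_counts)
    m = X.shape[1]
    mean = np.array([X[:, j].mean() for j in range(m)])
    var = np.array([X[:, j].var(ddof=1) for j in range(m)])
    disp = np.array([var[j] / mean[j] if mean[j] > 0 else 0.0 for j in range(m)])
    order = sorted(range(m), key=lambda j: (mean[j], j))
    bins = np.array_split(np.array(order), min(n_bins, m))
    nd = np.zeros(m)
    for b in bins:
        vals = [disp[j] for j in b]
        mu = float(np.mean(vals))
        sd = float(np.std(vals))
        for j in b:
            nd[j] = (disp[j] - mu) / sd if sd > 0 else 0.0
    return nd


# ---------------------------------------------------------------------------
# random tree pair generation for the alignment oracle tests
# ---------------------------------------------------------------------------

def random_tree_arrays(rng: np.random.Generator, max_nodes: int = 6, n_genes: int = 5):
    """A random rooted tree as (parents list, labels array)."""
    n = int(rng.integers(1, max_nodes + 1))
    parents = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
    labels = rng.normal(size=(n, n_genes))
    return parents, labels


def as_nested(parents: list[int], labels: np.ndarray):
    """Convert (parents, labels) into the nested-tuple oracle representation."""
    children: dict[int, list[int]] = {i: [] for i in range(len(parents))}
    for i, p in enumerate(parents):
        if p >= 0:
            children[p].append(i)

    def build(v: int):
        return (tuple(labels[v]), tuple(build(c) for c in children[v]))

    return build(0)


def as_trajectory_tree(parents: list[int], labels: np.ndarray):
    """Convert (parents, labels) into a TrajectoryTree with centroid labels."""
    from treecap.trajectory import Centroid, TrajectoryTree

    n = len(parents)
    edges = [(p, i) for i, p in enumerate(parents) if p >= 0]
    centroids = {
        i: Centroid(cluster_id=i, pc_median=np.zeros(2), expr_median=labels[i], n_cells=1)
        for i in range(n)
    }
    return TrajectoryTree(nodes=list(range(n)), edges=edges, root=0, centroids=centroids)


def spearman_gap_cost(x, y) -> float:
    from scipy.stats import spearmanr

    return 1.0 - float(spearmanr(np.asarray(x), np.asarray(y)).statistic)
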