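"""Start-cell selection, diffusion pseudotime, DTW, and gene kinetics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from treecap import (
    Clustering,
    ExpressionDataset,
    PseudotimeOrdering,
    diffusion_pseudotime,
    dtw_align,
    dtw_core,
    gene_kinetics,
    path_specific_genes,
    select_start_cell,
)
from treecap.cell_align import DTWAlignment

from conftest import make_gradient_dataset
from oracles import brute_force_dtw_cost


def _clustering(labels):
    labels = np.array(labels)
    return Clustering(labels=labels, n_clusters=labels.max() + 1, resolution=1.0, seed=0)


class TestSelectStartCell:
    def _line_ds(self, positions):
        lc = np.column_stack([positions, np.zeros_like(positions)])
        return ExpressionDataset(
            np.abs(lc), [f"c{i}" for i in range(len(positions))],
            ["g0", "g1"], log_counts=lc,
        )

    def test_diameter_endpoint_within_root_cluster(self):
        ds = self._line_ds(np.array([0.0, 1.0, 2.0]))
        assert select_start_cell(ds, _clustering([0, 0, 1]), 0) == "c0"

    def test_singleton_root_cluster(self):
        ds = self._line_ds(np.array([0.0, 1.0, 2.0]))
        assert select_start_cell(ds, _clustering([1, 0, 1]), 0) == "c1"

    def test_tie_broken_to_lower_index(self):
        ds = self._line_ds(np.array([0.0, 2.0, 1.0, 1.0]))  # c0 and c1 symmetric
        assert select_start_cell(ds, _clustering([0, 0, 1, 1]), 0) == "c0"

    def test_singleton_dataset_rejected(self):
        ds = self._line_ds(np.array([0.0]))
        with pytest.raises(ValueError):
            select_start_cell(ds, _clustering([0]), 0)


class TestDiffusionPseudotime:
    def test_start_cell_has_zero_pseudotime_and_order_recovers_gradient(self):
        ds = make_gradient_dataset(n=30)
        # full adaptive kernel: exact recovery of the generating order
        o = diffusion_pseudotime(ds, np.arange(30), "c0", k=5, n_dcs=5, dense=True)
        assert o.cell_ids[0] == "c0"
        assert o.pseudotime[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(o.pseudotime) >= 0)
        rho = spearmanr(ds.sim_time[o.cell_indices], o.pseudotime).statistic
        assert rho == pytest.approx(1.0)
        # kNN-truncated kernel: near-exact (local swaps only)
        o2 = diffusion_pseudotime(ds, np.arange(30), "c0", k=5, n_dcs=5)
        rho2 = spearmanr(ds.sim_time[o2.cell_indices], o2.pseudotime).statistic
        assert rho2 > 0.99

    def test_permutation_invariance(self, rng):
        ds = make_gradient_dataset(n=25, seed=3)
        o1 = diffusion_pseudotime(ds, np.arange(25), "c0", k=5, n_dcs=5)
        perm = rng.permutation(25)
        ds_p = ds.subset_cells(perm)
        o2 = diffusion_pseudotime(ds_p, np.arange(25), "c0", k=5, n_dcs=5)
        pt1 = dict(zip(o1.cell_ids, o1.pseudotime))
        pt2 = dict(zip(o2.cell_ids, o2.pseudotime))
        for cid in pt1:
            assert pt1[cid] == pytest.approx(pt2[cid], abs=1e-6)

    def test_disconnected_subgraph_reports_components(self):
        lc = np.vstack([np.random.default_rng(0).normal(0, 0.01, size=(10, 3)),
                        np.random.default_rng(1).normal(100, 0.01, size=(10, 3))])
        ds = ExpressionDataset(
            np.abs(lc), [f"c{i}" for i in range(20)], ["g0", "g1", "g2"], log_counts=lc
        )
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_pseudotime(ds, np.arange(20), "c0", k=3, n_dcs=3)

    def test_start_must_be_in_path(self):
        ds = make_gradient_dataset(n=10)
        with pytest.raises(ValueError, match="start cell"):
            diffusion_pseudotime(ds, np.arange(5), "c9", k=2, n_dcs=2)


class TestDtwCore:
    def test_identity_is_diagonal_with_zero_cost(self):
        D = 1.0 - np.eye(5)
        cost, path = dtw_core(D)
        assert cost == pytest.approx(0.0)
        assert path == [(i, i) for i in range(5)]

    def test_single_row_forced_warping(self):
        D = np.ones((1, 6))
        cost, path = dtw_core(D)
        assert cost == pytest.approx(6.0)
        assert path == [(0, j) for j in range(6)]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_path_enumeration(self, trial):
        rng = np.random.default_rng(500 + trial)
        D = rng.uniform(size=(6, 7))
        cost, path = dtw_core(D)
        assert cost == pytest.approx(brute_force_dtw_cost(D), abs=1e-12)
        # path validity invariants
        assert path[0] == (0, 0) and path[-1] == (5, 6)
        steps = {(b[0] - a[0], b[1] - a[1]) for a, b in zip(path, path[1:])}
        assert steps <= {(1, 0), (0, 1), (1, 1)}
        assert cost == pytest.approx(sum(D[i, j] for i, j in path), abs=1e-12)

    def test_cost_monotone_in_local_distances(self, rng):
        D = rng.uniform(size=(5, 5))
        base, path = dtw_core(D)
        D2 = D.copy()
        i, j = path[2]
        D2[i, j] += 0.5
        assert dtw_core(D2)[0] >= base

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_core(np.empty((0, 3)))


def _ordered_dataset(expr_by_gene, prefix):
    """Dataset whose cells are already in pseudotime order."""
    genes = list(expr_by_gene)
    M = np.column_stack([expr_by_gene[g] for g in genes])
    n = M.shape[0]
    ds = ExpressionDataset(
        np.abs(M) + 1.0,
        [f"{prefix}{i}" for i in range(n)],
        genes,
        log_counts=M,
    )
    ordering = PseudotimeOrdering(
        cell_ids=list(ds.cell_ids),
        pseudotime=np.linspace(0, 1, n),
        start_cell=ds.cell_ids[0],
        path_clusters=[0],
        cell_indices=np.arange(n),
    )
    return ds, ordering


class TestDtwAlign:
    def test_identical_series_zero_cost_diagonal(self, rng):
        expr = {f"g{j}": rng.normal(size=10) for j in range(5)}
        ds1, o1 = _ordered_dataset(expr, "a")
        ds2, o2 = _ordered_dataset(expr, "b")
        al = dtw_align(o1, o2, ds1, ds2, list(expr))
        assert al.total_cost == pytest.approx(0.0, abs=1e-9)
        assert al.warping_path == [(i, i) for i in range(10)]

    def test_empty_gene_list_rejected(self, rng):
        expr = {f"g{j}": rng.normal(size=4) for j in range(3)}
        ds1, o1 = _ordered_dataset(expr, "a")
        ds2, o2 = _ordered_dataset(expr, "b")
        with pytest.raises(ValueError):
            dtw_align(o1, o2, ds1, ds2, [])

    def test_constant_cell_named_in_error(self, rng):
        expr = {f"g{j}": rng.normal(size=4) for j in range(3)}
        ds1, o1 = _ordered_dataset(expr, "a")
        flat = {g: np.ones(4) * 2 for g in expr}
        ds2, o2 = _ordered_dataset(flat, "b")
        with pytest.raises(ValueError, match="zero rank variance"):
            dtw_align(o1, o2, ds1, ds2, list(expr))


class TestGeneKinetics:
    def _alignment(self, expr1, expr2):
        ds1, o1 = _ordered_dataset(expr1, "a")
        ds2, o2 = _ordered_dataset(expr2, "b")
        n = len(next(iter(expr1.values())))
        al = DTWAlignment(
            warping_path=[(i, i) for i in range(n)],
            total_cost=0.0, ordering_1=o1, ordering_2=o2, genes=list(expr1),
        )
        return al, ds1, ds2

    def test_slope_sign_groups(self, rng):
        n = 12
        up = np.linspace(0, 3, n)
        noise = rng.normal(scale=5.0, size=n)  # high-dispersion filler
        expr1 = {"rise": up, "const": np.zeros(n), "mirror": up, "noise": noise}
        expr2 = {"rise": 2 * up, "const": up, "mirror": up[::-1], "noise": noise}
        al, ds1, ds2 = self._alignment(expr1, expr2)
        out = {k.gene: k for k in gene_kinetics(al, ds1, ds2, dispersion_cutoff=-100.0)}
        assert out["rise"].group == "up_up"
        assert out["rise"].slope_1 > 0 and out["rise"].slope_2 > 0
        assert out["const"].group == "flat"  # constant in dataset 1 -> zero slope
        assert out["mirror"].group == "up_down"
        assert out["rise"].dtw_similarity == pytest.approx(0.0, abs=1e-9)

    def test_no_genes_pass_cutoff_warns_empty(self, rng):
        n = 8
        expr = {"g": np.linspace(0, 1, n), "h": rng.normal(size=n)}
        al, ds1, ds2 = self._alignment(expr, expr)
        with pytest.warns(UserWarning, match="dispersion cutoff"):
            assert gene_kinetics(al, ds1, ds2, dispersion_cutoff=1e6) == []


def test_path_specific_genes_set_difference():
    per_path = {"p1": ["a", "b", "c"], "p2": ["b", "d"], "p3": ["e"]}
    out = path_specific_genes(per_path)
    assert out == {"p1": ["a", "c"], "p2": ["d"], "p3": ["e"]}


# property-based check (derandomized): DTW DP vs exhaustive enumeration
from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.integers(1, 5), st.integers(1, 5), st.integers(0, 2**31 - 1)
)
def test_dtw_cost_matches_enumeration_property(n1, n2, seed):
    D = np.random.default_rng(seed).uniform(size=(n1, n2))
    cost, path = dtw_core(D)
    assert cost == pytest.approx(brute_force_dtw_cost(D), abs=1e-12)
    assert path[0] == (0, 0) and path[-1] == (n1 - 1, n2 - 1)
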