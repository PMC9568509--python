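"""I/O, filtering, normalization, HVG selection, PCA, and the kNN graph."""

import numpy as np
import pytest

from treecap import (
    ExpressionDataset,
    filter_cells_genes,
    knn_graph,
    load_counts,
    normalize_log,
    normalized_dispersion,
    pca,
    scale_min_max,
    select_hvg,
)

from oracles import normalized_dispersion_loops


class TestLoadCounts:
    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,gA,gB\nc1,1,2\nc2,0,3\nc3,4,0\n")
        ds = load_counts(p)
        assert (ds.n_cells, ds.n_genes) == (3, 2)
        assert ds.gene_names == ["gA", "gB"]
        assert ds.counts[2, 0] == 4

    def test_empty_file_is_io_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(OSError):
            load_counts(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            load_counts(tmp_path / "nope.csv")

    def test_mtx_with_mismatched_features(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n3 2 2\n1 1 5\n3 2 1\n"
        )
        (tmp_path / "features.tsv").write_text("g1\ng2\ng3\ng4\n")  # wrong length
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\nc3\n")
        with pytest.raises(ValueError, match="matches neither"):
            load_counts(tmp_path / "m.mtx")

    def test_mtx_orientation_resolved(self, tmp_path):
        # 3 genes x 2 cells on disk -> transposed to cells x genes
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n3 2 2\n1 1 5\n3 2 1\n"
        )
        (tmp_path / "features.tsv").write_text("g1\ng2\ng3\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        ds = load_counts(tmp_path / "m.mtx")
        assert (ds.n_cells, ds.n_genes) == (2, 3)
        assert ds.counts[0, 0] == 5 and ds.counts[1, 2] == 1

    def test_h5ad_roundtrip_with_ground_truth(self, tmp_path, sim_dataset):
        from treecap import to_anndata

        p = tmp_path / "d.h5ad"
        to_anndata(sim_dataset).write_h5ad(p)
        back = load_counts(p)
        np.testing.assert_allclose(back.counts, sim_dataset.counts)
        np.testing.assert_allclose(back.sim_time, sim_dataset.sim_time)
        assert list(back.branch_label) == list(sim_dataset.branch_label)

    def test_duplicate_gene_names_rejected(self):
        with pytest.raises(ValueError, match="duplicated gene names"):
            ExpressionDataset(np.ones((2, 2)), ["a", "b"], ["g", "g"])


class TestFilter:
    def test_cell_below_min_genes_removed(self):
        ds = ExpressionDataset(
            np.array([[1.0, 0, 0], [2, 3, 0], [1, 1, 1], [0, 2, 2]]),
            [f"c{i}" for i in range(4)],
            ["g0", "g1", "g2"],
        )
        out = filter_cells_genes(ds, min_genes=2, min_cells=0)
        assert out.cell_ids == ["c1", "c2", "c3"]

    def test_gene_below_min_cells_removed(self):
        ds = ExpressionDataset(
            np.array([[1.0, 1], [1, 1], [1, 0], [1, 0]]),
            [f"c{i}" for i in range(4)],
            ["common", "rare"],
        )
        out = filter_cells_genes(ds, min_genes=0, min_cells=3)
        assert out.gene_names == ["common"]

    def test_zero_thresholds_are_identity(self, tiny_ds):
        out = filter_cells_genes(tiny_ds, min_genes=0, min_cells=0)
        np.testing.assert_array_equal(out.counts, tiny_ds.counts)

    def test_idempotent(self, sim_dataset):
        once = filter_cells_genes(sim_dataset, min_genes=50, min_cells=3)
        twice = filter_cells_genes(once, min_genes=50, min_cells=3)
        assert once.cell_ids == twice.cell_ids and once.gene_names == twice.gene_names

    def test_all_cells_removed(self, tiny_ds):
        with pytest.raises(ValueError, match="empty dataset"):
            filter_cells_genes(tiny_ds, min_genes=1000, min_cells=0)


class TestNormalizeLog:
    def test_zero_total_cell_names_cell(self):
        ds = ExpressionDataset(np.array([[1.0, 2], [0, 0]]), ["ok", "empty"], ["g0", "g1"])
        with pytest.raises(ValueError, match="empty"):
            normalize_log(ds)

    def test_single_gene_cell_direct_value(self):
        ds = ExpressionDataset(np.array([[7.0]]), ["c"], ["g"])
        out = normalize_log(ds, target_sum=7.0)
        assert out.log_counts[0, 0] == pytest.approx(np.log1p(7.0))

    def test_zero_count_maps_to_zero_and_shape_preserved(self, tiny_ds):
        assert tiny_ds.log_counts.shape == tiny_ds.counts.shape
        assert tiny_ds.log_counts[0, 1] == 0.0  # count 0 -> log1p(0)

    def test_default_target_is_median_total(self):
        counts = np.array([[1.0, 1], [2, 2], [6, 6]])
        ds = ExpressionDataset(counts, ["a", "b", "c"], ["g0", "g1"])
        out = normalize_log(ds)
        # median total is 4, so cell b is scaled to sum 4
        np.testing.assert_allclose(np.expm1(out.log_counts[1]).sum(), 4.0)


class TestScaleMinMax:
    def test_affine_map(self):
        ds = ExpressionDataset(
            np.array([[-2.0, 5], [0, 5], [2, 5]]), ["a", "b", "c"], ["g", "const"]
        )
        out = scale_min_max(ds)
        np.testing.assert_allclose(out.counts[:, 0], [0, 0.5, 1.0])
        np.testing.assert_allclose(out.counts[:, 1], 0.0)  # constant gene -> 0

    def test_unit_interval_gene_unchanged(self):
        ds = ExpressionDataset(np.array([[0.0], [0.25], [1.0]]), ["a", "b", "c"], ["g"])
        np.testing.assert_allclose(scale_min_max(ds).counts[:, 0], [0, 0.25, 1.0])


class TestSelectHvg:
    def test_requires_exactly_one_criterion(self, tiny_ds):
        with pytest.raises(ValueError):
            select_hvg(tiny_ds)
        with pytest.raises(ValueError):
            select_hvg(tiny_ds, n_top=2, dispersion_cutoff=1.0)

    def test_n_top_equals_m_returns_all(self, tiny_ds):
        assert select_hvg(tiny_ds, n_top=4) == tiny_ds.gene_names

    def test_n_top_exceeding_m_errors(self, tiny_ds):
        with pytest.raises(ValueError):
            select_hvg(tiny_ds, n_top=5)

    def test_constant_gene_ranked_last(self):
        rng = np.random.default_rng(0)
        counts = np.column_stack([rng.poisson(5.0, 40), np.full(40, 3.0)])
        ds = normalize_log(
            ExpressionDataset(counts, [f"c{i}" for i in range(40)], ["varying", "constant"])
        )
        assert select_hvg(ds, n_top=1) == ["varying"]

    def test_matches_independent_binned_dispersion(self, sim_dataset):
        ds = normalize_log(sim_dataset)
        nd = normalized_dispersion(ds)
        nd_oracle = normalized_dispersion_loops(ds.log_counts)
        np.testing.assert_allclose(nd, nd_oracle, atol=1e-10)
        mine = set(select_hvg(ds, dispersion_cutoff=1.0))
        theirs = {g for g, v in zip(ds.gene_names, nd_oracle) if v > 1.0}
        assert mine == theirs


class TestPca:
    def test_axes_orthonormal_and_variance_bounded(self, sim_dataset):
        ds = normalize_log(sim_dataset)
        emb = pca(ds, p=10)
        np.testing.assert_allclose(emb.components @ emb.components.T, np.eye(10), atol=1e-8)
        total_var = ds.log_counts.var(axis=0, ddof=1).sum()
        assert emb.explained_variance.sum() <= total_var + 1e-8
        assert np.all(np.diff(emb.explained_variance) <= 1e-12)

    def test_p1_recovers_line_coordinates(self):
        pos = np.array([0.0, 1.0, 3.0])
        log_counts = np.column_stack([2 * pos, pos])
        ds = ExpressionDataset(
            np.expm1(log_counts), ["a", "b", "c"], ["g0", "g1"], log_counts=log_counts
        )
        emb = pca(ds, p=1)
        centered = (pos - pos.mean()) * np.sqrt(5)
        assert np.allclose(emb.Z[:, 0], centered) or np.allclose(emb.Z[:, 0], -centered)

    def test_collinear_data_second_component_zero(self):
        pos = np.linspace(0, 1, 5)
        log_counts = np.column_stack([pos, 3 * pos])
        ds = ExpressionDataset(
            np.expm1(log_counts), [f"c{i}" for i in range(5)], ["g0", "g1"], log_counts=log_counts
        )
        emb = pca(ds, p=2)
        assert emb.explained_variance[1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_cells_identical_rows(self, tiny_ds):
        ds = tiny_ds
        dup = ExpressionDataset(
            np.vstack([ds.counts, ds.counts[:1]]),
            ds.cell_ids + ["c0dup"],
            ds.gene_names,
            log_counts=np.vstack([ds.log_counts, ds.log_counts[:1]]),
        )
        emb = pca(dup, p=2)
        np.testing.assert_allclose(emb.Z[0], emb.Z[-1], atol=1e-10)

    def test_p_too_large(self, tiny_ds):
        with pytest.raises(ValueError):
            pca(tiny_ds, p=6)


class TestKnnGraph:
    @staticmethod
    def _emb(Z):
        from treecap import EmbeddingSpace

        Z = np.asarray(Z, dtype=float)
        return EmbeddingSpace(
            Z=Z, explained_variance=np.ones(Z.shape[1]), components=np.eye(Z.shape[1])
        )

    def test_k_max_gives_complete_graph(self, rng):
        emb = self._emb(rng.normal(size=(6, 2)))
        g = knn_graph(emb, k=5)
        assert len(g.edges) == 15

    def test_collinear_points_hand_checked(self):
        g = knn_graph(self._emb([[0.0], [1.0], [3.0]]), k=1)
        assert {tuple(e) for e in g.edges} == {(0, 1), (1, 2)}

    def test_duplicated_points_zero_weight(self):
        g = knn_graph(self._emb([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]]), k=1)
        assert 0.0 in g.weights

    def test_weights_are_exact_distances(self, rng):
        Z = rng.normal(size=(20, 3))
        g = knn_graph(self._emb(Z), k=4)
        for (i, j), w in zip(g.edges, g.weights):
            assert w == pytest.approx(np.linalg.norm(Z[i] - Z[j]), rel=1e-12, abs=0)

    def test_degree_at_least_k(self, rng):
        g = knn_graph(self._emb(rng.normal(size=(30, 2))), k=3)
        assert g.degrees().min() >= 3

    def test_k_out_of_range(self, rng):
        emb = self._emb(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError):
            knn_graph(emb, k=4)
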