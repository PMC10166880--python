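"""Gating on embeddings and scatters, label management, session persistence."""

import numpy as np
import pytest

import cellgate as cg
from cellgate.errors import AxesContextError, DomainError, FeatureLookupError

from oracle_geometry import ray_cast_inside


def _embedding_axes(name="umap"):
    return cg.AxesContext(kind="embedding", embedding_name=name)


SQUARE = [(-1.0, -1.0), (1.0, -1.0), (1.0, 1.0), (-1.0, 1.0)]


class TestSelectOnEmbedding:
    def test_cluster_gate_matches_ray_oracle(self, marker_dataset):
        ds, spec = marker_dataset
        poly = cg.reference_polygon(spec, 0, q=0.95)
        ps = cg.PolygonSet(axes=_embedding_axes(), polygons=[poly])
        res = cg.select_on_embedding(ds, "umap", ps, "sel")
        coords = ds.get_embedding("umap")
        rng = np.random.default_rng(5)
        idx = rng.choice(ds.n_cells, 300, replace=False)
        oracle = [ray_cast_inside(coords[i], poly.vertices, rng) for i in idx]
        assert list(res.membership[idx, 0]) == oracle
        assert list(ds.annotations["sel"]) == res.labels
        assert "sel" in ds.polygon_store

    def test_polygon_far_from_points_labels_everything_rest(self, tiny_dataset):
        ps = cg.PolygonSet.from_vertex_lists(
            _embedding_axes(), [[(100, 100), (101, 100), (101, 101)]]
        )
        res = cg.select_on_embedding(tiny_dataset, "umap", ps, "sel")
        assert res.labels == ["rest"] * 4
        assert not res.membership.any()

    def test_reapplication_is_idempotent(self, tiny_dataset):
        ps = cg.PolygonSet.from_vertex_lists(_embedding_axes(), [SQUARE])
        r1 = cg.select_on_embedding(tiny_dataset, "umap", ps, "sel")
        r2 = cg.select_on_embedding(tiny_dataset, "umap", ps, "sel")
        assert r1.labels == r2.labels
        assert list(tiny_dataset.annotations.columns).count("sel") == 1

    def test_unknown_embedding_is_lookup_error(self, tiny_dataset):
        ps = cg.PolygonSet.from_vertex_lists(_embedding_axes("tsne"), [SQUARE])
        with pytest.raises(FeatureLookupError):
            cg.select_on_embedding(tiny_dataset, "tsne", ps, "sel")

    def test_axes_kind_mismatch_is_context_error(self, tiny_dataset):
        scatter_axes = cg.AxesContext(kind="scatter", x_feature="CCR7", y_feature="SELL")
        ps = cg.PolygonSet.from_vertex_lists(scatter_axes, [SQUARE])
        with pytest.raises(AxesContextError):
            cg.select_on_embedding(tiny_dataset, "umap", ps, "sel")

    def test_embedding_name_mismatch_is_context_error(self, tiny_dataset):
        ps = cg.PolygonSet.from_vertex_lists(_embedding_axes("tsne"), [SQUARE])
        with pytest.raises(AxesContextError):
            cg.select_on_embedding(tiny_dataset, "umap", ps, "sel")

    def test_subset_consistency_labels_survive_cell_removal(self, marker_dataset):
        """Dropping non-selected cells then re-applying the session keeps labels."""
        ds, spec = marker_dataset
        poly = cg.reference_polygon(spec, 1, q=0.9)
        ps = cg.PolygonSet(axes=_embedding_axes(), polygons=[poly])
        res = cg.select_on_embedding(ds, "umap", ps, "keep")
        keep = np.array([lab != "rest" for lab in res.labels])
        # drop half of the non-selected cells
        drop = ~keep & (np.arange(ds.n_cells) % 2 == 0)
        sub = ds.subset(~drop)
        res2 = cg.select_on_embedding(sub, "umap", ps, "keep")
        expected = [lab for lab, d in zip(res.labels, drop) if not d]
        assert res2.labels == expected


class TestSelectOnScatter:
    def _quadrant_dataset(self):
        """Cells with raw (CD4, CD8) counts (100,1), (1,100), (50,50), (0,0)."""
        counts = np.array([[100, 1], [1, 100], [50, 50], [0, 0]])
        import scipy.sparse as sp

        return cg.CellDataset(
            counts=sp.csr_matrix(counts),
            cell_ids=["a", "b", "c", "d"],
            gene_ids=["CD4", "CD8"],
        )

    def test_quadrant_gates_split_double_positive_negative(self):
        ds = self._quadrant_dataset()
        axes = cg.AxesContext(kind="scatter", x_feature="CD4", y_feature="CD8")
        big = 1000.0
        ps = cg.PolygonSet.from_vertex_lists(
            axes,
            [
                [(10, -1), (big, -1), (big, 10), (10, 10)],  # x>10, y<=10
                [(-1, 10), (10, 10), (10, big), (-1, big)],  # x<=10, y>10
                [(10, 10), (big, 10), (big, big), (10, big)],  # both high
            ],
            names=["CD4", "CD8", "DP"],
        )
        res = cg.select_on_scatter(ds, ps, "gate")
        assert res.labels == ["CD4", "CD8", "DP", "rest"]

    def test_log10_gate_contains_log_transformed_cell(self):
        ds = self._quadrant_dataset()
        axes = cg.AxesContext(
            kind="scatter", x_feature="CD4", y_feature="CD8",
            x_scale="log10", y_scale="log10",
        )
        ps = cg.PolygonSet.from_vertex_lists(
            axes, [[(1, -0.5), (3, -0.5), (3, 0.5), (1, 0.5)]]
        )
        res = cg.select_on_scatter(ds, ps, "lg")
        # (100, 1) -> (2, 0) in log10 space: inside
        assert res.membership[0, 0]
        assert res.labels[0] == "0"

    def test_log_gating_equals_linear_gating_of_log_values(self, marker_dataset):
        """For positive counts, gating log10 display space == gating log10 values."""
        ds, _ = marker_dataset
        gate = [(0.0, 0.0), (2.0, 0.0), (2.0, 2.0), (0.0, 2.0)]
        log_axes = cg.AxesContext(
            kind="scatter", x_feature="CCR7", y_feature="SELL",
            x_scale="log10", y_scale="log10",
        )
        ps = cg.PolygonSet.from_vertex_lists(log_axes, [gate])
        res = cg.select_on_scatter(ds, ps, "logsel")
        x = ds.feature_values("CCR7")
        y = ds.feature_values("SELL")
        pos = (x > 0) & (y > 0)
        manual = cg.points_in_polygon(
            np.column_stack([np.log10(x[pos]), np.log10(y[pos])]),
            cg.Polygon("0", gate),
        )
        np.testing.assert_array_equal(res.membership[pos, 0], manual)

    def test_zero_counts_placed_at_log10_half(self):
        ds = self._quadrant_dataset()
        axes = cg.AxesContext(
            kind="scatter", x_feature="CD4", y_feature="CD8",
            x_scale="log10", y_scale="log10",
        )
        pts = cg.scatter_coordinates(ds, axes)
        np.testing.assert_allclose(pts[3], [np.log10(0.5), np.log10(0.5)])

    def test_normalized_layer_computed_on_the_fly(self, marker_dataset):
        ds, _ = marker_dataset
        ds.normalized = None
        axes = cg.AxesContext(
            kind="scatter", x_feature="CCR7", y_feature="SELL", layer="normalized"
        )
        ps = cg.PolygonSet.from_vertex_lists(axes, [[(0, 0), (10, 0), (10, 10), (0, 10)]])
        res = cg.select_on_scatter(ds, ps, "norm_gate")
        assert ds.normalized is not None
        assert len(res.labels) == ds.n_cells

    def test_negative_values_under_log_scale_rejected(self, tiny_dataset):
        tiny_dataset.normalized = tiny_dataset.counts.astype(float) * -1.0
        with pytest.raises((DomainError, Exception)):
            axes = cg.AxesContext(
                kind="scatter", x_feature="CCR7", y_feature="SELL",
                layer="normalized", x_scale="log10",
            )
            cg.scatter_coordinates(tiny_dataset, axes)


class TestRenameLabels:
    def _selected(self, tiny_dataset):
        ps = cg.PolygonSet.from_vertex_lists(
            _embedding_axes(), [[(-0.5, -0.5), (1.5, -0.5), (1.5, 0.5), (-0.5, 0.5)],
                                [(-0.5, 0.5), (0.5, 0.5), (0.5, 1.5), (-0.5, 1.5)]],
        )
        cg.select_on_embedding(tiny_dataset, "umap", ps, "sel")
        return tiny_dataset

    def test_default_integer_names_become_custom(self, tiny_dataset):
        ds = self._selected(tiny_dataset)
        cg.rename_labels(ds, "sel", {"0": "TH1", "1": "TH17"})
        assert set(ds.annotations["sel"]) <= {"TH1", "TH17", "rest"}
        assert "TH1" in set(ds.annotations["sel"])

    def test_empty_mapping_is_identity(self, tiny_dataset):
        ds = self._selected(tiny_dataset)
        before = list(ds.annotations["sel"])
        cg.rename_labels(ds, "sel", {})
        assert list(ds.annotations["sel"]) == before

    def test_unknown_source_label_errors_listing_valid(self, tiny_dataset):
        ds = self._selected(tiny_dataset)
        with pytest.raises(FeatureLookupError, match="valid labels"):
            cg.rename_labels(ds, "sel", {"2": "X"})

    def test_merging_rename_is_allowed_but_warned(self, tiny_dataset):
        ds = self._selected(tiny_dataset)
        with pytest.warns(UserWarning, match="merges"):
            cg.rename_labels(ds, "sel", {"0": "rest"})


class TestSessions:
    def test_save_load_reapply_reproduces_labels(self, tmp_path, marker_dataset):
        ds, spec = marker_dataset
        ps = cg.PolygonSet(
            axes=_embedding_axes(),
            polygons=[
                cg.reference_polygon(spec, 0, q=0.9, name="0"),
                cg.reference_polygon(spec, 1, q=0.9, name="1"),
            ],
        )
        res = cg.select_on_embedding(ds, "umap", ps, "sess")
        cg.save_session(ds, "sess", tmp_path / "s.json")
        loaded = cg.load_session(tmp_path / "s.json")
        assert loaded.names == ps.names
        res2 = cg.apply_session(ds, loaded, "sess2")
        assert res2.labels == res.labels

    def test_session_on_dataset_missing_embedding_is_context_error(
        self, tmp_path, tiny_dataset
    ):
        ps = cg.PolygonSet.from_vertex_lists(_embedding_axes("tsne"), [SQUARE])
        ps.save(tmp_path / "s.json")
        loaded = cg.load_session(tmp_path / "s.json")
        with pytest.raises((AxesContextError, FeatureLookupError)):
            cg.apply_session(tiny_dataset, loaded, "x")

    def test_negative_selection_composite_equals_set_intersection(self, marker_dataset):
        """Removing 'A,B' cells removes exactly members(A) & members(B)."""
        ds, spec = marker_dataset
        # two overlapping generous gates on the same cluster
        p0 = cg.reference_polygon(spec, 1, q=0.99, name="CCR7")
        p1 = cg.Polygon("SELL", p0.vertices + np.array([0.8, 0.0]))
        ps = cg.PolygonSet(axes=_embedding_axes(), polygons=[p0, p1])
        res = cg.select_on_embedding(ds, "umap", ps, "neg")
        both = res.membership[:, 0] & res.membership[:, 1]
        composite = np.array([lab == "CCR7,SELL" for lab in res.labels])
        assert both.sum() > 0
        np.testing.assert_array_equal(composite, both)
        reduced = ds.subset(~composite)
        assert reduced.n_cells == ds.n_cells - both.sum()
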