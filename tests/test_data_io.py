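"""Prior-network ingestion, expression IO, and co-expression augmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import celldriver as cd
from celldriver.data_io import (GeneGraph, LineageExpression, read_grn_edges,
                                spearman_matrix, write_grn)


def _write_edges(path, rows, header="source\ttarget\tdirected"):
    path.write_text(header + "\n" + "\n".join("\t".join(map(str, r)) for r in rows) + "\n")


class TestPriorEdgelist:
    def test_undirected_rows_expand_to_both_directions(self, tmp_path):
        p = tmp_path / "e.tsv"
        _write_edges(p, [("A", "B", 1), ("B", "C", 0)])
        g = cd.read_prior_edgelist(p)
        assert g.edge_set() == {("A", "B"), ("B", "C"), ("C", "B")}

    def test_duplicates_collapse(self, tmp_path):
        p = tmp_path / "e.tsv"
        _write_edges(p, [("A", "B", 1), ("A", "B", 1)])
        assert cd.read_prior_edgelist(p).n_edges == 1

    def test_self_loop_rows_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "e.tsv"
        _write_edges(p, [("A", "A", 1), ("A", "B", 1)])
        with caplog.at_level("WARNING", logger="celldriver"):
            g = cd.read_prior_edgelist(p)
        assert g.edge_set() == {("A", "B")}
        assert any("self-loop" in r.message for r in caplog.records)

    def test_empty_file_is_hard_error(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            cd.read_prior_edgelist(p)

    def test_unparsable_row_names_line_number(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("source\ttarget\tdirected\nA\tB\t1\n\tC\t1\n")
        with pytest.raises(ValueError, match="line 3"):
            cd.read_prior_edgelist(p)

    def test_row_order_does_not_matter(self, tmp_path):
        rows = [("A", "B", 1), ("B", "C", 0), ("C", "D", 1)]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        _write_edges(p1, rows)
        _write_edges(p2, rows[::-1])
        assert cd.read_prior_edgelist(p1).edge_set() == cd.read_prior_edgelist(p2).edge_set()


class TestRestrictToExpressed:
    def _graph(self, genes, pairs):
        idx = {g: i for i, g in enumerate(genes)}
        return GeneGraph(nodes=genes, edges=np.array(
            [(idx[s], idx[t]) for s, t in pairs]))

    def _expr(self, genes, m=5, seed=0):
        rng = np.random.default_rng(seed)
        return LineageExpression(cell_ids=[f"c{i}" for i in range(m)],
                                 gene_symbols=genes,
                                 values=rng.random((m, len(genes))))

    def test_intersection_and_node_order(self):
        g = self._graph(["A", "B", "C"], [("A", "B"), ("B", "C"), ("C", "B")])
        sub = cd.restrict_to_expressed(g, self._expr(["C", "B", "D"]))
        assert sub.nodes == ["C", "B"]  # follows expression order
        assert sub.edge_set() == {("B", "C"), ("C", "B")}

    def test_identical_gene_sets_preserve_edges(self):
        g = self._graph(["A", "B"], [("A", "B")])
        sub = cd.restrict_to_expressed(g, self._expr(["B", "A"]))
        assert sub.edge_set() == g.edge_set()

    def test_empty_intersection_is_error(self):
        g = self._graph(["A", "B"], [("A", "B")])
        with pytest.raises(ValueError, match="overlap"):
            cd.restrict_to_expressed(g, self._expr(["X", "Y"]))


class TestCoexpression:
    def _expr(self, values, genes):
        values = np.asarray(values, dtype=float)
        return LineageExpression(cell_ids=[f"c{i}" for i in range(len(values))],
                                 gene_symbols=genes, values=values)

    def test_spearman_matches_rank_formula(self):
        rng = np.random.default_rng(1)
        x = rng.random((30, 4))
        rho = spearman_matrix(x)
        # direct rank-correlation for one pair
        ra, rb = rankdata(x[:, 0]), rankdata(x[:, 2])
        expect = np.corrcoef(ra, rb)[0, 1]
        assert rho[0, 2] == pytest.approx(expect, abs=1e-12)

    def test_low_correlation_leaves_graph_unchanged(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(6)]
        expr = self._expr(rng.random((50, 6)), genes)
        g = GeneGraph(nodes=genes, edges=np.array([(0, 1)]))
        out = cd.augment_with_coexpression(g, expr, top_frac=0.5, rho_min=0.95)
        assert out.edge_set() == g.edge_set()

    def test_perfect_pair_added_bidirectionally(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(8)]
        vals = rng.random((40, 8))
        vals[:, 5] = 2 * vals[:, 2] + 1  # rho = 1 between g2 and g5
        expr = self._expr(vals, genes)
        g = GeneGraph(nodes=genes, edges=np.array([(0, 1)]))
        out = cd.augment_with_coexpression(g, expr, top_frac=1 / 28, rho_min=0.6)
        assert ("g2", "g5") in out.edge_set() and ("g5", "g2") in out.edge_set()
        origins = dict(zip(map(tuple, out.edges), out.edge_origin))
        idx = {g_: i for i, g_ in enumerate(out.nodes)}
        assert origins[(idx["g2"], idx["g5"])] == "coexpression"

    def test_existing_prior_edge_keeps_origin_and_count(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(6)]
        vals = rng.random((40, 6))
        vals[:, 1] = vals[:, 0] * 3  # rho=1 between g0 and g1
        expr = self._expr(vals, genes)
        g = GeneGraph(nodes=genes,
                      edges=np.array([(0, 1), (1, 0)]))
        out = cd.augment_with_coexpression(g, expr, top_frac=1 / 15, rho_min=0.6)
        assert out.n_edges == 2
        assert set(out.edge_origin) == {"prior"}

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(10)]
        vals = rng.random((60, 10))
        vals[:, 3] = vals[:, 7] + 0.01 * rng.random(60)
        expr = self._expr(vals, genes)
        g = GeneGraph(nodes=genes, edges=np.array([(0, 1)]))
        once = cd.augment_with_coexpression(g, expr)
        twice = cd.augment_with_coexpression(once, expr)
        assert once.edge_set() == twice.edge_set()

    def test_constant_gene_excluded_with_warning(self, caplog):
        genes = ["a", "b", "c"]
        vals = np.column_stack([np.ones(20), np.arange(20.0),
                                np.arange(20.0) * 2])
        expr = self._expr(vals, genes)
        g = GeneGraph(nodes=genes, edges=np.array([(0, 1)]))
        with caplog.at_level("WARNING", logger="celldriver"):
            out = cd.augment_with_coexpression(g, expr, top_frac=1.0, rho_min=0.6)
        assert not any(("a" in {out.nodes[i], out.nodes[j]})
                       and o == "coexpression"
                       for (i, j), o in zip(out.edges, out.edge_origin))
        assert any("constant" in r.message for r in caplog.records)


class TestExpressionIO:
    def _expr(self):
        rng = np.random.default_rng(7)
        return LineageExpression(cell_ids=[f"c{i}" for i in range(5)],
                                 gene_symbols=[f"g{i}" for i in range(4)],
                                 values=rng.random((5, 4)).round(6))

    @pytest.mark.parametrize("fmt", ["csv", "tsv", "mtx", "h5ad"])
    def test_round_trip_preserves_content(self, tmp_path, fmt):
        expr = self._expr()
        if fmt in ("csv", "tsv"):
            path = tmp_path / f"x.{fmt}"
            cd.data_io.write_expression(expr, path)
        elif fmt == "mtx":
            from scipy.io import mmwrite
            from scipy.sparse import csr_matrix
            path = tmp_path / "x.mtx"
            mmwrite(str(path), csr_matrix(expr.values))
            (tmp_path / "genes.txt").write_text("\n".join(expr.gene_symbols))
            (tmp_path / "cells.txt").write_text("\n".join(expr.cell_ids))
        else:
            import anndata
            path = tmp_path / "x.h5ad"
            ad = anndata.AnnData(X=expr.values)
            ad.obs_names = expr.cell_ids
            ad.var_names = expr.gene_symbols
            ad.write_h5ad(path)
        back = cd.read_expression(path)
        assert back.cell_ids == expr.cell_ids
        assert back.gene_symbols == expr.gene_symbols
        np.testing.assert_allclose(back.values, expr.values, atol=1e-12)

    def test_mtx_with_no_explicit_entries_is_all_zero(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        mmwrite(str(tmp_path / "x.mtx"), csr_matrix((3, 2)))
        (tmp_path / "genes.txt").write_text("g0\ng1")
        (tmp_path / "cells.txt").write_text("c0\nc1\nc2")
        back = cd.read_expression(tmp_path / "x.mtx")
        assert back.values.sum() == 0

    def test_mtx_shape_mismatch_is_error(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        mmwrite(str(tmp_path / "x.mtx"), csr_matrix((3, 2)))
        (tmp_path / "genes.txt").write_text("g0\ng1\ng2")
        (tmp_path / "cells.txt").write_text("c0\nc1\nc2")
        with pytest.raises(ValueError, match="shape"):
            cd.read_expression(tmp_path / "x.mtx")

    def test_grn_tsv_round_trip(self, tmp_path):
        grn = cd.grn.LineageGRN(nodes=["a", "b", "c"],
                                edges=np.array([(0, 1), (2, 1)]),
                                weights=np.array([1.5, 0.5]),
                                origin=["prior", "coexpression"], k_d=8)
        write_grn(grn, tmp_path / "g.tsv")
        df = read_grn_edges(tmp_path / "g.tsv")
        assert set(zip(df["source"], df["target"])) == {("a", "b"), ("c", "b")}
        assert set(df["origin"]) == {"prior", "coexpression"}
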