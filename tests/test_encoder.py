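"""Attention scoring, normalization, corruption, infomax loss, training."""

import math

import numpy as np
import pytest

import celldriver as cd
from celldriver.data_io import GeneGraph
from celldriver.encoder import (GRNAttentionEncoder, attention_score,
                                corrupt_features, de_scalar,
                                dgi_loss_reference, normalize_attention)
from celldriver._autograd import Tensor


class TestDeScalar:
    def test_zero_parameters_give_half(self):
        np.testing.assert_allclose(de_scalar(np.array([0.0, 1.0, 5.0]), 0, 0), 0.5)

    def test_zero_magnitude_gives_half(self):
        assert de_scalar(np.array([0.0]), 1.0, 0.0)[0] == 0.5

    def test_monotone_in_magnitude_for_positive_gain(self):
        d = de_scalar(np.array([0.1, 0.5, 2.0]), 1.3, -0.2)
        assert d[0] < d[1] < d[2]
        assert np.all((d > 0) & (d < 1))


class TestAttentionScore:
    W = np.eye(3)

    def test_orthogonal_projections_score_zero(self):
        assert attention_score([1, 0, 0], [0, 1, 0], self.W, self.W, 0.9) == 0.0

    def test_identical_projections_score_dj(self):
        assert attention_score([1, 2, 3], [1, 2, 3], self.W, self.W, 1.0) \
            == pytest.approx(1.0)

    def test_antiparallel_projections_keep_magnitude(self):
        v = np.array([1.0, -2.0, 0.5])
        assert attention_score(v, -v, self.W, self.W, 0.8) == pytest.approx(0.8)

    def test_zero_norm_projection_scores_zero(self):
        assert attention_score([0, 0, 0], [1, 1, 1], self.W, self.W, 0.7) == 0.0

    def test_scale_invariance_of_cosine(self):
        rng = np.random.default_rng(5)
        hi, hj = rng.normal(size=3), rng.normal(size=3)
        wa, wb = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        s1 = attention_score(hi, hj, wa, wb, 0.6)
        s2 = attention_score(hi * 37.0, hj, wa, wb, 0.6)
        assert s1 == pytest.approx(s2, rel=1e-12)


class TestNormalizeAttention:
    def test_equal_scores_are_uniform(self):
        a = normalize_attention(np.full(5, 0.3), tau=0.25)
        np.testing.assert_allclose(a, 0.2)

    def test_two_scores_match_closed_form(self):
        a = normalize_attention(np.array([1.0, 0.0]), tau=0.25)
        e4 = math.exp(4.0)
        np.testing.assert_allclose(a, [e4 / (e4 + 1), 1 / (e4 + 1)], atol=1e-12)

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = normalize_attention(rng.normal(size=rng.integers(1, 9)), 0.25)
            assert a.sum() == pytest.approx(1.0)
            assert np.all(a >= 0)


class TestCorruptFeatures:
    def test_row_multiset_preserved(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=(10, 4))
        hc = corrupt_features(h, seed=3)
        np.testing.assert_allclose(np.sort(h, axis=0), np.sort(hc, axis=0))

    def test_same_seed_same_permutation(self):
        h = np.arange(20.0).reshape(10, 2)
        np.testing.assert_array_equal(corrupt_features(h, 5),
                                      corrupt_features(h, 5))


class TestDgiLoss:
    def test_uniform_discrimination_is_ln2(self):
        n, f = 8, 4
        h = np.zeros((n, f))   # logits all zero -> sigmoid 0.5 everywhere
        loss = dgi_loss_reference(h, h, np.ones(f), np.eye(f))
        assert loss == pytest.approx(math.log(2.0))

    def test_perfect_discrimination_drives_loss_to_zero(self):
        h_real = np.full((4, 2), 50.0)
        h_corr = -h_real
        loss = dgi_loss_reference(h_real, h_corr, np.ones(2) / 2, np.eye(2))
        assert 0 <= loss < 1e-8

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            loss = dgi_loss_reference(rng.normal(size=(6, 3)),
                                      rng.normal(size=(6, 3)),
                                      rng.random(3), rng.normal(size=(3, 3)))
            assert loss >= 0


class TestTrainedEncoder:
    def test_attention_rows_sum_to_one(self, tiny_trained):
        assert tiny_trained["attention"].check_normalized() < 1e-6

    def test_training_reduces_loss(self, tiny):
        graph = cd.restrict_to_expressed(tiny.prior, tiny.expression)
        expr = cd.bin_pseudotime(tiny.expression, 4)
        de = cd.compute_logfc(expr)
        cfg = cd.EncoderConfig(epochs=60, seed=0, resample_corruption=False)
        first, last = _loss_trajectory(graph, expr, de, cfg)
        assert np.isfinite(last)
        assert last < first

    def test_same_seed_reproduces_attention_bitwise(self, tiny):
        graph = cd.restrict_to_expressed(tiny.prior, tiny.expression)
        expr = cd.bin_pseudotime(tiny.expression, 4)
        de = cd.compute_logfc(expr)
        cfg = cd.EncoderConfig(epochs=15, seed=21)
        _, att1, _ = cd.train_encoder(graph, expr, de, cfg)
        _, att2, _ = cd.train_encoder(graph, expr, de, cfg)
        for key in att1.alpha:
            assert np.abs(att1.alpha[key] - att2.alpha[key]).max() < 1e-6

    def test_embedding_width_is_two_directions_times_heads(self, tiny_trained):
        emb = tiny_trained["embeddings"]
        cfg_out = 64  # 2 directions x 4 heads x 8 per head
        assert emb.values.shape == (len(emb.genes), cfg_out)
        assert np.all(np.isfinite(emb.values))

    def test_isolated_node_attends_only_to_itself(self):
        genes = ["a", "b", "c"]
        graph = GeneGraph(nodes=genes, edges=np.array([(0, 1)]))
        rng = np.random.default_rng(0)
        expr = cd.data_io.LineageExpression(
            cell_ids=[f"c{i}" for i in range(30)], gene_symbols=genes,
            values=rng.random((30, 3)), pseudotime=np.linspace(0, 1, 30))
        expr = cd.bin_pseudotime(expr, 2)
        de = cd.compute_logfc(expr)
        cfg = cd.EncoderConfig(epochs=2, seed=0)
        _, att, _ = cd.train_encoder(graph, expr, de, cfg)
        for (layer, direction), a in att.alpha.items():
            cen = att.center[direction]
            # gene c (index 2) has no neighbors in either direction
            self_rows = np.flatnonzero(cen == 2)
            np.testing.assert_allclose(a[self_rows], 1.0, atol=1e-12)

    def test_node_relabeling_permutes_embeddings(self, tiny):
        graph = cd.restrict_to_expressed(tiny.prior, tiny.expression)
        expr = cd.bin_pseudotime(tiny.expression, 4)
        de = cd.compute_logfc(expr)
        from celldriver.encoder import node_features
        cfg = cd.EncoderConfig(epochs=1, seed=5)
        x = node_features(expr, graph)
        l = np.array([de.l[de.gene_symbols.index(g)] for g in graph.nodes])
        model = GRNAttentionEncoder(graph, expr.n_cells, cfg)
        emb, _ = model.forward(Tensor(x), model.de_encoding(l))

        perm = np.random.default_rng(4).permutation(graph.n_nodes)
        inv = np.argsort(perm)
        pg = GeneGraph(nodes=[graph.nodes[i] for i in perm],
                       edges=np.array([(inv[i], inv[j]) for i, j in graph.edges]))
        model_p = GRNAttentionEncoder(pg, expr.n_cells, cfg)  # same init (same dims/seed)
        emb_p, _ = model_p.forward(Tensor(x[perm]), model_p.de_encoding(l[perm]))
        np.testing.assert_allclose(emb_p.data, emb.data[perm], atol=1e-8)

    def test_de_ablation_gives_uniform_scaling(self, tiny):
        graph = cd.restrict_to_expressed(tiny.prior, tiny.expression)
        expr = cd.bin_pseudotime(tiny.expression, 4)
        de = cd.compute_logfc(expr)
        cfg = cd.EncoderConfig(epochs=2, seed=0, use_de_encoding=False)
        _, _, enc = cd.train_encoder(graph, expr, de, cfg)
        np.testing.assert_allclose(enc.D, 0.5)


def _loss_trajectory(graph, expr, de, cfg):
    """Replicate the training loop, returning (first, last) objective values
    on the same fixed corruption."""
    from celldriver._autograd import Adam, backward
    from celldriver.encoder import node_features
    model = GRNAttentionEncoder(graph, expr.n_cells, cfg)
    x = node_features(expr, graph)
    l = np.array([de.l[de.gene_symbols.index(g)] for g in graph.nodes])
    opt = Adam(model.params(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    perm = model.rng.permutation(model.n)
    first = last = None
    for _ in range(cfg.epochs):
        D = model.de_encoding(l)
        e_r, _ = model.forward(Tensor(x), D)
        e_c, _ = model.forward(Tensor(x[perm]), D)
        loss = model.dgi_loss(e_r, e_c)
        last = float(loss.data)
        if first is None:
            first = last
        opt.zero_grad()
        backward(loss)
        opt.step()
    return first, last
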