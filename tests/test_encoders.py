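import numpy as np
import pytest

from wmagt import EncoderConfig, knn_sparsify, normalize_adjacency
from wmagt._autodiff import Tensor
from wmagt.encoders import (attention_weights, encode_nodes, gcn_layer,
                            init_encoder_params, mixed_aggregate,
                            pairwise_pool, transformer_layer,
                            weighted_projection)


def brute_force_pairwise_pool(xw, A):
    """Independent oracle: explicit sum over ordered distinct neighbour pairs."""
    n, d = xw.shape
    Z = np.zeros((n, d))
    for i in range(n):
        for c in range(d):
            total = 0.0
            for j in range(n):
                for k in range(n):
                    if j != k:
                        total += A[i, j] * A[i, k] * xw[j, c] * xw[k, c]
            Z[i, c] = total
    return Z


class TestPairwisePool:
    def test_single_neighbour_gives_zero(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        xw = np.array([[2.0], [3.0]])
        out = pairwise_pool(Tensor(xw), A).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_two_neighbour_hand_case(self):
        # node 0 has binary-weight neighbours with features 1 and 2:
        # (1+2)^2 - (1+4) = 4 = 2 * (1*2)
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        xw = np.array([[0.0], [1.0], [2.0]])
        out = pairwise_pool(Tensor(xw), A).data
        assert out[0, 0] == pytest.approx(4.0)

    def test_empty_neighbourhood_zero_row(self):
        A = np.zeros((3, 3))
        xw = np.ones((3, 2))
        np.testing.assert_allclose(pairwise_pool(Tensor(xw), A).data, 0.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 12))
            d = int(rng.integers(1, 4))
            A = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
            xw = rng.standard_normal((n, d))
            got = pairwise_pool(Tensor(xw), A).data
            want = brute_force_pairwise_pool(xw, A)
            np.testing.assert_allclose(got, want, atol=1e-8)


class TestGcnLayer:
    def test_isolated_nodes_identity_weights(self):
        out = gcn_layer(Tensor(np.eye(2)), np.eye(2), Tensor(np.eye(2)))
        np.testing.assert_allclose(out.data, np.eye(2))

    def test_relu_clamps_negative(self):
        out = gcn_layer(Tensor(-np.ones((2, 2))), np.eye(2), Tensor(np.eye(2)))
        np.testing.assert_allclose(out.data, 0.0)

    def test_single_edge_hand_case(self):
        norm = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        out = gcn_layer(Tensor([[1.0], [3.0]]), norm, Tensor([[1.0]]))
        np.testing.assert_allclose(out.data, [[2.0], [2.0]])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            gcn_layer(Tensor(np.ones((2, 3))), np.eye(2), Tensor(np.ones((2, 1))))


class TestMixedAggregate:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.A = rng.random((5, 5))
        self.A = (self.A + self.A.T) / 2
        self.norm = normalize_adjacency(self.A)
        self.X = rng.standard_normal((5, 3))
        self.W = rng.standard_normal((3, 3))

    def test_beta_zero_is_pure_gcn_branch(self):
        out = mixed_aggregate(Tensor(self.X), self.A, self.norm,
                              Tensor(self.W), 1.0, 0.0).data
        gcn = np.maximum(self.norm @ self.X @ self.W, 0.0)
        np.testing.assert_allclose(out, gcn, atol=1e-12)

    def test_alpha_zero_single_neighbour_graph_is_zero(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = mixed_aggregate(Tensor(np.ones((2, 2))), A,
                              normalize_adjacency(A), Tensor(np.eye(2)),
                              0.0, 1.0).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_unit_weights_sum_of_branches(self):
        both = mixed_aggregate(Tensor(self.X), self.A, self.norm,
                               Tensor(self.W), 1.0, 1.0).data
        gcn_only = mixed_aggregate(Tensor(self.X), self.A, self.norm,
                                   Tensor(self.W), 1.0, 0.0).data
        pool_only = mixed_aggregate(Tensor(self.X), self.A, self.norm,
                                    Tensor(self.W), 0.0, 1.0).data
        np.testing.assert_allclose(both, gcn_only + pool_only, atol=1e-12)


class TestAttention:
    def test_uniform_scores_uniform_weights(self):
        emb = np.ones((4, 2))  # identical embeddings -> equal scores
        mask = np.ones((4, 4), dtype=bool)
        attn = attention_weights(Tensor(emb), Tensor(np.eye(2)), mask).data
        np.testing.assert_allclose(attn, 0.25)

    def test_singleton_mask_self_weight_one(self):
        emb = np.random.default_rng(0).standard_normal((3, 2))
        mask = np.eye(3, dtype=bool)
        attn = attention_weights(Tensor(emb), Tensor(np.eye(2)), mask).data
        np.testing.assert_allclose(attn, np.eye(3), atol=1e-12)

    def test_closed_form_two_target_softmax(self):
        # scores 0 and ln 2 -> weights 1/3 and 2/3
        from wmagt._autodiff import masked_softmax
        scores = Tensor(np.array([[0.0, np.log(2.0)]]))
        out = masked_softmax(scores, np.ones((1, 2), dtype=bool)).data
        np.testing.assert_allclose(out, [[1 / 3, 2 / 3]], atol=1e-12)

    def test_rows_are_probability_vectors_on_random_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            emb = rng.standard_normal((n, 4))
            mask = rng.random((n, n)) < 0.4
            np.fill_diagonal(mask, True)
            attn = attention_weights(Tensor(emb), Tensor(np.eye(4)), mask).data
            np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-10)
            assert (attn >= 0).all()
            assert np.all(attn[~mask] == 0)


class TestTransformerLayer:
    def _graph_and_params(self, n=6, seed=0, **cfg_kw):
        rng = np.random.default_rng(seed)
        cfg = EncoderConfig(embed_dim=8, num_heads=2, **cfg_kw)
        params = init_encoder_params(rng, n, cfg)
        emb = rng.standard_normal((n, 8))
        mask = rng.random((n, n)) < 0.5
        np.fill_diagonal(mask, True)
        mask |= mask.T
        return emb, params, mask, cfg

    def test_permutation_equivariance(self):
        emb, params, mask, cfg = self._graph_and_params()
        out = transformer_layer(Tensor(emb), params, mask, cfg).data
        perm = np.random.default_rng(3).permutation(len(emb))
        out_p = transformer_layer(Tensor(emb[perm]), params,
                                  mask[np.ix_(perm, perm)], cfg).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)

    def test_zero_feedforward_leaves_attention_block(self):
        emb, params, mask, cfg = self._graph_and_params()
        for key in ("ff_w1", "ff_b1", "ff_w2", "ff_b2"):
            params[key].data[:] = 0.0
        out = transformer_layer(Tensor(emb), params, mask, cfg).data
        # recompute the attention block alone
        from wmagt._autodiff import concat, masked_softmax
        heads = []
        x = Tensor(emb)
        for w_h in params["heads"]:
            proj = x @ w_h
            attn = masked_softmax((proj @ proj.T) * (1 / np.sqrt(proj.shape[1])),
                                  mask)
            heads.append(attn @ proj)
        attn_out = (concat(heads, axis=1) @ params["w_out"] + params["b_out"]).data
        np.testing.assert_allclose(out, attn_out, atol=1e-12)

    def test_single_head_concat_degenerate(self):
        emb, params, mask, cfg = self._graph_and_params()
        cfg1 = EncoderConfig(embed_dim=8, num_heads=1)
        rng = np.random.default_rng(9)
        p1 = init_encoder_params(rng, len(emb), cfg1)
        out = transformer_layer(Tensor(emb), p1, mask, cfg1).data
        assert out.shape == emb.shape

    def test_sequential_block_differs(self):
        emb, params, mask, cfg = self._graph_and_params()
        seq_cfg = EncoderConfig(embed_dim=8, num_heads=2,
                                transformer_block="sequential")
        par = transformer_layer(Tensor(emb), params, mask, cfg).data
        seq = transformer_layer(Tensor(emb), params, mask, seq_cfg).data
        assert not np.allclose(par, seq)


class TestWeightedProjection:
    def test_identity_norm_zero_bias(self, rng):
        X = rng.standard_normal((4, 3))
        W = rng.standard_normal((3, 2))
        out = weighted_projection(Tensor(X), Tensor(W)).data
        np.testing.assert_allclose(out, X @ W, atol=1e-12)

    def test_zero_weight_bias_rows(self):
        out = weighted_projection(Tensor(np.ones((3, 2))),
                                  Tensor(np.zeros((2, 2))),
                                  bias=Tensor(np.array([1.0, 2.0]))).data
        np.testing.assert_allclose(out, np.tile([1.0, 2.0], (3, 1)))

    def test_gcn_propagation_without_activation(self, rng):
        A = (rng.random((5, 5)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        norm = normalize_adjacency(A)
        X = rng.standard_normal((5, 3))
        W = rng.standard_normal((3, 3))
        out = weighted_projection(Tensor(X), Tensor(W), norm_matrix=norm).data
        np.testing.assert_allclose(out, norm @ X @ W, atol=1e-12)


class TestEncodeNodes:
    def _setup(self, lam, seed=0):
        rng = np.random.default_rng(seed)
        S = rng.random((7, 7))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        graph = knn_sparsify(S, [f"n{i}" for i in range(7)], k=3)
        W = graph.sparse_adjacency.copy()
        np.fill_diagonal(W, 0.0)
        norm = normalize_adjacency(W)
        cfg = EncoderConfig(embed_dim=8, num_heads=2, lambda_mix=lam)
        params = init_encoder_params(np.random.default_rng(1), 7, cfg)
        return graph, norm, params, cfg

    def test_lambda_interpolates_between_branches(self):
        graph, norm, params, _ = self._setup(0.5)
        outs = {}
        for lam in (0.0, 0.25, 0.8, 1.0):
            cfg = EncoderConfig(embed_dim=8, num_heads=2, lambda_mix=lam)
            outs[lam] = encode_nodes(graph, norm, params, cfg).data
        for lam in (0.25, 0.8):
            expect = lam * outs[1.0] + (1 - lam) * outs[0.0]
            np.testing.assert_allclose(outs[lam], expect, atol=1e-10)

    def test_eval_mode_deterministic(self):
        graph, norm, params, cfg = self._setup(0.8)
        a = encode_nodes(graph, norm, params, cfg).data
        b = encode_nodes(graph, norm, params, cfg).data
        np.testing.assert_array_equal(a, b)

    def test_output_finite_and_correct_shape(self):
        graph, norm, params, cfg = self._setup(0.8)
        out = encode_nodes(graph, norm, params, cfg).data
        assert out.shape == (7, 8)
        assert np.isfinite(out).all()

    def test_dropout_requires_rng(self):
        graph, norm, params, cfg = self._setup(0.8)
        with pytest.raises(ValueError, match="rng"):
            encode_nodes(graph, norm, params, cfg, training=True)


def test_encoder_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(embed_dim=10, num_heads=4)
    with pytest.raises(ValueError):
        EncoderConfig(lambda_mix=1.5)
    with pytest.raises(ValueError):
        EncoderConfig(dropout=1.0)
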