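"""Attention, aggregation and forward-pass semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import reference_forward
from lagat.model import (
    ModelConfig,
    ModelParams,
    aggregate,
    attention_weights,
    init_params,
    lagat_forward,
    masked_softmax,
    score_binary,
    score_multiclass,
)
from lagat.autodiff import Tensor
from lagat.sampling import sample_subgraph
from lagat.synthetic import SyntheticSpec, generate_kg


class TestAttentionWeights:
    def test_orthogonal_query_gives_uniform_weights(self):
        q = np.array([1.0, 0.0])
        nbrs = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, -1.0], [0.0, 0.5]])
        w = attention_weights(q, nbrs, mode="lagat")
        np.testing.assert_allclose(w, [0.25] * 4)

    def test_two_neighbor_closed_form(self):
        # logits (1, 0) -> softmax = (e/(1+e), 1/(1+e))
        q = np.array([1.0, 0.0])
        nbrs = np.array([[1.0, 0.0], [0.0, 1.0]])
        w = attention_weights(q, nbrs, mode="lagat")
        e = np.e
        np.testing.assert_allclose(w, [e / (1 + e), 1 / (1 + e)], atol=1e-12)
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=1e-4)

    def test_gat_const_ignores_query(self):
        rng = np.random.default_rng(0)
        w = attention_weights(rng.normal(size=3), rng.normal(size=(4, 3)), "gat_const")
        np.testing.assert_allclose(w, [0.25] * 4)

    def test_masked_entries_get_zero_weight(self):
        q = np.ones(2)
        nbrs = np.ones((4, 2))
        mask = np.array([True, True, False, False])
        w = attention_weights(q, nbrs, "lagat", mask=mask)
        np.testing.assert_allclose(w, [0.5, 0.5, 0.0, 0.0])

    def test_all_masked_gives_zero_vector(self):
        w = attention_weights(np.ones(2), np.ones((3, 2)), "lagat",
                              mask=np.zeros(3, dtype=bool))
        np.testing.assert_array_equal(w, np.zeros(3))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            attention_weights(np.ones(3), np.ones((4, 2)))

    def test_raw_mode_returns_inner_products(self):
        q = np.array([2.0, 0.0])
        nbrs = np.array([[1.0, 0.0], [3.0, 1.0]])
        w = attention_weights(q, nbrs, "lagat", raw=True)
        np.testing.assert_allclose(w, [2.0, 6.0])


class TestMaskedSoftmax:
    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 2**32 - 1))
    def test_normalization_and_shift_invariance(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 9))
        logits = rng.normal(scale=3, size=k)
        mask = rng.random(k) < 0.8
        w = masked_softmax(logits, mask)
        if mask.any():
            assert abs(w.sum() - 1.0) < 1e-6
        assert np.all(w >= 0) and np.all(w[~mask] == 0)
        shifted = masked_softmax(logits + rng.normal() * 10, mask)
        np.testing.assert_allclose(w, shifted, atol=1e-9)


class TestAggregate:
    def test_neighbor_identity_weight_applies_leaky_relu(self, toy_kg):
        cfg = ModelConfig(num_entities=toy_kg.num_entities, dim=2,
                          neighbor_samples=2)
        params = init_params(cfg, np.random.default_rng(0))
        params.tensors["W_0"] = Tensor(np.eye(2), requires_grad=True)
        params.tensors["b_0"] = Tensor(np.zeros(2), requires_grad=True)
        out = aggregate(np.zeros(2), np.array([2.0, -2.0]), params, hop=0)
        np.testing.assert_allclose(out, [2.0, -0.2])

    def test_zero_neighbor_sum_gives_zero(self, toy_kg):
        cfg = ModelConfig(num_entities=toy_kg.num_entities, dim=2,
                          neighbor_samples=2)
        params = init_params(cfg, np.random.default_rng(0))
        params.tensors["b_0"] = Tensor(np.zeros(2), requires_grad=True)
        out = aggregate(np.ones(2), np.zeros(2), params, hop=0, aggregator="neighbor")
        np.testing.assert_allclose(out, np.zeros(2))

    def test_concat_identity_blocks_sum_inputs(self, toy_kg):
        cfg = ModelConfig(num_entities=toy_kg.num_entities, dim=2,
                          neighbor_samples=2, aggregator="concat")
        params = init_params(cfg, np.random.default_rng(0))
        params.tensors["W_0"] = Tensor(np.vstack([np.eye(2), np.eye(2)]),
                                       requires_grad=True)
        params.tensors["b_0"] = Tensor(np.zeros(2), requires_grad=True)
        out = aggregate(np.array([1.0, 0.0]), np.array([0.0, 1.0]), params, hop=0)
        np.testing.assert_allclose(out, [1.0, 1.0])

    def test_unknown_aggregator_rejected(self, toy_kg):
        cfg = ModelConfig(num_entities=toy_kg.num_entities, dim=2,
                          neighbor_samples=2)
        params = init_params(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="aggregator"):
            aggregate(np.zeros(2), np.zeros(2), params, aggregator="mean")


class TestScores:
    def test_orthogonal_drugs_score_half(self):
        assert score_binary(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.5

    def test_unit_vector_closed_form(self):
        v = np.array([1.0, 0.0])
        assert abs(score_binary(v, v) - 1 / (1 + np.exp(-1))) < 1e-12
        assert abs(score_binary(v, v) - 0.7311) < 1e-4

    def test_antiparallel_closed_form(self):
        v = np.array([1.0, 1.0, 1.0])
        assert abs(score_binary(v, -v) - 1 / (1 + np.exp(3))) < 1e-12
        assert abs(score_binary(v, -v) - 0.0474) < 1e-4

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            score_binary(np.ones(3), np.ones(4))

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_binary_score_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 8))
        assert score_binary(a, b) == score_binary(b, a)

    def test_multiclass_zero_head_is_uniform(self, toy_kg):
        cfg = ModelConfig(num_entities=toy_kg.num_entities, dim=2, hop=1,
                          neighbor_samples=2, num_classes=86)
        params = init_params(cfg, np.random.default_rng(0))
        params.tensors["head_W2"] = Tensor(
            np.zeros_like(params["head_W2"].data), requires_grad=True
        )
        out = score_multiclass(np.ones(cfg.out_dim), np.ones(cfg.out_dim), params)
        np.testing.assert_allclose(out, np.full(86, 1 / 86), atol=1e-12)
        assert abs(out.sum() - 1.0) < 1e-6

    def test_multiclass_hand_computed_softmax(self, toy_kg):
        cfg = ModelConfig(num_entities=toy_kg.num_entities, dim=1, hop=1,
                          neighbor_samples=2, layer_agg=False, num_classes=3)
        params = init_params(cfg, np.random.default_rng(0))
        # passthrough hidden layer (identity on positives), hand-set logits map
        params.tensors["head_W1"] = Tensor(np.eye(2), requires_grad=True)
        params.tensors["head_b1"] = Tensor(np.zeros(2), requires_grad=True)
        W2 = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
        params.tensors["head_W2"] = Tensor(W2, requires_grad=True)
        params.tensors["head_b2"] = Tensor(np.zeros(3), requires_grad=True)
        out = score_multiclass(np.array([1.0]), np.array([2.0]), params)
        logits = np.array([1.0, 2.0, -1.0])
        want = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(out, want, atol=1e-12)

    def test_binary_config_has_no_head(self, toy_kg):
        cfg = ModelConfig(num_entities=toy_kg.num_entities, dim=2,
                          neighbor_samples=2)
        params = init_params(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="head"):
            score_multiclass(np.ones(4), np.ones(4), params)


class TestForward:
    def _setup(self, kg, **cfg_kw):
        defaults = dict(num_entities=kg.num_entities, dim=4, hop=1,
                        neighbor_samples=3)
        defaults.update(cfg_kw)
        cfg = ModelConfig(**defaults)
        params = init_params(cfg, np.random.default_rng(11))
        return cfg, params

    @pytest.mark.parametrize("hop,dim", [(1, 8), (1, 64), (2, 8), (2, 64)])
    def test_layer_aggregation_dimension_law(self, toy_kg, hop, dim):
        for layer_agg, want in [(True, (hop + 1) * dim), (False, dim)]:
            cfg, params = self._setup(toy_kg, hop=hop, dim=dim,
                                      layer_agg=layer_agg)
            rng = np.random.default_rng(5)
            sub_u = sample_subgraph(toy_kg, 0, hop, 3, rng)
            sub_v = sample_subgraph(toy_kg, 1, hop, 3, rng)
            out = lagat_forward((0, 1), sub_u, sub_v, params, toy_kg.sentinel)
            assert out.z_u.shape == (want,)
            assert out.z_v.shape == (want,)

    def test_const_attention_with_identity_weight_is_leaky_mean(self, toy_kg):
        cfg, params = self._setup(toy_kg, dim=4, attention="gat_const",
                                  layer_agg=False)
        params.tensors["W_0"] = Tensor(np.eye(4), requires_grad=True)
        params.tensors["b_0"] = Tensor(np.zeros(4), requires_grad=True)
        rng = np.random.default_rng(3)
        sub_u = sample_subgraph(toy_kg, 0, 1, 3, rng)
        sub_v = sample_subgraph(toy_kg, 1, 1, 3, rng)
        out = lagat_forward((0, 1), sub_u, sub_v, params, toy_kg.sentinel)
        emb = params["embedding"].data
        mean = emb[sub_u.layers[0][0]].mean(axis=0)
        want = np.where(mean >= 0, mean, 0.1 * mean)
        np.testing.assert_allclose(out.z_u, want, atol=1e-12)

    def test_link_awareness_distinct_queries_distinct_weights(self):
        rng = np.random.default_rng(0)
        nbrs = rng.normal(size=(4, 8))
        w1 = attention_weights(rng.normal(size=8), nbrs, "lagat")
        w2 = attention_weights(rng.normal(size=8), nbrs, "lagat")
        assert not np.allclose(w1, w2)
        c1 = attention_weights(rng.normal(size=8), nbrs, "gat_const")
        c2 = attention_weights(rng.normal(size=8), nbrs, "gat_const")
        np.testing.assert_array_equal(c1, c2)

    def test_neighbor_permutation_leaves_output_unchanged(self, toy_kg):
        cfg, params = self._setup(toy_kg)
        rng = np.random.default_rng(9)
        sub_u = sample_subgraph(toy_kg, 0, 1, 3, rng)
        sub_v = sample_subgraph(toy_kg, 1, 1, 3, rng)
        out1 = lagat_forward((0, 1), sub_u, sub_v, params, toy_kg.sentinel)
        perm = np.random.default_rng(1).permutation(3)
        sub_u.layers[0] = sub_u.layers[0][:, perm]
        out2 = lagat_forward((0, 1), sub_u, sub_v, params, toy_kg.sentinel)
        np.testing.assert_allclose(out1.z_u, out2.z_u, atol=1e-12)
        assert out1.score == pytest.approx(out2.score, abs=1e-12)

    @pytest.mark.parametrize("aggregator", ["neighbor", "concat"])
    @pytest.mark.parametrize("attention", ["lagat", "gat_const"])
    @pytest.mark.parametrize("num_classes", [2, 5])
    def test_forward_matches_double_loop_reference(self, aggregator, attention,
                                                   num_classes):
        kg, _, _ = generate_kg(
            SyntheticSpec(n_drugs=6, n_bridge_entities=2, n_noise_entities=4,
                          edges_per_drug=3, p_bridge=0.5, seed=4)
        )
        cfg = ModelConfig(num_entities=kg.num_entities, dim=4, hop=2,
                          neighbor_samples=3, aggregator=aggregator,
                          attention=attention, num_classes=num_classes)
        params = init_params(cfg, np.random.default_rng(8))
        rng = np.random.default_rng(21)
        sub_u = sample_subgraph(kg, 0, 2, 3, rng)
        sub_v = sample_subgraph(kg, 1, 2, 3, rng)
        got = lagat_forward((0, 1), sub_u, sub_v, params, kg.sentinel)
        z_u, z_v, score = reference_forward((0, 1), sub_u, sub_v, params,
                                            kg.sentinel)
        np.testing.assert_allclose(got.z_u, z_u, atol=1e-6)
        np.testing.assert_allclose(got.z_v, z_v, atol=1e-6)
        np.testing.assert_allclose(got.score, score, atol=1e-6)

    def test_config_sample_mismatch_rejected(self, toy_kg):
        cfg, params = self._setup(toy_kg, neighbor_samples=3)
        rng = np.random.default_rng(0)
        sub_u = sample_subgraph(toy_kg, 0, 1, 5, rng)
        sub_v = sample_subgraph(toy_kg, 1, 1, 5, rng)
        with pytest.raises(ValueError, match="does not match"):
            lagat_forward((0, 1), sub_u, sub_v, params, toy_kg.sentinel)

    def test_attention_records_normalized_and_shaped(self, toy_kg):
        cfg, params = self._setup(toy_kg)
        rng = np.random.default_rng(2)
        sub_u = sample_subgraph(toy_kg, 0, 1, 3, rng)
        sub_v = sample_subgraph(toy_kg, 1, 1, 3, rng)
        out = lagat_forward((0, 1), sub_u, sub_v, params, toy_kg.sentinel,
                            collect_attention=True)
        assert len(out.records) == 2  # one root record per side at H=1
        for rec in out.records:
            assert len(rec.neighbors) == len(rec.weights) == 3
            assert abs(rec.weights.sum() - 1.0) < 1e-6
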