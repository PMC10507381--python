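"""Attention math against brute-force oracles, permutation invariance,
and architecture conformance."""

import numpy as np
import pytest

from histomil.aggregator import (AggregatorConfig, AttentionMILConfig,
                                 AttentionMILModel, MeanPoolModel,
                                 TransformerAggregator,
                                 attention_mil_forward, forward_bag,
                                 load_checkpoint, mean_pool_forward,
                                 multi_head_attention, save_checkpoint,
                                 self_attention)


def naive_self_attention(Q, K, V):
    """Two-loop softmax attention oracle."""
    n = Q.shape[0]
    out = np.zeros((n, V.shape[1]))
    for i in range(n):
        scores = np.array([Q[i] @ K[j] / np.sqrt(Q.shape[1])
                           for j in range(K.shape[0])])
        e = np.exp(scores - scores.max())
        a = e / e.sum()
        out[i] = sum(a[j] * V[j] for j in range(K.shape[0]))
    return out


class TestSelfAttention:
    def test_single_element_returns_value(self, rng):
        Q = rng.normal(size=(1, 4))
        K = rng.normal(size=(1, 4))
        V = rng.normal(size=(1, 3))
        np.testing.assert_allclose(self_attention(Q, K, V), V)

    def test_zero_scores_average_values(self, rng):
        V = rng.normal(size=(5, 3))
        Z = np.zeros((5, 4))
        out = self_attention(Z, Z, V)
        np.testing.assert_allclose(out, np.tile(V.mean(0), (5, 1)),
                                   atol=1e-12)

    def test_matches_two_loop_oracle(self, rng):
        Q = rng.integers(-3, 4, size=(3, 2)).astype(float)
        K = rng.integers(-3, 4, size=(3, 2)).astype(float)
        V = rng.integers(-3, 4, size=(3, 2)).astype(float)
        np.testing.assert_allclose(self_attention(Q, K, V),
                                   naive_self_attention(Q, K, V), atol=1e-6)

    def test_nonfinite_input_rejected(self):
        bad = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            self_attention(bad, bad, bad)


def naive_mha(x, model, layer_index):
    """Per-head brute-force multi-head attention oracle built directly
    from the weight matrices."""
    cfg = model.config
    p = {k: v.data for k, v in model.params.items()}
    pre = f"layer{layer_index - 1}_"
    heads = []
    for i in range(cfg.n_heads):
        sl = slice(i * cfg.d_k, (i + 1) * cfg.d_k)
        Q = x @ p[pre + "Wq"][:, sl] + p[pre + "bq"][sl]
        K = x @ p[pre + "Wk"][:, sl] + p[pre + "bk"][sl]
        V = x @ p[pre + "Wv"][:, sl] + p[pre + "bv"][sl]
        heads.append(naive_self_attention(Q, K, V))
    return np.concatenate(heads, axis=1) @ p[pre + "Wo"] + p[pre + "bo"]


class TestMultiHeadAttention:
    def test_matches_per_head_oracle_many_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(50):
            n = int(rng.integers(1, 6))
            h = int(rng.choice([1, 2, 4]))
            d_model = int(h * rng.integers(1, 3))
            cfg = AggregatorConfig(d_in=4, d_model=d_model, n_layers=2,
                                   n_heads=h, mlp_hidden=8,
                                   head_hidden=4)
            model = TransformerAggregator(cfg, seed=trial)
            x = rng.normal(size=(n, d_model))
            layer = int(rng.integers(1, 3))
            out, A = multi_head_attention(x, model, layer)
            np.testing.assert_allclose(out, naive_mha(x, model, layer),
                                       atol=1e-6)
            np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-5)

    def test_single_head_reduces_to_self_attention(self, rng):
        cfg = AggregatorConfig(d_in=4, d_model=6, n_layers=1, n_heads=1,
                               mlp_hidden=8, head_hidden=4, qkv_bias=False)
        model = TransformerAggregator(cfg, seed=0)
        x = rng.normal(size=(4, 6))
        p = {k: v.data for k, v in model.params.items()}
        expected = self_attention(x @ p["layer0_Wq"], x @ p["layer0_Wk"],
                                  x @ p["layer0_Wv"]) @ p["layer0_Wo"]
        out, _ = multi_head_attention(x, model, 1)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_block_decomposition_over_heads(self, rng):
        cfg = AggregatorConfig(d_in=4, d_model=8, n_layers=1, n_heads=2,
                               mlp_hidden=8, head_hidden=4)
        model = TransformerAggregator(cfg, seed=1)
        x = rng.normal(size=(5, 8))
        p = {k: v.data for k, v in model.params.items()}
        total = np.zeros((5, 8))
        for i in range(2):
            sl = slice(i * 4, (i + 1) * 4)
            Q = x @ p["layer0_Wq"][:, sl] + p["layer0_bq"][sl]
            K = x @ p["layer0_Wk"][:, sl] + p["layer0_bk"][sl]
            V = x @ p["layer0_Wv"][:, sl] + p["layer0_bv"][sl]
            total += naive_self_attention(Q, K, V) @ p["layer0_Wo"][sl, :]
        total += p["layer0_bo"]
        out, _ = multi_head_attention(x, model, 1)
        np.testing.assert_allclose(out, total, atol=1e-8)

    def test_patch_permutation_equivariance_class_token_fixed(self, rng):
        cfg = AggregatorConfig(d_in=4, d_model=8, n_layers=1, n_heads=2,
                               mlp_hidden=8, head_hidden=4)
        model = TransformerAggregator(cfg, seed=2)
        n = 6
        x = rng.normal(size=(n + 1, 8))  # row 0 = class token
        perm = rng.permutation(n)
        xp = np.concatenate([x[:1], x[1:][perm]], axis=0)
        out, _ = multi_head_attention(x, model, 1)
        outp, _ = multi_head_attention(xp, model, 1)
        np.testing.assert_allclose(outp[0], out[0], atol=1e-10)
        np.testing.assert_allclose(outp[1:], out[1:][perm], atol=1e-10)


class TestForwardBag:
    def test_identical_tiles_collapse_to_singleton_mean_mode(self, rng):
        # exact exchangeability: with mean-token pooling every row of a
        # constant bag transforms identically, so bag size cancels; with
        # a class token its self-attention weight depends on bag size
        # and the collapse is only asymptotic
        cfg = AggregatorConfig(d_in=16, d_model=16, n_layers=2, n_heads=4,
                               mlp_hidden=32, head_hidden=16,
                               pooling_mode="mean_token")
        model = TransformerAggregator(cfg, seed=7)
        tile = rng.normal(size=(1, 16))
        many = np.repeat(tile, 12, axis=0)
        p1 = forward_bag(tile, model)
        pn = forward_bag(many, model)
        np.testing.assert_allclose(pn.logits, p1.logits, atol=1e-8)

    def test_permutation_invariance(self, small_model, rng):
        x = rng.normal(size=(40, 16))
        base = forward_bag(x, small_model).logits
        for _ in range(5):
            perm = forward_bag(x[rng.permutation(40)], small_model).logits
            np.testing.assert_allclose(perm, base, rtol=1e-4, atol=1e-9)

    def test_constant_head_gives_constant_probability(self, rng):
        cfg = AggregatorConfig(d_in=8, d_model=8, n_heads=2, mlp_hidden=16,
                               head_hidden=8)
        model = TransformerAggregator(cfg, seed=0)
        model.params["head0_W1"].data[:] = 0.0
        model.params["head0_W2"].data[:] = 0.0
        model.params["head0_b2"].data[:] = 1.25
        for n in (1, 5, 20):
            p = forward_bag(rng.normal(size=(n, 8)), model)
            np.testing.assert_allclose(p.probabilities,
                                       1 / (1 + np.exp(-1.25)), atol=1e-12)

    def test_attention_rows_sum_to_one(self, small_model, rng):
        p = forward_bag(rng.normal(size=(17, 16)), small_model,
                        capture_attention=True)
        for layer in p.attention.layers:
            assert layer.shape == (4, 18, 18)
            np.testing.assert_allclose(layer.sum(axis=-1), 1.0, atol=1e-5)
            assert (layer >= 0).all()

    def test_empty_and_nan_bags_rejected(self, small_model):
        with pytest.raises(ValueError):
            forward_bag(np.empty((0, 16)), small_model)
        with pytest.raises(ValueError):
            forward_bag(np.full((3, 16), np.nan), small_model)

    def test_mean_token_mode_runs(self, rng):
        cfg = AggregatorConfig(d_in=8, d_model=8, n_heads=2, mlp_hidden=16,
                               head_hidden=8, pooling_mode="mean_token")
        model = TransformerAggregator(cfg, seed=0)
        p = forward_bag(rng.normal(size=(5, 8)), model,
                        capture_attention=True)
        assert p.attention.layers[0].shape == (2, 5, 5)
        assert 0 < p.probabilities[0] < 1

    def test_multi_target_one_logit_per_token(self, rng):
        cfg = AggregatorConfig(d_in=8, d_model=8, n_heads=2, mlp_hidden=16,
                               head_hidden=8, n_class_tokens=3)
        model = TransformerAggregator(cfg, seed=0)
        p = forward_bag(rng.normal(size=(5, 8)), model,
                        capture_attention=True)
        assert p.logits.shape == (3,)
        assert p.attention.layers[0].shape == (2, 8, 8)


class TestArchitectureConformance:
    def test_default_dimensions(self):
        cfg = AggregatorConfig()
        assert cfg.n_layers == 2
        assert cfg.n_heads == 8
        assert cfg.d_k == 64 and cfg.d_v == 64
        assert cfg.n_heads * cfg.d_v == cfg.d_model == 512
        assert cfg.d_in == 768

    def test_parameter_shapes_match_config(self):
        cfg = AggregatorConfig(d_in=24, d_model=16, n_layers=3, n_heads=4,
                               mlp_hidden=32, head_hidden=16)
        model = TransformerAggregator(cfg, seed=0)
        p = model.params
        assert p["proj_W"].shape == (24, 16)
        for l in range(3):
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                assert p[f"layer{l}_{nm}"].shape == (16, 16)
            assert p[f"layer{l}_mlp_W1"].shape == (16, 32)
        assert p["cls"].shape == (1, 16)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            AggregatorConfig(d_model=10, n_heads=4)


class TestAttentionMIL:
    def test_singleton_weight_is_one(self, rng):
        model = AttentionMILModel(AttentionMILConfig(d_in=8, d_hidden=8,
                                                     d_attn=4), seed=0)
        p = attention_mil_forward(rng.normal(size=(1, 8)), model)
        np.testing.assert_allclose(p.tile_weights, [1.0])

    def test_weights_normalized(self, rng):
        model = AttentionMILModel(AttentionMILConfig(d_in=8, d_hidden=8,
                                                     d_attn=4), seed=0)
        for n in (2, 10, 50):
            p = attention_mil_forward(rng.normal(size=(n, 8)), model)
            assert p.tile_weights.shape == (n,)
            np.testing.assert_allclose(p.tile_weights.sum(), 1.0, atol=1e-9)

    def test_two_tile_weights_match_closed_form(self, rng):
        model = AttentionMILModel(AttentionMILConfig(d_in=4, d_hidden=4,
                                                     d_attn=3), seed=3)
        x = rng.normal(size=(2, 4))
        p = {k: v.data for k, v in model.params.items()}
        e = np.maximum(x @ p["proj_W"] + p["proj_b"], 0)
        s = (np.tanh(e @ p["V"]) * (1 / (1 + np.exp(-(e @ p["U"]))))) @ p["w"]
        a = np.exp(s - s.max())
        a = (a / a.sum()).ravel()
        pred = attention_mil_forward(x, model)
        np.testing.assert_allclose(pred.tile_weights, a, atol=1e-10)
        logit = (a @ e) @ p["clf_W"] + p["clf_b"]
        np.testing.assert_allclose(pred.logits, logit.ravel(), atol=1e-10)

    def test_permutation_invariance(self, rng):
        model = AttentionMILModel(AttentionMILConfig(d_in=8, d_hidden=8,
                                                     d_attn=4), seed=0)
        x = rng.normal(size=(30, 8))
        base = attention_mil_forward(x, model).logits
        perm = attention_mil_forward(x[rng.permutation(30)], model).logits
        np.testing.assert_allclose(perm, base, rtol=1e-4, atol=1e-10)


class TestMeanPool:
    def test_identical_tiles_equal_singleton(self, rng):
        model = MeanPoolModel(d_in=8, seed=0)
        tile = rng.normal(size=(1, 8))
        many = np.repeat(tile, 9, axis=0)
        np.testing.assert_allclose(mean_pool_forward(many, model).logits,
                                   mean_pool_forward(tile, model).logits,
                                   atol=1e-9)

    def test_equals_manual_composition(self, rng):
        model = MeanPoolModel(d_in=8, seed=0)
        x = rng.normal(size=(12, 8))
        manual = (x.mean(0) @ model.params["W"].data
                  + model.params["b"].data)
        np.testing.assert_allclose(mean_pool_forward(x, model).logits,
                                   manual, atol=1e-10)

    def test_duplication_invariance(self, rng):
        model = MeanPoolModel(d_in=8, seed=0)
        x = rng.normal(size=(6, 8))
        doubled = np.concatenate([x, x], axis=0)
        np.testing.assert_allclose(mean_pool_forward(doubled, model).logits,
                                   mean_pool_forward(x, model).logits,
                                   atol=1e-9)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        cfg = AggregatorConfig(d_in=8, d_model=8, n_heads=2, mlp_hidden=16,
                               head_hidden=8)
        model = TransformerAggregator(cfg, seed=4)
        x = rng.normal(size=(6, 8))
        before = forward_bag(x, model).logits
        save_checkpoint(tmp_path / "ck.npz", model,
                        metadata={"fold": 2, "seed": 9, "target": "MSI"})
        loaded, meta = load_checkpoint(tmp_path / "ck.npz")
        np.testing.assert_array_equal(forward_bag(x, loaded).logits, before)
        assert meta == {"fold": 2, "seed": 9, "target": "MSI"}
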