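"""Architecture contracts: loop-based attention oracles, masking, padding
invariance, ablation, determinism and checkpointing."""

import numpy as np
import pytest

from seqddg.autodiff import Tensor
from seqddg.network import (
    AttentionMaps,
    FeatureBatch,
    Featurizer,
    Model,
    ModelConfig,
    _attend,
    batch_records,
    embed,
    forward,
    mutual_attention,
    predict_ddg,
    self_attention,
)

from conftest import random_record


def small_model(**kw):
    defaults = dict(hidden_size=4, n_heads=2, dropout_rate=0.1, fc_sizes=(8, 4, 1), seed=3)
    defaults.update(kw)
    return Model(ModelConfig(**defaults))


# ---------------------------------------------------------------------------
# Independent loop oracles


def loop_softmax(scores):
    e = np.exp(scores - scores.max())
    return e / e.sum()


def loop_self_attention(model, h, mask):
    """Nested-loop scaled dot-product self-attention: per head
    softmax(QKᵀ/√d_k)·V, heads concatenated, output-mixed, plus residual."""
    cfg = model.config
    wq, wk = model.params["self.wq"].data, model.params["self.wk"].data
    wv, wo = model.params["self.wv"].data, model.params["self.wo"].data
    batch, n, d = h.shape
    dk = cfg.d_head
    out = np.zeros_like(h)
    for b in range(batch):
        q, k, v = h[b] @ wq, h[b] @ wk, h[b] @ wv
        mixed = np.zeros((n, d))
        for head in range(cfg.n_heads):
            sl = slice(head * dk, (head + 1) * dk)
            for i in range(n):
                scores = np.full(n, -np.inf)
                for j in range(n):
                    if mask[b, j]:
                        scores[j] = q[i, sl] @ k[j, sl] / np.sqrt(dk)
                attn = loop_softmax(scores)
                for j in range(n):
                    mixed[i, sl] += attn[j] * v[j, sl]
        out[b] = mixed @ wo + h[b]
    return out


def loop_mutual_attention(model, h_q, h_kv, mask_kv):
    """Loop oracle for cross attention: no residual, no output mixing;
    also returns the head-averaged map."""
    cfg = model.config
    wq, wk, wv = (model.params[f"mutual.{w}"].data for w in ("wq", "wk", "wv"))
    batch, nq, d = h_q.shape
    nk = h_kv.shape[1]
    dk = cfg.d_head
    out = np.zeros((batch, nq, d))
    maps = np.zeros((batch, nq, nk))
    for b in range(batch):
        q, k, v = h_q[b] @ wq, h_kv[b] @ wk, h_kv[b] @ wv
        for head in range(cfg.n_heads):
            sl = slice(head * dk, (head + 1) * dk)
            for i in range(nq):
                scores = np.full(nk, -np.inf)
                for j in range(nk):
                    if mask_kv[b, j]:
                        scores[j] = q[i, sl] @ k[j, sl] / np.sqrt(dk)
                attn = loop_softmax(scores)
                maps[b, i] += attn / cfg.n_heads
                for j in range(nk):
                    out[b, i, sl] += attn[j] * v[j, sl]
    return out, maps


class TestAttentionOracles:
    @pytest.mark.parametrize("n_heads,n,batch", [(1, 3, 1), (2, 5, 2), (3, 4, 2)])
    def test_self_attention_matches_loops(self, rng, n_heads, n, batch):
        model = small_model(n_heads=n_heads, hidden_size=max(2, n_heads))
        d = model.config.d_model
        h = rng.normal(scale=0.5, size=(batch, n, d))
        mask = np.ones((batch, n))
        if n > 2:
            mask[-1, -1] = 0.0  # one padded key position
        got = self_attention(model, Tensor(h), mask, training=False).data
        want = loop_self_attention(model, h, mask)
        np.testing.assert_allclose(got, want, atol=1e-6)

    @pytest.mark.parametrize("nq,nk", [(2, 3), (5, 4), (1, 5)])
    def test_mutual_attention_matches_loops(self, rng, nq, nk):
        model = small_model(n_heads=2, hidden_size=2)
        d = model.config.d_model
        h_q = rng.normal(scale=0.5, size=(2, nq, d))
        h_kv = rng.normal(scale=0.5, size=(2, nk, d))
        mask_kv = np.ones((2, nk))
        mask_kv[0, -1] = 0.0
        got_out, got_map = mutual_attention(model, Tensor(h_q), Tensor(h_kv), mask_kv)
        want_out, want_map = loop_mutual_attention(model, h_q, h_kv, mask_kv)
        np.testing.assert_allclose(got_out.data, want_out, atol=1e-6)
        np.testing.assert_allclose(got_map, want_map, atol=1e-6)

    def test_single_key_attends_fully(self, rng):
        # With one key position every query row attends to it with weight 1.
        model = small_model(n_heads=2, hidden_size=2)
        d = model.config.d_model
        h_q = rng.normal(size=(1, 4, d))
        h_kv = rng.normal(size=(1, 1, d))
        out, amap = mutual_attention(model, Tensor(h_q), Tensor(h_kv), np.ones((1, 1)))
        np.testing.assert_allclose(amap, 1.0)
        expected = np.tile(h_kv[0] @ model.params["mutual.wv"].data, (4, 1))
        np.testing.assert_allclose(out.data[0], expected, atol=1e-10)

    def test_rows_stochastic_over_unmasked_keys(self, rng):
        model = small_model(n_heads=3, hidden_size=3)
        d = model.config.d_model
        h = rng.normal(size=(3, 6, d))
        mask = (rng.random((3, 6)) < 0.7).astype(float)
        mask[:, 0] = 1.0  # at least one real key per sequence
        _, attn = _attend(model, "self", Tensor(h), Tensor(h), mask)
        sums = attn.data.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)
        # masked keys receive exactly zero weight
        masked_cols = attn.data * (1.0 - mask)[:, None, None, :]
        np.testing.assert_allclose(masked_cols, 0.0, atol=1e-12)


class TestEmbed:
    def test_output_shape(self, rng):
        model = small_model(hidden_size=8, n_heads=2)
        x = rng.normal(size=(2, 10, 40))
        out = embed(model, Tensor(x), np.ones((2, 10)))
        assert out.shape == (2, 10, 24)

    def test_zero_input_zero_biases_gives_zero_output(self):
        model = small_model()
        out = embed(model, Tensor(np.zeros((1, 6, 40))), np.ones((1, 6)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_feature_width_enforced(self):
        model = small_model()
        with pytest.raises(ValueError, match="width 40"):
            embed(model, Tensor(np.zeros((1, 6, 39))), np.ones((1, 6)))


class TestForward:
    def test_padding_invariance(self, rng):
        # Appending padded positions must not change predictions.
        model = small_model()
        rec = random_record(rng, len_ab=9, len_ag=7)
        batch = batch_records([rec])
        base, _ = forward(model, batch)
        padded = FeatureBatch(
            features={
                role: np.pad(arr, ((0, 0), (0, 4), (0, 0)))
                for role, arr in batch.features.items()
            },
            masks={role: np.pad(m, ((0, 0), (0, 4))) for role, m in batch.masks.items()},
            record_ids=batch.record_ids,
        )
        got, _ = forward(model, padded)
        np.testing.assert_allclose(got.data, base.data, atol=1e-5)

    def test_mixed_length_batch_matches_singletons(self, rng):
        model = small_model()
        recs = [random_record(rng, len_ab=12, len_ag=6), random_record(rng, len_ab=7, len_ag=10)]
        together, _ = forward(model, batch_records(recs))
        separate = [forward(model, batch_records([r]))[0].data[0] for r in recs]
        np.testing.assert_allclose(together.data, separate, atol=1e-8)

    def test_batch_permutation_stability(self, rng):
        model = small_model()
        recs = [random_record(rng, len_ab=10, len_ag=8) for _ in range(5)]
        base, _ = forward(model, batch_records(recs))
        perm = [3, 1, 4, 0, 2]
        permuted, _ = forward(model, batch_records([recs[i] for i in perm]))
        np.testing.assert_allclose(permuted.data, base.data[perm], atol=1e-10)

    def test_evaluation_mode_is_deterministic(self, rng):
        model = small_model()
        recs = [random_record(rng) for _ in range(3)]
        a, _ = predict_ddg(model, recs)
        b, _ = predict_ddg(model, recs)
        np.testing.assert_array_equal(a, b)

    def test_map_shapes_match_sequence_lengths(self, rng):
        model = small_model()
        rec = random_record(rng, len_ab=11, len_ag=6)
        _, maps = predict_ddg(model, [rec])
        assert maps[0].w_ag_ab_wt.shape == (6, 11)
        np.testing.assert_allclose(maps[0].w_ag_ab_wt.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(maps[0].w_ag_ab_mt.sum(axis=1), 1.0, atol=1e-6)

    def test_ablation_same_head_width_and_finite(self, rng):
        full = small_model()
        ablated = small_model(use_attention=False)
        assert full.params["fc0.w"].shape == ablated.params["fc0.w"].shape
        recs = [random_record(rng) for _ in range(3)]
        preds, maps = predict_ddg(ablated, recs)
        assert np.isfinite(preds).all()
        assert maps == []

    def test_dropout_only_in_training(self, rng):
        model = small_model(dropout_rate=0.5, hidden_size=8, seed=0)
        recs = [random_record(rng) for _ in range(4)]
        batch = batch_records(recs)
        e1, _ = forward(model, batch)
        e2, _ = forward(model, batch)
        np.testing.assert_array_equal(e1.data, e2.data)
        assert np.any(e1.data != 0.0)  # head is not degenerate for this seed
        t1, _ = forward(model, batch, training=True, rng=np.random.default_rng(0))
        t2, _ = forward(model, batch, training=True, rng=np.random.default_rng(1))
        assert not np.allclose(t1.data, t2.data)


class TestModelState:
    @pytest.mark.parametrize("kw", [dict(hidden_size=6, n_heads=2), dict(hidden_size=8, n_heads=3), dict(hidden_size=4, n_heads=4, use_attention=False)])
    def test_shape_audit_passes_for_valid_configs(self, kw):
        model = small_model(**kw)
        shapes = model.shape_audit()
        d = model.config.d_model
        assert shapes["ln.gain"] == (d,)
        assert shapes["fc0.w"][0] == 4 * d

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_size=5, n_heads=4)  # 15 not divisible by 4
        with pytest.raises(ValueError):
            ModelConfig(kernel_sizes=(2, 3, 5))  # even kernel
        with pytest.raises(ValueError):
            ModelConfig(fc_sizes=(16, 8, 2))  # non-scalar output

    def test_same_seed_same_parameters(self):
        a, b = small_model(seed=11), small_model(seed=11)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name].data, b.params[name].data)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = small_model()
        path = model.save(tmp_path / "ckpt.npz")
        loaded = Model.load(path)
        assert loaded.config == model.config
        rec = random_record(rng)
        np.testing.assert_array_equal(
            predict_ddg(model, [rec])[0], predict_ddg(loaded, [rec])[0]
        )
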