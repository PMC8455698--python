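"""Network building blocks: attention weights, Conv/unfold, message passing,
self-attention and the decoder, each against hand-unrolled oracles."""

import numpy as np
import pytest

from jcouple.autodiff import Tensor
from jcouple.nn import (
    DEFAULT_ATTENTION_COEFFS,
    ModelConfig,
    angle_attention,
    bond_mp_step,
    conv_unfold,
    coupling_mp_step,
    decode_scc,
    edge_attention,
    embed,
    multi_head_attention,
    scaled_dot_attention,
)

rng = np.random.default_rng(0)


class TestAngleAttention:
    def test_closed_form_values(self):
        # A'cos²θ + B'cosθ + C' at the defaults (0.12, 0.99, 0.27)
        assert angle_attention([90.0]) == pytest.approx(0.27, abs=1e-12)
        assert angle_attention([0.0]) == pytest.approx(1.38, abs=1e-12)
        assert angle_attention([0.0, 180.0]) == pytest.approx(0.39, abs=1e-12)

    def test_no_neighbours_is_neutral(self):
        assert angle_attention([]) == 1.0

    def test_monotone_decreasing_in_theta(self):
        thetas = np.linspace(0, 180, 181)
        vals = [angle_attention([t]) for t in thetas]
        assert np.all(np.diff(vals) < 0)

    def test_equals_brute_force_term_mean(self):
        a, b, c = DEFAULT_ATTENTION_COEFFS
        for _ in range(20):
            thetas = rng.uniform(0, 180, size=rng.integers(1, 6))
            brute = np.mean(
                [a * np.cos(np.radians(t)) ** 2 + b * np.cos(np.radians(t)) + c for t in thetas]
            )
            assert angle_attention(thetas) == pytest.approx(brute, abs=1e-12)

    def test_differentiable_edge_version_matches_scalar(self):
        coeffs = Tensor(np.array(DEFAULT_ATTENTION_COEFFS), requires_grad=True)
        thetas = [[30.0, 100.0], [], [90.0]]
        cos_flat = np.cos(np.radians(np.concatenate([t for t in thetas if t])))
        edge_ids = np.array([0, 0, 2])
        attn = edge_attention(cos_flat, edge_ids, 3, coeffs)
        expect = [angle_attention(t) for t in thetas]
        np.testing.assert_allclose(attn.data, expect, atol=1e-12)


class TestConvUnfold:
    def test_sliding_window_rows(self):
        h = Tensor(np.array([[1.0, 2.0, 3.0, 4.0]]))
        u = conv_unfold(h, 2)  # identity map
        np.testing.assert_allclose(u.data[0], [[1, 2], [2, 3], [3, 4], [4, 0]])

    def test_zero_vector_gives_zero_matrix(self):
        u = conv_unfold(Tensor(np.zeros((2, 6))), 3)
        assert np.all(u.data == 0)

    def test_padding_count_in_last_rows(self):
        d, w = 8, 4
        h = Tensor(rng.uniform(1, 2, size=(1, d)))  # strictly nonzero entries
        u = conv_unfold(h, w).data[0]
        for r in range(d):
            n_pad = max(0, r + w - d)
            assert np.count_nonzero(u[r] == 0) == n_pad
        np.testing.assert_allclose(u[d - 1], [h.data[0, d - 1], 0, 0, 0])

    def test_learned_position_wise_map(self):
        h = Tensor(rng.normal(size=(3, 4)))
        w = Tensor(rng.normal(size=(2, 2)))
        b = Tensor(rng.normal(size=(2,)))
        got = conv_unfold(h, 2, w, b).data
        raw = conv_unfold(h, 2).data
        np.testing.assert_allclose(got, raw @ w.data + b.data, atol=1e-12)


class TestMessagePassing:
    def _edges(self):
        src = np.array([0, 1])
        dst = np.array([1, 0])
        e = Tensor(rng.normal(size=(2, 4, 2)))
        return src, dst, e

    def test_zero_conv_is_residual_identity(self):
        h = Tensor(rng.normal(size=(2, 4)))
        src, dst, e = self._edges()
        w = Tensor(np.zeros((2, 2)))
        b = Tensor(np.zeros(2))
        out = bond_mp_step(h, src, dst, e, w, b, attn=Tensor(np.ones(2)))
        np.testing.assert_array_equal(out.data, h.data)

    def test_isolated_atom_unchanged(self):
        h = Tensor(rng.normal(size=(3, 4)))
        src, dst, e = self._edges()  # atom 2 has no edges
        w = Tensor(rng.normal(size=(2, 2)))
        b = Tensor(rng.normal(size=(2,)))
        out = bond_mp_step(h, src, dst, e, w, b, attn=Tensor(np.ones(2)))
        np.testing.assert_array_equal(out.data[2], h.data[2])

    def test_two_atom_hand_unrolled_oracle(self):
        d, win = 4, 2
        h = Tensor(rng.normal(size=(2, d)))
        src, dst, e = self._edges()
        w = Tensor(rng.normal(size=(win, win)))
        b = Tensor(rng.normal(size=(win,)))
        attn = Tensor(np.array([0.7, 1.3]))
        out = bond_mp_step(h, src, dst, e, w, b, attn=attn).data

        def oracle(v_new, w_src, a, ev):
            # fully scalar recomputation of one directed message
            msg = np.zeros(d)
            for r in range(d):
                row = np.zeros(win)
                for c in range(win):
                    row[c] = h.data[w_src, r + c] if r + c < d else 0.0
                row = row @ w.data + b.data
                msg[r] = a * float((row * ev[r]).sum())
            return h.data[v_new] + msg

        np.testing.assert_allclose(out[1], oracle(1, 0, 0.7, e.data[0]), atol=1e-10)
        np.testing.assert_allclose(out[0], oracle(0, 1, 1.3, e.data[1]), atol=1e-10)

    def test_coupling_step_equals_bond_step_with_unit_attn(self):
        h = Tensor(rng.normal(size=(2, 4)))
        src, dst, e = self._edges()
        w = Tensor(rng.normal(size=(2, 2)))
        b = Tensor(rng.normal(size=(2,)))
        got = coupling_mp_step(h, src, dst, e, w, b).data
        ref = bond_mp_step(h, src, dst, e, w, b, attn=Tensor(np.ones(2))).data
        np.testing.assert_allclose(got, ref, atol=1e-14)


class TestSelfAttention:
    def test_single_token_returns_its_value(self):
        v = Tensor(rng.normal(size=(1, 1, 4)))
        q = Tensor(rng.normal(size=(1, 1, 4)))
        out, wts = scaled_dot_attention(q, q, v)
        np.testing.assert_allclose(out.data, v.data, atol=1e-12)
        np.testing.assert_allclose(wts.data, 1.0)

    def test_weight_rows_sum_to_one(self):
        q = Tensor(rng.normal(size=(2, 5, 4)))
        _, wts = scaled_dot_attention(q, q, q)
        np.testing.assert_allclose(wts.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_identical_keys_average_values(self):
        k = Tensor(np.ones((1, 4, 3)))
        q = Tensor(rng.normal(size=(1, 4, 3)))
        v = Tensor(rng.normal(size=(1, 4, 3)))
        out, _ = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(
            out.data, np.broadcast_to(v.data.mean(axis=1, keepdims=True), v.shape), atol=1e-12
        )

    def test_single_head_reduces_to_scaled_dot_plus_mix(self):
        d = 4
        tok = Tensor(rng.normal(size=(1, 3, d)))
        wq, wk, wv, wo = (Tensor(rng.normal(size=(d, d))) for _ in range(4))
        got = multi_head_attention(tok, wq, wk, wv, wo, n_heads=1, scale=np.sqrt(d))
        ref, _ = scaled_dot_attention(tok @ wq, tok @ wk, tok @ wv, scale=np.sqrt(d))
        np.testing.assert_allclose(got.data, (ref @ wo).data, atol=1e-12)

    def test_output_width_is_d_model(self):
        d = 8
        tok = Tensor(rng.normal(size=(3, 5, d)))
        wq, wk, wv, wo = (Tensor(rng.normal(size=(d, d))) for _ in range(4))
        out = multi_head_attention(tok, wq, wk, wv, wo, n_heads=4)
        assert out.shape == (3, 5, d)

    def test_two_head_hand_unrolled(self):
        d, hds = 4, 2
        tok = Tensor(rng.normal(size=(1, 3, d)))
        wq, wk, wv, wo = (Tensor(rng.normal(size=(d, d))) for _ in range(4))
        scale = np.sqrt(d)
        got = multi_head_attention(tok, wq, wk, wv, wo, n_heads=hds, scale=scale).data[0]

        x = tok.data[0]
        heads = []
        for hh in range(hds):
            sl = slice(hh * d // hds, (hh + 1) * d // hds)
            q, k, v = x @ wq.data[:, sl], x @ wk.data[:, sl], x @ wv.data[:, sl]
            s = q @ k.T / scale
            p = np.exp(s - s.max(axis=-1, keepdims=True))
            p /= p.sum(axis=-1, keepdims=True)
            heads.append(p @ v)
        ref = np.concatenate(heads, axis=-1) @ wo.data
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_mask_restricts_attention(self):
        d = 4
        tok = Tensor(rng.normal(size=(2, 3, d)))
        wq, wk, wv, wo = (Tensor(rng.normal(size=(d, d))) for _ in range(4))
        mask = np.array([[1, 1, 0], [1, 1, 1]])
        full = multi_head_attention(tok, wq, wk, wv, wo, 2, mask=mask).data
        # changing a masked-out token must not affect valid outputs
        tok2 = Tensor(np.concatenate([tok.data[:, :2], rng.normal(size=(2, 1, d))], axis=1))
        other = multi_head_attention(tok2, wq, wk, wv, wo, 2, mask=mask).data
        np.testing.assert_allclose(full[0, :2], other[0, :2], atol=1e-12)


class TestEmbedAndDecode:
    def test_embed_reshape_convention(self):
        d, w = 4, 2
        weight = Tensor(np.diag(np.arange(d * w, dtype=float)))
        bias = Tensor(np.zeros(d * w))
        out = embed(Tensor(np.ones((1, d * w))), weight, bias, matrix_shape=(d, w)).data[0]
        for r in range(d):
            for c in range(w):
                assert out[r, c] == r * w + c  # row-major slot r*w + c

    def test_zero_final_layer_outputs_bias(self):
        d = 4
        f0, f1 = Tensor(rng.normal(size=(3, d))), Tensor(rng.normal(size=(3, d)))
        fm = Tensor(rng.normal(size=(3, d // 2)))
        mlp = [
            (Tensor(rng.normal(size=(2 * d + d // 2, 5))), Tensor(rng.normal(size=(5,)))),
            (Tensor(np.zeros((5, 1))), Tensor(np.array([3.25]))),
        ]
        out = decode_scc(f0, f1, fm, mlp)
        np.testing.assert_allclose(out.data, 3.25)

    def test_swapping_atoms_changes_prediction(self):
        d = 4
        f0, f1 = Tensor(rng.normal(size=(1, d))), Tensor(rng.normal(size=(1, d)))
        fm = Tensor(rng.normal(size=(1, d // 2)))
        mlp = [(Tensor(rng.normal(size=(2 * d + d // 2, 1))), Tensor(np.zeros(1)))]
        a = decode_scc(f0, f1, fm, mlp).data
        b = decode_scc(f1, f0, fm, mlp).data
        assert not np.allclose(a, b)

    def test_hand_unrolled_single_hidden_layer(self):
        d = 2
        f0 = Tensor(np.array([[1.0, -2.0]]))
        f1 = Tensor(np.array([[0.5, 0.0]]))
        fm = Tensor(np.array([[2.0]]))
        w0 = Tensor(np.arange(10, dtype=float).reshape(5, 2) / 10)
        b0 = Tensor(np.array([0.1, -0.2]))
        w1 = Tensor(np.array([[1.0], [-1.0]]))
        b1 = Tensor(np.array([0.5]))
        out = decode_scc(f0, f1, fm, [(w0, b0), (w1, b1)]).data
        z = np.array([1.0, -2.0, 0.5, 0.0, 2.0])
        hid = np.maximum(z @ w0.data + b0.data, 0)
        expect = hid @ w1.data + b1.data
        np.testing.assert_allclose(out, expect.ravel(), atol=1e-12)


class TestModelConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=6, n_heads=4)
        with pytest.raises(ValueError):
            ModelConfig(d_model=7)

    def test_softmax_scale_variants(self):
        assert ModelConfig(d_model=64, n_heads=4).softmax_scale == pytest.approx(8.0)
        assert ModelConfig(
            d_model=64, n_heads=4, attention_scale="d_head"
        ).softmax_scale == pytest.approx(4.0)
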