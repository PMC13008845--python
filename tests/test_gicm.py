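"""Global-context gate: local branch, QKV, attention against scalar oracles."""

import numpy as np
import pytest

from yolobt import nn
from yolobt.nn import autograd as ag
from yolobt import gicm as gm
import oracles


def tt(a):
    return ag.tensor(a, dtype=np.float64)


@pytest.fixture(autouse=True)
def _seed():
    nn.set_init_seed(31)


class TestLocalBranch:
    def test_output_single_channel_in_unit_interval(self, rng):
        lb = gm.LocalBranch(4, 2)
        lb.eval()
        x = ag.tensor(rng.standard_normal((2, 4, 6, 6)).astype(np.float32))
        out = lb(x)
        assert out.shape == (2, 1, 6, 6)
        assert ((out.data > 0) & (out.data < 1)).all()

    def test_five_branches_preserve_dims(self, rng):
        lb = gm.LocalBranch(3, 2)
        lb.eval()
        x = ag.tensor(rng.standard_normal((1, 3, 9, 9)).astype(np.float32))
        for k, branch in zip(gm.KERNEL_SET, lb.branches):
            assert branch.conv.kernel_size == k
            assert branch.conv.padding == k // 2
            assert branch(x).shape == (1, 2, 9, 9)

    def test_matches_scalar_composition_oracle(self, rng):
        lb = gm.LocalBranch(2, 1, reduction=1)
        lb.eval()
        x = rng.standard_normal((1, 2, 5, 5)).astype(np.float32)
        got = lb(ag.tensor(x)).data[0]
        feats = []
        for k, branch in zip(gm.KERNEL_SET, lb.branches):
            y = oracles.conv2d(x[0], branch.conv.weight.data, None,
                               padding=k // 2)
            y = oracles.bn_eval(y, branch.bn.weight.data, branch.bn.bias.data,
                                branch.bn._buffers["running_mean"],
                                branch.bn._buffers["running_var"])
            feats.append(oracles.silu(y))
        cat = np.concatenate(feats, axis=0)
        _, rew = oracles.cbam_channel(cat, lb.channel_att.fc1.weight.data,
                                      lb.channel_att.fc2.weight.data)
        red = oracles.conv2d(rew, lb.reduce.weight.data, lb.reduce.bias.data)
        expect = oracles.sigmoid(red)
        np.testing.assert_allclose(got, expect, rtol=1e-4, atol=1e-6)


class TestGlobalGate:
    def test_shape_preserved_and_contraction(self, rng):
        g = gm.GICM(4, 2, d_k=3, token_pool=400)
        x = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
        out = g.global_gate(ag.tensor(x))
        assert out.shape == x.shape
        assert (np.abs(out.data) <= np.abs(x) + 1e-7).all()

    def test_matches_composed_oracle(self, rng):
        g = gm.GICM(3, 2, d_k=2)
        x = rng.standard_normal((1, 3, 6, 6)).astype(np.float32)
        got = g.global_gate(ag.tensor(x)).data[0]
        s = oracles.cbam_spatial(x[0].astype(np.float64),
                                 g.spatial_att.conv.weight.data,
                                 g.spatial_att.conv.bias.data)
        np.testing.assert_allclose(got, x[0] * s, rtol=1e-4, atol=1e-6)


class TestQKVProject:
    def test_identity_gate(self, rng):
        g = gm.GICM(3, 2, d_k=2)
        xg = ag.tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32))
        ones = ag.tensor(np.ones((1, 1, 4, 4), dtype=np.float32))
        _, _, v = g.qkv(xg, ones)
        plain = g.v_proj(xg)
        np.testing.assert_allclose(v.data, plain.data, rtol=1e-6)

    def test_zero_gate_zero_value(self, rng):
        g = gm.GICM(3, 2, d_k=2)
        xg = ag.tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32))
        zeros = ag.tensor(np.zeros((1, 1, 4, 4), dtype=np.float32))
        _, _, v = g.qkv(xg, zeros)
        np.testing.assert_allclose(v.data, 0.0)

    def test_matches_scalar_oracle(self, rng):
        g = gm.GICM(2, 1, d_k=2)
        xg = rng.standard_normal((1, 2, 3, 3)).astype(np.float32)
        l = rng.random((1, 1, 3, 3)).astype(np.float32)
        k, q, v = g.qkv(ag.tensor(xg), ag.tensor(l))
        ek = oracles.conv2d(xg[0], g.k_proj.weight.data, g.k_proj.bias.data)
        ev = oracles.conv2d(xg[0], g.v_proj.weight.data, g.v_proj.bias.data) \
            * l[0]
        np.testing.assert_allclose(k.data[0], ek, rtol=1e-5)
        np.testing.assert_allclose(v.data[0], ev, rtol=1e-5)


class TestAttentionMix:
    def test_rows_sum_to_one(self, rng):
        q = tt(rng.standard_normal((2, 6, 3)))
        k = tt(rng.standard_normal((2, 6, 3)))
        v = tt(rng.standard_normal((2, 6, 4)))
        _, w = gm.attention_mix(k, q, v, d_k=3)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_token_passthrough(self, rng):
        q, k = tt(rng.standard_normal((1, 1, 3))), tt(rng.standard_normal((1, 1, 3)))
        v = tt(rng.standard_normal((1, 1, 4)))
        out, _ = gm.attention_mix(k, q, v, d_k=3)
        np.testing.assert_allclose(out.data, v.data, rtol=1e-12)

    def test_matches_scalar_oracle_with_dk_scaling(self, rng):
        q = rng.standard_normal((1, 4, 3))
        k = rng.standard_normal((1, 4, 3))
        v = rng.standard_normal((1, 4, 5))
        out, _ = gm.attention_mix(tt(k), tt(q), tt(v), d_k=3)
        expect = oracles.attention(q[0], k[0], v[0], 3)
        np.testing.assert_allclose(out.data[0], expect, rtol=1e-6)

    def test_invalid_dk_rejected(self, rng):
        with pytest.raises(ValueError):
            gm.attention_mix(tt(np.zeros((1, 2, 2))), tt(np.zeros((1, 2, 2))),
                             tt(np.zeros((1, 2, 2))), d_k=0)


class TestGICMForward:
    def test_shape_preserved(self, rng):
        g = gm.GICM(4, 2, d_k=3, token_pool=400)
        g.eval()
        x = ag.tensor(rng.standard_normal((2, 4, 5, 5)).astype(np.float32))
        assert g(x).shape == (2, 4, 5, 5)

    def test_zero_local_gate_zeroes_output(self, rng):
        g = gm.GICM(4, 2, d_k=3)
        g.eval()
        # force the local gate's final conv to a large negative bias
        g.local.reduce.weight.data[:] = 0
        g.local.reduce.bias.data[:] = -50.0
        x = ag.tensor(rng.standard_normal((1, 4, 5, 5)).astype(np.float32))
        out = g(x)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_small_input_bypasses_pooling(self, rng):
        g = gm.GICM(3, 2, d_k=2, token_pool=400)
        g.eval()
        x = ag.tensor(rng.standard_normal((1, 3, 6, 6)).astype(np.float32))
        out_direct = g(x).data
        l = g.local(x)
        xg = g.global_gate(x)
        k, q, v = g.qkv(xg, l)
        out_manual, _ = gm.attention_mix(
            gm._tokens(k), gm._tokens(q), gm._tokens(v), g.d_k)
        out_manual = ag.transpose(out_manual, (0, 2, 1)).data.reshape(1, 3, 6, 6)
        np.testing.assert_allclose(out_direct, out_manual, rtol=1e-6)

    def test_pooling_path_roundtrip_shape(self, rng):
        g = gm.GICM(3, 2, d_k=2, token_pool=4)
        g.eval()
        x = ag.tensor(rng.standard_normal((1, 3, 8, 8)).astype(np.float32))
        assert g(x).shape == (1, 3, 8, 8)

    def test_gating_monotonicity(self, rng):
        # scaling the local gate by alpha scales the output by exactly alpha
        g = gm.GICM(3, 2, d_k=2)
        g.eval()
        x = ag.tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32))
        l = g.local(x)
        xg = g.global_gate(x)
        k, q, v = g.qkv(xg, l)
        base, _ = gm.attention_mix(gm._tokens(k), gm._tokens(q),
                                   gm._tokens(v), g.d_k)
        alpha = 0.37
        k2, q2, v2 = g.qkv(xg, l * alpha)
        scaled, _ = gm.attention_mix(gm._tokens(k2), gm._tokens(q2),
                                     gm._tokens(v2), g.d_k)
        np.testing.assert_allclose(scaled.data, alpha * base.data, rtol=1e-5)

    def test_full_module_oracle_small_instance(self, rng):
        g = gm.GICM(2, 1, d_k=2, reduction=1)
        g.eval()
        x = rng.standard_normal((1, 2, 3, 3)).astype(np.float32)
        got = g(ag.tensor(x)).data[0]
        l = g.local(ag.tensor(x)).data[0]          # verified elsewhere
        s = oracles.cbam_spatial(x[0].astype(np.float64),
                                 g.spatial_att.conv.weight.data,
                                 g.spatial_att.conv.bias.data)
        xg = x[0] * s
        k = oracles.conv2d(xg, g.k_proj.weight.data, g.k_proj.bias.data)
        q = oracles.conv2d(xg, g.q_proj.weight.data, g.q_proj.bias.data)
        v = oracles.conv2d(xg, g.v_proj.weight.data, g.v_proj.bias.data) * l
        tok = lambda a: a.reshape(a.shape[0], -1).T
        out = oracles.attention(tok(q), tok(k), tok(v), 2)
        expect = out.T.reshape(2, 3, 3)
        np.testing.assert_allclose(got, expect, rtol=1e-4, atol=1e-6)
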