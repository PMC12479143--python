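"""Prediction network: shapes, attention arithmetic, equivariance, wiring."""

import numpy as np
import pytest

from hypersar import SarpNet, SarpNetConfig
from hypersar.errors import ConfigError, InvalidArgumentError
from hypersar.nn import Tensor
from hypersar.sarpnet import CrossAttentionBlock
from hypersar.nn.layers import seeded_rngs


@pytest.fixture(scope="module")
def net():
    return SarpNet(seed=0)


def _inputs(rng, n=40, batch=None):
    shape_x = (n, 6) if batch is None else (batch, n, 6)
    shape_p = (48,) if batch is None else (batch, 48)
    x = rng.random(shape_x)
    psi = rng.random(shape_p) * 2 * np.pi
    return x, psi


class TestEmbedding:
    def test_shapes(self, net, rng):
        x, psi = _inputs(rng, n=10)
        f_p, f_a = net.embed_inputs(x, psi)
        assert f_p.shape == (10, 128)
        assert f_a.shape == (48, 128)

    def test_zero_phases_give_identical_antenna_inputs(self, rng):
        """All-zero phases make every antenna's raw feature identical; the
        embedding may still distinguish antennas through its per-antenna
        weights, but it must be deterministic and finite."""
        net = SarpNet(seed=1)
        _, f_a1 = net.embed_inputs(rng.random((5, 6)), np.zeros(48))
        _, f_a2 = net.embed_inputs(rng.random((5, 6)), np.zeros(48))
        assert np.allclose(f_a1.data, f_a2.data)
        assert np.all(np.isfinite(f_a1.data))

    def test_duplicate_points_embed_identically(self, net, rng):
        x, psi = _inputs(rng, n=6)
        x[3] = x[0]
        f_p, _ = net.embed_inputs(x, psi)
        assert np.allclose(f_p.data[3], f_p.data[0])

    def test_phase_wrap_invariance(self, net, rng):
        """Phases enter as (cos, sin): adding 2*pi leaves the network output
        unchanged."""
        x, psi = _inputs(rng, n=12)
        assert np.allclose(net.predict(x, psi), net.predict(x, psi + 2 * np.pi), atol=1e-10)

    def test_nan_inputs_rejected(self, net, rng):
        x, psi = _inputs(rng, n=5)
        x[0, 0] = np.nan
        with pytest.raises(InvalidArgumentError):
            net.embed_inputs(x, psi)

    def test_wrong_widths_rejected(self, net, rng):
        with pytest.raises(InvalidArgumentError):
            net.embed_inputs(rng.random((5, 4)), rng.random(48))
        with pytest.raises(InvalidArgumentError):
            net.embed_inputs(rng.random((5, 6)), rng.random(24))


class TestCrossAttention:
    def test_rows_stochastic(self, net, rng):
        x, psi = _inputs(rng, n=30)
        f_p, f_a = net.embed_inputs(x, psi)
        for block in net.blocks:
            att = block.attention(f_p, f_a)
            assert att.shape == (30, 48)
            assert np.allclose(att.data.sum(axis=-1), 1.0, atol=1e-6)
            f_p = block(f_p, f_a)

    def test_identical_keys_give_uniform_attention(self, rng):
        block = CrossAttentionBlock(8, 8, seeded_rngs(0, 5))
        f_p = Tensor(rng.normal(size=(5, 8)))
        f_a = Tensor(np.tile(rng.normal(size=(1, 8)), (6, 1)))  # identical rows
        att = block.attention(f_p, f_a)
        assert np.allclose(att.data, 1.0 / 6.0, atol=1e-12)
        # Z is then the column-mean of V for every point
        v = f_a.data @ block.w_v.data
        z = att.data @ v
        assert np.allclose(z, v.mean(axis=0), atol=1e-12)

    def test_matches_dense_oracle(self, rng):
        """Block output equals an independently coded dense evaluation of the
        attention equations on a tiny instance."""
        width = 4
        block = CrossAttentionBlock(width, width, seeded_rngs(3, 5))
        f_p = rng.normal(size=(3, width))
        f_a = rng.normal(size=(2, width))

        # hand-rolled reference, explicit loops
        q = f_p @ block.w_q.data
        k = f_a @ block.w_k.data
        v = f_a @ block.w_v.data
        att = np.zeros((3, 2))
        for i in range(3):
            logits = np.array([q[i] @ k[j] / np.sqrt(width) for j in range(2)])
            e = np.exp(logits - logits.max())
            att[i] = e / e.sum()
        z = att @ v
        mu = z.mean(axis=1, keepdims=True)
        sd = np.sqrt(z.var(axis=1, keepdims=True) + 1e-5)
        normed = (z - mu) / sd * block.norm.gain.data + block.norm.bias.data
        h1 = np.maximum(normed @ block.mlp1.weight.data + block.mlp1.bias.data, 0.0)
        expected = h1 @ block.mlp2.weight.data + block.mlp2.bias.data + f_p

        got = block(Tensor(f_p), Tensor(f_a)).data
        assert np.allclose(got, expected, atol=1e-6)

    def test_width_mismatch_rejected(self, rng):
        block = CrossAttentionBlock(8, 8, seeded_rngs(0, 5))
        with pytest.raises(ConfigError):
            block.attention(Tensor(rng.normal(size=(5, 7))), Tensor(rng.normal(size=(6, 8))))
        with pytest.raises(ConfigError):
            CrossAttentionBlock(8, 4, seeded_rngs(0, 5))


class TestForward:
    def test_output_shape_and_finiteness(self, net, rng):
        x, psi = _inputs(rng, n=50)
        out = net.predict(x, psi)
        assert out.shape == (50,)
        assert np.all(np.isfinite(out))

    def test_batched_matches_single(self, net, rng):
        x, psi = _inputs(rng, n=20, batch=3)
        batched = net.predict(x, psi)
        assert batched.shape == (3, 20)
        for b in range(3):
            assert np.allclose(batched[b], net.predict(x[b], psi[b]), atol=1e-8)

    def test_point_permutation_equivariance(self, net, rng):
        x, psi = _inputs(rng, n=25)
        perm = rng.permutation(25)
        out = net.predict(x, psi)
        out_perm = net.predict(x[perm], psi)
        assert np.allclose(out_perm, out[perm], atol=1e-8)

    def test_sensitive_to_single_phase(self, net, rng):
        x, psi = _inputs(rng, n=15)
        psi2 = psi.copy()
        psi2[11] += 1.0
        assert not np.allclose(net.predict(x, psi), net.predict(x, psi2))

    def test_gradient_reaches_every_parameter(self, rng):
        net = SarpNet(seed=2)
        x, psi = _inputs(rng, n=12, batch=2)
        out = net(x, psi)
        (out * out).mean().backward()
        for p in net.parameters():
            assert p.grad is not None and np.any(p.grad != 0)

    def test_seed_controls_init(self, rng):
        x, psi = _inputs(rng, n=8)
        assert np.allclose(SarpNet(seed=4).predict(x, psi), SarpNet(seed=4).predict(x, psi))
        assert not np.allclose(SarpNet(seed=4).predict(x, psi), SarpNet(seed=5).predict(x, psi))

    def test_relu_embedding_variant_runs(self, rng):
        net = SarpNet(SarpNetConfig(point_activation="relu"), seed=0)
        x, psi = _inputs(rng, n=9)
        assert net.predict(x, psi).shape == (9,)
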