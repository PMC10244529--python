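"""Grid-wise attention: partition/ungrid geometry, attention normalisation,
squeeze-and-expand pooling, and the LGFE bottleneck."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hmhn import nn
from hmhn.gwa import (GWABlock, GridSpec, LGFE, LGFEConfig, grid_attention,
                      lgfe_forward, partition_grid, squeeze_expand,
                      ungrid_and_weight)
from hmhn.gwa import _partition, _pad_to_grid, _ungrid
from hmhn.nn.tensor import Tensor

rng = np.random.default_rng(3)


class TestPartition:
    def test_identity_partition(self):
        img = rng.random((3, 224, 224))
        gs = partition_grid(img, GridSpec(1, 1, 224, 224, 3))
        assert gs.grids.shape == (1, 3, 224, 224)
        np.testing.assert_array_equal(gs.grids[0], img)

    def test_exact_divisibility(self):
        img = rng.random((3, 224, 224))
        gs = partition_grid(img, GridSpec(2, 2, 224, 224, 3))
        assert gs.grids.shape == (4, 3, 112, 112)
        assert gs.origins == [(0, 0), (0, 1), (1, 0), (1, 1)]
        np.testing.assert_array_equal(gs.grids[3], img[:, 112:, 112:])

    def test_padding_to_next_multiple(self):
        """3×3 grid on 224² pads to 225² and yields nine 75² cells placed by
        row-major index arithmetic on the padded image."""
        img = rng.random((3, 224, 224))
        spec = GridSpec(3, 3, 224, 224, 3)
        assert (spec.H_pad, spec.W_pad, spec.grid_h) == (225, 225, 75)
        gs = partition_grid(img, spec)
        assert gs.grids.shape == (9, 3, 75, 75)
        padded = np.pad(img, [(0, 0), (0, 1), (0, 1)], mode="reflect")
        for g, (i, j) in zip(gs.grids, gs.origins):
            np.testing.assert_array_equal(
                g, padded[:, 75 * i:75 * (i + 1), 75 * j:75 * (j + 1)])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            partition_grid(rng.random((224, 224)), GridSpec(2, 2, 224, 224, 3))
        with pytest.raises(ValueError):
            GridSpec(0, 2, 224, 224, 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(h=st.integers(1, 5), w=st.integers(1, 5),
           H=st.integers(5, 40), W=st.integers(5, 40),
           policy=st.sampled_from(["reflect", "zero"]))
    def test_ungrid_partition_roundtrip(self, h, w, H, W, policy):
        """ungrid ∘ partition is the identity (bit-exact) after cropping."""
        img = np.random.default_rng(H * 100 + W).random((2, H, W)).astype(np.float32)
        spec = GridSpec(h, w, H, W, 2, policy)
        t = _partition(_pad_to_grid(Tensor(img), spec), spec)
        back = _ungrid(t, spec).numpy()[..., :H, :W]
        np.testing.assert_array_equal(back, img)


class TestAttention:
    def spec(self, p=4, q=4, C=2, hw=(2, 2)):
        return GridSpec(hw[0], hw[1], p * hw[0], q * hw[1], C)

    def test_uniform_rows_for_constant_features(self):
        spec = self.spec()
        feat = np.full((4, 2, 4, 4), 3.7)
        att = grid_attention(feat, spec)
        np.testing.assert_allclose(att, 0.25, atol=1e-7)

    def test_two_by_two_closed_form(self):
        """Identity-patch query with d_k=2 gives softmax([1/√2, 0]) rows."""
        spec = GridSpec(1, 1, 2, 2, 1)
        feat = np.array([[[[1.0, 0.0], [0.0, 1.0]]]])
        att = grid_attention(feat, spec)
        e = np.exp(1 / np.sqrt(2))
        expect = np.array([[e / (e + 1), 1 / (e + 1)],
                           [1 / (e + 1), e / (e + 1)]])
        np.testing.assert_allclose(att[0, 0], expect, atol=1e-6)
        np.testing.assert_allclose(att[0, 0, 0], [0.6698, 0.3302], atol=2e-4)

    def test_rows_sum_to_one_and_values_in_unit_interval(self):
        spec = self.spec(5, 7, 3, (2, 3))
        feat = rng.normal(size=(6, 3, 5, 7)).astype(np.float32)
        att = grid_attention(feat, spec)
        assert att.shape == (6, 3, 5, 5)
        np.testing.assert_allclose(att.sum(-1), 1.0, atol=1e-6)
        assert (att > 0).all() and (att < 1).all()

    def test_channel_permutation_equivariance(self):
        """Permuting feature channels permutes the per-channel grid weights
        identically (the attention path treats channels independently)."""
        from hmhn.gwa import grid_weights

        spec = self.spec(4, 4, 3)
        feat = rng.normal(size=(4, 3, 4, 4))
        perm = [2, 0, 1]
        w1 = grid_weights(feat, spec)
        w2 = grid_weights(feat[:, perm], spec)
        np.testing.assert_allclose(w2, w1[:, perm], atol=1e-7)
        # the weights genuinely discriminate between grids and channels
        assert w1[:, :, 0, 0].std() > 1e-3

    def test_grid_weights_pool_attended_features(self):
        """The grid weight equals the mean of Att·q, not of Att alone (whose
        mean is the constant 1/p for any row-stochastic matrix)."""
        spec = GridSpec(1, 1, 2, 2, 1)
        feat = np.array([[[[1.0, 0.0], [0.5, 2.0]]]])
        from hmhn.gwa import grid_weights

        att = grid_attention(feat, spec)
        expect = (att[0, 0] @ feat[0, 0]).mean()
        got = grid_weights(feat, spec)
        np.testing.assert_allclose(got, expect, atol=1e-7)
        # pooling Att alone would give exactly 1/p = 0.5; the attended pool
        # reflects the feature content instead
        assert abs(got[0, 0, 0, 0] - 0.5) > 1e-2


class TestSqueezeExpand:
    def test_constant_matrix(self):
        spec = GridSpec(1, 1, 2, 2, 1)
        att = np.full((1, 1, 2, 2), 0.77)
        np.testing.assert_allclose(squeeze_expand(att, spec), 0.77)

    def test_direct_mean(self):
        spec = GridSpec(1, 1, 2, 2, 1)
        att = np.array([[[[1.0, 2.0], [3.0, 4.0]]]])
        np.testing.assert_allclose(squeeze_expand(att, spec),
                                   np.full((1, 1, 2, 2), 2.5))

    def test_output_shape_contract(self):
        spec = GridSpec(2, 3, 8, 9, 4)
        att = rng.random((6, 4, 4, 4))
        assert squeeze_expand(att, spec).shape == (6, 4, 4, 3)


class TestUngridAndWeight:
    def test_unit_weights_identity(self):
        img = rng.random((3, 10, 10))
        spec = GridSpec(2, 2, 10, 10, 3)
        w = np.ones((4, 3, 5, 5))
        np.testing.assert_array_equal(ungrid_and_weight(w, img, spec), img)

    def test_zero_weights_annihilate(self):
        img = rng.random((3, 10, 10))
        spec = GridSpec(2, 2, 10, 10, 3)
        out = ungrid_and_weight(np.zeros((4, 3, 5, 5)), img, spec)
        np.testing.assert_array_equal(out, np.zeros_like(img))

    def test_blockwise_scaling_matches_hand_indexing(self):
        img = rng.random((1, 4, 4))
        spec = GridSpec(2, 2, 4, 4, 1)
        scalars = [1.0, 2.0, 3.0, 4.0]
        w = np.stack([np.full((1, 2, 2), s) for s in scalars])
        out = ungrid_and_weight(w, img, spec)
        expect = img.copy()
        expect[:, :2, :2] *= 1.0
        expect[:, :2, 2:] *= 2.0
        expect[:, 2:, :2] *= 3.0
        expect[:, 2:, 2:] *= 4.0
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_grid_count_mismatch_raises(self):
        spec = GridSpec(2, 2, 4, 4, 1)
        with pytest.raises(ValueError):
            ungrid_and_weight(np.ones((3, 1, 2, 2)), rng.random((1, 4, 4)), spec)


class TestLGFE:
    def test_shape_preserved(self):
        nn.manual_seed(0)
        lgfe = LGFE(3, LGFEConfig(4))
        gs = partition_grid(rng.random((3, 12, 12)), GridSpec(2, 2, 12, 12, 3))
        out = lgfe_forward(gs, lgfe)
        assert out.shape == gs.grids.shape

    def test_zero_input_maps_to_zero_in_eval(self):
        """With unit running stats, zero biases and zero input, every layer of
        the bottleneck is exactly zero (LeakyReLU(0) = 0)."""
        nn.manual_seed(0)
        lgfe = LGFE(3, LGFEConfig(2)).eval()
        for conv in (lgfe.net._modules["0"], lgfe.net._modules["3"]):
            conv.bias.data[...] = 0.0
        out = lgfe(Tensor(np.zeros((4, 3, 5, 5), dtype=np.float32))).numpy()
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_naive_per_pixel_oracle(self):
        """Fixed-seed forward equals an independently coded per-pixel
        evaluation of the conv1×1/BN/LeakyReLU stack in eval mode."""
        nn.manual_seed(5)
        lgfe = LGFE(3, LGFEConfig(4)).eval()
        # randomise the BN buffers so the oracle exercises them
        r = np.random.default_rng(0)
        for bn in (lgfe.net._modules["1"], lgfe.net._modules["4"]):
            bn.running_mean[...] = r.normal(size=bn.running_mean.shape)
            bn.running_var[...] = r.random(bn.running_var.shape) + 0.5
            bn.weight.data[...] = r.normal(size=bn.weight.shape)
            bn.bias.data[...] = r.normal(size=bn.bias.shape)
        x = r.normal(size=(2, 3, 4, 4)).astype(np.float32)
        got = lgfe(Tensor(x)).numpy()

        def conv1x1(a, conv):
            w = conv.weight.data[:, :, 0, 0]
            out = np.zeros((a.shape[0], w.shape[0], *a.shape[2:]))
            for n in range(a.shape[0]):
                for co in range(w.shape[0]):
                    for i in range(a.shape[2]):
                        for j in range(a.shape[3]):
                            out[n, co, i, j] = (w[co] * a[n, :, i, j]).sum() + conv.bias.data[co]
            return out

        def bn_eval(a, bn):
            return (bn.weight.data[:, None, None] * (a - bn.running_mean[:, None, None])
                    / np.sqrt(bn.running_var[:, None, None] + bn.eps)
                    + bn.bias.data[:, None, None])

        def lrelu(a):
            return np.where(a > 0, a, 0.01 * a)

        ref = x.astype(np.float64)
        mods = lgfe.net._modules
        ref = lrelu(np.stack([bn_eval(s, mods["1"]) for s in conv1x1(ref, mods["0"])]))
        ref = lrelu(np.stack([bn_eval(s, mods["4"]) for s in conv1x1(ref, mods["3"])]))
        np.testing.assert_allclose(got, ref, atol=1e-4)

    def test_channel_mismatch_raises(self):
        nn.manual_seed(0)
        lgfe = LGFE(3)
        with pytest.raises(ValueError):
            lgfe(Tensor(np.zeros((1, 5, 4, 4), dtype=np.float32)))


class TestGWABlock:
    @pytest.mark.parametrize("hw,size", [((3, 3), 16), ((2, 2), 16), ((3, 3), 20)])
    def test_end_to_end_shape_preserved(self, hw, size):
        nn.manual_seed(1)
        gwa = GWABlock(3, *hw).eval()
        x = rng.random((2, 3, size, size)).astype(np.float32)
        out = gwa(Tensor(x))
        assert out.shape == x.shape
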