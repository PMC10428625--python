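"""Architecture contracts: size formula, RFB/ASPP blocks, backbone taps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cropseg import nn
from cropseg.model import (
    ASPP,
    ConvGeometry,
    ModelConfig,
    build_aspp,
    build_backbone,
    build_mssnet,
    build_rfb,
    conv_output_size,
    shape_trace,
)


class TestConvOutputSize:
    def test_dilated_example(self):
        # (16 + 2*2 - 2*(3-1) - 1)//1 + 1 = 16
        g = ConvGeometry(16, 16, (3, 3), (1, 1), (2, 2), (2, 2))
        assert conv_output_size(g) == (16, 16)

    def test_same_conv_identity(self):
        g = ConvGeometry(16, 16, (3, 3), (1, 1), (1, 1), (1, 1))
        assert conv_output_size(g) == (16, 16)

    def test_strided(self):
        g = ConvGeometry(7, 7, (3, 3), (2, 2), (1, 1), (1, 1))
        assert conv_output_size(g) == (4, 4)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            conv_output_size(ConvGeometry(3, 3, (7, 7), (1, 1), (0, 0), (2, 2)))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        h=st.integers(7, 33),
        k=st.sampled_from([1, 3, 5, 7]),
        s=st.sampled_from([1, 2]),
        p=st.integers(0, 4),
        a=st.sampled_from([1, 2, 4]),
    )
    def test_formula_matches_executed_convolution(self, h, k, s, p, a):
        """Oracle equivalence: the arithmetic agrees with an actual conv run."""
        g = ConvGeometry(h, h, (k, k), (s, s), (p, p), (a, a))
        conv = nn.Conv2d(1, 1, k, stride=s, padding=p, dilation=a,
                         rng=np.random.default_rng(0))
        x = np.zeros((1, 1, h, h), dtype=np.float32)
        try:
            expected = conv_output_size(g)
        except ValueError:
            # dilated kernel does not fit: executed conv yields no output
            extent = a * (k - 1) + 1
            assert h + 2 * p < extent
            return
        out = conv.forward(x)
        assert out.shape[2:] == expected


class TestRFB:
    def test_output_channels(self):
        rfb = build_rfb(256, (1, 3, 5), 768, seed=0)
        y = rfb.forward(np.zeros((1, 256, 16, 16), np.float32))
        assert y.shape == (1, 768, 16, 16)

    def test_branches_preserve_width_and_size(self):
        rfb = build_rfb(256, (1, 3, 5), 768, seed=0)
        b2, b3, b4 = rfb.branch_outputs(np.zeros((1, 256, 16, 16), np.float32))
        for b in (b2, b3, b4):
            assert b.shape == (1, 256, 16, 16)

    def test_dilated_padding_solves_size_preservation(self):
        """Padding of each dilated conv satisfies out == in in the size formula."""
        for d in (1, 3, 5, 7):
            pad = nn.same_padding(3, d)
            g = ConvGeometry(16, 16, (3, 3), (1, 1), (pad, pad), (d, d))
            assert conv_output_size(g) == (16, 16)

    def test_channel_mismatch_raises(self):
        rfb = build_rfb(256, (1, 3, 5), 768, seed=0)
        with pytest.raises(ValueError):
            rfb.forward(np.zeros((1, 64, 16, 16), np.float32))


class TestASPP:
    def test_spatial_preserved_and_fusion_width(self):
        aspp = build_aspp(32, (1, 2, 4, 8), 96, seed=0)
        y = aspp.forward(np.zeros((1, 32, 16, 16), np.float32))
        assert y.shape == (1, 96, 16, 16)

    def test_gradient_flows(self, rng):
        aspp = ASPP(4, (1, 2, 4, 8), 8, rng=rng)
        x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        y = aspp.forward(x, train=True)
        dx = aspp.backward(np.ones_like(y))
        assert dx.shape == x.shape


class TestBackbone:
    def test_reduced_taps_at_128(self):
        cfg = ModelConfig(input_size=128, backbone="reduced")
        bb = build_backbone(cfg)
        low, high = bb.forward(np.zeros((1, 3, 128, 128), np.float32))
        assert low.shape == (1, 64, 32, 32)
        assert high.shape == (1, 256, 8, 8)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=100)


@pytest.fixture(scope="module")
def small_model():
    cfg = ModelConfig(input_size=64, backbone="reduced", rfb_out_channels=96,
                      decoder_channels=(64, 48), seed=5)
    return build_mssnet(cfg)


class TestMSSNet:
    def test_trace_checkpoints_consistent(self, small_model):
        tr = shape_trace(small_model)
        assert tr["backbone_low"] == (16, 16, 64)
        assert tr["backbone_high"] == (4, 4, 256)
        assert tr["rfb_out"] == (4, 4, 96)
        assert tr["post_skip_concat"] == (16, 16, 64 + 64)
        assert tr["logits"] == (64, 64, 3)

    def test_softmax_output_normalized(self, small_model, rng):
        probs = small_model.forward(rng.random((1, 3, 64, 64), dtype=np.float32))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_weights(self):
        cfg = ModelConfig(input_size=64, backbone="reduced", rfb_out_channels=64,
                          decoder_channels=(48, 32), seed=9)
        m1, m2 = build_mssnet(cfg), build_mssnet(cfg)
        for p1, p2 in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_class_channel_permutation_equivariance(self, small_model, rng):
        """Permuting the classifier's output filters permutes the softmax map."""
        x = rng.random((1, 3, 64, 64), dtype=np.float32)
        base = small_model.forward(x)
        perm = np.array([2, 0, 1])
        w, b = small_model.classifier.weight, small_model.classifier.bias
        w_old, b_old = w.value.copy(), b.value.copy()
        try:
            w.value[...] = w_old[perm]
            b.value[...] = b_old[perm]
            permuted = small_model.forward(x)
        finally:
            w.value[...] = w_old
            b.value[...] = b_old
        np.testing.assert_allclose(permuted, base[:, perm], atol=1e-5)
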