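"""Octave-convolution core: resampling primitives, the convolution itself,
and the four-path octave forward, all checked against loop-based oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from octaveqrs.octconv import (
    FrequencyFactorizedMap,
    OctConvLayer,
    average_pool_halve,
    conv1d,
    octconv_forward,
    split_channels,
    upsample_double,
)

from .oracles import conv1d_loops, octconv_loops, pool_mean_of_pairs, upsample_repeat


class TestAveragePoolHalve:
    def test_mean_of_pairs(self):
        x = np.array([[1.0, 3.0, 5.0, 7.0]])
        np.testing.assert_allclose(average_pool_halve(x), [[2.0, 6.0]])

    def test_constant_fixed_point(self):
        x = np.full((3, 10), 4.2)
        np.testing.assert_allclose(average_pool_halve(x), np.full((3, 5), 4.2))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((2, 100))
        expected = np.stack([pool_mean_of_pairs(ch) for ch in x])
        np.testing.assert_allclose(average_pool_halve(x), expected, atol=1e-12)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError, match="even"):
            average_pool_halve(np.zeros((1, 7)))


class TestUpsampleDouble:
    def test_repeats_samples(self):
        np.testing.assert_allclose(upsample_double(np.array([[2.0, 6.0]])), [[2, 2, 6, 6]])

    def test_constant_round_trip(self):
        x = np.full((2, 8), -1.5)
        np.testing.assert_allclose(upsample_double(average_pool_halve(x)), x)

    def test_matches_index_mapping_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((3, 50))
        expected = np.stack([upsample_repeat(ch) for ch in x])
        np.testing.assert_allclose(upsample_double(x), expected)


class TestConv1d:
    def test_identity_kernel(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 20))
        w = np.eye(3)[:, :, None]
        np.testing.assert_allclose(conv1d(x, w), x, atol=1e-12)

    def test_zero_weights_bias_only(self):
        x = np.ones((2, 10))
        y = conv1d(x, np.zeros((4, 2, 3)), bias=np.array([1.0, -2.0, 0.5, 0.0]))
        np.testing.assert_allclose(y, np.tile([[1.0], [-2.0], [0.5], [0.0]], 10))

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 8])
    def test_matches_triple_loop_oracle(self, k):
        rng = np.random.default_rng(k)
        x = rng.standard_normal((2, 12))
        w = rng.standard_normal((3, 2, k))
        b = rng.standard_normal(3)
        np.testing.assert_allclose(conv1d(x, w, b), conv1d_loops(x, w, b), atol=1e-10)

    def test_length_preserved_and_channel_mismatch(self):
        x = np.zeros((2, 16))
        assert conv1d(x, np.zeros((5, 2, 8))).shape == (5, 16)
        with pytest.raises(ValueError, match="channels"):
            conv1d(x, np.zeros((5, 3, 3)))

    def test_batched_matches_per_instance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((4, 2, 10))
        w = rng.standard_normal((3, 2, 5))
        batched = conv1d(x, w)
        for i in range(4):
            np.testing.assert_allclose(batched[i], conv1d(x[i], w), atol=1e-12)


def random_layer(rng, c_in=4, c_out=4, k=3, a_in=0.5, a_out=0.5):
    layer = OctConvLayer.init_glorot(k, c_in, c_out, a_in, a_out, rng)
    # Glorot leaves biases zero; randomize them so oracle checks cover bias
    layer.bias_high = rng.standard_normal(layer.bias_high.shape)
    layer.bias_low = rng.standard_normal(layer.bias_low.shape)
    return layer


class TestOctConvForward:
    def test_alpha_zero_reduces_to_vanilla(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal((4, 16))
        w = rng.standard_normal((6, 4, 5))
        b = rng.standard_normal(6)
        layer = OctConvLayer.from_vanilla(w, b, alpha_in=0.0, alpha_out=0.0)
        out = octconv_forward(FrequencyFactorizedMap(high=x, low=None, alpha=0.0), layer)
        assert out.low is None
        assert np.max(np.abs(out.high - conv1d(x, w, b))) <= 1e-6

    def test_zero_weights_zero_output(self):
        x = np.random.default_rng(3).standard_normal((4, 8))
        layer = OctConvLayer(3, 4, 4, alpha_in=0.0, alpha_out=0.5)
        out = octconv_forward(FrequencyFactorizedMap(high=x, low=None, alpha=0.0), layer)
        np.testing.assert_allclose(out.high, 0.0)
        np.testing.assert_allclose(out.low, 0.0)

    def test_matches_equation_oracle(self):
        rng = np.random.default_rng(31)
        layer = random_layer(rng, c_in=4, c_out=4, k=3)
        xh = rng.standard_normal((2, 8))
        xl = rng.standard_normal((2, 4))
        out = octconv_forward(FrequencyFactorizedMap(high=xh, low=xl, alpha=0.5), layer)
        eh, el = octconv_loops(xh, xl, layer)
        np.testing.assert_allclose(out.high, eh, atol=1e-8)
        np.testing.assert_allclose(out.low, el, atol=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_agreement_random_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        k = int(rng.choice([1, 3, 5, 8]))
        c_in = int(rng.integers(2, 9))
        c_out = int(rng.integers(2, 9))
        length = int(rng.choice([8, 12, 16]))
        a_in = float(rng.choice([0.25, 0.5, 0.75]))
        a_out = float(rng.choice([0.25, 0.5, 0.75]))
        layer = random_layer(rng, c_in, c_out, k, a_in, a_out)
        ih, il = split_channels(c_in, a_in)
        xh = rng.standard_normal((ih, length)) if ih else None
        xl = rng.standard_normal((il, length // 2)) if il else None
        out = octconv_forward(FrequencyFactorizedMap(high=xh, low=xl, alpha=a_in), layer)
        eh, el = octconv_loops(xh, xl, layer)
        if eh is not None:
            np.testing.assert_allclose(out.high, eh, atol=1e-8)
        if el is not None:
            np.testing.assert_allclose(out.low, el, atol=1e-8)

    def test_alpha_mismatch_rejected(self):
        layer = OctConvLayer(3, 4, 4, alpha_in=0.5, alpha_out=0.5)
        x = FrequencyFactorizedMap(high=np.zeros((4, 8)), low=None, alpha=0.0)
        with pytest.raises(ValueError, match="alpha"):
            octconv_forward(x, layer)

    def test_odd_high_length_rejected_when_pooling_needed(self):
        layer = OctConvLayer(3, 4, 4, alpha_in=0.0, alpha_out=0.5)
        x = FrequencyFactorizedMap(high=np.zeros((4, 7)), low=None, alpha=0.0)
        with pytest.raises(ValueError, match="even"):
            octconv_forward(x, layer)


class TestInvariants:
    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.5, 0.75])
    def test_parameter_conservation(self, alpha):
        rng = np.random.default_rng(7)
        layer = OctConvLayer.init_glorot(5, 64, 128, alpha, alpha, rng)
        assert layer.num_parameters == 64 * 128 * 5 + 128

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.75])
    def test_length_preserved(self, alpha):
        rng = np.random.default_rng(8)
        layer = random_layer(rng, 4, 4, 5, alpha, alpha)
        ih, il = split_channels(4, alpha)
        x = FrequencyFactorizedMap(
            high=rng.standard_normal((ih, 16)),
            low=rng.standard_normal((il, 8)),
            alpha=alpha,
        )
        out = octconv_forward(x, layer)
        assert out.high.shape[-1] == 16

    def test_linearity_with_zero_bias(self):
        rng = np.random.default_rng(9)
        layer = OctConvLayer.init_glorot(3, 4, 4, 0.5, 0.5, rng)
        xh = rng.standard_normal((2, 12))
        xl = rng.standard_normal((2, 6))
        one = octconv_forward(FrequencyFactorizedMap(high=xh, low=xl, alpha=0.5), layer)
        scaled = octconv_forward(
            FrequencyFactorizedMap(high=3.0 * xh, low=3.0 * xl, alpha=0.5), layer
        )
        np.testing.assert_allclose(scaled.high, 3.0 * one.high, atol=1e-9)
        np.testing.assert_allclose(scaled.low, 3.0 * one.low, atol=1e-9)

    def test_channel_split_round(self):
        assert split_channels(128, 0.25) == (96, 32)
        assert split_channels(64, 0.75) == (16, 48)
        assert split_channels(10, 0.0) == (10, 0)
        assert split_channels(10, 1.0) == (0, 10)


finite_maps = hnp.arrays(
    np.float64,
    st.tuples(st.integers(1, 4), st.integers(1, 16).map(lambda n: 2 * n)),
    elements=st.floats(-1e6, 1e6),
)


class TestResamplingProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(finite_maps)
    def test_pool_of_upsample_is_identity(self, x):
        np.testing.assert_allclose(average_pool_halve(upsample_double(x)), x, rtol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(finite_maps)
    def test_upsample_of_pool_preserves_pair_means(self, x):
        y = upsample_double(average_pool_halve(x))
        pairs = x.reshape(x.shape[0], -1, 2).mean(axis=-1)
        np.testing.assert_allclose(
            y.reshape(x.shape[0], -1, 2).mean(axis=-1), pairs, rtol=1e-12
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(finite_maps, st.floats(-10, 10))
    def test_pool_and_upsample_are_linear(self, x, scale):
        np.testing.assert_allclose(
            average_pool_halve(scale * x), scale * average_pool_halve(x), rtol=1e-9, atol=1e-6
        )
        np.testing.assert_allclose(
            upsample_double(scale * x), scale * upsample_double(x), rtol=1e-9, atol=1e-6
        )
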