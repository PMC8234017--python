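"""Convolution lowering: output sizes, im2col, tiled matmul, layers, pooling."""

import numpy as np
import pytest

from agemm.fixed_point import requantize_array
from agemm.fixtures import gen_backbone_table, gen_layer
from agemm.lowering import (
    LayerConfig,
    Tensor,
    conv_layer,
    filters_to_matrix,
    im2col,
    lower,
    maxpool,
    output_size,
    tiled_matmul,
    upsample,
)
from agemm.cost import layer_invocations
from agemm.multipliers import make_multiplier

from _oracles import conv_loop, matmul_loop


@pytest.mark.parametrize(
    "I, F, S, layer_type, O",
    [
        (416, 3, 2, "conv", 208),
        (104, 3, 1, "conv", 104),
        (13, 1, 1, "conv", 13),
        (104, 2, 2, "pool", 52),
        (13, 2, 0.5, "upsample", 26),
    ],
)
def test_output_size(I, F, S, layer_type, O):
    assert output_size(I, F, S, layer_type) == O


def test_output_size_rejects_fractional_pool():
    with pytest.raises(ValueError):
        output_size(13, 2, 2, "pool")


def test_layer_config_validates_output():
    with pytest.raises(ValueError):
        LayerConfig("conv", I=416, C=3, F=3, S=2, K=32, O=100)


def test_backbone_table_rows_validate():
    cfgs = gen_backbone_table()
    assert len(cfgs) == 25
    first = cfgs[0]
    assert (first.layer_type, first.I, first.C, first.F, first.S, first.K, first.O) == (
        "conv", 416, 3, 3, 2, 32, 208,
    )


class TestIm2col:
    def test_1x1_filter_is_a_reshape(self):
        x = Tensor(np.arange(16, dtype=np.int64).reshape(1, 4, 4))
        m = im2col(x, F=1, S=1)
        assert m.shape == (1, 16)
        np.testing.assert_array_equal(m[0], np.arange(16))

    def test_2x2_input_3x3_filter_corners(self):
        x = Tensor(np.ones((1, 2, 2), dtype=np.int64))
        m = im2col(x, F=3, S=1)
        assert m.shape == (9, 4)
        # every padded corner patch sees exactly the four real pixels
        assert (m != 0).sum(axis=0).tolist() == [4, 4, 4, 4]

    def test_zero_tensor(self):
        x = Tensor(np.zeros((3, 5, 5), dtype=np.int64))
        assert not im2col(x, F=3, S=1).any()

    def test_channel_major_order(self):
        # the center output position's patch covers the whole 3x3 input,
        # so its column equals the channel-major flattened tensor
        x = Tensor(np.arange(2 * 3 * 3, dtype=np.int64).reshape(2, 3, 3))
        m = im2col(x, F=3, S=1)
        assert m.shape == (18, 9)
        np.testing.assert_array_equal(m[:, 4], x.payloads.ravel())


class TestFilterMatrix:
    def test_shapes_and_roundtrip(self):
        rng = np.random.default_rng(0)
        filters = rng.integers(-100, 100, (5, 2, 3, 3))
        fm = filters_to_matrix(filters)
        assert fm.shape == (5, 18)
        np.testing.assert_array_equal(fm.reshape(5, 2, 3, 3), filters)

    def test_delta_filter(self):
        filters = np.zeros((1, 2, 3, 3), dtype=np.int64)
        filters[0, 1, 2, 0] = 7  # channel-major index 1*9 + 2*3 + 0
        fm = filters_to_matrix(filters)
        assert fm[0, 15] == 7 and (fm != 0).sum() == 1

    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            filters_to_matrix(np.zeros((2, 3, 3)))


class TestTiledMatmul:
    def test_single_tile_single_call(self):
        x, filters, cfg = gen_layer(0, I=2, C=1, F=2, S=1, K=4)
        lm = lower(x, filters, 1)
        mul = make_multiplier("exact")
        tiled_matmul(lm, mul)
        assert mul.calls == 64  # one gemm_update

    def test_matches_loop_oracle_and_count_formula(self):
        for seed in range(5):
            x, filters, cfg = gen_layer(seed, I=6, C=2, F=3, S=1, K=5)
            lm = lower(x, filters, 1)
            mul = make_multiplier("exact")
            out = tiled_matmul(lm, mul)
            fm = lm.filter_matrix[: lm.K, : lm.CF2].tolist()
            im = lm.input_matrix[: lm.CF2, : lm.O**2].tolist()
            assert out.tolist() == matmul_loop(fm, im)
            assert mul.calls == 64 * layer_invocations(cfg)


class TestConvLayer:
    def test_identity_1x1_filter(self):
        x, _, _ = gen_layer(1, I=5, C=1, F=1, S=1, K=1)
        filters = np.full((1, 1, 1, 1), 4096, dtype=np.int64)  # 1.0 in Q(16,12)
        cfg = LayerConfig("conv", I=5, C=1, F=1, S=1, K=1, O=5)
        y = conv_layer(x, filters, cfg, make_multiplier("exact"), activation="identity")
        np.testing.assert_array_equal(y.payloads, x.payloads)

    def test_zero_filters(self):
        x, filters, cfg = gen_layer(2, I=4, C=2, F=3, S=1, K=3)
        y = conv_layer(x, np.zeros_like(filters), cfg, make_multiplier("exact"))
        assert not y.payloads.any()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_convolution(self, seed):
        x, filters, cfg = gen_layer(seed, I=8, C=2, F=3, S=1, K=4)
        y = conv_layer(x, filters, cfg, make_multiplier("exact"), activation="identity")
        ref = conv_loop(x.payloads.tolist(), filters.tolist(), 1)
        ref = requantize_array(np.array(ref), 24)
        np.testing.assert_array_equal(y.payloads, ref)

    def test_leaky_relu_scales_negatives_only(self):
        x, _, _ = gen_layer(1, I=4, C=1, F=1, S=1, K=1)
        filters = np.full((1, 1, 1, 1), 4096, dtype=np.int64)
        cfg = LayerConfig("conv", I=4, C=1, F=1, S=1, K=1, O=4)
        y = conv_layer(x, filters, cfg, make_multiplier("exact"), activation="leaky_relu")
        p = x.payloads
        slope = 409  # floor(0.1 * 2^12)
        expected = np.where(p >= 0, p, (p * slope) >> 12)
        np.testing.assert_array_equal(y.payloads, expected)

    def test_mitchell_deviation_shrinks_with_trunc_width(self):
        """Wider dynamic truncation gives outputs closer to the exact path."""
        from agemm.multipliers import Multiplier, MultiplierSpec

        x, filters, cfg = gen_layer(5, I=8, C=2, F=3, S=1, K=4)
        exact = conv_layer(x, filters, cfg, make_multiplier("exact"), activation="identity")
        devs = []
        for w in (3, 6, 12):
            mul = Multiplier(MultiplierSpec("mitchell_dynamic_trunc", trunc_width=w))
            y = conv_layer(x, filters, cfg, mul, activation="identity")
            devs.append(np.abs(y.payloads - exact.payloads).mean())
        assert devs[0] >= devs[1] >= devs[2]
        assert devs[2] / 32767 < 0.05  # bounded relative deviation

    def test_shape_validation(self):
        x, filters, cfg = gen_layer(0, I=8, C=2, F=3, S=1, K=4)
        with pytest.raises(ValueError):
            conv_layer(x, filters[:, :1], cfg, make_multiplier("exact"))


class TestPoolingAndUpsampling:
    def test_maxpool_block(self):
        x = Tensor(np.array([[[1, 2], [3, 4]]], dtype=np.int64))
        assert maxpool(x).payloads.tolist() == [[[4]]]

    def test_constant_tensors(self):
        x = Tensor(np.full((2, 4, 4), 9, dtype=np.int64))
        assert (maxpool(x).payloads == 9).all() and maxpool(x).shape == (2, 2, 2)
        assert (upsample(x).payloads == 9).all() and upsample(x).shape == (2, 8, 8)

    def test_upsample_of_pool_restores_shape(self):
        x = Tensor(np.arange(32, dtype=np.int64).reshape(2, 4, 4))
        assert upsample(maxpool(x)).shape == x.shape

    def test_odd_pooling_rejected(self):
        with pytest.raises(ValueError):
            maxpool(Tensor(np.zeros((1, 3, 4), dtype=np.int64)))

    def test_no_multiplications(self):
        # pooling and upsampling never touch the multiplier counter
        x = Tensor(np.arange(32, dtype=np.int64).reshape(2, 4, 4))
        mul = make_multiplier("exact")
        maxpool(x)
        upsample(x)
        assert mul.calls == 0
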