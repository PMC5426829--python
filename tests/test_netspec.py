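"""Network graph: builder contracts, shape inference, parameter counts."""

import math

import numpy as np
import pytest

import deepcount as dc
from deepcount.netspec import (LayerSpec, NetworkSpec, ShapeError, SAME, VALID)


def _oracle_shapes(spec, input_size):
    """Independent per-layer shape arithmetic (plain loops, no shared code
    with infer_shapes beyond the padding convention definition)."""
    shapes = {}
    for n in spec.nodes:
        if n.kind == "input":
            shapes[n.name] = (input_size, input_size, 3)
            continue
        src = [shapes[i] for i in n.inputs]
        h, w = src[0][0], src[0][1] if len(src[0]) == 3 else (None, None)
        if n.kind in ("conv", "maxpool", "avgpool"):
            def out(sz, k):
                if n.padding == "SAME":
                    return math.ceil(sz / n.stride)
                return (sz - k) // n.stride + 1
            oh, ow = out(src[0][0], n.kernel[0]), out(src[0][1], n.kernel[1])
            c = n.out_channels if n.kind == "conv" else src[0][2]
            shapes[n.name] = (oh, ow, c)
        elif n.kind == "concat":
            shapes[n.name] = (src[0][0], src[0][1], sum(s[2] for s in src))
        elif n.kind == "flatten":
            shapes[n.name] = (src[0][0] * src[0][1] * src[0][2],)
        elif n.kind == "fc":
            shapes[n.name] = (n.out_channels,)
        else:
            shapes[n.name] = src[0]
    return shapes


class TestDeepcountBuilder:
    def test_stem_maps_rgb_to_64_feature_maps(self):
        spec = dc.build_deepcount_network(1.0, 128)
        stem = spec.node("stem_7x7")
        assert stem.kernel == (7, 7) and stem.stride == 2
        assert stem.out_channels == 64
        assert dc.infer_shapes(spec)["stem_7x7"] == (64, 64, 64)

    def test_head_fc_width_768_and_dropout_keep(self):
        spec = dc.build_deepcount_network(1.0, 128)
        assert spec.node("head_fc").out_channels == 768
        assert spec.node("head_dropout").keep_prob == pytest.approx(0.65)

    def test_a_module_projection_is_192_channels(self):
        spec = dc.build_deepcount_network(1.0, 128)
        assert spec.node("a1_proj").out_channels == 192
        assert spec.node("a2_proj").out_channels == 192

    def test_reduction_widens_by_256_and_halves_space(self):
        spec = dc.build_deepcount_network(1.0, 128)
        shapes = dc.infer_shapes(spec)
        h_in, w_in, c_in = shapes["a2_relu"]
        h_out, w_out, c_out = shapes["red_concat"]
        assert c_out == c_in + 256
        assert h_out == (h_in - 3) // 2 + 1 == 15

    def test_batchnorm_follows_every_conv(self):
        for spec in (dc.build_deepcount_network(0.5, 64),
                     dc.build_shallow_network(64)):
            consumers = {}
            for n in spec.nodes:
                for i in n.inputs:
                    consumers.setdefault(i, []).append(n.kind)
            for n in spec.nodes:
                if n.kind == "conv":
                    assert consumers[n.name] == ["batchnorm"], n.name
            spec.validate()

    def test_width_multiplier_scales_parameter_count(self):
        counts = [dc.count_parameters(dc.build_deepcount_network(wm, 64))
                  for wm in (0.25, 0.5, 1.0)]
        assert counts[0] < counts[1] < counts[2]

    def test_input_too_small_raises(self):
        with pytest.raises(ValueError):
            dc.build_deepcount_network(1.0, 16)


class TestShallowBuilder:
    def test_two_convs_two_fcs_scalar_output(self):
        spec = dc.build_shallow_network(64)
        kinds = [n.kind for n in spec.nodes]
        assert kinds.count("conv") == 2
        assert kinds.count("fc") == 2
        assert spec.nodes[-1].kind == "fc" and spec.nodes[-1].out_channels == 1

    def test_forward_smoke_three_finite_values(self):
        spec = dc.build_shallow_network(32)
        params = dc.xavier_init(spec, 1)
        x = np.random.default_rng(0).integers(0, 256, (3, 32, 32, 3),
                                              dtype=np.uint8)
        out = dc.forward(spec, params, x)
        assert out.shape == (3,)
        assert np.all(np.isfinite(out))


class TestShapeInference:
    @pytest.mark.parametrize("size", [32, 64, 128])
    @pytest.mark.parametrize("builder,kw", [
        (dc.build_deepcount_network, {"width_multiplier": 0.5}),
        (dc.build_shallow_network, {}),
    ])
    def test_agrees_with_independent_oracle(self, size, builder, kw):
        spec = builder(input_size=size, **kw)
        assert dc.infer_shapes(spec, size) == _oracle_shapes(spec, size)

    def test_valid_stride2_shrink(self):
        spec = NetworkSpec("t", 32, [
            LayerSpec("input", "input"),
            LayerSpec("p", "maxpool", ("input",), kernel=(3, 3), stride=2,
                      padding=VALID),
        ])
        assert dc.infer_shapes(spec)["p"] == (15, 15, 3)

    def test_residual_channel_mismatch_raises_naming_node(self):
        spec = NetworkSpec("t", 16, [
            LayerSpec("input", "input"),
            LayerSpec("c", "conv", ("input",), kernel=(1, 1), out_channels=5),
            LayerSpec("c_bn", "batchnorm", ("c",)),
            LayerSpec("bad_add", "residual_add", ("input", "c_bn")),
        ])
        with pytest.raises(ShapeError, match="bad_add"):
            dc.infer_shapes(spec)


class TestParameterCount:
    def test_pointwise_conv(self):
        spec = NetworkSpec("t", 16, [
            LayerSpec("input", "input"),
            LayerSpec("up", "conv", ("input",), kernel=(1, 1), out_channels=64),
            LayerSpec("up_bn", "batchnorm", ("up",)),
            LayerSpec("c", "conv", ("up_bn",), kernel=(1, 1), out_channels=32),
            LayerSpec("c_bn", "batchnorm", ("c",)),
        ])
        # 1·1·64·32 kernel weights, no conv bias
        assert dc.count_parameters(spec) == (3 * 64 + 2 * 64) + 2048 + 2 * 32

    def test_fc_with_bias(self):
        spec = NetworkSpec("t", 16, [
            LayerSpec("input", "input"),
            LayerSpec("f", "flatten", ("input",)),
            LayerSpec("fc", "fc", ("f",), out_channels=768),
        ])
        d = 16 * 16 * 3
        assert dc.count_parameters(spec) == d * 768 + 768


def test_json_roundtrip():
    spec = dc.build_deepcount_network(0.5, 64)
    again = NetworkSpec.from_json(spec.to_json())
    assert again.nodes == spec.nodes
    assert again.input_size == spec.input_size


def test_validate_rejects_conv_without_batchnorm():
    spec = NetworkSpec("t", 16, [
        LayerSpec("input", "input"),
        LayerSpec("c", "conv", ("input",), kernel=(3, 3), out_channels=4),
        LayerSpec("r", "relu", ("c",)),
        LayerSpec("f", "flatten", ("r",)),
        LayerSpec("o", "fc", ("f",), out_channels=1),
    ])
    with pytest.raises(ValueError, match="batchnorm"):
        spec.validate()


class TestForwardContract:
    def test_inference_deterministic_and_permutation_equivariant(self):
        spec = dc.build_deepcount_network(0.25, 32)
        params = dc.xavier_init(spec, 3)
        rng = np.random.default_rng(4)
        x = rng.integers(0, 256, (6, 32, 32, 3), dtype=np.uint8)
        out1 = dc.forward(spec, params, x)
        out2 = dc.forward(spec, params, x)
        np.testing.assert_array_equal(out1, out2)
        perm = rng.permutation(6)
        np.testing.assert_allclose(dc.forward(spec, params, x[perm]),
                                   out1[perm], rtol=1e-4, atol=1e-4)

    def test_wrong_input_size_raises(self):
        spec = dc.build_deepcount_network(0.25, 32)
        params = dc.xavier_init(spec, 0)
        x = np.zeros((2, 64, 64, 3), dtype=np.uint8)
        with pytest.raises(ShapeError):
            dc.forward(spec, params, x)
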