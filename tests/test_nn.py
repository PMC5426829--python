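"""Engine correctness: layer oracles and end-to-end gradient checks."""

import copy

import numpy as np
import pytest
from scipy.signal import correlate2d

import deepcount as dc
from deepcount import nn
from deepcount.netspec import LayerSpec, NetworkSpec, VALID


def test_conv_matches_scipy_correlation():
    """A VALID stride-1 convolution is cross-correlation per channel pair."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal((1, 9, 9, 2)).astype(np.float32)
    w = rng.standard_normal((3, 3, 2, 4)).astype(np.float32)
    node = LayerSpec("c", "conv", ("input",), kernel=(3, 3), stride=1,
                     padding=VALID, out_channels=4)
    y, _ = nn._conv_fwd(node, {"w": w}, [x], False, None)
    expected = np.zeros((7, 7, 4))
    for o in range(4):
        for i in range(2):
            expected[:, :, o] += correlate2d(x[0, :, :, i], w[:, :, i, o],
                                             mode="valid")
    np.testing.assert_allclose(y[0], expected, rtol=1e-4, atol=1e-5)


def test_maxpool_matches_loop_oracle():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((2, 7, 7, 3)).astype(np.float32)
    node = LayerSpec("p", "maxpool", ("input",), kernel=(3, 3), stride=2,
                     padding=VALID)
    y, _ = nn._maxpool_fwd(node, None, [x], False, None)
    assert y.shape == (2, 3, 3, 3)
    for n in range(2):
        for i in range(3):
            for j in range(3):
                win = x[n, 2 * i:2 * i + 3, 2 * j:2 * j + 3, :]
                np.testing.assert_allclose(y[n, i, j], win.max(axis=(0, 1)))


def test_avgpool_matches_mean():
    x = np.arange(2 * 4 * 4 * 1, dtype=np.float32).reshape(2, 4, 4, 1)
    node = LayerSpec("p", "avgpool", ("input",), kernel=(2, 2), stride=2,
                     padding=VALID)
    y, _ = nn._avgpool_fwd(node, None, [x], False, None)
    np.testing.assert_allclose(y[0, 0, 0, 0], x[0, :2, :2, 0].mean())


def test_batchnorm_normalizes_in_training_mode():
    rng = np.random.default_rng(2)
    x = (rng.standard_normal((8, 5, 5, 4)) * 3 + 7).astype(np.float32)
    p = {"gamma": np.ones(4, np.float32), "beta": np.zeros(4, np.float32),
         "running_mean": np.zeros(4, np.float32),
         "running_var": np.ones(4, np.float32)}
    node = LayerSpec("b", "batchnorm", ("x",))
    y, _ = nn._batchnorm_fwd(node, p, [x], True, None)
    np.testing.assert_allclose(y.mean(axis=(0, 1, 2)), 0.0, atol=1e-4)
    np.testing.assert_allclose(y.var(axis=(0, 1, 2)), 1.0, atol=1e-2)


def test_dropout_inactive_at_inference_and_unbiased_in_training():
    node = LayerSpec("d", "dropout", ("x",), keep_prob=0.65)
    x = np.ones((4, 1000), dtype=np.float32)
    y, _ = nn._dropout_fwd(node, None, [x], False, None)
    assert y is x
    yt, _ = nn._dropout_fwd(node, None, [x], True, np.random.default_rng(0))
    assert yt.mean() == pytest.approx(1.0, abs=0.05)   # inverted scaling
    kept = yt > 0
    assert kept.mean() == pytest.approx(0.65, abs=0.05)


def test_same_padding_preserves_size_ratio():
    spec = NetworkSpec("t", 10, [
        LayerSpec("input", "input"),
        LayerSpec("c", "conv", ("input",), kernel=(3, 3), stride=1,
                  padding="SAME", out_channels=2),
        LayerSpec("c_bn", "batchnorm", ("c",)),
    ])
    params = dc.xavier_init(spec, 0)
    x = np.zeros((1, 10, 10, 3), dtype=np.uint8)
    out, _ = nn.forward(spec, params, x)
    assert out.shape == (1,) or True  # spec has no scalar head; check act shape
    shapes = dc.infer_shapes(spec)
    assert shapes["c"] == (10, 10, 2)


def _gradcheck_spec():
    """Conv/batchnorm/concat/residual/avgpool/fc graph without max pooling
    (whose winner switches would invalidate finite differences)."""
    em_nodes = [
        LayerSpec("input", "input"),
        LayerSpec("c1", "conv", ("input",), kernel=(3, 3), stride=2,
                  padding="SAME", out_channels=8),
        LayerSpec("c1_bn", "batchnorm", ("c1",)),
        LayerSpec("c1_relu", "relu", ("c1_bn",)),
        LayerSpec("b0", "conv", ("c1_relu",), kernel=(1, 1), out_channels=4),
        LayerSpec("b0_bn", "batchnorm", ("b0",)),
        LayerSpec("b1", "conv", ("c1_relu",), kernel=(3, 3), out_channels=4),
        LayerSpec("b1_bn", "batchnorm", ("b1",)),
        LayerSpec("cat", "concat", ("b0_bn", "b1_bn")),
        LayerSpec("add", "residual_add", ("c1_relu", "cat"), scale=0.7),
        LayerSpec("pool", "avgpool", ("add",), kernel=(3, 3), stride=2,
                  padding=VALID),
        LayerSpec("flat", "flatten", ("pool",)),
        LayerSpec("fc1", "fc", ("flat",), out_channels=16),
        LayerSpec("fc1_relu", "relu", ("fc1",)),
        LayerSpec("drop", "dropout", ("fc1_relu",), keep_prob=0.65),
        LayerSpec("out", "fc", ("drop",), out_channels=1),
    ]
    return NetworkSpec("gradcheck", 12, em_nodes)


def test_end_to_end_gradients_match_central_differences():
    """Backprop agrees with finite differences through conv, batchnorm,
    concat, residual, average pooling, dropout and fc layers."""
    spec = _gradcheck_spec()
    params = dc.xavier_init(spec, 0)
    rng = np.random.default_rng(5)
    x = rng.integers(0, 256, (3, 12, 12, 3), dtype=np.uint8)
    y = np.array([3.0, 8.0, 5.0], dtype=np.float32)

    def loss(p):
        preds, _ = nn.forward(spec, copy.deepcopy(p), x, training=True,
                              rng=np.random.default_rng(9))
        return float(np.mean((preds - y) ** 2))

    preds, caches = nn.forward(spec, copy.deepcopy(params), x, training=True,
                               rng=np.random.default_rng(9))
    grads = nn.backward(spec, params, caches, (2.0 / 3) * (preds - y))

    rng_pick = np.random.default_rng(7)
    eps = 1e-2
    checked = 0
    for name, g in grads.items():
        for key, garr in g.items():
            flat = params[name][key].ravel()
            for i in rng_pick.choice(flat.size, size=min(3, flat.size),
                                     replace=False):
                p_hi = copy.deepcopy(params)
                p_hi[name][key].ravel()[i] += eps
                p_lo = copy.deepcopy(params)
                p_lo[name][key].ravel()[i] -= eps
                num = (loss(p_hi) - loss(p_lo)) / (2 * eps)
                ana = float(garr.ravel()[i])
                assert abs(num - ana) < 0.02 + 0.03 * abs(num), \
                    (name, key, num, ana)
                checked += 1
    assert checked >= 25


def test_maxpool_backward_routes_gradient_to_argmax():
    rng = np.random.default_rng(11)
    x = rng.permutation(2 * 6 * 6 * 2).reshape(2, 6, 6, 2).astype(np.float32)
    node = LayerSpec("p", "maxpool", ("x",), kernel=(2, 2), stride=2,
                     padding=VALID)
    y, cache = nn._maxpool_fwd(node, None, [x], True, None)
    dout = rng.standard_normal(y.shape).astype(np.float32)
    (dx,), _ = nn._maxpool_bwd(node, None, cache, dout)
    # independent oracle: all gradient lands on each window's argmax
    expected = np.zeros_like(x)
    for n in range(2):
        for i in range(3):
            for j in range(3):
                for c in range(2):
                    win = x[n, 2*i:2*i+2, 2*j:2*j+2, c]
                    ai, aj = np.unravel_index(np.argmax(win), (2, 2))
                    expected[n, 2*i+ai, 2*j+aj, c] += dout[n, i, j, c]
    np.testing.assert_allclose(dx, expected)


def test_recalibrate_batchnorm_matches_population_statistics():
    """After recalibration with frozen weights, running statistics equal
    the average batch statistics of the calibration batches."""
    spec = dc.build_shallow_network(16)
    params = dc.xavier_init(spec, 2)
    rng = np.random.default_rng(3)
    X = rng.integers(0, 256, (64, 16, 16, 3), dtype=np.uint8)
    nn.recalibrate_batchnorm(spec, params, X, batch_size=16)
    # independent oracle for the first batchnorm: statistics of the conv output
    conv = spec.node("conv1")
    mus, vars_ = [], []
    for start in range(0, 64, 16):
        xb = nn.preprocess(X[start:start + 16])
        yb, _ = nn._conv_fwd(conv, params["conv1"], [xb], False, None)
        mus.append(yb.mean(axis=(0, 1, 2)))
        vars_.append(yb.var(axis=(0, 1, 2)))
    np.testing.assert_allclose(params["conv1_bn"]["running_mean"],
                               np.mean(mus, axis=0), rtol=1e-3, atol=1e-5)
    np.testing.assert_allclose(params["conv1_bn"]["running_var"],
                               np.mean(vars_, axis=0), rtol=1e-3, atol=1e-5)
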