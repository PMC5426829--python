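"""NumPy execution engine for :class:`~deepcount.netspec.NetworkSpec`.

Activations are stored NHWC in float32.  Convolutions use im2col views
(stride tricks) feeding a single BLAS matmul per layer, forward and
backward; pooling gradients are scattered with a small loop over the
window offsets.  The engine supports exactly the node kinds the spec
layer emits and is deliberately minimal: no graphs-of-graphs, no lazy
evaluation, no device abstraction.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .netspec import NetworkSpec, LayerSpec, SAME, ShapeError

EPS = 1e-3          # batchnorm variance floor
BN_MOMENTUM = 0.1   # running = (1-m)*running + m*batch


def _pad_amount(size: int, k: int, stride: int, padding: str) -> tuple[int, int]:
    if padding != SAME:
        return 0, 0
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2  # TF convention: extra on the right


def _window_view(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,H,W,C) -> strided view (N,OH,OW,kh,kw,C); no copy."""
    n, h, w, c = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    sn, sh, sw, sc = x.strides
    return as_strided(
        x, (n, oh, ow, kh, kw, c),
        (sn, sh * stride, sw * stride, sh, sw, sc), writeable=False)


def _pad_nhwc(x: np.ndarray, ph: tuple[int, int], pw: tuple[int, int]) -> np.ndarray:
    if ph == (0, 0) and pw == (0, 0):
        return x
    return np.pad(x, ((0, 0), ph, pw, (0, 0)))


def _unpad_nhwc(x: np.ndarray, ph, pw, h: int, w: int) -> np.ndarray:
    if ph == (0, 0) and pw == (0, 0):
        return x
    return x[:, ph[0]:ph[0] + h, pw[0]:pw[0] + w, :]


# ----------------------------------------------------------------------
# per-kind forward/backward.  Each forward returns (y, cache); each
# backward takes (node, params, cache, dout) and returns (dins, grads).


def _conv_fwd(node: LayerSpec, p, xs, training, rng):
    x = xs[0]
    kh, kw = node.kernel
    ph = _pad_amount(x.shape[1], kh, node.stride, node.padding)
    pw = _pad_amount(x.shape[2], kw, node.stride, node.padding)
    xp = _pad_nhwc(x, ph, pw)
    view = _window_view(xp, kh, kw, node.stride)
    n, oh, ow = view.shape[:3]
    cin = x.shape[3]
    col = np.ascontiguousarray(view).reshape(n * oh * ow, kh * kw * cin)
    w2 = p["w"].reshape(kh * kw * cin, node.out_channels)
    y = (col @ w2).reshape(n, oh, ow, node.out_channels)
    cache = (col, x.shape, xp.shape, ph, pw) if training else None
    return y, cache


def _conv_bwd(node: LayerSpec, p, cache, dout):
    col, xshape, xpshape, ph, pw = cache
    kh, kw = node.kernel
    n, oh, ow, cout = dout.shape
    cin = xshape[3]
    d2 = dout.reshape(n * oh * ow, cout)
    dw = (col.T @ d2).reshape(kh, kw, cin, cout)
    dcol = (d2 @ p["w"].reshape(kh * kw * cin, cout).T) \
        .reshape(n, oh, ow, kh, kw, cin)
    dxp = np.zeros(xpshape, dtype=np.float32)
    s = node.stride
    for i in range(kh):
        for j in range(kw):
            dxp[:, i:i + oh * s:s, j:j + ow * s:s, :] += dcol[:, :, :, i, j, :]
    dx = _unpad_nhwc(dxp, ph, pw, xshape[1], xshape[2])
    return [dx], {"w": dw}


def _maxpool_fwd(node: LayerSpec, p, xs, training, rng):
    x = xs[0]
    kh, kw = node.kernel
    ph = _pad_amount(x.shape[1], kh, node.stride, node.padding)
    pw = _pad_amount(x.shape[2], kw, node.stride, node.padding)
    xp = _pad_nhwc(x, ph, pw) if (ph != (0, 0) or pw != (0, 0)) else x
    if xp is x and node.padding == SAME:
        xp = x
    view = _window_view(xp, kh, kw, node.stride)
    y = view.max(axis=(3, 4))
    cache = (view, y, x.shape, xp.shape, ph, pw) if training else None
    return y, cache


def _maxpool_bwd(node: LayerSpec, p, cache, dout):
    view, y, xshape, xpshape, ph, pw = cache
    kh, kw = node.kernel
    s = node.stride
    n, oh, ow = y.shape[:3]
    dxp = np.zeros(xpshape, dtype=np.float32)
    taken = np.zeros(y.shape, dtype=bool)
    for i in range(kh):
        for j in range(kw):
            hit = (view[:, :, :, i, j, :] == y) & ~taken
            taken |= hit
            dxp[:, i:i + oh * s:s, j:j + ow * s:s, :] += np.where(hit, dout, 0.0)
    dx = _unpad_nhwc(dxp, ph, pw, xshape[1], xshape[2])
    return [dx], {}


def _avgpool_fwd(node: LayerSpec, p, xs, training, rng):
    x = xs[0]
    kh, kw = node.kernel
    ph = _pad_amount(x.shape[1], kh, node.stride, node.padding)
    pw = _pad_amount(x.shape[2], kw, node.stride, node.padding)
    xp = _pad_nhwc(x, ph, pw)
    view = _window_view(xp, kh, kw, node.stride)
    y = view.mean(axis=(3, 4), dtype=np.float32)
    cache = (x.shape, xp.shape, ph, pw, y.shape) if training else None
    return y, cache


def _avgpool_bwd(node: LayerSpec, p, cache, dout):
    xshape, xpshape, ph, pw, yshape = cache
    kh, kw = node.kernel
    s = node.stride
    n, oh, ow = yshape[:3]
    share = dout / (kh * kw)
    dxp = np.zeros(xpshape, dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i:i + oh * s:s, j:j + ow * s:s, :] += share
    dx = _unpad_nhwc(dxp, ph, pw, xshape[1], xshape[2])
    return [dx], {}


def _bn_axes(x: np.ndarray) -> tuple:
    return (0, 1, 2) if x.ndim == 4 else (0,)


def _batchnorm_fwd(node: LayerSpec, p, xs, training, rng, momentum=None):
    x = xs[0]
    axes = _bn_axes(x)
    if training or momentum is not None:
        m = BN_MOMENTUM if momentum is None else momentum
        mu = x.mean(axis=axes, dtype=np.float32)
        var = x.var(axis=axes, dtype=np.float32)
        # running statistics are updated in place by the trainer contract
        p["running_mean"] *= (1.0 - m)
        p["running_mean"] += m * mu
        p["running_var"] *= (1.0 - m)
        p["running_var"] += m * var
    else:
        mu = p["running_mean"]
        var = p["running_var"]
    inv_std = 1.0 / np.sqrt(var + EPS)
    xhat = (x - mu) * inv_std
    y = p["gamma"] * xhat + p["beta"]
    cache = (xhat, inv_std) if training else None
    return y.astype(np.float32, copy=False), cache


def _batchnorm_bwd(node: LayerSpec, p, cache, dout):
    xhat, inv_std = cache
    axes = _bn_axes(xhat)
    m = float(np.prod([xhat.shape[a] for a in axes]))
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dx = (p["gamma"] * inv_std) * (
        dout - dbeta / m - xhat * (dgamma / m))
    return [dx.astype(np.float32, copy=False)], {"gamma": dgamma, "beta": dbeta}


def _relu_fwd(node, p, xs, training, rng):
    y = np.maximum(xs[0], 0.0)
    return y, (y if training else None)


def _relu_bwd(node, p, cache, dout):
    return [np.where(cache > 0.0, dout, 0.0)], {}


def _fc_fwd(node, p, xs, training, rng):
    x = xs[0]
    y = x @ p["w"] + p["b"]
    return y, (x if training else None)


def _fc_bwd(node, p, cache, dout):
    x = cache
    return [dout @ p["w"].T], {"w": x.T @ dout, "b": dout.sum(axis=0)}


def _dropout_fwd(node, p, xs, training, rng):
    x = xs[0]
    if not training or node.keep_prob >= 1.0:
        return x, None
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    mask = (rng.random(x.shape, dtype=np.float32) < node.keep_prob)
    scale = np.float32(1.0 / node.keep_prob)
    return x * mask * scale, (mask, scale)


def _dropout_bwd(node, p, cache, dout):
    if cache is None:
        return [dout], {}
    mask, scale = cache
    return [dout * mask * scale], {}


def _flatten_fwd(node, p, xs, training, rng):
    x = xs[0]
    return x.reshape(x.shape[0], -1), (x.shape if training else None)


def _flatten_bwd(node, p, cache, dout):
    return [dout.reshape(cache)], {}


def _concat_fwd(node, p, xs, training, rng):
    widths = [x.shape[-1] for x in xs]
    return np.concatenate(xs, axis=-1), (widths if training else None)


def _concat_bwd(node, p, cache, dout):
    splits = np.cumsum(cache[:-1])
    return list(np.split(dout, splits, axis=-1)), {}


def _residual_fwd(node, p, xs, training, rng):
    a, b = xs
    if a.shape != b.shape:
        raise ShapeError(
            f"{node.name}: residual operands {a.shape} vs {b.shape}")
    return a + np.float32(node.scale) * b, None


def _residual_bwd(node, p, cache, dout):
    return [dout, np.float32(node.scale) * dout], {}


_FWD = {
    "conv": _conv_fwd, "maxpool": _maxpool_fwd, "avgpool": _avgpool_fwd,
    "batchnorm": _batchnorm_fwd, "relu": _relu_fwd, "fc": _fc_fwd,
    "dropout": _dropout_fwd, "flatten": _flatten_fwd, "concat": _concat_fwd,
    "residual_add": _residual_fwd,
}
_BWD = {
    "conv": _conv_bwd, "maxpool": _maxpool_bwd, "avgpool": _avgpool_bwd,
    "batchnorm": _batchnorm_bwd, "relu": _relu_bwd, "fc": _fc_bwd,
    "dropout": _dropout_bwd, "flatten": _flatten_bwd, "concat": _concat_bwd,
    "residual_add": _residual_bwd,
}


def preprocess(images: np.ndarray) -> np.ndarray:
    """uint8 RGB batch -> float32 in [-1, 1]."""
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    if x.shape[-1] != 3:
        raise ShapeError(f"expected H×W×3 images, got shape {x.shape}")
    return (x.astype(np.float32) / 127.5) - 1.0


def forward(spec: NetworkSpec, params: Mapping[str, dict], images: np.ndarray,
            training: bool = False, rng: np.random.Generator | None = None,
            bn_momentum: float | None = None):
    """Run the graph; returns (predictions, caches).

    ``predictions`` is a 1-D float vector, one count per image.  The
    caches dict (one entry per node, populated only in training mode)
    feeds :func:`backward`.  ``bn_momentum`` overrides the batchnorm
    running-statistics update (used for post-training recalibration,
    where batch statistics are consumed even outside training mode).
    """
    x = preprocess(images)
    if x.shape[1] != spec.input_size or x.shape[2] != spec.input_size:
        raise ShapeError(
            f"input: expected {spec.input_size}×{spec.input_size} images, "
            f"got {x.shape[1]}×{x.shape[2]}")
    acts: dict[str, np.ndarray] = {}
    caches: dict[str, object] = {}
    for node in spec.nodes:
        if node.kind == "input":
            acts[node.name] = x
            continue
        xs = [acts[i] for i in node.inputs]
        if node.kind == "batchnorm":
            y, c = _batchnorm_fwd(node, params.get(node.name), xs, training,
                                  rng, bn_momentum)
        else:
            y, c = _FWD[node.kind](node, params.get(node.name), xs, training, rng)
        acts[node.name] = y
        caches[node.name] = c
    out = acts[spec.output][:, 0]
    if training:
        caches["__acts__"] = acts
    return out, caches


def backward(spec: NetworkSpec, params: Mapping[str, dict], caches: dict,
             dout: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
    """Backpropagate d(loss)/d(output) through the graph.

    Returns gradients for every trainable array, keyed like ``params``.
    """
    grads: dict[str, dict[str, np.ndarray]] = {}
    dacts: dict[str, np.ndarray] = {spec.output: dout[:, None].astype(np.float32)}
    for node in reversed(spec.nodes):
        if node.kind == "input":
            continue
        d = dacts.pop(node.name, None)
        if d is None:
            continue
        dins, g = _BWD[node.kind](node, params.get(node.name), caches[node.name], d)
        if g:
            grads[node.name] = g
        for name, di in zip(node.inputs, dins):
            if name in dacts:
                dacts[name] = dacts[name] + di
            else:
                dacts[name] = di
    return grads


def recalibrate_batchnorm(spec: NetworkSpec, params: Mapping[str, dict],
                          images: np.ndarray, batch_size: int = 64,
                          max_batches: int = 16) -> None:
    """Recompute batchnorm running statistics with frozen weights.

    During training the running statistics trail the rapidly moving
    weights; this replaces them, in place, with the average batch
    statistics of up to ``max_batches`` forward passes (momentum 1/k
    yields the exact running average).  Dropout stays inactive.
    """
    for arrs in params.values():
        if "running_mean" in arrs:
            arrs["running_mean"][:] = 0.0
            arrs["running_var"][:] = 0.0
    n = len(images)
    k = 0
    for start in range(0, n, batch_size):
        if k >= max_batches:
            break
        k += 1
        forward(spec, params, images[start:start + batch_size],
                training=False, bn_momentum=1.0 / k)
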