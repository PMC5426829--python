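"""Training loop for the counting networks.

The recipe is fixed by design: Xavier (Glorot) initialization, Adam at a
constant learning rate of 1e-3, mean-squared-error cost on the raw
(unrounded) count, dropout with keep probability 0.65 on the hidden
fully connected layer, batch normalization after every convolution, and
an exponential moving average (EMA) of the weights used at evaluation
time.  Three epochs suffice: the synthetic counting task converges
quickly.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .netspec import NetworkSpec, infer_shapes

TRAINABLE_KEYS = ("w", "b", "gamma", "beta")

ParameterSet = dict  # node name -> {array name -> ndarray}


@dataclass
class TrainConfig:
    epochs: int = 3
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    batch_size: int = 64
    dropout_keep: float = 0.65
    ema_decay: float = 0.999
    # TensorFlow-style dynamic EMA: effective decay min(d, (1+t)/(10+t)).
    # Without it the shadow weights stay dominated by the random init for
    # the first ~1/(1-d) steps.
    ema_dynamic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not (0.0 < self.dropout_keep <= 1.0):
            raise ValueError("dropout_keep must be in (0, 1]")
        if not (0.0 <= self.ema_decay < 1.0):
            raise ValueError("ema_decay must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainedModel:
    spec: NetworkSpec
    params: ParameterSet
    ema_params: ParameterSet
    history: list[float]
    config: TrainConfig

    def predict(self, images: np.ndarray, batch_size: int = 256,
                use_ema: bool = True, rounded: bool = False) -> np.ndarray:
        """Predict counts for a batch of uint8 RGB images (EMA weights by
        default; rounding is half-up, for reporting only)."""
        params = self.ema_params if use_ema else self.params
        out = predict(self.spec, params, images, batch_size=batch_size)
        return round_half_up(out) if rounded else out


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from .5 upward (3.5 -> 4)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


# ----------------------------------------------------------------------


def xavier_init(spec: NetworkSpec, seed: int = 0) -> ParameterSet:
    """Glorot-uniform weights (variance 2/(fan_in+fan_out)); zero biases;
    batchnorm scale 1, shift 0, running mean 0 / variance 1."""
    rng = np.random.default_rng(seed)
    shapes = infer_shapes(spec)
    params: ParameterSet = {}
    for node in spec.nodes:
        if node.kind == "conv":
            kh, kw = node.kernel
            cin = shapes[node.inputs[0]][2]
            cout = node.out_channels
            fan_in, fan_out = kh * kw * cin, kh * kw * cout
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, (kh, kw, cin, cout))
            params[node.name] = {"w": w.astype(np.float32)}
        elif node.kind == "fc":
            d = shapes[node.inputs[0]][0]
            m = node.out_channels
            limit = math.sqrt(6.0 / (d + m))
            params[node.name] = {
                "w": rng.uniform(-limit, limit, (d, m)).astype(np.float32),
                "b": np.zeros(m, dtype=np.float32),
            }
        elif node.kind == "batchnorm":
            c = shapes[node.name][-1]
            params[node.name] = {
                "gamma": np.ones(c, dtype=np.float32),
                "beta": np.zeros(c, dtype=np.float32),
                "running_mean": np.zeros(c, dtype=np.float32),
                "running_var": np.ones(c, dtype=np.float32),
            }
    return params


def mse_loss(predictions: Sequence[float], labels: Sequence[float]) -> float:
    """Mean squared error between predicted and actual counts."""
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if p.size == 0:
        raise ValueError("mse_loss of empty vectors is undefined")
    return float(np.mean((p - y) ** 2))


def ema_update(ema: ParameterSet, params: ParameterSet, decay: float
               ) -> ParameterSet:
    """One EMA step on the trainable arrays: decay*ema + (1-decay)*params.

    Returns a new ParameterSet; non-trainable arrays (batchnorm running
    statistics) are carried over from ``params`` so the shadow copy is
    directly usable for inference.
    """
    if not (0.0 <= decay <= 1.0):
        raise ValueError("decay must be in [0, 1]")
    out: ParameterSet = {}
    for name, arrs in params.items():
        out[name] = {}
        for key, arr in arrs.items():
            if key in TRAINABLE_KEYS:
                prev = ema[name][key]
                if prev.shape != arr.shape:
                    raise ValueError(f"{name}.{key}: shape mismatch")
                out[name][key] = decay * prev + (1.0 - decay) * arr
            else:
                out[name][key] = arr.copy()
    return out


class _Adam:
    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: ParameterSet, grads: Mapping) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.adam_beta1 ** self.t
        bc2 = 1.0 - c.adam_beta2 ** self.t
        for name, g in grads.items():
            for key, grad in g.items():
                grad = grad.astype(np.float32, copy=False)
                mk = self.m.setdefault((name, key), np.zeros_like(grad))
                vk = self.v.setdefault((name, key), np.zeros_like(grad))
                mk *= c.adam_beta1
                mk += (1.0 - c.adam_beta1) * grad
                vk *= c.adam_beta2
                vk += (1.0 - c.adam_beta2) * grad * grad
                update = (mk / bc1) / (np.sqrt(vk / bc2) + c.adam_epsilon)
                params[name][key] -= np.float32(c.learning_rate) * update


class DivergenceError(RuntimeError):
    def __init__(self, step: int, loss: float):
        super().__init__(f"non-finite training loss at step {step}: {loss}")
        self.step = step


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    """Accept (X, y) arrays, a sequence of (image, count) pairs, or a
    DatasetManifest; return a uint8 image stack and float labels."""
    from .synthgen import DatasetManifest, load_dataset

    if isinstance(data, DatasetManifest):
        data = list(load_dataset(data))
    if isinstance(data, tuple) and len(data) == 2 and isinstance(data[0], np.ndarray):
        X, y = data
    else:
        pairs = list(data)
        X = np.stack([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
    return np.asarray(X), np.asarray(y, dtype=np.float32)


def _effective_decay(cfg: TrainConfig, t: int) -> float:
    if cfg.ema_dynamic:
        return min(cfg.ema_decay, (1.0 + t) / (10.0 + t))
    return cfg.ema_decay


def train(spec: NetworkSpec, train_data, val_data=None,
          config: TrainConfig | None = None,
          log_every: int = 0) -> TrainedModel:
    """Train ``spec`` on labeled images.

    ``train_data``/``val_data`` may be a DatasetManifest, a sequence of
    (image, count) pairs, or an ``(X, y)`` array pair.  A fixed
    ``config.seed`` fixes initialization, shuffling and dropout masks,
    so loss histories are exactly reproducible.
    """
    config = config or TrainConfig()
    X, y = _as_arrays(train_data)
    if len(X) == 0:
        raise ValueError("training set is empty")
    # the dropout node carries the keep probability; honor the config
    if any(n.kind == "dropout" and n.keep_prob != config.dropout_keep
           for n in spec.nodes):
        from dataclasses import replace
        spec = NetworkSpec(spec.name, spec.input_size, [
            replace(n, keep_prob=config.dropout_keep) if n.kind == "dropout"
            else n for n in spec.nodes])

    root = np.random.SeedSequence(config.seed)
    init_seed, shuffle_seed, dropout_seed = root.generate_state(3) % (2 ** 31)
    params = xavier_init(spec, int(init_seed))
    ema = copy.deepcopy(params)
    opt = _Adam(config)
    shuffle_rng = np.random.default_rng(int(shuffle_seed))
    dropout_rng = np.random.default_rng(int(dropout_seed))

    n = len(X)
    steps_per_epoch = math.ceil(n / config.batch_size)
    history: list[float] = []
    t = 0
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            xb, yb = X[idx], y[idx]
            preds, caches = nn.forward(spec, params, xb, training=True,
                                       rng=dropout_rng)
            loss = mse_loss(preds, yb)
            if not np.isfinite(loss):
                raise DivergenceError(t, loss)
            history.append(loss)
            dout = (2.0 / len(yb)) * (preds - yb)
            grads = nn.backward(spec, params, caches, dout)
            opt.step(params, grads)
            ema = ema_update(ema, params, _effective_decay(config, t))
            t += 1
            if log_every and t % log_every == 0:
                print(f"step {t}/{steps_per_epoch * config.epochs}  "
                      f"train mse {loss:.3f}")
    # batchnorm statistics trail the moving weights; replace them with
    # averaged batch statistics under the final (and EMA) weights
    nn.recalibrate_batchnorm(spec, params, X, batch_size=config.batch_size)
    nn.recalibrate_batchnorm(spec, ema, X, batch_size=config.batch_size)
    model = TrainedModel(spec, params, ema, history, config)
    if val_data is not None and log_every:
        Xv, yv = _as_arrays(val_data)
        print(f"validation mse {mse_loss(model.predict(Xv), yv):.3f}")
    return model


def predict(spec: NetworkSpec, params: ParameterSet, images: np.ndarray,
            batch_size: int = 256) -> np.ndarray:
    """Deterministic inference in batches; returns raw real-valued counts."""
    X = np.asarray(images)
    if X.ndim == 3:
        X = X[None]
    chunks = [
        nn.forward(spec, params, X[i:i + batch_size], training=False)[0]
        for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(chunks)


# ----------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: TrainedModel, out_dir: str | Path) -> Path:
    """Write spec JSON, parameter arrays (npz), EMA arrays, training
    history CSV and the train config to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "spec.json").write_text(model.spec.to_json())
    for fname, pset in (("params.npz", model.params),
                        ("ema_params.npz", model.ema_params)):
        flat = {f"{name}/{key}": arr for name, arrs in pset.items()
                for key, arr in arrs.items()}
        np.savez(out / fname, **flat)
    with open(out / "history.csv", "w") as fh:
        fh.write("step,mse\n")
        fh.writelines(f"{i},{v}\n" for i, v in enumerate(model.history))
    (out / "train_config.json").write_text(json.dumps(asdict(model.config)))
    return out


def load_checkpoint(ckpt_dir: str | Path) -> TrainedModel:
    ckpt = Path(ckpt_dir)
    spec = NetworkSpec.from_json((ckpt / "spec.json").read_text())

    def unflatten(path: Path) -> ParameterSet:
        pset: ParameterSet = {}
        with np.load(path) as z:
            for flat_key in z.files:
                name, key = flat_key.split("/")
                pset.setdefault(name, {})[key] = z[flat_key]
        return pset

    import pandas as pd
    history = pd.read_csv(ckpt / "history.csv")["mse"].tolist()
    cfg = TrainConfig(**json.loads((ckpt / "train_config.json").read_text()))
    return TrainedModel(spec, unflatten(ckpt / "params.npz"),
                        unflatten(ckpt / "ema_params.npz"), history, cfg)
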