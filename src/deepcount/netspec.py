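"""Declarative specification of the counting networks.

A :class:`NetworkSpec` is an ordered DAG of primitive nodes (convolution,
pooling, batch normalization, ReLU, fully connected, dropout, flatten,
concat, residual addition).  The two builders emit the modified
Inception-ResNet count-regression network and the shallow two-conv /
two-fc baseline.  Shape inference, parameter counting and JSON
round-tripping work on the spec alone, without any numerical engine;
:func:`forward` evaluates a spec given a parameter set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

SAME = "SAME"
VALID = "VALID"

_KINDS = {
    "input", "conv", "maxpool", "avgpool", "batchnorm", "relu",
    "fc", "dropout", "flatten", "concat", "residual_add",
}


class ShapeError(ValueError):
    """Raised when a node's input shapes are incompatible with the graph."""


@dataclass(frozen=True)
class LayerSpec:
    """One primitive node of the network graph.

    ``inputs`` names the producing nodes; all kinds take a single input
    except ``concat`` and ``residual_add``.  ``residual_add`` computes
    ``inputs[0] + scale * inputs[1]`` (identity path first).
    """

    name: str
    kind: str
    inputs: tuple[str, ...] = ()
    kernel: tuple[int, int] | None = None
    stride: int = 1
    padding: str = SAME
    out_channels: int | None = None
    keep_prob: float | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kernel is not None and min(self.kernel) < 1:
            raise ValueError(f"{self.name}: kernel dims must be >= 1")
        if self.stride < 1:
            raise ValueError(f"{self.name}: stride must be >= 1")
        if self.padding not in (SAME, VALID):
            raise ValueError(f"{self.name}: padding must be SAME or VALID")
        if self.kind in ("conv", "fc") and (self.out_channels or 0) < 1:
            raise ValueError(f"{self.name}: out_channels must be >= 1")
        if self.kind == "dropout" and not (0.0 < (self.keep_prob or 0.0) <= 1.0):
            raise ValueError(f"{self.name}: keep_prob must be in (0, 1]")


@dataclass(frozen=True)
class InceptionResNetAConfig:
    """Widths of the modified Inception-ResNet-A block.

    Three parallel branches (1x1; 1x1->3x3; 1x1->3x3->3x3) are
    concatenated and linearly projected by a 1x1 convolution back to the
    block's input width so the residual addition is shape-compatible.
    The projection width (192 at full scale) is the block's defining
    modification: the original block projects to 256.
    """

    branch0: int = 32
    branch1: tuple[int, int] = (32, 32)
    branch2: tuple[int, int, int] = (32, 48, 64)
    linear_projection_channels: int = 192
    residual_scale: float = 1.0


@dataclass(frozen=True)
class ReductionConfig:
    """Widths of the modified reduction block.

    Left branch: 3x3 max pool, stride 2, VALID.  Middle branch ends in a
    stride-2 VALID conv of ``middle_out`` channels (128, down from 192).
    Right branch is a 1x1 -> 3x3 -> 3x3 -> stride-2-3x3 chain with widths
    ``right`` (192/128/128/128, down from 256/256/320/320).  Output width
    is input + middle_out + right[-1].
    """

    middle_in: int = 128
    middle_out: int = 128
    right: tuple[int, int, int, int] = (192, 128, 128, 128)


@dataclass
class NetworkSpec:
    """Ordered DAG of named nodes with a single scalar-per-image output."""

    name: str
    input_size: int
    nodes: list[LayerSpec] = field(default_factory=list)

    @property
    def output(self) -> str:
        return self.nodes[-1].name

    def node(self, name: str) -> LayerSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    # --- serialization ------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "input_size": self.input_size,
            "nodes": [asdict(n) for n in self.nodes],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        payload = json.loads(text)
        nodes = []
        for d in payload["nodes"]:
            if d.get("kernel") is not None:
                d["kernel"] = tuple(d["kernel"])
            d["inputs"] = tuple(d["inputs"])
            nodes.append(LayerSpec(**d))
        return cls(payload["name"], payload["input_size"], nodes)

    def validate(self) -> None:
        """Check graph invariants: DAG order, batchnorm after every conv,
        known inputs, scalar output."""
        seen: set[str] = set()
        consumers: dict[str, list[LayerSpec]] = {}
        for n in self.nodes:
            if n.name in seen:
                raise ValueError(f"duplicate node name {n.name!r}")
            for i in n.inputs:
                if i not in seen:
                    raise ValueError(f"{n.name}: input {i!r} not yet defined")
                consumers.setdefault(i, []).append(n)
            seen.add(n.name)
        for n in self.nodes:
            if n.kind == "conv":
                after = consumers.get(n.name, [])
                if len(after) != 1 or after[0].kind != "batchnorm":
                    raise ValueError(
                        f"{n.name}: every convolution must be immediately "
                        "followed by a batchnorm node")
        out = self.nodes[-1]
        if not (out.kind == "fc" and out.out_channels == 1):
            raise ValueError("network output must be a single scalar per image")


# ----------------------------------------------------------------------
# shape arithmetic


def _conv_out(size: int, k: int, stride: int, padding: str) -> int:
    if padding == SAME:
        return math.ceil(size / stride)
    out = (size - k) // stride + 1
    if out < 1:
        raise ShapeError(f"spatial size {size} too small for kernel {k} VALID")
    return out


def infer_shapes(spec: NetworkSpec, input_size: int | None = None
                 ) -> dict[str, tuple[int, ...]]:
    """Annotate every node with its output shape.

    Spatial nodes map to ``(height, width, channels)``; post-flatten
    nodes map to ``(features,)``.  SAME preserves ``ceil(size/stride)``;
    VALID gives ``floor((size - k)/stride) + 1``.
    """
    size = spec.input_size if input_size is None else input_size
    shapes: dict[str, tuple[int, ...]] = {}
    for n in spec.nodes:
        if n.kind == "input":
            shapes[n.name] = (size, size, 3)
            continue
        ins = [shapes[i] for i in n.inputs]
        s = ins[0]
        if n.kind == "conv":
            h = _conv_out(s[0], n.kernel[0], n.stride, n.padding)
            w = _conv_out(s[1], n.kernel[1], n.stride, n.padding)
            shapes[n.name] = (h, w, n.out_channels)
        elif n.kind in ("maxpool", "avgpool"):
            h = _conv_out(s[0], n.kernel[0], n.stride, n.padding)
            w = _conv_out(s[1], n.kernel[1], n.stride, n.padding)
            shapes[n.name] = (h, w, s[2])
        elif n.kind in ("batchnorm", "relu", "dropout"):
            shapes[n.name] = s
        elif n.kind == "flatten":
            shapes[n.name] = (int(np.prod(s)),)
        elif n.kind == "fc":
            if len(s) != 1:
                raise ShapeError(f"{n.name}: fc requires flattened input, got {s}")
            shapes[n.name] = (n.out_channels,)
        elif n.kind == "concat":
            if any(t[:2] != s[:2] for t in ins):
                raise ShapeError(f"{n.name}: concat spatial mismatch {ins}")
            shapes[n.name] = (s[0], s[1], sum(t[2] for t in ins))
        elif n.kind == "residual_add":
            if len(ins) != 2 or ins[0] != ins[1]:
                raise ShapeError(
                    f"{n.name}: residual operands must match, got {ins}")
            shapes[n.name] = s
    return shapes


def count_parameters(spec: NetworkSpec, input_size: int | None = None) -> int:
    """Exact trainable parameter total: conv kernels (bias-free — a
    batchnorm always follows), fc weights + biases, batchnorm scale/shift."""
    shapes = infer_shapes(spec, input_size)
    total = 0
    for n in spec.nodes:
        if n.kind == "conv":
            cin = shapes[n.inputs[0]][2]
            total += n.kernel[0] * n.kernel[1] * cin * n.out_channels
        elif n.kind == "fc":
            d = shapes[n.inputs[0]][0]
            total += d * n.out_channels + n.out_channels
        elif n.kind == "batchnorm":
            c = shapes[n.name][-1]
            total += 2 * c
    return total


# ----------------------------------------------------------------------
# builders


def _ch(c: int, wm: float) -> int:
    return max(1, round(c * wm))


class _Emitter:
    def __init__(self) -> None:
        self.nodes: list[LayerSpec] = []
        self.last = "input"

    def add(self, name: str, kind: str, inputs: Sequence[str] | None = None,
            **kw) -> str:
        inputs = tuple(inputs) if inputs is not None else (self.last,)
        self.nodes.append(LayerSpec(name=name, kind=kind, inputs=inputs, **kw))
        self.last = name
        return name

    def conv_bn(self, name: str, out_channels: int, kernel: tuple[int, int],
                stride: int = 1, padding: str = SAME, relu: bool = True,
                inputs: Sequence[str] | None = None) -> str:
        self.add(name, "conv", inputs, kernel=kernel, stride=stride,
                 padding=padding, out_channels=out_channels)
        self.add(name + "_bn", "batchnorm")
        if relu:
            self.add(name + "_relu", "relu")
        return self.last


def _emit_inception_a(em: _Emitter, prefix: str, in_channels: int,
                      cfg: InceptionResNetAConfig) -> str:
    block_in = em.last
    if cfg.linear_projection_channels != in_channels:
        raise ShapeError(
            f"{prefix}: linear projection must output {in_channels} channels "
            f"to match the residual input, got {cfg.linear_projection_channels}")
    b0 = em.conv_bn(f"{prefix}_b0_1x1", cfg.branch0, (1, 1), inputs=[block_in])
    em.conv_bn(f"{prefix}_b1_1x1", cfg.branch1[0], (1, 1), inputs=[block_in])
    b1 = em.conv_bn(f"{prefix}_b1_3x3", cfg.branch1[1], (3, 3))
    em.conv_bn(f"{prefix}_b2_1x1", cfg.branch2[0], (1, 1), inputs=[block_in])
    em.conv_bn(f"{prefix}_b2_3x3a", cfg.branch2[1], (3, 3))
    b2 = em.conv_bn(f"{prefix}_b2_3x3b", cfg.branch2[2], (3, 3))
    em.add(f"{prefix}_concat", "concat", [b0, b1, b2])
    # linear projection: batchnorm but no ReLU before the residual addition
    proj = em.conv_bn(f"{prefix}_proj", cfg.linear_projection_channels, (1, 1),
                      relu=False)
    em.add(f"{prefix}_add", "residual_add", [block_in, proj],
           scale=cfg.residual_scale)
    return em.add(f"{prefix}_relu", "relu")


def _emit_reduction(em: _Emitter, prefix: str, cfg: ReductionConfig) -> str:
    block_in = em.last
    left = em.add(f"{prefix}_pool", "maxpool", [block_in], kernel=(3, 3),
                  stride=2, padding=VALID)
    em.conv_bn(f"{prefix}_mid_1x1", cfg.middle_in, (1, 1), inputs=[block_in])
    mid = em.conv_bn(f"{prefix}_mid_3x3", cfg.middle_out, (3, 3), stride=2,
                     padding=VALID)
    em.conv_bn(f"{prefix}_right_1x1", cfg.right[0], (1, 1), inputs=[block_in])
    em.conv_bn(f"{prefix}_right_3x3a", cfg.right[1], (3, 3))
    em.conv_bn(f"{prefix}_right_3x3b", cfg.right[2], (3, 3))
    right = em.conv_bn(f"{prefix}_right_3x3c", cfg.right[3], (3, 3), stride=2,
                       padding=VALID)
    return em.add(f"{prefix}_concat", "concat", [left, mid, right])


def build_deepcount_network(width_multiplier: float = 1.0,
                            input_size: int = 128,
                            dropout_keep: float = 0.65) -> NetworkSpec:
    """Build the modified Inception-ResNet counting network.

    Stem: 7x7/2 conv (64·wm maps) -> 3x3/2 max pool -> 1x1 conv -> 5x5
    conv (192·wm); then two modified A blocks, the modified reduction,
    two more A blocks, and the head (3x3 average pool -> fc 768·wm ->
    dropout keep 0.65 -> fc 1).  Batch normalization follows every
    convolution.  ``width_multiplier`` scales every width; 1.0 is the
    full-scale network.
    """
    if width_multiplier <= 0:
        raise ValueError("width_multiplier must be > 0")
    if input_size < 32:
        raise ValueError("input_size must be >= 32")
    wm = width_multiplier
    em = _Emitter()
    em.add("input", "input", inputs=())
    em.conv_bn("stem_7x7", _ch(64, wm), (7, 7), stride=2, padding=SAME)
    em.add("stem_pool", "maxpool", kernel=(3, 3), stride=2, padding=VALID)
    em.conv_bn("stem_1x1", _ch(80, wm), (1, 1))
    em.conv_bn("stem_5x5", _ch(192, wm), (5, 5))

    c = _ch(192, wm)
    a_cfg = InceptionResNetAConfig(
        branch0=_ch(32, wm),
        branch1=(_ch(32, wm), _ch(32, wm)),
        branch2=(_ch(32, wm), _ch(48, wm), _ch(64, wm)),
        linear_projection_channels=c,
    )
    _emit_inception_a(em, "a1", c, a_cfg)
    _emit_inception_a(em, "a2", c, a_cfg)

    red = ReductionConfig(
        middle_in=_ch(128, wm), middle_out=_ch(128, wm),
        right=(_ch(192, wm), _ch(128, wm), _ch(128, wm), _ch(128, wm)))
    _emit_reduction(em, "red", red)

    c2 = c + red.middle_out + red.right[3]
    a_cfg2 = InceptionResNetAConfig(
        branch0=_ch(32, wm),
        branch1=(_ch(32, wm), _ch(32, wm)),
        branch2=(_ch(32, wm), _ch(48, wm), _ch(64, wm)),
        linear_projection_channels=c2,
    )
    _emit_inception_a(em, "a3", c2, a_cfg2)
    _emit_inception_a(em, "a4", c2, a_cfg2)

    em.add("head_pool", "avgpool", kernel=(3, 3), stride=2, padding=VALID)
    em.add("head_flatten", "flatten")
    em.add("head_fc", "fc", out_channels=_ch(768, wm))
    em.add("head_fc_relu", "relu")
    em.add("head_dropout", "dropout", keep_prob=dropout_keep)
    em.add("head_out", "fc", out_channels=1)

    spec = NetworkSpec("deepcount", input_size, em.nodes)
    spec.validate()
    infer_shapes(spec)  # raises on an infeasible stride schedule
    return spec


def build_shallow_network(input_size: int = 128) -> NetworkSpec:
    """Two convolutional layers and two fully connected layers — the
    weak comparison network."""
    if input_size < 16:
        raise ValueError("input_size must be >= 16")
    em = _Emitter()
    em.add("input", "input", inputs=())
    em.conv_bn("conv1", 16, (5, 5), stride=2, padding=SAME)
    em.add("pool1", "maxpool", kernel=(3, 3), stride=2, padding=VALID)
    em.conv_bn("conv2", 32, (5, 5), stride=1, padding=SAME)
    em.add("pool2", "maxpool", kernel=(3, 3), stride=2, padding=VALID)
    em.add("flatten", "flatten")
    em.add("fc1", "fc", out_channels=64)
    em.add("fc1_relu", "relu")
    em.add("fc_out", "fc", out_channels=1)
    spec = NetworkSpec("shallow", input_size, em.nodes)
    spec.validate()
    infer_shapes(spec)
    return spec


def forward(spec: NetworkSpec, params: Mapping[str, dict], images: np.ndarray,
            training_mode: bool = False,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Evaluate the network on a batch of H×W×3 images.

    Returns one real count per image.  Dropout is active only when
    ``training_mode`` is true (then ``rng`` drives the masks); inference
    is deterministic.
    """
    from . import nn

    return nn.forward(spec, params, images, training=training_mode, rng=rng)[0]
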