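"""Declarative CNN architecture specs with framework-independent shape inference.

Five architectures are buildable for the two-class (PD vs. healthy-control)
brain-image task: a VGG16 backbone, DenseNet-121, DenseNet+LSTM, an
InceptionV3-style network, and the hybrid model — a VGG16 backbone feeding
two inception-reduction blocks and a global-average-pooled classification
head.  A `ModelSpec` is a named DAG of `LayerSpec`s whose output shapes are
inferred by standard convolution arithmetic, so the feature-map contracts of
each block (7x7x512 -> 7x7x640 -> 3x3x832 -> 1024 -> 1) are testable without
any deep-learning framework.

Per-branch channel widths inside the inception-reduction blocks are fixed by
the `_B2_*` / `_B3_*` constants below; they are chosen so the concatenated
block outputs hit exactly 640 and 832 channels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from math import ceil, floor
from typing import Iterable, NamedTuple

import yaml

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "ShapeTriple",
    "HeadSpec",
    "ArchitectureError",
    "infer_shapes",
    "build_vgg16_backbone",
    "build_block2",
    "build_block3",
    "build_hybrid",
    "build_model",
    "materialize",
    "MODEL_NAMES",
]

MODEL_NAMES = ("vgg16", "densenet", "densenet_lstm", "inceptionv3", "hybrid")

_OPS = {
    "conv",
    "maxpool",
    "avgpool",
    "global_avg_pool",
    "dense",
    "dropout",
    "concat",
    "activation",
    "batchnorm",
    "flatten",
    "lstm",
    "input",
}


class ArchitectureError(ValueError):
    """A layer produced an invalid (non-positive) feature-map dimension."""


class ShapeTriple(NamedTuple):
    height: int
    width: int
    channels: int


@dataclass(frozen=True)
class LayerSpec:
    """One node of the layer graph.

    ``inputs`` names upstream layers (more than one only for ``concat``).
    ``kernel``/``stride``/``padding`` apply to conv and pooling ops;
    ``units`` is the output width of conv (filters), dense and lstm layers;
    ``rate`` is the dropout rate.
    """

    name: str
    op: str
    inputs: tuple[str, ...] = ()
    kernel: tuple[int, int] | None = None
    stride: tuple[int, int] = (1, 1)
    padding: str = "same"
    units: int | None = None
    activation: str | None = None
    rate: float | None = None

    def __post_init__(self):
        if self.op not in _OPS:
            raise ValueError(f"unknown op {self.op!r} in layer {self.name!r}")
        if self.kernel is not None and (self.kernel[0] < 1 or self.kernel[1] < 1):
            raise ValueError(f"non-positive kernel in layer {self.name!r}")
        if self.stride[0] < 1 or self.stride[1] < 1:
            raise ValueError(f"non-positive stride in layer {self.name!r}")
        if self.padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid' in {self.name!r}")


@dataclass
class ModelSpec:
    """An acyclic layer graph with an input shape and named block boundaries."""

    name: str
    layers: list[LayerSpec] = field(default_factory=list)
    input_shape: tuple[int, int, int] = (224, 224, 3)
    blocks: dict[str, str] = field(default_factory=dict)  # block name -> boundary layer

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    @property
    def output_layer(self) -> str:
        return self.layers[-1].name

    def to_yaml(self) -> str:
        shapes = infer_shapes(self)
        doc = {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "blocks": dict(self.blocks),
            "layers": [
                {
                    "name": l.name,
                    "op": l.op,
                    "inputs": list(l.inputs),
                    **({"kernel": list(l.kernel)} if l.kernel else {}),
                    **({"stride": list(l.stride)} if l.stride != (1, 1) else {}),
                    **({"padding": l.padding} if l.op in ("conv", "maxpool", "avgpool") else {}),
                    **({"units": l.units} if l.units is not None else {}),
                    **({"activation": l.activation} if l.activation else {}),
                    **({"rate": l.rate} if l.rate is not None else {}),
                    "output_shape": list(shapes[l.name]),
                }
                for l in self.layers
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        doc = yaml.safe_load(text)
        layers = [
            LayerSpec(
                name=d["name"],
                op=d["op"],
                inputs=tuple(d.get("inputs", ())),
                kernel=tuple(d["kernel"]) if "kernel" in d else None,
                stride=tuple(d.get("stride", (1, 1))),
                padding=d.get("padding", "same"),
                units=d.get("units"),
                activation=d.get("activation"),
                rate=d.get("rate"),
            )
            for d in doc["layers"]
        ]
        return cls(
            name=doc["name"],
            layers=layers,
            input_shape=tuple(doc["input_shape"]),
            blocks=dict(doc.get("blocks", {})),
        )


@dataclass(frozen=True)
class HeadSpec:
    """The shared classification head: two hidden dense layers then sigmoid."""

    dense_units: tuple[int, int] = (256, 128)
    dropout_rate: float = 0.20
    activation: str = "relu"

    def __post_init__(self):
        d1, d2 = self.dense_units
        if not (d1 >= d2 >= 1):
            raise ValueError("dense_units must satisfy d1 >= d2 >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# shape inference


def _spatial_out(size: int, k: int, stride: int, padding: str) -> int:
    if padding == "same":
        return ceil(size / stride)
    return floor((size - k) / stride) + 1


def infer_shapes(model: ModelSpec) -> dict[str, tuple]:
    """Output shape of every layer, in graph order.

    Conv/pool use the standard arithmetic (``same`` preserves size at stride
    1 and rounds up under stride; ``valid`` gives floor((in-k)/stride)+1);
    concat sums channels across inputs with equal spatial dims; global
    average pooling yields (1, 1, C); dense and lstm yield (units,).
    """
    shapes: dict[str, tuple] = {"__input__": tuple(model.input_shape)}
    for layer in model.layers:
        ins = layer.inputs or ("__input__",)
        missing = [n for n in ins if n not in shapes]
        if missing:
            raise ArchitectureError(f"layer {layer.name!r} references unknown {missing}")
        in_shapes = [shapes[n] for n in ins]
        shapes[layer.name] = _layer_out(layer, in_shapes)
    shapes.pop("__input__")
    return shapes


def _layer_out(layer: LayerSpec, in_shapes: list[tuple]) -> tuple:
    op = layer.op
    if op == "concat":
        h, w = in_shapes[0][0], in_shapes[0][1]
        for s in in_shapes:
            if (s[0], s[1]) != (h, w):
                raise ArchitectureError(
                    f"concat {layer.name!r}: spatial dims differ across inputs {in_shapes}"
                )
        return (h, w, sum(s[2] for s in in_shapes))
    s = in_shapes[0]
    if op in ("conv", "maxpool", "avgpool"):
        if len(s) != 3:
            raise ArchitectureError(f"{op} layer {layer.name!r} needs a 3-D input, got {s}")
        k = layer.kernel or ((1, 1) if op == "conv" else (2, 2))
        h = _spatial_out(s[0], k[0], layer.stride[0], layer.padding)
        w = _spatial_out(s[1], k[1], layer.stride[1], layer.padding)
        if h < 1 or w < 1:
            raise ArchitectureError(
                f"layer {layer.name!r} produces non-positive spatial dims ({h}, {w})"
            )
        c = layer.units if op == "conv" else s[2]
        return (h, w, c)
    if op == "global_avg_pool":
        if len(s) != 3:
            raise ArchitectureError(f"global_avg_pool {layer.name!r} needs 3-D input")
        return (1, 1, s[2])
    if op == "flatten":
        n = 1
        for d in s:
            n *= d
        return (n,)
    if op == "dense":
        return (layer.units,)
    if op == "lstm":
        # rows of a feature map become timesteps: H steps of W*C features
        if len(s) != 3:
            raise ArchitectureError(f"lstm {layer.name!r} needs a 3-D input, got {s}")
        return (layer.units,)
    if op in ("dropout", "activation", "batchnorm", "input"):
        return s
    raise ArchitectureError(f"cannot infer shape for op {op!r}")


# ---------------------------------------------------------------------------
# builders


class _Graph:
    """Small helper to append layers in a chain while allowing branches."""

    def __init__(self, prefix: str = ""):
        self.layers: list[LayerSpec] = []
        self.prefix = prefix

    def add(self, name: str, op: str, inputs, **kw) -> str:
        if isinstance(inputs, str):
            inputs = (inputs,)
        name = self.prefix + name
        self.layers.append(LayerSpec(name=name, op=op, inputs=tuple(inputs), **kw))
        return name

    def conv(self, name, inp, filters, kernel, stride=(1, 1), padding="same", act="relu"):
        return self.add(
            name, "conv", inp, units=filters, kernel=kernel, stride=stride,
            padding=padding, activation=act,
        )


def build_vgg16_backbone(graph: _Graph | None = None, inp: str | tuple = ()) -> list[LayerSpec]:
    """The 13-convolution VGG16 feature extractor.

    Filter plan 64,64 | 128,128 | 256x3 | 512x3 | 512x3 with 3x3 kernels,
    stride 1, same padding and ReLU, a 2x2/stride-2 max pool closing each
    stage; 224x224x3 in, 7x7x512 out.
    """
    g = graph or _Graph()
    plan = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]
    prev = inp
    i = 0
    for stage, (filters, reps) in enumerate(plan, start=1):
        for r in range(1, reps + 1):
            i += 1
            prev = g.conv(f"vgg_conv{stage}_{r}", prev, filters, (3, 3))
        prev = g.add(
            f"vgg_pool{stage}", "maxpool", prev, kernel=(2, 2), stride=(2, 2), padding="same"
        )
    return g.layers if graph is None else prev  # type: ignore[return-value]


# Branch widths for the two inception-reduction blocks.  Only the concatenated
# totals (640 and 832 channels) are architectural contracts; the per-branch
# split is this package's allocation.
_B2_INCEPTION = {"a": 64, "b": (96, 128), "c": (64, 96, 96), "pool_proj": 64}  # -> 352
_B2_REDUCTION = {"a": 160, "b": (96, 128, 128)}  # 160 + 128 + 352(pool) -> 640
_B3_INCEPTION = {"a": 128, "b": (96, 96, 128), "c": (96, 96, 96, 96, 128), "pool_proj": 128}  # -> 512
_B3_REDUCTION = {"a": (96, 160), "b": (96, 96, 112, 160)}  # 160 + 160 + 512(pool) -> 832


def build_block2(graph: _Graph, inp: str) -> str:
    """First inception-reduction block: 7x7x512 in, 7x7x640 out.

    Inception part: four 1x1 convs, three 3x3 convs and a 3x3 max pool
    across four parallel branches, concatenated.  Reduction part: three 3x3
    convs, one 1x1 conv and a max pool, all stride 1 / same padding so the
    7x7 spatial extent is preserved.
    """
    g = graph
    # inception
    a = g.conv("b2i_a_1x1", inp, _B2_INCEPTION["a"], (1, 1))
    b = g.conv("b2i_b_1x1", inp, _B2_INCEPTION["b"][0], (1, 1))
    b = g.conv("b2i_b_3x3", b, _B2_INCEPTION["b"][1], (3, 3))
    c = g.conv("b2i_c_1x1", inp, _B2_INCEPTION["c"][0], (1, 1))
    c = g.conv("b2i_c_3x3a", c, _B2_INCEPTION["c"][1], (3, 3))
    c = g.conv("b2i_c_3x3b", c, _B2_INCEPTION["c"][2], (3, 3))
    d = g.add("b2i_pool", "maxpool", inp, kernel=(3, 3), stride=(1, 1), padding="same")
    d = g.conv("b2i_pool_1x1", d, _B2_INCEPTION["pool_proj"], (1, 1))
    cat = g.add("b2i_concat", "concat", (a, b, c, d))
    # reduction (stride 1 / same: spatial extent preserved per the 7x7 contract)
    ra = g.conv("b2r_a_3x3", cat, _B2_REDUCTION["a"], (3, 3))
    rb = g.conv("b2r_b_1x1", cat, _B2_REDUCTION["b"][0], (1, 1))
    rb = g.conv("b2r_b_3x3a", rb, _B2_REDUCTION["b"][1], (3, 3))
    rb = g.conv("b2r_b_3x3b", rb, _B2_REDUCTION["b"][2], (3, 3))
    rc = g.add("b2r_pool", "maxpool", cat, kernel=(3, 3), stride=(1, 1), padding="same")
    return g.add("block2_out", "concat", (ra, rb, rc))


def build_block3(graph: _Graph, inp: str) -> str:
    """Second inception-reduction block: 7x7x640 in, 3x3x832 out.

    Inception part factorizes 7x7 kernels into (7x1)+(1x7) pairs — four 1x1
    convs, three factorized pairs and a 3x3 average pool, concatenated at
    stride 1 / same.  Reduction part (two 1x1, two 3x3, one factorized pair,
    one 3x3 max pool) closes with stride-2 valid stages taking 7x7 to 3x3.
    """
    g = graph
    a = g.conv("b3i_a_1x1", inp, _B3_INCEPTION["a"], (1, 1))
    b = g.conv("b3i_b_1x1", inp, _B3_INCEPTION["b"][0], (1, 1))
    b = g.conv("b3i_b_7x1", b, _B3_INCEPTION["b"][1], (7, 1))
    b = g.conv("b3i_b_1x7", b, _B3_INCEPTION["b"][2], (1, 7))
    c = g.conv("b3i_c_1x1", inp, _B3_INCEPTION["c"][0], (1, 1))
    c = g.conv("b3i_c_7x1a", c, _B3_INCEPTION["c"][1], (7, 1))
    c = g.conv("b3i_c_1x7a", c, _B3_INCEPTION["c"][2], (1, 7))
    c = g.conv("b3i_c_7x1b", c, _B3_INCEPTION["c"][3], (7, 1))
    c = g.conv("b3i_c_1x7b", c, _B3_INCEPTION["c"][4], (1, 7))
    d = g.add("b3i_pool", "avgpool", inp, kernel=(3, 3), stride=(1, 1), padding="same")
    d = g.conv("b3i_pool_1x1", d, _B3_INCEPTION["pool_proj"], (1, 1))
    cat = g.add("b3i_concat", "concat", (a, b, c, d))
    # reduction: final stages run stride 2 / valid to reach 3x3
    ra = g.conv("b3r_a_1x1", cat, _B3_REDUCTION["a"][0], (1, 1))
    ra = g.conv(
        "b3r_a_3x3", ra, _B3_REDUCTION["a"][1], (3, 3), stride=(2, 2), padding="valid"
    )
    rb = g.conv("b3r_b_1x1", cat, _B3_REDUCTION["b"][0], (1, 1))
    rb = g.conv("b3r_b_7x1", rb, _B3_REDUCTION["b"][1], (7, 1))
    rb = g.conv("b3r_b_1x7", rb, _B3_REDUCTION["b"][2], (1, 7))
    rb = g.conv(
        "b3r_b_3x3", rb, _B3_REDUCTION["b"][3], (3, 3), stride=(2, 2), padding="valid"
    )
    rc = g.add(
        "b3r_pool", "maxpool", cat, kernel=(3, 3), stride=(2, 2), padding="valid"
    )
    return g.add("block3_out", "concat", (ra, rb, rc))


def _attach_head(g: _Graph, inp: str, head: HeadSpec) -> str:
    """Two dense+BN+dropout stages and a single sigmoid output unit."""
    d1, d2 = head.dense_units
    x = g.add("head_dense1", "dense", inp, units=d1, activation=head.activation)
    x = g.add("head_bn1", "batchnorm", x)
    x = g.add("head_drop1", "dropout", x, rate=head.dropout_rate)
    x = g.add("head_dense2", "dense", x, units=d2, activation=head.activation)
    x = g.add("head_bn2", "batchnorm", x)
    x = g.add("head_drop2", "dropout", x, rate=head.dropout_rate)
    return g.add("output", "dense", x, units=1, activation="sigmoid")


def build_hybrid(head: HeadSpec | None = None) -> ModelSpec:
    """The hybrid model: VGG16 backbone + two inception-reduction blocks.

    Block shapes follow the published contract: Block-1 emits 7x7x512,
    Block-2 7x7x640, Block-3 3x3x832.  A 1x1 projection conv lifts the 832
    channels to 1024 so the globally average-pooled vector entering the
    fully connected stage has length 1024; the head closes with one sigmoid
    unit for the PD-vs-HC decision.
    """
    head = head or HeadSpec()
    g = _Graph()
    b1 = build_vgg16_backbone(g, ())
    b2 = build_block2(g, b1)
    b3 = build_block3(g, b2)
    proj = g.conv("block4_proj_1x1", b3, 1024, (1, 1))
    gap = g.add("block4_gap", "global_avg_pool", proj)
    fc = g.add("block4_fc", "dense", gap, units=1024, activation="relu")
    out = _attach_head(g, fc, head)
    return ModelSpec(
        name="hybrid",
        layers=g.layers,
        blocks={
            "block1": b1,
            "block2": b2,
            "block3": b3,
            "block4_gap": gap,
            "block4_fc": fc,
            "output": out,
        },
    )


def _build_densenet_features(g: _Graph, inp: str | tuple = ()) -> str:
    """DenseNet-121 feature extractor: 224x224x3 in, 7x7x1024 out."""
    x = g.conv("dn_stem_conv", inp, 64, (7, 7), stride=(2, 2))
    x = g.add("dn_stem_pool", "maxpool", x, kernel=(3, 3), stride=(2, 2), padding="same")
    growth = 32
    channels = 64
    for bi, n_layers in enumerate([6, 12, 24, 16], start=1):
        for li in range(1, n_layers + 1):
            y = g.conv(f"dn{bi}_{li}_bottleneck", x, 4 * growth, (1, 1))
            y = g.conv(f"dn{bi}_{li}_conv", y, growth, (3, 3))
            x = g.add(f"dn{bi}_{li}_concat", "concat", (x, y))
            channels += growth
        if bi < 4:
            channels //= 2
            x = g.conv(f"dn{bi}_transition", x, channels, (1, 1))
            x = g.add(
                f"dn{bi}_transition_pool", "avgpool", x, kernel=(2, 2), stride=(2, 2),
                padding="same",
            )
    return x


def _build_inception_features(g: _Graph, inp: str | tuple = ()) -> str:
    """InceptionV3-style feature extractor with the 32/32/64-filter stem."""
    x = g.conv("inc_stem_conv1", inp, 32, (3, 3), stride=(2, 2), padding="valid")
    x = g.conv("inc_stem_conv2", x, 32, (3, 3), padding="valid")
    x = g.conv("inc_stem_conv3", x, 64, (3, 3))
    x = g.add("inc_stem_pool", "maxpool", x, kernel=(3, 3), stride=(2, 2), padding="valid")
    # representative inception modules at decreasing spatial scale
    for mi, pool_after in ((1, True), (2, True), (3, False)):
        p = f"inc_m{mi}_"
        a = g.conv(p + "a_1x1", x, 64, (1, 1))
        b = g.conv(p + "b_1x1", x, 48, (1, 1))
        b = g.conv(p + "b_3x3", b, 64, (3, 3))
        c = g.conv(p + "c_1x1", x, 64, (1, 1))
        c = g.conv(p + "c_5x5", c, 96, (5, 5))
        d = g.add(p + "pool", "avgpool", x, kernel=(3, 3), stride=(1, 1), padding="same")
        d = g.conv(p + "pool_1x1", d, 64, (1, 1))
        x = g.add(p + "concat", "concat", (a, b, c, d))
        if pool_after:
            x = g.add(p + "down", "maxpool", x, kernel=(3, 3), stride=(2, 2), padding="valid")
    return x


def build_model(name: str, head: HeadSpec | None = None, hp=None) -> ModelSpec:
    """Build one of the five architectures with the shared classification head.

    ``hp`` may carry a ``dense_units`` entry (from hyperparameter search);
    it overrides the head's first dense width, with the second fixed at half.
    """
    head = head or HeadSpec()
    if hp is not None:
        units = None
        if isinstance(hp, dict):
            units = hp.get("dense_units")
        else:
            units = getattr(hp, "values", {}).get("dense_units")
        if units is not None:
            head = HeadSpec(
                dense_units=(int(units), max(1, int(units) // 2)),
                dropout_rate=head.dropout_rate,
                activation=head.activation,
            )
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if name == "hybrid":
        return build_hybrid(head)
    g = _Graph()
    if name == "vgg16":
        x = build_vgg16_backbone(g, ())
        x = g.add("flatten", "flatten", x)
        out = _attach_head(g, x, head)
        return ModelSpec(name=name, layers=g.layers, blocks={"features": "vgg_pool5", "output": out})
    if name == "densenet":
        x = _build_densenet_features(g)
        x = g.add("gap", "global_avg_pool", x)
        out = _attach_head(g, x, head)
        return ModelSpec(name=name, layers=g.layers, blocks={"features": "dn4_16_concat", "output": out})
    if name == "densenet_lstm":
        x = _build_densenet_features(g)
        # feature-map rows become timesteps: 7 steps of 7*1024 features
        x = g.add("lstm", "lstm", x, units=head.dense_units[1])
        out = _attach_head(g, x, head)
        return ModelSpec(name=name, layers=g.layers, blocks={"features": "lstm", "output": out})
    # inceptionv3
    x = _build_inception_features(g)
    x = g.add("gap", "global_avg_pool", x)
    out = _attach_head(g, x, head)
    return ModelSpec(name=name, layers=g.layers, blocks={"features": "inc_m3_concat", "output": out})


def materialize(model: ModelSpec, adapter=None, seed: int = 0):
    """Instantiate a runnable model from a spec via a framework adapter.

    With no adapter, the bundled NumPy inference adapter is used: it builds
    random-initialized weights and a forward pass whose actual array shapes
    serve as an independent check of `infer_shapes`.  Pass ``adapter="keras"``
    to request a Keras build (requires tensorflow/keras to be installed).
    """
    if adapter in (None, "numpy"):
        from .adapters import NumpyModel

        return NumpyModel(model, seed=seed)
    if adapter == "keras":
        try:
            import keras  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the keras adapter needs tensorflow/keras installed: "
                "pip install tensorflow — or use the default NumPy adapter"
            ) from exc
        from .adapters import build_keras  # pragma: no cover

        return build_keras(model)  # pragma: no cover
    raise ValueError(f"unknown adapter {adapter!r}")
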