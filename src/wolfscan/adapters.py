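"""Framework adapters that turn a `ModelSpec` into a runnable model.

`NumpyModel` is a self-contained inference engine: every layer gets
random-initialized weights and a NumPy forward pass (im2col convolutions,
window pooling, a standard LSTM recurrence).  Running a batch through it
yields the *actual* array shape at every layer, which makes it an
independent cross-check of `models.infer_shapes` — the two compute shapes
by entirely different routes (symbolic arithmetic vs. concrete arrays).

A Keras build hook is provided for users with tensorflow installed; it is
optional and never required by the toolkit itself.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .models import LayerSpec, ModelSpec

__all__ = ["NumpyModel"]


def _pad_amount(size: int, k: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def _im2col(x: np.ndarray, k: tuple[int, int], stride: tuple[int, int], padding: str,
            pad_value: float = 0.0) -> np.ndarray:
    """(H, W, C) -> (H_out, W_out, kh*kw*C) patch matrix."""
    if padding == "same":
        (pt, pb) = _pad_amount(x.shape[0], k[0], stride[0])
        (pl, pr) = _pad_amount(x.shape[1], k[1], stride[1])
        x = np.pad(x, ((pt, pb), (pl, pr), (0, 0)), constant_values=pad_value)
    win = sliding_window_view(x, (k[0], k[1]), axis=(0, 1))  # (H', W', C, kh, kw)
    win = win[:: stride[0], :: stride[1]]
    h, w = win.shape[0], win.shape[1]
    return win.transpose(0, 1, 3, 4, 2).reshape(h, w, -1)


def _activate(x: np.ndarray, name: str | None) -> np.ndarray:
    if name in (None, "linear"):
        return x
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if name == "tanh":
        return np.tanh(x)
    raise ValueError(f"unknown activation {name!r}")


class NumpyModel:
    """Random-weight NumPy realization of a `ModelSpec` (inference only)."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self._weights: dict[str, tuple] = {}

    def _weight(self, key: str, shape: tuple) -> np.ndarray:
        if key not in self._weights:
            scale = 1.0 / np.sqrt(max(1, int(np.prod(shape[:-1]))))
            self._weights[key] = (scale * self.rng.standard_normal(shape)).astype(np.float32)
        return self._weights[key]

    def forward(self, image: np.ndarray) -> tuple[np.ndarray, dict[str, tuple]]:
        """Run one image through the graph.

        Returns the output array and a mapping layer name -> observed output
        shape (the shape oracle).
        """
        x0 = np.asarray(image, dtype=np.float32)
        if x0.shape != tuple(self.spec.input_shape):
            raise ValueError(
                f"input shape {x0.shape} != spec input {self.spec.input_shape}"
            )
        acts: dict[str, np.ndarray] = {"__input__": x0}
        shapes: dict[str, tuple] = {}
        for layer in self.spec.layers:
            ins = layer.inputs or ("__input__",)
            out = self._apply(layer, [acts[n] for n in ins])
            acts[layer.name] = out
            shapes[layer.name] = tuple(out.shape)
        return acts[self.spec.layers[-1].name], shapes

    def observed_shapes(self, image: np.ndarray | None = None) -> dict[str, tuple]:
        if image is None:
            image = np.zeros(self.spec.input_shape, dtype=np.float32)
        return self.forward(image)[1]

    def _apply(self, layer: LayerSpec, inputs: list[np.ndarray]) -> np.ndarray:
        op = layer.op
        if op == "concat":
            return np.concatenate(inputs, axis=-1)
        x = inputs[0]
        if op == "conv":
            k = layer.kernel or (1, 1)
            cols = _im2col(x, k, layer.stride, layer.padding)
            w = self._weight(layer.name + "/w", (cols.shape[-1], layer.units))
            b = self._weight(layer.name + "/b", (layer.units,))
            return _activate(cols @ w + b, layer.activation)
        if op in ("maxpool", "avgpool"):
            k = layer.kernel or (2, 2)
            pad_value = -np.inf if op == "maxpool" else 0.0
            cols = _im2col(x, k, layer.stride, layer.padding, pad_value=pad_value)
            c = x.shape[-1]
            cols = cols.reshape(cols.shape[0], cols.shape[1], k[0] * k[1], c)
            return cols.max(axis=2) if op == "maxpool" else cols.mean(axis=2)
        if op == "global_avg_pool":
            return x.mean(axis=(0, 1), keepdims=True)
        if op == "flatten":
            return x.reshape(-1)
        if op == "dense":
            v = x.reshape(-1)
            w = self._weight(layer.name + "/w", (v.shape[0], layer.units))
            b = self._weight(layer.name + "/b", (layer.units,))
            return _activate(v @ w + b, layer.activation)
        if op == "lstm":
            return self._lstm(layer, x)
        if op in ("dropout", "activation", "batchnorm"):
            return _activate(x, layer.activation) if op == "activation" else x
        raise ValueError(f"cannot execute op {op!r}")

    def _lstm(self, layer: LayerSpec, x: np.ndarray) -> np.ndarray:
        # rows as timesteps: (H, W, C) -> H steps of W*C features
        seq = x.reshape(x.shape[0], -1)
        n_in, n_units = seq.shape[1], layer.units
        W = self._weight(layer.name + "/W", (n_in, 4 * n_units))
        U = self._weight(layer.name + "/U", (n_units, 4 * n_units))
        b = self._weight(layer.name + "/b", (4 * n_units,))
        h = np.zeros(n_units, dtype=np.float32)
        c = np.zeros(n_units, dtype=np.float32)
        for t in range(seq.shape[0]):
            z = seq[t] @ W + h @ U + b
            i, f, g, o = np.split(z, 4)
            i, f, o = (1 / (1 + np.exp(-i)), 1 / (1 + np.exp(-f)), 1 / (1 + np.exp(-o)))
            c = f * c + i * np.tanh(g)
            h = o * np.tanh(c)
        return h


def build_keras(spec: ModelSpec):  # pragma: no cover - optional dependency path
    """Build a trainable Keras model from a spec (requires tensorflow)."""
    import keras
    from keras import layers as kl

    tensors = {"__input__": keras.Input(shape=spec.input_shape)}
    for layer in spec.layers:
        ins = layer.inputs or ("__input__",)
        xs = [tensors[n] for n in ins]
        x = xs[0]
        if layer.op == "conv":
            x = kl.Conv2D(layer.units, layer.kernel or (1, 1), strides=layer.stride,
                          padding=layer.padding, activation=layer.activation)(x)
        elif layer.op == "maxpool":
            x = kl.MaxPooling2D(layer.kernel or (2, 2), strides=layer.stride,
                                padding=layer.padding)(x)
        elif layer.op == "avgpool":
            x = kl.AveragePooling2D(layer.kernel or (2, 2), strides=layer.stride,
                                    padding=layer.padding)(x)
        elif layer.op == "global_avg_pool":
            x = kl.GlobalAveragePooling2D(keepdims=True)(x)
        elif layer.op == "flatten":
            x = kl.Flatten()(x)
        elif layer.op == "dense":
            if len(x.shape) > 2:
                x = kl.Flatten()(x)
            x = kl.Dense(layer.units, activation=layer.activation)(x)
        elif layer.op == "dropout":
            x = kl.Dropout(layer.rate or 0.0)(x)
        elif layer.op == "batchnorm":
            x = kl.BatchNormalization()(x)
        elif layer.op == "activation":
            x = kl.Activation(layer.activation)(x)
        elif layer.op == "lstm":
            x = kl.Reshape((x.shape[1], -1))(x)
            x = kl.LSTM(layer.units)(x)
        elif layer.op == "concat":
            x = kl.Concatenate(axis=-1)(xs)
        tensors[layer.name] = x
    model = keras.Model(tensors["__input__"], tensors[spec.layers[-1].name], name=spec.name)
    model.compile(optimizer="adam", loss="binary_crossentropy", metrics=["accuracy"])
    return model
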