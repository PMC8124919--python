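"""The three window classifiers: 1D-CNN, LSTM and convLSTM.

Each builder returns a :class:`ModelSpec` whose ``layer_table`` reproduces
the architecture tables the models were specified from — layer type, output
shape for one sample, and parameter count per layer. Input is always a
``(400, 6)`` window (2 s at 200 Hz, six scaled IMU channels); output is a
3-class softmax over (shot, pass, null).

Default hyperparameters are the optima of a 500-trial Bayesian search run on
the original (proprietary) dataset; the search spaces themselves are exposed
in :mod:`kicksense.nn.search`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import (
    BatchNorm,
    Conv1D,
    ConvLSTM,
    Dense,
    Dropout,
    Flatten,
    Layer,
    LSTMLast,
    MaxPool1D,
    ReLU,
    softmax,
)

__all__ = ["ModelSpec", "WINDOW_SHAPE", "CLASSES", "build_cnn", "build_lstm",
           "build_convlstm", "save_model", "load_model"]

WINDOW_SHAPE = (400, 6)
#: fixed class order of the softmax head
CLASSES = ("shot", "pass", "null")


@dataclass
class LayerRow:
    """One row of an architecture table."""

    layer_type: str
    hyperparams: str
    output_shape: tuple[int, ...]
    n_params: int


@dataclass
class ModelSpec:
    """An assembled network plus its training hyperparameters and table."""

    arch: str
    layers: list[Layer]
    layer_table: list[LayerRow]
    learning_rate: float
    clipvalue: float | None = None
    input_reshape: tuple[int, ...] | None = None  # applied after the batch axis
    hyperparams: dict = field(default_factory=dict)

    @property
    def total_params(self) -> int:
        return sum(r.n_params for r in self.layer_table)

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.shape[1:] != WINDOW_SHAPE:
            raise ValueError(
                f"expected input of shape (N, {WINDOW_SHAPE[0]}, {WINDOW_SHAPE[1]}), "
                f"got {x.shape}"
            )
        if self.input_reshape is not None:
            x = x.reshape(x.shape[0], *self.input_reshape)
        return x

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = self._prepare(x)
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (softmax of the logits) for a batch or window."""
        x = np.asarray(x)
        single = x.ndim == 2
        if single:
            x = x[None]
        p = softmax(self.forward(x, training=False))
        return p[0] if single else p

    def predict_classes(self, x: np.ndarray) -> list[str]:
        p = self.predict_proba(np.asarray(x))
        return [CLASSES[i] for i in np.argmax(p, axis=-1)]

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            layer.params = copy.deepcopy(w)

    def astype(self, dtype) -> "ModelSpec":
        for layer in self.layers:
            layer.astype(dtype)
        return self

    def penalty(self) -> float:
        return sum(
            layer.penalty() for layer in self.layers if isinstance(layer, Dense)
        )


def build_cnn(
    filters: tuple[int, int, int] = (256, 128, 16),
    kernel_size: int = 3,
    pool_size: int = 2,
    dropouts: tuple[float, float, float] = (0.30228, 0.03576, 0.43372),
    learning_rate: float = 0.09996,
    seed: int = 0,
) -> ModelSpec:
    """Three valid conv+ReLU+pool blocks, dropout, and a softmax head.

    With the defaults the per-layer table is
    (398, 256)/4864 → pool → (197, 128)/98,432 → (96, 16)/6160 → flatten 768
    → dense(3)/2307.
    """
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    table: list[LayerRow] = []
    length, cin = WINDOW_SHAPE
    for bi, f in enumerate(filters):
        conv = Conv1D(cin, f, kernel_size, rng)
        length = conv.out_length(length)
        layers += [conv, ReLU()]
        table.append(
            LayerRow("1D Convolution",
                     f"filter{bi + 1}: {f}, kernelsize: {kernel_size}",
                     (length, f), conv.n_params)
        )
        if bi > 0:
            drop = Dropout(dropouts[bi - 1])
            layers.append(drop)
            table.append(
                LayerRow("Dropout", f"dropout{bi - 1 + 1}: {drop.rate:g}",
                         (length, f), 0)
            )
        pool = MaxPool1D(pool_size)
        length = pool.out_length(length)
        layers.append(pool)
        table.append(LayerRow("Max-pooling", f"poolsize: {pool_size}",
                              (length, f), 0))
        cin = f
    flat = length * cin
    layers.append(Flatten())
    table.append(LayerRow("Fully-connected", "", (flat,), 0))
    drop3 = Dropout(dropouts[2])
    layers.append(drop3)
    table.append(LayerRow("Dropout", f"dropout3: {drop3.rate:g}", (flat,), 0))
    dense = Dense(flat, len(CLASSES), rng)
    layers.append(dense)
    table.append(LayerRow("Dense", "", (len(CLASSES),), dense.n_params))
    return ModelSpec(
        arch="cnn", layers=layers, layer_table=table, learning_rate=learning_rate,
        hyperparams={"filters": filters, "kernel_size": kernel_size,
                     "pool_size": pool_size, "dropouts": dropouts},
    )


def build_lstm(
    units: int = 64,
    l1: float = 0.00013,
    l2: float = 0.00111,
    clipvalue: float = 0.19517,
    learning_rate: float = 0.06955,
    seed: int = 0,
) -> ModelSpec:
    """One 64-unit LSTM (last output), feature normalization, penalized head.

    The recurrent layer carries two bias vectors per gate set (input-path and
    recurrent-path), giving 4·64·(6+64) + 2·4·64 = 18,432 parameters.
    """
    rng = np.random.default_rng(seed)
    lstm = LSTMLast(WINDOW_SHAPE[1], units, rng)
    bn = BatchNorm(units)
    dense = Dense(units, len(CLASSES), rng, l1=l1, l2=l2)
    table = [
        LayerRow("LSTM", f"units: {units}", (units,), lstm.n_params),
        LayerRow("BatchNorm", "", (units,), bn.n_params),
        LayerRow("Dense", "", (len(CLASSES),), dense.n_params),
    ]
    return ModelSpec(
        arch="lstm", layers=[lstm, bn, dense], layer_table=table,
        learning_rate=learning_rate, clipvalue=clipvalue,
        hyperparams={"units": units, "l1": l1, "l2": l2},
    )


def build_convlstm(
    filters: int = 128,
    kernel_size: int = 3,
    num_segments: int = 8,
    dropout: float = 0.22620,
    learning_rate: float = 0.09403,
    seed: int = 0,
) -> ModelSpec:
    """Segmented convolutional LSTM: the 400-sample window is cut into
    ``num_segments`` recurrent steps over a 1×(400/num_segments) grid.

    With 8 segments and 128 filters: grid width 50, valid input conv → 48
    spatial positions, 4·128·(1·3·(6+128)+1) = 206,336 recurrent parameters,
    flatten 48·128 = 6144, dense (6144+1)·3 = 18,435.
    """
    length, cin = WINDOW_SHAPE
    if length % num_segments != 0:
        raise ValueError(
            f"window length {length} not divisible by num_segments={num_segments}"
        )
    seg_w = length // num_segments
    rng = np.random.default_rng(seed)
    clstm = ConvLSTM(cin, filters, kernel_size, rng)
    wout = seg_w - kernel_size + 1
    drop = Dropout(dropout)
    flat = wout * filters
    dense = Dense(flat, len(CLASSES), rng)
    table = [
        LayerRow("convLSTM2D", f"filter1: {filters}, kernelsize: {kernel_size}",
                 (1, wout, filters), clstm.n_params),
        LayerRow("Dropout", f"dropout: {dropout:g}", (1, wout, filters), 0),
        LayerRow("Fully-connected", "", (flat,), 0),
        LayerRow("Dense", "", (len(CLASSES),), dense.n_params),
    ]
    return ModelSpec(
        arch="convlstm", layers=[clstm, drop, Flatten(), dense], layer_table=table,
        learning_rate=learning_rate,
        input_reshape=(num_segments, seg_w, cin),
        hyperparams={"filters": filters, "kernel_size": kernel_size,
                     "num_segments": num_segments, "dropout": dropout},
    )


def save_model(spec: ModelSpec, path) -> None:
    """Checkpoint a model: architecture id, hyperparameters, weights (npz)."""
    import json

    arrays = {}
    for li, layer in enumerate(spec.layers):
        for key, val in layer.params.items():
            arrays[f"{li}:{key}"] = val
    meta = json.dumps({"arch": spec.arch, "hyperparams": spec.hyperparams,
                       "learning_rate": spec.learning_rate})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> ModelSpec:
    """Rebuild a checkpointed model and restore its weights."""
    import json

    from . import models as _m

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        builder = {"cnn": _m.build_cnn, "lstm": _m.build_lstm,
                   "convlstm": _m.build_convlstm}[meta["arch"]]
        hp = {k: tuple(v) if isinstance(v, list) else v
              for k, v in meta["hyperparams"].items()}
        spec = builder(learning_rate=meta["learning_rate"], **hp)
        for name in data.files:
            if name == "__meta__":
                continue
            li, key = name.split(":", 1)
            spec.layers[int(li)].params[key] = data[name]
    return spec
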