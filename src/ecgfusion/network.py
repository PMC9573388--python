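"""The parallel cross convolutional recurrent network.

Two branches process each heartbeat jointly: an LSTM stack reads the 1-D
beat waveform (temporal morphology) and a stack of convolutional blocks
reads its CWT scalogram (time-frequency texture).  After the first and
second stages the branch outputs are *cross-fused*: the LSTM sequence is
reinterpreted as a 2-D grid whose column count matches the current
convolutional map width, concatenated with the conv map along the first
spatial axis, and the fused map is routed onward into BOTH branches —
back to a sequence for the next LSTM layer, and directly into the next
conv block.  The third-stage outputs are flattened and concatenated into
one feature vector feeding dropout -> dense(ReLU) -> dense(softmax).

Each conv block is conv 3x3 (size-preserving) + ReLU -> max-pool 2x2
with ceiling semantics -> dropout -> batch normalization.  Ceiling
pooling is what produces the odd-to-odd map sizes of the reference
configuration (135 -> 68, 25 -> 13).

When the sequence length is not a multiple of the conv map width the
sequence is zero-padded up to the next multiple before the grid reshape;
the default configuration (200 timesteps, 50-wide maps) needs no
padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as sigmoid

from .layers import (
    LSTM,
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    MaxPool2x2Ceil,
    ReLU,
    softmax,
)

__all__ = [
    "ModelConfig",
    "ShapeTrace",
    "LstmCellParams",
    "lstm_reference_step",
    "cell_params_from_layer",
    "conv_block_shape",
    "reshape_seq_to_grid",
    "grid_to_seq",
    "cross_fuse",
    "trace_shapes",
    "build_model",
    "ParallelCrossNetwork",
    "count_parameters",
    "count_parameters_closed_form",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    The fusion rule requires ``lstm_units[i] == conv_filters[i]`` so the
    concatenated maps share a channel count at every stage.
    """

    seq_len: int = 200
    image_shape: tuple[int, int] = (100, 100)
    lstm_units: tuple[int, int, int] = (16, 32, 64)
    conv_filters: tuple[int, int, int] = (16, 32, 64)
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    dropout_rate: float = 0.1
    dense_units: int = 128
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.seq_len < 1 or self.dense_units < 1 or self.n_classes < 2:
            raise ValueError("dimensions must be positive (n_classes >= 2)")
        if any(u < 1 for u in self.lstm_units) or any(f < 1 for f in self.conv_filters):
            raise ValueError("unit/filter counts must be positive")
        if len(self.lstm_units) != 3 or len(self.conv_filters) != 3:
            raise ValueError("expect three LSTM layers and three conv blocks")
        if tuple(self.lstm_units) != tuple(self.conv_filters):
            raise ValueError(
                "cross-fusion requires lstm_units[i] == conv_filters[i] "
                f"(got {self.lstm_units} vs {self.conv_filters})"
            )
        if any(d < 2 for d in self.image_shape):
            raise ValueError("image dimensions must be >= 2")


@dataclass
class ShapeTrace:
    """Ordered (layer name, output shape) rows of the built network."""

    rows: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)

    def add(self, name: str, shape: tuple[int, ...]) -> None:
        self.rows.append((name, tuple(int(d) for d in shape)))

    def shape(self, name: str) -> tuple[int, ...]:
        for n, s in self.rows:
            if n == name:
                return s
        raise KeyError(name)

    def to_tsv(self) -> str:
        lines = ["Layer\tOutput Volume"]
        for name, shape in self.rows:
            pretty = f"({', '.join(str(d) for d in shape)})"
            lines.append(f"{name}\t{pretty}")
        return "\n".join(lines)

    def __iter__(self):
        return iter(self.rows)

    def __eq__(self, other) -> bool:
        if isinstance(other, ShapeTrace):
            return self.rows == other.rows
        return self.rows == list(other)


# ---------------------------------------------------------------------------
# reference LSTM cell (the oracle the vectorized layer is checked against)


@dataclass
class LstmCellParams:
    """Per-gate weights acting on the concatenation [h_prev, x].

    Each matrix has shape (hidden, hidden + input); biases have shape
    (hidden,).
    """

    w_f: np.ndarray
    w_i: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    @property
    def hidden(self) -> int:
        return self.w_f.shape[0]


def lstm_reference_step(x, h_prev, c_prev, params: LstmCellParams):
    """One LSTM step computed gate by gate from the defining equations.

    f = sigma(W_f [h, x] + b_f), i = sigma(W_i [h, x] + b_i),
    o = sigma(W_o [h, x] + b_o), c = f*c_prev + i*tanh(W_c [h, x] + b_c),
    h = o * tanh(c).  Used as the independent oracle for the vectorized
    BPTT layer; kept deliberately naive.
    """
    x = np.asarray(x, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    hdim = params.hidden
    if h_prev.shape != (hdim,) or c_prev.shape != (hdim,):
        raise ValueError("state shapes inconsistent with parameters")
    z = np.concatenate([h_prev, x])
    if params.w_f.shape[1] != z.size:
        raise ValueError("weight shapes inconsistent with input size")
    f = sigmoid(params.w_f @ z + params.b_f)
    i = sigmoid(params.w_i @ z + params.b_i)
    o = sigmoid(params.w_o @ z + params.b_o)
    c = f * c_prev + i * np.tanh(params.w_c @ z + params.b_c)
    h = o * np.tanh(c)
    return h, c


def cell_params_from_layer(layer: LSTM) -> LstmCellParams:
    """Repack a fused-weight LSTM layer into per-gate reference params."""
    hdim, idim = layer.units, layer.input_size
    w = layer.w.value  # (I+H, 4H), input-then-state rows, gate order i,f,g,o
    b = layer.b.value

    def gate(k):
        wk = w[:, k * hdim : (k + 1) * hdim].T  # (H, I+H) in [x, h] order
        return np.concatenate([wk[:, idim:], wk[:, :idim]], axis=1), \
            b[k * hdim : (k + 1) * hdim]

    w_i, b_i = gate(0)
    w_f, b_f = gate(1)
    w_c, b_c = gate(2)
    w_o, b_o = gate(3)
    return LstmCellParams(w_f=w_f, w_i=w_i, w_o=w_o, w_c=w_c,
                          b_f=b_f, b_i=b_i, b_o=b_o, b_c=b_c)


# ---------------------------------------------------------------------------
# shape arithmetic


def conv_block_shape(input_shape, filters: int):
    """Output shape of one conv block: (ceil(h/2), ceil(w/2), filters)."""
    if filters <= 0:
        raise ValueError("filters must be positive")
    h, w = input_shape[0], input_shape[1]
    if h < 2 or w < 2:
        raise ValueError("spatial dims must be >= 2")
    return (math.ceil(h / 2), math.ceil(w / 2), filters)


def reshape_seq_to_grid(seq_shape, rows: int, cols: int):
    """(T, C) -> (rows, cols, C); requires T == rows * cols."""
    t, c = seq_shape
    if rows * cols != t:
        raise ValueError(
            f"cannot reshape sequence of length {t} into {rows}x{cols} grid "
            f"({rows}*{cols} = {rows * cols})"
        )
    return (rows, cols, c)


def grid_to_seq(grid_shape):
    """(rows, cols, C) -> (rows * cols, C), row-major."""
    r, c, ch = grid_shape
    return (r * c, ch)


def cross_fuse(top_shape, bottom_shape):
    """Concatenate along the first spatial axis; cols/channels must match."""
    r1, c1, ch1 = top_shape
    r2, c2, ch2 = bottom_shape
    if c1 != c2 or ch1 != ch2:
        raise ValueError(
            f"cross-fusion needs matching columns and channels: "
            f"{top_shape} vs {bottom_shape}"
        )
    return (r1 + r2, c1, ch1)


def _padded_rows(t: int, cols: int) -> int:
    return math.ceil(t / cols)


def trace_shapes(cfg: ModelConfig | None = None) -> ShapeTrace:
    """Layer-by-layer output shapes, in the reference table's row order."""
    cfg = cfg or ModelConfig()
    u1, u2, u3 = cfg.lstm_units
    f1, f2, f3 = cfg.conv_filters
    tr = ShapeTrace()
    tr.add("Input_1", (cfg.seq_len, 1))
    tr.add("Input_2", (*cfg.image_shape, 1))
    tr.add("Lstm_unit_1", (cfg.seq_len, u1))
    cb1 = conv_block_shape((*cfg.image_shape, 1), f1)
    tr.add("Conv_block_1", cb1)
    c1 = cb1[1]
    r1 = _padded_rows(cfg.seq_len, c1)
    g1 = reshape_seq_to_grid((r1 * c1, u1), r1, c1)
    tr.add("Reshape_1", g1)
    cat1 = cross_fuse(g1, cb1)
    tr.add("Concatenate_1", cat1)
    s2 = grid_to_seq(cat1)
    tr.add("Reshape_2", s2)
    tr.add("Lstm_unit_2", (s2[0], u2))
    cb2 = conv_block_shape(cat1, f2)
    tr.add("Conv_block_2", cb2)
    c2 = cb2[1]
    r2 = _padded_rows(s2[0], c2)
    g2 = reshape_seq_to_grid((r2 * c2, u2), r2, c2)
    tr.add("Reshape_3", g2)
    cat2 = cross_fuse(g2, cb2)
    tr.add("Concatenate_2", cat2)
    s3 = grid_to_seq(cat2)
    tr.add("Reshape_4", s3)
    tr.add("Lstm_unit_3", (s3[0], u3))
    cb3 = conv_block_shape(cat2, f3)
    tr.add("Conv_block_3", cb3)
    flat1 = s3[0] * u3
    flat2 = cb3[0] * cb3[1] * cb3[2]
    tr.add("Flatten_1", (flat1,))
    tr.add("Flatten_2", (flat2,))
    tr.add("Concatenate_3", (flat1 + flat2,))
    tr.add("Dropout", (flat1 + flat2,))
    tr.add("Dense_1", (cfg.dense_units,))
    tr.add("Dense_2", (cfg.n_classes,))
    return tr


# ---------------------------------------------------------------------------
# the network proper


class _ConvBlock:
    """conv 3x3 + ReLU -> max-pool 2x2 (ceil) -> dropout -> batch norm."""

    def __init__(self, in_ch, filters, rate, rng, kernel=(3, 3), name="block"):
        self.conv = Conv2D(in_ch, filters, rng, kernel=kernel, name=f"{name}.conv")
        self.relu = ReLU()
        self.pool = MaxPool2x2Ceil()
        self.drop = Dropout(rate, rng)
        self.bn = BatchNorm(filters, name=f"{name}.bn")
        self._chain = [self.conv, self.relu, self.pool, self.drop, self.bn]

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, training=False):
        for layer in self._chain:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self._chain):
            dy = layer.backward(dy)
        return dy


class ParallelCrossNetwork:
    """The two-branch cross-fused classifier, NumPy end to end.

    ``forward`` takes a batch of beat sequences ``(B, T, 1)`` and
    scalogram images ``(B, H, W, 1)`` and returns class probabilities;
    ``backward`` takes d(loss)/d(logits) and populates parameter
    gradients for an optimizer.
    """

    def __init__(self, cfg: ModelConfig, seed: int | None = 0):
        self.cfg = cfg
        self.trace = trace_shapes(cfg)
        rng = np.random.default_rng(seed)
        self.rng = rng
        u1, u2, u3 = cfg.lstm_units
        f1, f2, f3 = cfg.conv_filters
        rate = cfg.dropout_rate

        self.lstm1 = LSTM(1, u1, rng, name="lstm1")
        self.block1 = _ConvBlock(1, f1, rate, rng, cfg.kernel, name="block1")
        self.lstm2 = LSTM(f1, u2, rng, name="lstm2")
        self.block2 = _ConvBlock(f1, f2, rate, rng, cfg.kernel, name="block2")
        self.lstm3 = LSTM(f2, u3, rng, name="lstm3")
        self.block3 = _ConvBlock(f2, f3, rate, rng, cfg.kernel, name="block3")

        flat1 = self.trace.shape("Flatten_1")[0]
        flat2 = self.trace.shape("Flatten_2")[0]
        self.drop = Dropout(rate, rng)
        self.dense1 = Dense(flat1 + flat2, cfg.dense_units, rng, name="dense1")
        self.relu = ReLU()
        self.dense2 = Dense(cfg.dense_units, cfg.n_classes, rng, name="dense2")

        self._c1 = self.trace.shape("Conv_block_1")[1]
        self._c2 = self.trace.shape("Conv_block_2")[1]
        self._flat1 = flat1

    # -- parameters --------------------------------------------------------

    def params(self):
        out = []
        for part in (self.lstm1, self.block1, self.lstm2, self.block2,
                     self.lstm3, self.block3, self.dense1, self.dense2):
            out.extend(part.params())
        return out

    # -- sequence <-> grid plumbing ----------------------------------------

    @staticmethod
    def _seq_to_grid(h, cols):
        b, t, c = h.shape
        rows = _padded_rows(t, cols)
        pad = rows * cols - t
        if pad:
            h = np.concatenate([h, np.zeros((b, pad, c))], axis=1)
        return h.reshape(b, rows, cols, c), t

    @staticmethod
    def _grid_to_seq_grad(dg, t):
        b, r, c, ch = dg.shape
        return dg.reshape(b, r * c, ch)[:, :t, :]

    # -- forward / backward ------------------------------------------------

    def forward(self, seq, img, training=False):
        seq = np.asarray(seq, dtype=float)
        img = np.asarray(img, dtype=float)
        if seq.ndim == 2:
            seq = seq[:, :, None]
        if img.ndim == 3:
            img = img[:, :, :, None]
        if seq.shape[1] != self.cfg.seq_len or img.shape[1:3] != tuple(
            self.cfg.image_shape
        ):
            raise ValueError(
                f"input shapes {seq.shape[1:]}, {img.shape[1:]} do not match "
                f"model config (seq_len={self.cfg.seq_len}, "
                f"image_shape={self.cfg.image_shape})"
            )
        h1 = self.lstm1.forward(seq, training)
        g1, t1 = self._seq_to_grid(h1, self._c1)
        fmap1 = self.block1.forward(img, training)
        cat1 = np.concatenate([g1, fmap1], axis=1)

        b = cat1.shape[0]
        s2 = cat1.reshape(b, -1, cat1.shape[-1])
        h2 = self.lstm2.forward(s2, training)
        g2, t2 = self._seq_to_grid(h2, self._c2)
        fmap2 = self.block2.forward(cat1, training)
        cat2 = np.concatenate([g2, fmap2], axis=1)

        s3 = cat2.reshape(b, -1, cat2.shape[-1])
        h3 = self.lstm3.forward(s3, training)
        fl1 = h3.reshape(b, -1)
        fmap3 = self.block3.forward(cat2, training)
        fl2 = fmap3.reshape(b, -1)
        cat3 = np.concatenate([fl1, fl2], axis=1)

        d = self.drop.forward(cat3, training)
        z1 = self.dense1.forward(d, training)
        a1 = self.relu.forward(z1, training)
        logits = self.dense2.forward(a1, training)

        if training:
            self._shapes = (h1.shape, g1.shape, cat1.shape, t1, h2.shape,
                            g2.shape, cat2.shape, t2, h3.shape, fmap3.shape)
        return softmax(logits)

    def backward(self, dlogits):
        (h1s, g1s, cat1s, t1, h2s, g2s, cat2s, t2, h3s, f3s) = self._shapes
        da1 = self.dense2.backward(dlogits)
        dz1 = self.relu.backward(da1)
        dd = self.dense1.backward(dz1)
        dcat3 = self.drop.backward(dd)

        b = dcat3.shape[0]
        dfl1 = dcat3[:, : self._flat1]
        dfl2 = dcat3[:, self._flat1 :]
        dcat2 = self.block3.backward(dfl2.reshape(f3s))
        dh3 = dfl1.reshape(h3s)
        ds3 = self.lstm3.backward(dh3)
        dcat2 = dcat2 + ds3.reshape(cat2s)

        r_top2 = g2s[1]
        dg2 = dcat2[:, :r_top2]
        dfmap2 = dcat2[:, r_top2:]
        dcat1 = self.block2.backward(dfmap2)
        dh2 = self._grid_to_seq_grad(dg2, t2)
        ds2 = self.lstm2.backward(dh2)
        dcat1 = dcat1 + ds2.reshape(cat1s)

        r_top1 = g1s[1]
        dg1 = dcat1[:, :r_top1]
        dfmap1 = dcat1[:, r_top1:]
        dimg = self.block1.backward(dfmap1)
        dh1 = self._grid_to_seq_grad(dg1, t1)
        dseq = self.lstm1.backward(dh1)
        return dseq, dimg

    # -- convenience -------------------------------------------------------

    def predict_proba(self, seq, img, batch_size: int = 256):
        seq = np.asarray(seq, dtype=float)
        out = []
        for lo in range(0, seq.shape[0], batch_size):
            out.append(self.forward(seq[lo : lo + batch_size],
                                    img[lo : lo + batch_size], training=False))
        return np.concatenate(out, axis=0)

    def make_optimizer(self, lr: float = 1e-4) -> Adam:
        return Adam(self.params(), lr=lr)

    # -- persistence -------------------------------------------------------

    def _state_arrays(self):
        state = {p.name: p.value for p in self.params()}
        for bname, block in (("block1", self.block1), ("block2", self.block2),
                             ("block3", self.block3)):
            state[f"{bname}.bn.running_mean"] = block.bn.running_mean
            state[f"{bname}.bn.running_var"] = block.bn.running_var
        return state

    def save(self, path) -> None:
        """Persist weights, batch-norm statistics and config (.npz)."""
        import json

        cfg = {k: getattr(self.cfg, k) for k in (
            "seq_len", "image_shape", "lstm_units", "conv_filters", "kernel",
            "pool", "dropout_rate", "dense_units", "n_classes")}
        np.savez(path, __config__=json.dumps(cfg), **self._state_arrays())

    @classmethod
    def load(cls, path) -> "ParallelCrossNetwork":
        import json

        with np.load(path, allow_pickle=False) as data:
            cfg_raw = json.loads(str(data["__config__"]))
            for key in ("image_shape", "lstm_units", "conv_filters", "kernel",
                        "pool"):
                cfg_raw[key] = tuple(cfg_raw[key])
            model = cls(ModelConfig(**cfg_raw), seed=0)
            state = model._state_arrays()
            for name, arr in state.items():
                arr[...] = data[name]
        return model


def build_model(cfg: ModelConfig | None = None, seed: int | None = 0):
    """Build the network and return it with its layer shape trace."""
    cfg = cfg or ModelConfig()
    model = ParallelCrossNetwork(cfg, seed=seed)
    return model, model.trace


def count_parameters(model: ParallelCrossNetwork) -> int:
    """Total trainable parameters held by the built network."""
    return int(sum(p.size for p in model.params()))


def count_parameters_closed_form(cfg: ModelConfig | None = None) -> int:
    """Per-layer closed-form parameter sum.

    conv: kh*kw*C_in*F + F; LSTM: 4*((I + H)*H + H); batch norm: 2*C
    trainable; dense: I*O + O.  Must equal :func:`count_parameters`
    exactly.
    """
    cfg = cfg or ModelConfig()
    tr = trace_shapes(cfg)
    u1, u2, u3 = cfg.lstm_units
    f1, f2, f3 = cfg.conv_filters
    kh, kw = cfg.kernel

    def lstm(i, h):
        return 4 * ((i + h) * h + h)

    def conv(cin, f):
        return kh * kw * cin * f + f

    def dense(i, o):
        return i * o + o

    flat1 = tr.shape("Flatten_1")[0]
    flat2 = tr.shape("Flatten_2")[0]
    total = (
        lstm(1, u1) + lstm(f1, u2) + lstm(f2, u3)
        + conv(1, f1) + conv(f1, f2) + conv(f2, f3)
        + 2 * (f1 + f2 + f3)
        + dense(flat1 + flat2, cfg.dense_units)
        + dense(cfg.dense_units, cfg.n_classes)
    )
    return int(total)
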