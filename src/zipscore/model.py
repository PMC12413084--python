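"""Feed-forward regressor mapping hexapeptides to steric-zipper propensity (REU).

The reference architecture is a fully connected network: the 6×20 one-hot
encoding (flattened to 120 inputs) feeds a 120-unit hidden layer, a ReLU, and
a single linear output node.  Training minimises the mean squared error
between predicted and reference scores.  Variants (wider hidden layer, an
extra hidden layer, a small 1-D convolutional net over the position axis) are
available through :class:`TrainingConfig.architecture_variant`.

Scores are in Rosetta Energy Units (REU); more negative means a more
favourable zipper arrangement.  A hexapeptide is called a zipper when its
score is at or below −23 REU.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import (
    DEFAULT_ALPHABET,
    HEX_LENGTH,
    AminoAlphabet,
    digits_to_onehot,
    seqs_to_digits,
)

#: REU threshold at or below which a hexapeptide is called a steric zipper.
ZIPPER_THRESHOLD = -23.0


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")


class ModelFormatError(ValueError):
    """Model weights have inconsistent shapes or a bad serialization."""


@dataclass(frozen=True)
class ScoredSegment:
    """A hexapeptide with its reference score.

    ``reliable`` is False iff the sequence contains proline: the original
    structure-based corpus scored proline-containing segments erratically
    high, so their predictions are flagged.
    """

    hexapeptide: str
    score: float

    @property
    def reliable(self) -> bool:
        return "P" not in self.hexapeptide


@dataclass
class TrainingConfig:
    epochs: int = 1000
    learning_rate: float = 1e-3
    batch_size: int = 1024
    seed: int = 0
    split_fractions: tuple = (0.791, 0.177, 0.032)
    architecture_variant: str = "fc120"
    hidden: int | None = None       # override hidden width (fc_expanded)
    conv_channels: int = 32         # channel width of the conv1d variant
    exclude_proline: bool = True    # drop P-containing pairs before splitting

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive")
        if len(self.split_fractions) != 3 or not math.isclose(
            sum(self.split_fractions), 1.0, abs_tol=1e-9
        ):
            raise ValueError("split_fractions must be three fractions summing to 1")
        if any(not 0 < f < 1 for f in self.split_fractions):
            raise ValueError("split fractions must lie in (0, 1)")
        if self.architecture_variant not in {
            "fc120", "fc_expanded", "fc_extra_layer", "conv1d",
        }:
            raise ValueError(f"unknown architecture variant {self.architecture_variant!r}")


# ---------------------------------------------------------------------------
# layers


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        s = 1.0 / math.sqrt(n_in)
        self.W = rng.uniform(-s, s, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, g):
        return np.where(self._mask, g, 0)

    def params(self):
        return []


class _Reshape:
    """Flat one-hot (B, 6*A) <-> per-position (B, 6, A)."""

    def __init__(self, alphabet_size: int):
        self.a = alphabet_size

    def forward(self, x):
        return x.reshape(x.shape[0], HEX_LENGTH, self.a)

    def backward(self, g):
        return g.reshape(g.shape[0], HEX_LENGTH * self.a)

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def params(self):
        return []


class _Conv1d:
    """Same-padded 1-D convolution over the 6 sequence positions (im2col)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = c_in * kernel
        s = 1.0 / math.sqrt(fan_in)
        self.kernel = kernel
        self.W = rng.uniform(-s, s, size=(kernel * c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x):
        b, length, c = x.shape
        k = self.kernel
        pad = k // 2
        xp = np.zeros((b, length + 2 * pad, c), dtype=x.dtype)
        xp[:, pad:pad + length] = x
        cols = np.empty((b, length, k * c), dtype=x.dtype)
        for j in range(k):
            cols[:, :, j * c:(j + 1) * c] = xp[:, j:j + length]
        return cols

    def forward(self, x):
        self._xshape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.W + self.b

    def backward(self, g):
        b, length, _ = self._xshape
        k = self.kernel
        c = self._xshape[2]
        flat_cols = self._cols.reshape(-1, k * c)
        flat_g = g.reshape(-1, g.shape[-1])
        self.dW[...] = flat_cols.T @ flat_g
        self.db[...] = flat_g.sum(axis=0)
        dcols = (flat_g @ self.W.T).reshape(b, length, k * c)
        pad = k // 2
        dxp = np.zeros((b, length + 2 * pad, c), dtype=g.dtype)
        for j in range(k):
            dxp[:, j:j + length] += dcols[:, :, j * c:(j + 1) * c]
        return dxp[:, pad:pad + length]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


def _build_layers(variant: str, alphabet: AminoAlphabet, rng: np.random.Generator,
                  hidden: int | None, conv_channels: int):
    n_in = HEX_LENGTH * alphabet.size
    if variant == "fc120":
        h = hidden or n_in
        return [_Dense(n_in, h, rng), _ReLU(), _Dense(h, 1, rng)]
    if variant == "fc_expanded":
        h = hidden or 500
        return [_Dense(n_in, h, rng), _ReLU(), _Dense(h, 1, rng)]
    if variant == "fc_extra_layer":
        h = hidden or n_in
        return [
            _Dense(n_in, h, rng), _ReLU(),
            _Dense(h, h, rng), _ReLU(),
            _Dense(h, 1, rng),
        ]
    if variant == "conv1d":
        c = conv_channels
        layers = [_Reshape(alphabet.size), _Conv1d(alphabet.size, c, 1, rng), _ReLU()]
        for _ in range(4):  # 5 conv layers in total, kernel-3 after the embedding
            layers += [_Conv1d(c, c, 3, rng), _ReLU()]
        layers += [_Flatten(), _Dense(HEX_LENGTH * c, 1, rng)]
        return layers
    raise ValueError(variant)


_LAYER_TYPES = {"Dense": _Dense, "ReLU": _ReLU, "Reshape": _Reshape,
                "Flatten": _Flatten, "Conv1d": _Conv1d}


# ---------------------------------------------------------------------------
# model container


@dataclass
class ScoreModel:
    """Weights of the hexapeptide score regressor plus training provenance.

    For the two-dense-layer variants the properties :attr:`W1`, :attr:`b1`,
    :attr:`W2`, :attr:`b2` expose the familiar parameter blocks (input→hidden
    matrix, hidden biases, hidden→output vector, output bias).
    """

    layers: list
    alphabet: AminoAlphabet = DEFAULT_ALPHABET
    metadata: dict = field(default_factory=dict)

    # -- fc-style parameter views ------------------------------------------
    def _dense(self, which: int) -> _Dense:
        dense = [l for l in self.layers if isinstance(l, _Dense)]
        if len(dense) != 2:
            raise ModelFormatError("W1/b1/W2/b2 views require a two-dense-layer net")
        return dense[which]

    @property
    def W1(self):
        return self._dense(0).W

    @property
    def b1(self):
        return self._dense(0).b

    @property
    def W2(self):
        return self._dense(1).W[:, 0]

    @property
    def b2(self):
        return float(self._dense(1).b[0])

    # -- prediction ---------------------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]

    def predict_onehot(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != HEX_LENGTH * self.alphabet.size:
            raise ModelFormatError(
                f"expected one-hot input of width {HEX_LENGTH * self.alphabet.size}, "
                f"got shape {x.shape}"
            )
        return self._forward(x.astype(np.float32, copy=False))

    def predict_digits(self, digits: np.ndarray, batch_size: int = 65536) -> np.ndarray:
        out = np.empty(digits.shape[0], dtype=np.float32)
        for lo in range(0, digits.shape[0], batch_size):
            chunk = digits[lo:lo + batch_size]
            out[lo:lo + chunk.shape[0]] = self._forward(
                digits_to_onehot(chunk, self.alphabet)
            )
        return out

    def predict(self, seqs) -> np.ndarray:
        """Scores (REU) for a collection of hexapeptides, order-preserving."""
        return self.predict_digits(seqs_to_digits(list(seqs), self.alphabet))

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        spec = []
        arrays = {}
        for i, layer in enumerate(self.layers):
            name = type(layer).__name__.lstrip("_")
            entry = {"type": name}
            if isinstance(layer, _Dense):
                arrays[f"W_{i}"] = layer.W
                arrays[f"b_{i}"] = layer.b
            elif isinstance(layer, _Conv1d):
                entry["kernel"] = layer.kernel
                arrays[f"W_{i}"] = layer.W
                arrays[f"b_{i}"] = layer.b
            elif isinstance(layer, _Reshape):
                entry["a"] = layer.a
            spec.append(entry)
        arrays["__spec__"] = np.frombuffer(
            json.dumps(
                {"layers": spec, "alphabet": self.alphabet.letters,
                 "metadata": self.metadata}
            ).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ScoreModel":
        with np.load(path) as data:
            try:
                meta = json.loads(bytes(data["__spec__"]).decode())
            except Exception as exc:
                raise ModelFormatError(f"unreadable model file {path}") from exc
            layers = []
            for i, entry in enumerate(meta["layers"]):
                t = entry["type"]
                if t == "Dense":
                    layer = _Dense.__new__(_Dense)
                    layer.W = data[f"W_{i}"]
                    layer.b = data[f"b_{i}"]
                    layer.dW = np.zeros_like(layer.W)
                    layer.db = np.zeros_like(layer.b)
                elif t == "Conv1d":
                    layer = _Conv1d.__new__(_Conv1d)
                    layer.kernel = entry["kernel"]
                    layer.W = data[f"W_{i}"]
                    layer.b = data[f"b_{i}"]
                    layer.dW = np.zeros_like(layer.W)
                    layer.db = np.zeros_like(layer.b)
                elif t == "ReLU":
                    layer = _ReLU()
                elif t == "Reshape":
                    layer = _Reshape(entry["a"])
                elif t == "Flatten":
                    layer = _Flatten()
                else:
                    raise ModelFormatError(f"unknown layer type {t!r}")
                layers.append(layer)
        return cls(layers=layers, alphabet=AminoAlphabet(meta["alphabet"]),
                   metadata=meta["metadata"])

    def model_id(self) -> str:
        """Short provenance hash of the weights (used in score-table headers)."""
        import hashlib

        h = hashlib.sha256()
        for layer in self.layers:
            for arr, _ in layer.params():
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]


def predict_score(model: ScoreModel, seq: str) -> float:
    """Predicted zipper-propensity score (REU) of one hexapeptide."""
    return float(model.predict([seq])[0])


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * math.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for i, (p, g) in enumerate(self.params):
            self.m[i] += (1 - self.b1) * (g - self.m[i])
            self.v[i] += (1 - self.b2) * (g * g - self.v[i])
            p -= lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)


@dataclass
class TrainResult:
    model: ScoreModel
    history: pd.DataFrame          # columns epoch, train_mse, val_mse
    splits: dict                   # name -> (sequences, scores) arrays

    def holdout_mse(self, split: str = "test") -> float:
        seqs, scores = self.splits[split]
        pred = self.model.predict(list(seqs))
        return float(np.mean((pred - scores) ** 2))


def _normalize_data(data):
    if isinstance(data, pd.DataFrame):
        return data["sequence"].tolist(), data["score"].to_numpy(dtype=np.float64)
    if isinstance(data, tuple) and len(data) == 2:
        seqs, scores = data
        return list(seqs), np.asarray(scores, dtype=np.float64)
    seqs, scores = [], []
    for seg in data:
        seqs.append(seg.hexapeptide)
        scores.append(seg.score)
    return seqs, np.asarray(scores, dtype=np.float64)


def split_sizes(n: int, fractions) -> tuple:
    """Floor-rounded split sizes; the remainder goes to the training split."""
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    return n - n_val - n_test, n_val, n_test


def train_model(data, cfg: TrainingConfig, alphabet: AminoAlphabet = DEFAULT_ALPHABET,
                ) -> TrainResult:
    """Fit the score regressor on (hexapeptide, score) pairs.

    The corpus is shuffled with the seeded generator, split at the configured
    fractions (train / validation / test, floor-rounded, remainder to train)
    and optimised with Adam on minibatch MSE.  Identical seed, data and config
    give identical weights and loss traces.
    """
    seqs, scores = _normalize_data(data)
    if len(seqs) == 0:
        raise ValueError("training data is empty")
    if cfg.exclude_proline:
        keep = [i for i, s in enumerate(seqs) if "P" not in s]
        if not keep:
            raise ValueError("all segments contain proline; nothing to train on")
        seqs = [seqs[i] for i in keep]
        scores = scores[keep]

    digits = seqs_to_digits(seqs, alphabet)
    y = scores.astype(np.float32)
    n = len(seqs)

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_train, n_val, n_test = split_sizes(n, cfg.split_fractions)
    idx_train = perm[:n_train]
    idx_val = perm[n_train:n_train + n_val]
    idx_test = perm[n_train + n_val:]

    X = digits_to_onehot(digits, alphabet)
    X_train, y_train = X[idx_train], y[idx_train]
    X_val, y_val = X[idx_val], y[idx_val]

    layers = _build_layers(cfg.architecture_variant, alphabet, rng,
                           cfg.hidden, cfg.conv_channels)
    # start the output node at the training-target mean so the optimizer
    # spends its steps on structure, not on the offset
    for layer in reversed(layers):
        if isinstance(layer, _Dense):
            layer.b[:] = np.float32(y_train.mean()) if n_train else 0.0
            break

    model = ScoreModel(layers=layers, alphabet=alphabet, metadata={
        "variant": cfg.architecture_variant,
        "seed": cfg.seed,
        "epochs": cfg.epochs,
        "n_train": int(n_train),
        "n_val": int(n_val),
        "n_test": int(n_test),
        "exclude_proline": cfg.exclude_proline,
    })
    params = [p for layer in layers for p in layer.params()]
    opt = _Adam(params, cfg.learning_rate)

    hist = {"epoch": [], "train_mse": [], "val_mse": []}
    bs = cfg.batch_size
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n_train)
        sse = 0.0
        for lo in range(0, n_train, bs):
            sel = order[lo:lo + bs]
            xb, yb = X_train[sel], y_train[sel]
            pred = model._forward(xb)
            resid = pred - yb
            sse += float(resid @ resid)
            g = (2.0 / len(sel)) * resid.astype(np.float32)
            grad = g[:, None]
            for layer in reversed(layers):
                grad = layer.backward(grad)
            opt.step()
        train_mse = sse / max(n_train, 1)
        if not math.isfinite(train_mse):
            raise DivergenceError(epoch)
        if n_val:
            val_pred = model.predict_onehot(X_val)
            val_mse = float(np.mean((val_pred - y_val) ** 2))
        else:
            val_mse = float("nan")
        hist["epoch"].append(epoch)
        hist["train_mse"].append(train_mse)
        hist["val_mse"].append(val_mse)

    seq_arr = np.array(seqs)
    splits = {
        "train": (seq_arr[idx_train], scores[idx_train]),
        "validation": (seq_arr[idx_val], scores[idx_val]),
        "test": (seq_arr[idx_test], scores[idx_test]),
    }
    return TrainResult(model=model, history=pd.DataFrame(hist), splits=splits)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_error_bands(pred, truth, bands) -> np.ndarray:
    """Fraction of predictions within ±band of the truth, per band (inclusive)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    err = np.abs(pred - truth)
    return np.array([np.mean(err <= b) for b in bands])


def classify_zipper(score: float, threshold: float = ZIPPER_THRESHOLD) -> bool:
    """True (positive: predicted steric zipper) iff ``score <= threshold``."""
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    return score <= threshold


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Accuracy, sensitivity and specificity from confusion counts.

    An undefined ratio (empty positive or negative class) is returned as
    ``None`` rather than 0.
    """
    if min(tp, tn, fp, fn) < 0 or tp + tn + fp + fn == 0:
        raise ValueError("counts must be non-negative with a positive total")
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
    }
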