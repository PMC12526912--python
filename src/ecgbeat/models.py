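"""The three classifier architectures, their parameter accounting, and the
training/evaluation harness.

Architectures are declared as ordered layer lists (``ArchitectureSpec``)
whose parameter counts are computable in closed form, independently of the
backend that executes them:

* LSTM-Sequential — LSTM(u) → Dense(128, tanh) → Dense(5, softmax), on the
  9-step RR-feature sequence (u ∈ {256, 512});
* Bi-LSTM — Bidirectional LSTM(256) → Dense(256, tanh) → Dense(5, softmax);
* LSTM-FCN — a small LSTM(8)+Dropout(0.8) branch and a Conv1D(128,8) →
  BN → ReLU → Conv1D(256,5) → BN → ReLU → Conv1D(128,3) → BN → ReLU →
  GlobalAvgPool branch over the permuted input, concatenated into a
  softmax classifier.

Training follows a fixed protocol: stratified 70/30 split, one-hot
targets, categorical cross-entropy, Adam at learning rate 0.001, batch
size 256, up to 50 epochs with optional early stopping.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from ecgbeat import nn
from ecgbeat.features import FeatureMatrix

logger = logging.getLogger(__name__)

AAMI_CLASSES = ("N", "S", "V", "F", "Q")


class ModelError(ValueError):
    """Invalid architecture spec or training input."""


@dataclass(frozen=True)
class LayerSpec:
    """One declarative layer; sizes suffice to count its parameters."""

    kind: str          # input|lstm|bilstm|dense|softmax_dense|conv1d|
                       # batchnorm|activation|dropout|permute|
                       # global_avg_pool|concat
    units: int = 0     # LSTM units / dense width / conv filters
    kernel: int = 0
    rate: float = 0.0
    activation: str = "linear"


@dataclass(frozen=True)
class ArchitectureSpec:
    """A named network: a layer chain, or the two-branch LSTM-FCN graph."""

    name: str
    input_length: int
    layers: tuple[LayerSpec, ...]
    input_dim: int = 1
    n_classes: int = 5
    graph: str = "chain"    # chain | lstm_fcn


def build_lstm_sequential(input_length: int = 9, lstm_units: int = 256) -> ArchitectureSpec:
    """LSTM-Sequential (the paper's LSTM-256/LSTM-512 depending on units)."""
    return ArchitectureSpec(
        name="lstm_sequential",
        input_length=input_length,
        layers=(
            LayerSpec("input"),
            LayerSpec("lstm", units=lstm_units),
            LayerSpec("dense", units=128, activation="tanh"),
            LayerSpec("softmax_dense", units=5, activation="softmax"),
        ),
    )


def build_bilstm(input_length: int = 9, lstm_units: int = 256) -> ArchitectureSpec:
    return ArchitectureSpec(
        name="bilstm",
        input_length=input_length,
        layers=(
            LayerSpec("input"),
            LayerSpec("bilstm", units=lstm_units),
            LayerSpec("dense", units=256, activation="tanh"),
            LayerSpec("softmax_dense", units=5, activation="softmax"),
        ),
    )


def build_lstm_fcn(max_len: int = 100, num_cells: int = 8, nb_class: int = 5) -> ArchitectureSpec:
    """LSTM-FCN: LSTM branch on the raw sequence, conv branch on the
    permuted (channels-as-length) view, concatenated before softmax."""
    return ArchitectureSpec(
        name="lstm_fcn",
        input_length=max_len,
        n_classes=nb_class,
        graph="lstm_fcn",
        layers=(
            LayerSpec("input"),
            LayerSpec("lstm", units=num_cells),
            LayerSpec("dropout", rate=0.8),
            LayerSpec("permute"),
            LayerSpec("conv1d", units=128, kernel=8),
            LayerSpec("batchnorm", units=128),
            LayerSpec("activation", activation="relu"),
            LayerSpec("conv1d", units=256, kernel=5),
            LayerSpec("batchnorm", units=256),
            LayerSpec("activation", activation="relu"),
            LayerSpec("conv1d", units=128, kernel=3),
            LayerSpec("batchnorm", units=128),
            LayerSpec("activation", activation="relu"),
            LayerSpec("global_avg_pool"),
            LayerSpec("concat"),
            LayerSpec("softmax_dense", units=nb_class, activation="softmax"),
        ),
    )


def layer_parameter_counts(spec: ArchitectureSpec) -> list[int]:
    """Closed-form parameter count for every layer, in spec order.

    LSTM counts use the single-bias convention ``4·(u·(u+d)+u)``; conv
    counts are ``c·k·f + f``; batch-norm counts include the two running
    statistics (``4·c``), matching how framework summaries print them.
    """
    counts: list[int] = []
    d = spec.input_dim          # feature width flowing through a chain
    conv_channels = None        # channel width in the conv branch
    lstm_out = None             # width of the LSTM branch at the concat
    for layer in spec.layers:
        k = layer.kind
        if k == "input":
            counts.append(0)
        elif k == "lstm":
            u = layer.units
            counts.append(4 * (u * (u + spec.input_dim) + u))
            d = u
            lstm_out = u
        elif k == "bilstm":
            u = layer.units
            counts.append(2 * 4 * (u * (u + spec.input_dim) + u))
            d = 2 * u
        elif k == "dense":
            counts.append(d * layer.units + layer.units)
            d = layer.units
        elif k == "softmax_dense":
            if spec.graph == "lstm_fcn":
                in_dim = (lstm_out or 0) + (conv_channels or 0)
            else:
                in_dim = d
            counts.append(in_dim * layer.units + layer.units)
            d = layer.units
        elif k == "permute":
            counts.append(0)
            conv_channels = spec.input_length   # time axis becomes channels
        elif k == "conv1d":
            if conv_channels is None:
                raise ModelError("conv1d requires a preceding permute/conv")
            counts.append(conv_channels * layer.kernel * layer.units + layer.units)
            conv_channels = layer.units
        elif k == "batchnorm":
            counts.append(4 * layer.units)
        elif k in ("activation", "dropout", "global_avg_pool", "concat"):
            counts.append(0)
        else:
            raise ModelError(f"unknown layer kind {k!r}")
    return counts


def parameter_count(spec: ArchitectureSpec) -> int:
    """Total closed-form parameter count of an architecture."""
    return int(sum(layer_parameter_counts(spec)))


def instantiate(spec: ArchitectureSpec, seed: int = 0) -> nn.Network:
    """Build a runnable backend network from the declarative spec.

    The instantiated network's parameter total must (and is tested to)
    equal :func:`parameter_count` of the same spec.
    """
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(seed + 1)
    if spec.graph == "chain":
        layers: list[nn.Layer] = []
        d = spec.input_dim
        for layer in spec.layers:
            if layer.kind == "input":
                continue
            if layer.kind == "lstm":
                layers.append(nn.LSTM(d, layer.units, rng))
                d = layer.units
            elif layer.kind == "bilstm":
                layers.append(nn.Bidirectional(d, layer.units, rng))
                d = 2 * layer.units
            elif layer.kind in ("dense", "softmax_dense"):
                layers.append(nn.Dense(d, layer.units, layer.activation, rng))
                d = layer.units
            elif layer.kind == "dropout":
                layers.append(nn.Dropout(layer.rate, drop_rng))
            else:
                raise ModelError(f"layer {layer.kind!r} unsupported in a chain")
        return nn.Chain(layers)

    if spec.graph != "lstm_fcn":
        raise ModelError(f"unknown graph kind {spec.graph!r}")
    lstm_units = next(l.units for l in spec.layers if l.kind == "lstm")
    drop_rate = next(l.rate for l in spec.layers if l.kind == "dropout")
    lstm_branch: list[nn.Layer] = [
        nn.LSTM(spec.input_dim, lstm_units, rng),
        nn.Dropout(drop_rate, drop_rng),
    ]
    conv_branch: list[nn.Layer] = [nn.Permute()]
    channels = spec.input_length
    for layer in spec.layers:
        if layer.kind == "conv1d":
            conv_branch += [
                nn.Conv1D(channels, layer.units, layer.kernel, rng),
                nn.BatchNorm(layer.units),
                _ReLU(),
            ]
            channels = layer.units
    conv_branch.append(nn.GlobalAvgPool())
    head = nn.Dense(lstm_units + channels, spec.n_classes, "softmax", rng)
    return nn.TwoBranch(lstm_branch, conv_branch, head)


class _ReLU(nn.Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters (defaults follow the study protocol)."""

    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 0.001
    test_fraction: float = 0.30
    seed: int = 0
    early_stopping_patience: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ModelError("test_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ModelError("epochs and batch_size must be positive")


@dataclass
class TrainedModel:
    network: nn.Network
    spec: ArchitectureSpec
    classes: tuple[str, ...]
    history: dict = field(default_factory=dict)
    X_test: np.ndarray = None
    y_test: np.ndarray = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = _as_sequences(X, self.spec.input_length)
        return self.network.predict_proba(X)

    def predict(self, X: np.ndarray) -> tuple[list[str], np.ndarray]:
        """Labels and confidences (the max class posterior per row)."""
        probs = self.predict_proba(X)
        idx = probs.argmax(axis=1)
        return [self.classes[i] for i in idx], probs[np.arange(len(idx)), idx]


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray
    macro_precision: float = 0.0
    macro_recall: float = 0.0
    macro_f1: float = 0.0


def _as_sequences(X: np.ndarray, input_length: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[:, :, None]
    if X.shape[1] != input_length:
        raise ModelError(
            f"feature length {X.shape[1]} does not match model input "
            f"{input_length}; resample rows first")
    return X


def _encode_labels(labels) -> np.ndarray:
    idx = {c: i for i, c in enumerate(AAMI_CLASSES)}
    try:
        return np.asarray([idx[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ModelError(f"unknown class label {exc.args[0]!r}") from exc


def train(
    spec: ArchitectureSpec,
    features: FeatureMatrix | tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Train an architecture on labelled per-beat features.

    The 70/30 split is stratified by class at the configured seed (falling
    back, with a warning, to an unstratified split if a class has a single
    member).  Classes absent from the training split stay in the output
    space.  Returns the trained model with its held-out test set attached.
    """
    config = config or TrainConfig()
    if isinstance(features, FeatureMatrix):
        X, labels = features.X, features.labels
    else:
        X, labels = features
    y = labels if isinstance(labels, np.ndarray) and labels.dtype.kind in "iu" \
        else _encode_labels(labels)
    X = _as_sequences(X, spec.input_length)
    present = np.unique(y)
    if len(present) < 2:
        raise ModelError("training requires at least 2 classes")

    try:
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=config.test_fraction,
            stratify=y, random_state=config.seed)
    except ValueError:
        warnings.warn("stratified split infeasible; falling back to random split")
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=config.test_fraction,
            random_state=config.seed)
    missing = set(present) - set(np.unique(y[idx_train]))
    if missing:
        warnings.warn(f"classes {sorted(missing)} absent from the training split")

    onehot = np.eye(spec.n_classes)[y]
    net = instantiate(spec, seed=config.seed)
    opt = nn.Adam(net.trainable(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    Xtr, Ytr = X[idx_train], onehot[idx_train]
    Xte, yte = X[idx_test], y[idx_test]
    history = {"loss": [], "val_loss": [], "split": (idx_train, idx_test)}
    best_val = np.inf
    since_best = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            logits = net.forward(Xtr[sel], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, Ytr[sel])
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(sel)
        history["loss"].append(epoch_loss / len(Xtr))
        val_logits = net.forward(Xte, training=False)
        val_loss, _ = nn.softmax_cross_entropy(val_logits, onehot[idx_test])
        history["val_loss"].append(val_loss)
        logger.info("epoch %d loss %.4f val %.4f", epoch + 1,
                    history["loss"][-1], val_loss)
        if config.early_stopping_patience is not None:
            if val_loss < best_val - 1e-6:
                best_val, since_best = val_loss, 0
            else:
                since_best += 1
                if since_best >= config.early_stopping_patience:
                    break

    return TrainedModel(net, spec, AAMI_CLASSES, history, Xte, yte)


def evaluate(
    model: TrainedModel,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | list[str] | None = None,
) -> EvalReport:
    """Score a trained model: confusion matrix, support-weighted metrics,
    and per-class accuracy (the per-class recall, the only per-class
    scalar a single confusion matrix defines)."""
    if X_test is None:
        X_test, y_test = model.X_test, model.y_test
    if X_test is None or len(X_test) == 0:
        raise ModelError("empty test set")
    y = y_test if isinstance(y_test, np.ndarray) and y_test.dtype.kind in "iu" \
        else _encode_labels(y_test)
    pred = model.predict_proba(X_test).argmax(axis=1)
    return report_from_predictions(y, pred)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    n_cls = len(AAMI_CLASSES)
    confusion = np.zeros((n_cls, n_cls), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t, p] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    pw, rw, fw, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=range(n_cls), average="weighted", zero_division=0)
    pm, rm, fm, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=range(n_cls), average="macro", zero_division=0)
    row_sums = confusion.sum(axis=1)
    per_class = {
        cls: (float(confusion[i, i] / row_sums[i]) if row_sums[i] else 0.0)
        for i, cls in enumerate(AAMI_CLASSES)
    }
    return EvalReport(
        accuracy=accuracy, precision=float(pw), recall=float(rw), f1=float(fw),
        per_class_accuracy=per_class, confusion=confusion,
        macro_precision=float(pm), macro_recall=float(rm), macro_f1=float(fm),
    )


# ---------------------------------------------------------------------------
# Persistence (backend-independent spec + weight arrays)
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write ``<path>.json`` (architecture) and ``<path>.npz`` (weights)."""
    path = Path(path)
    spec = model.spec
    payload = {
        "name": spec.name,
        "input_length": spec.input_length,
        "input_dim": spec.input_dim,
        "n_classes": spec.n_classes,
        "graph": spec.graph,
        "layers": [vars(l) for l in spec.layers],
        "classes": list(model.classes),
        "stream_batch_size": 1,   # streaming export contract
    }
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    arrays = {}
    for i, layer in enumerate(model.network.layers):
        for j, p in enumerate(layer.params):
            arrays[f"l{i}p{j}"] = p
    np.savez(path.with_suffix(".npz"), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    payload = json.loads(path.with_suffix(".json").read_text())
    spec = ArchitectureSpec(
        name=payload["name"], input_length=payload["input_length"],
        input_dim=payload["input_dim"], n_classes=payload["n_classes"],
        graph=payload["graph"],
        layers=tuple(LayerSpec(**l) for l in payload["layers"]),
    )
    net = instantiate(spec, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        for i, layer in enumerate(net.layers):
            for j, p in enumerate(layer.params):
                p[...] = data[f"l{i}p{j}"]
    return TrainedModel(net, spec, tuple(payload["classes"]))
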