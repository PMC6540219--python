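"""Bidirectional LSTM classification network and its training loop.

Topology (matching the study design): a one-dimensional sequence input — each
coefficient of the reduced feature vector is one timestep — into a BiLSTM with
100 hidden units per direction, 50% (inverted) dropout on the readout, two
fully connected layers, and a softmax output.  The sequence-to-label readout
concatenates the final hidden states of the forward and backward passes
(length 200).  Training minimizes mean cross-entropy with minibatch Adam
(batch 10, initial learning rate 0.01, 400 epochs by default) under global
L2 gradient-norm clipping at threshold 1.

Everything is plain numpy with analytic gradients; :func:`gradient_check`
verifies them against central finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .datasets import LabeledFeatureSet
from .lstm import (
    LSTMParameters,
    lstm_sequence_backward,
    lstm_sequence_forward,
    pack_parameters,
    unpack_gradients,
)

__all__ = [
    "NetworkTopology",
    "TrainingConfig",
    "NetworkModel",
    "TrainingLog",
    "TrainingDivergedError",
    "bilstm_forward",
    "network_forward",
    "train",
    "predict",
    "gradient_check",
    "save_model",
    "load_model",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the log so far."""

    def __init__(self, message: str, log: "TrainingLog") -> None:
        super().__init__(message)
        self.log = log


@dataclass(frozen=True)
class NetworkTopology:
    """Architecture sizes; defaults follow the study network."""

    hidden_units: int = 100
    fc_hidden: int = 64
    dropout_rate: float = 0.5
    input_dim: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.hidden_units, self.fc_hidden, self.input_dim) < 1:
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings; defaults follow the study protocol."""

    epochs: int = 400
    minibatch: int = 10
    learning_rate: float = 0.01
    gradient_threshold: float = 1.0
    clip_mode: Literal["norm", "value"] = "norm"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    seed: int = 0
    # training arithmetic; inference and gradient checking always run in
    # double precision
    precision: Literal["single", "double"] = "single"

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.minibatch < 1 or self.learning_rate < 0:
            raise ValueError("epochs/minibatch/learning_rate out of range")


@dataclass
class NetworkModel:
    """A trained (or freshly initialized) BiLSTM classifier."""

    forward_params: LSTMParameters
    backward_params: LSTMParameters
    fc1_W: np.ndarray
    fc1_b: np.ndarray
    fc2_W: np.ndarray
    fc2_b: np.ndarray
    n_classes: int
    dropout_rate: float = 0.5
    trained_width: int | None = None  # sequence length seen by train()

    def __post_init__(self) -> None:
        if self.fc2_W.shape[0] != self.n_classes:
            raise ValueError("fc2 output width must equal n_classes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def hidden(self) -> int:
        return self.forward_params.hidden

    @classmethod
    def initialize(
        cls,
        topology: NetworkTopology,
        n_classes: int,
        rng: np.random.Generator,
    ) -> "NetworkModel":
        H, F = topology.hidden_units, topology.fc_hidden
        fwd = LSTMParameters.initialize(H, topology.input_dim, rng)
        bwd = LSTMParameters.initialize(H, topology.input_dim, rng)
        lim1 = np.sqrt(6.0 / (2 * H + F))
        lim2 = np.sqrt(6.0 / (F + n_classes))
        return cls(
            forward_params=fwd,
            backward_params=bwd,
            fc1_W=rng.uniform(-lim1, lim1, size=(F, 2 * H)),
            fc1_b=np.zeros(F),
            fc2_W=rng.uniform(-lim2, lim2, size=(n_classes, F)),
            fc2_b=np.zeros(n_classes),
            n_classes=n_classes,
            dropout_rate=topology.dropout_rate,
        )


@dataclass
class TrainingLog:
    """Per-iteration loss and minibatch accuracy (training-curve data)."""

    epoch: list[int] = field(default_factory=list)
    iteration: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def append(self, epoch: int, iteration: int, loss: float, acc: float) -> None:
        self.epoch.append(epoch)
        self.iteration.append(iteration)
        self.loss.append(loss)
        self.accuracy.append(acc)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": self.epoch, "iteration": self.iteration,
             "loss": self.loss, "accuracy": self.accuracy}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def epoch_mean_loss(self, epoch: int) -> float:
        sel = [l for e, l in zip(self.epoch, self.loss) if e == epoch]
        return float(np.mean(sel))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _forward_batch(
    X: np.ndarray,
    model: NetworkModel,
    packed: tuple,
    dropout_mask: np.ndarray | None,
    need_cache: bool,
    caches: tuple = (None, None),
):
    """Shared forward pass.  ``X`` is (batch, time); input dim is 1."""
    (Wr_f, Wx_f, b_f), (Wr_b, Wx_b, b_b) = packed
    Xf = X[:, :, None]
    Xb = Xf[:, ::-1, :]
    hf, cache_f = lstm_sequence_forward(Xf, Wr_f, Wx_f, b_f,
                                        return_cache=need_cache, cache=caches[0])
    hb, cache_b = lstm_sequence_forward(Xb, Wr_b, Wx_b, b_b,
                                        return_cache=need_cache, cache=caches[1])
    readout = np.concatenate([hf, hb], axis=1)
    dropped = readout * dropout_mask if dropout_mask is not None else readout
    z1 = dropped @ model.fc1_W.T + model.fc1_b
    a1 = np.maximum(z1, 0.0)
    logits = a1 @ model.fc2_W.T + model.fc2_b
    probs = _softmax(logits)
    return probs, (cache_f, cache_b, dropped, a1)


def bilstm_forward(sequence: np.ndarray, model: NetworkModel) -> np.ndarray:
    """BiLSTM representation of one 1-D sequence: concatenated final hidden
    states of the forward pass and of the pass over the reversed sequence
    (length ``2 * hidden``), from zero initial states."""
    seq = np.asarray(sequence, dtype=np.float64).ravel()
    if seq.size == 0:
        raise ValueError("sequence must be nonempty")
    packed = (pack_parameters(model.forward_params),
              pack_parameters(model.backward_params))
    (Wr_f, Wx_f, b_f), (Wr_b, Wx_b, b_b) = packed
    X = seq[None, :, None]
    hf, _ = lstm_sequence_forward(X, Wr_f, Wx_f, b_f, return_cache=False)
    hb, _ = lstm_sequence_forward(X[:, ::-1, :].copy(), Wr_b, Wx_b, b_b,
                                  return_cache=False)
    return np.concatenate([hf[0], hb[0]])


def network_forward(
    feature_vector: np.ndarray,
    model: NetworkModel,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class probabilities for one reduced feature vector.

    With ``training=True`` inverted dropout is applied to the BiLSTM readout
    (an ``rng`` is then required); at inference the pass is deterministic.
    """
    x = np.asarray(feature_vector, dtype=np.float64).ravel()
    if not np.isfinite(x).all():
        raise ValueError("feature vector contains non-finite values")
    mask = None
    if training and model.dropout_rate > 0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - model.dropout_rate
        mask = (rng.random((1, 2 * model.hidden)) < keep) / keep
    packed = (pack_parameters(model.forward_params),
              pack_parameters(model.backward_params))
    probs, _ = _forward_batch(x[None, :], model, packed, mask, need_cache=False)
    return probs[0]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _param_list(model: NetworkModel, packed) -> list[np.ndarray]:
    (Wr_f, Wx_f, b_f), (Wr_b, Wx_b, b_b) = packed
    return [Wr_f, Wx_f, b_f, Wr_b, Wx_b, b_b,
            model.fc1_W, model.fc1_b, model.fc2_W, model.fc2_b]


def _batch_gradients(
    X: np.ndarray,
    y: np.ndarray,
    model: NetworkModel,
    packed,
    dropout_mask: np.ndarray | None,
    cache_pool: dict | None = None,
) -> tuple[float, float, list[np.ndarray]]:
    """Mean cross-entropy loss, minibatch accuracy, and gradients in the
    :func:`_param_list` ordering.

    ``cache_pool`` (keyed by batch size) lets successive minibatches reuse
    the sequence workspaces instead of reallocating them every step.
    """
    (Wr_f, _, _), (Wr_b, _, _) = packed
    B = X.shape[0]
    caches = (None, None) if cache_pool is None else cache_pool.get(B, (None, None))
    probs, (cache_f, cache_b, dropped, a1) = _forward_batch(
        X, model, packed, dropout_mask, need_cache=True, caches=caches
    )
    if cache_pool is not None:
        cache_pool[B] = (cache_f, cache_b)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
    acc = float(np.mean(probs.argmax(axis=1) == y))

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    dfc2_W = dlogits.T @ a1
    dfc2_b = dlogits.sum(axis=0)
    da1 = dlogits @ model.fc2_W
    da1[a1 <= 0.0] = 0.0
    dfc1_W = da1.T @ dropped
    dfc1_b = da1.sum(axis=0)
    dreadout = da1 @ model.fc1_W
    if dropout_mask is not None:
        dreadout = dreadout * dropout_mask
    H = model.hidden
    dWr_f, dWx_f, db_f = lstm_sequence_backward(dreadout[:, :H], cache_f, Wr_f)
    dWr_b, dWx_b, db_b = lstm_sequence_backward(dreadout[:, H:], cache_b, Wr_b)
    grads = [dWr_f, dWx_f, db_f, dWr_b, dWx_b, db_b,
             dfc1_W, dfc1_b, dfc2_W, dfc2_b]
    return loss, acc, grads


def _clip_gradients(grads: list[np.ndarray], threshold: float,
                    mode: str) -> None:
    if mode == "value":
        for g in grads:
            np.clip(g, -threshold, threshold, out=g)
        return
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > threshold:
        scale = threshold / total
        for g in grads:
            g *= scale


def train(
    data: LabeledFeatureSet | np.ndarray,
    labels: np.ndarray | None = None,
    config: TrainingConfig = TrainingConfig(),
    topology: NetworkTopology = NetworkTopology(),
) -> tuple[NetworkModel, TrainingLog]:
    """Train the BiLSTM classifier on (reduced) feature vectors.

    ``data`` is either a :class:`LabeledFeatureSet` or a plain feature matrix
    with ``labels`` given separately — transformed coefficient rows may be
    signed, which the raw-activation container does not allow.  Minibatches
    are reshuffled every epoch from a seed-controlled stream; gradients are
    clipped (global L2 norm by default) before the Adam update.  Deterministic
    given ``config.seed``.
    """
    if isinstance(data, LabeledFeatureSet):
        X, y = data.features, data.labels
    else:
        if labels is None:
            raise ValueError("labels required when passing a bare feature matrix")
        X = np.asarray(data, dtype=np.float64)
        y = np.asarray(labels, dtype=np.int64)
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least two classes present")
    n_classes = int(classes.max()) + 1
    rng = np.random.default_rng(config.seed)
    model = NetworkModel.initialize(topology, n_classes, rng)
    dtype = np.float32 if config.precision == "single" else np.float64
    X = X.astype(dtype, copy=False)
    packed = tuple(
        tuple(a.astype(dtype) for a in pack_parameters(p))
        for p in (model.forward_params, model.backward_params)
    )
    model.fc1_W = model.fc1_W.astype(dtype)
    model.fc1_b = model.fc1_b.astype(dtype)
    model.fc2_W = model.fc2_W.astype(dtype)
    model.fc2_b = model.fc2_b.astype(dtype)
    params = _param_list(model, packed)

    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps = config.adam_beta1, config.adam_beta2, config.adam_epsilon
    keep = 1.0 - model.dropout_rate
    log = TrainingLog()
    step = 0
    n = X.shape[0]
    cache_pool: dict = {}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.minibatch):
            idx = order[start:start + config.minibatch]
            Xb, yb = X[idx], y[idx]
            mask = None
            if model.dropout_rate > 0:
                mask = ((rng.random((idx.size, 2 * model.hidden)) < keep)
                        / keep).astype(dtype)
            loss, acc, grads = _batch_gradients(Xb, yb, model, packed, mask,
                                                cache_pool=cache_pool)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, iteration {step}", log
                )
            _clip_gradients(grads, config.gradient_threshold, config.clip_mode)
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= b1
                mi += (1 - b1) * g
                vi *= b2
                vi += (1 - b2) * g * g
                p -= lr_t * mi / (np.sqrt(vi) + eps)
            log.append(epoch, step, loss, acc)

    # write packed weights back into the per-gate (double precision) layout
    H = model.hidden
    for params_obj, (Wr, Wx, b) in zip(
        (model.forward_params, model.backward_params), packed
    ):
        blocks = unpack_gradients(Wr, Wx, b, H)
        for name, arr in blocks.items():
            setattr(params_obj, name, arr.astype(np.float64))
    model.fc1_W = model.fc1_W.astype(np.float64)
    model.fc1_b = model.fc1_b.astype(np.float64)
    model.fc2_W = model.fc2_W.astype(np.float64)
    model.fc2_b = model.fc2_b.astype(np.float64)
    model.trained_width = X.shape[1]
    return model, log


def predict(
    model: NetworkModel, features: np.ndarray, batch_size: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (argmax; ties to the lower class index) and the full
    probability matrix, row order preserved."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    if model.trained_width is not None and X.shape[1] != model.trained_width:
        raise ValueError(
            f"feature width {X.shape[1]} does not match the training width "
            f"{model.trained_width}"
        )
    packed = (pack_parameters(model.forward_params),
              pack_parameters(model.backward_params))
    probs = np.empty((X.shape[0], model.n_classes))
    for start in range(0, X.shape[0], batch_size):
        chunk = X[start:start + batch_size]
        p, _ = _forward_batch(chunk, model, packed, None, need_cache=False)
        probs[start:start + chunk.shape[0]] = p
    return probs.argmax(axis=1), probs


# ---------------------------------------------------------------------------
# Gradient verification
# ---------------------------------------------------------------------------

def gradient_check(
    model: NetworkModel,
    x: np.ndarray,
    y: int,
    step: float = 1e-6,
) -> float:
    """Max relative error between analytic and central-difference gradients.

    Intended for tiny models (a few hidden units, short sequences); iterates
    over every parameter entry.  Dropout is disabled so the loss is a
    deterministic function of the parameters.

    The denominator of the relative error is floored at 1e-4: central
    differences at step 1e-6 carry ~1e-10 of cancellation noise, so
    near-zero gradients would otherwise report spurious relative error that
    reflects the probe, not the analytic gradients.
    """
    x = np.asarray(x, dtype=np.float64).ravel()[None, :]
    yv = np.array([int(y)])
    packed = (pack_parameters(model.forward_params),
              pack_parameters(model.backward_params))
    params = _param_list(model, packed)
    _, _, grads = _batch_gradients(x, yv, model, packed, None)

    def loss_at() -> float:
        l, _, _ = _batch_gradients(x, yv, model, packed, None)
        return l

    worst = 0.0
    for p, g in zip(params, grads):
        flat = p.ravel()
        gflat = g.ravel()
        for j in range(flat.size):
            orig = flat[j]
            flat[j] = orig + step
            lp = loss_at()
            flat[j] = orig - step
            lm = loss_at()
            flat[j] = orig
            numeric = (lp - lm) / (2 * step)
            denom = max(abs(numeric) + abs(gflat[j]), 1e-4)
            worst = max(worst, abs(numeric - gflat[j]) / denom)
    return worst


# ---------------------------------------------------------------------------
# Serialization: JSON metadata + npz arrays
# ---------------------------------------------------------------------------

def save_model(model: NetworkModel, path: str | Path) -> None:
    """Write ``<path>.npz`` (arrays) and ``<path>.json`` (topology)."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {
        "fc1_W": model.fc1_W, "fc1_b": model.fc1_b,
        "fc2_W": model.fc2_W, "fc2_b": model.fc2_b,
    }
    for prefix, p in (("fwd", model.forward_params), ("bwd", model.backward_params)):
        for name in ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o"):
            arrays[f"{prefix}_{name}"] = getattr(p, name)
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"hidden": model.hidden, "n_classes": model.n_classes,
            "dropout_rate": model.dropout_rate,
            "input_dim": model.forward_params.input_dim,
            "trained_width": model.trained_width}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> NetworkModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as arrays:
        def lstm(prefix: str) -> LSTMParameters:
            kw = {name: arrays[f"{prefix}_{name}"]
                  for name in ("W_f", "W_i", "W_c", "W_o",
                               "b_f", "b_i", "b_c", "b_o")}
            return LSTMParameters(**kw)
        return NetworkModel(
            forward_params=lstm("fwd"),
            backward_params=lstm("bwd"),
            fc1_W=arrays["fc1_W"], fc1_b=arrays["fc1_b"],
            fc2_W=arrays["fc2_W"], fc2_b=arrays["fc2_b"],
            n_classes=int(meta["n_classes"]),
            dropout_rate=float(meta["dropout_rate"]),
            trained_width=meta.get("trained_width"),
        )
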