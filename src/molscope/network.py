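"""Feedforward network on fingerprint bits with white-box access.

A deliberately small stack: one or two ReLU hidden layers of 512 neurons on a
2048-bit input, a logistic output neuron, binary cross-entropy loss, Adam,
inverted dropout on the hidden layers and L2 regularization applied to the
hidden-layer weights only.  Training runs for at most ``max_epochs`` epochs
with early stopping on validation ROC-AUC: the parameter snapshot of the best
epoch is kept (ties broken toward the earlier epoch).

Everything is plain NumPy so that weights, hidden activations and exact
gradients are directly accessible to the interpretability machinery; inference
always runs with dropout disabled and accepts fractional inputs (needed for
the straight-line paths of integrated gradients).

Weight initialization is He-normal for hidden layers and Glorot-normal for the
output layer, drawn from a generator seeded by ``NetConfig.seed``; the scheme
and seed are stored in checkpoints, so trainings are exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
from sklearn.metrics import roc_auc_score

from .chem import Fingerprint, fingerprint_matrix

__all__ = ["NetConfig", "TrainedModel", "train", "predict", "hidden_activations", "input_weights"]


@dataclass
class NetConfig:
    """Architecture and optimizer settings.

    ``one_layer()`` and ``two_layer()`` give the two reference configurations
    (one hidden layer: lr 0.001, dropout 0.5, L2 0.001; two hidden layers:
    lr 0.0001, dropout 0.2, L2 0).
    """

    n_hidden_layers: int = 1
    hidden_size: int = 512
    learning_rate: float = 1e-3
    dropout: float = 0.5
    l2: float = 1e-3
    max_epochs: int = 10
    batch_size: int = 16
    seed: int = 0
    n_bits: int = 2048

    def __post_init__(self):
        if self.n_hidden_layers not in (1, 2):
            raise ValueError("n_hidden_layers must be 1 or 2")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def one_layer(cls, **kw) -> "NetConfig":
        base = dict(n_hidden_layers=1, learning_rate=1e-3, dropout=0.5, l2=1e-3)
        base.update(kw)
        return cls(**base)

    @classmethod
    def two_layer(cls, **kw) -> "NetConfig":
        base = dict(n_hidden_layers=2, learning_rate=1e-4, dropout=0.2, l2=0.0)
        base.update(kw)
        return cls(**base)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return np.atleast_2d(X).astype(np.float64)
    if isinstance(X, Fingerprint):
        return X.as_input()[None, :]
    X = list(X)
    if X and isinstance(X[0], np.ndarray):
        return np.stack(X).astype(np.float64)
    return fingerprint_matrix(X)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainedModel:
    """Weights, biases and training provenance of a fitted network.

    ``weights[l]`` has shape (fan_in, fan_out); hidden layers are ReLU, the
    output is a single logistic unit.  The forward pass is deterministic
    (dropout is a training-time device only).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: NetConfig
    best_epoch: int = 0
    val_history: list[tuple[int, float]] = field(default_factory=list)

    # -- construction -------------------------------------------------------

    @classmethod
    def initialize(cls, cfg: NetConfig, rng: np.random.Generator) -> "TrainedModel":
        sizes = [cfg.n_bits] + [cfg.hidden_size] * cfg.n_hidden_layers + [1]
        weights, biases = [], []
        for l, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            if l < len(sizes) - 2:  # He for ReLU layers
                scale = np.sqrt(2.0 / fan_in)
            else:  # Glorot for the logistic output
                scale = np.sqrt(2.0 / (fan_in + fan_out))
            weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return cls(weights=weights, biases=biases, config=cfg)

    @classmethod
    def from_weights(cls, weights, biases, config: NetConfig | None = None) -> "TrainedModel":
        """Hand-set model (used for engineered fixtures and worked examples)."""
        weights = [np.atleast_2d(np.asarray(w, dtype=np.float64)) for w in weights]
        biases = [np.atleast_1d(np.asarray(b, dtype=np.float64)) for b in biases]
        if config is None:
            config = NetConfig(
                n_hidden_layers=len(weights) - 1,
                hidden_size=weights[0].shape[1],
                n_bits=weights[0].shape[0],
                dropout=0.0,
                l2=0.0,
            )
        return cls(weights=weights, biases=biases, config=config)

    # -- forward passes ------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def _check_input(self, X: np.ndarray) -> None:
        if X.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"input length {X.shape[1]} != model input size {self.weights[0].shape[0]}"
            )

    def forward(self, X) -> dict:
        """Full forward pass returning pre-activations and activations per layer."""
        X = _as_matrix(X)
        self._check_input(X)
        pre, act = [], [X]
        h = X
        for l in range(self.n_layers):
            z = h @ self.weights[l] + self.biases[l]
            pre.append(z)
            h = np.maximum(z, 0.0) if l < self.n_layers - 1 else _sigmoid(z)
            act.append(h)
        return {"pre": pre, "act": act, "logit": pre[-1][:, 0], "proba": act[-1][:, 0]}

    def predict_proba(self, X) -> np.ndarray:
        return self.forward(X)["proba"]

    # -- persistence ---------------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Checkpoint: self-describing JSON sidecar + npz weight archive."""
        prefix = Path(prefix)
        meta = {
            "config": asdict(self.config),
            "best_epoch": self.best_epoch,
            "val_history": self.val_history,
            "init_scheme": "he-normal hidden / glorot-normal output",
            "shapes": [list(w.shape) for w in self.weights],
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        arrays = {}
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{l}"] = w
            arrays[f"b{l}"] = b
        np.savez(prefix.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, prefix: str | Path) -> "TrainedModel":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        data = np.load(prefix.with_suffix(".npz"))
        n = len(meta["shapes"])
        model = cls(
            weights=[data[f"W{l}"] for l in range(n)],
            biases=[data[f"b{l}"] for l in range(n)],
            config=NetConfig(**meta["config"]),
            best_epoch=meta["best_epoch"],
            val_history=[tuple(t) for t in meta["val_history"]],
        )
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _prepare_split(split) -> tuple[np.ndarray, np.ndarray]:
    if not split:
        raise ValueError("empty data split")
    fps, labels = zip(*split)
    X = _as_matrix(list(fps)) if not isinstance(fps[0], np.ndarray) else np.stack(fps).astype(float)
    y = np.asarray(labels, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("split contains a single class")
    return X, y


def train(train_split, val_split, cfg: NetConfig) -> TrainedModel:
    """Fit with Adam/BCE and keep the epoch snapshot with best validation ROC-AUC.

    Both splits are sequences of (fingerprint-or-array, label) pairs and must
    contain both classes.  Identical seed, data order and config give identical
    parameters.
    """
    X, y = _prepare_split(train_split)
    Xv, yv = _prepare_split(val_split)
    rng = np.random.default_rng(cfg.seed)
    model = TrainedModel.initialize(cfg, rng)
    n = X.shape[0]
    # Adam state
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_auc, best_epoch = -np.inf, -1
    best_weights = [w.copy() for w in model.weights]
    best_biases = [b.copy() for b in model.biases]
    history: list[tuple[int, float]] = []
    n_hidden = model.n_layers - 1
    keep = 1.0 - cfg.dropout
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            bsz = len(idx)
            # forward with inverted dropout on hidden activations
            h = xb
            acts = [xb]
            pres = []
            masks = []
            for l in range(model.n_layers):
                z = h @ model.weights[l] + model.biases[l]
                pres.append(z)
                if l < model.n_layers - 1:
                    h = np.maximum(z, 0.0)
                    if cfg.dropout > 0:
                        mask = (rng.random(h.shape) < keep) / keep
                        h = h * mask
                        masks.append(mask)
                    else:
                        masks.append(None)
                else:
                    h = _sigmoid(z)
                acts.append(h)
            # backward: d BCE/d z_out = p - y (mean over batch)
            delta = (acts[-1] - yb[:, None]) / bsz
            t += 1
            for l in range(model.n_layers - 1, -1, -1):
                gw = acts[l].T @ delta
                gb = delta.sum(axis=0)
                if cfg.l2 > 0 and l < n_hidden:  # hidden-layer weights only
                    gw = gw + cfg.l2 * model.weights[l]
                if l > 0:
                    delta = delta @ model.weights[l].T
                    if masks[l - 1] is not None:
                        delta = delta * masks[l - 1]
                    delta = delta * (pres[l - 1] > 0)
                # Adam update
                m_w[l] = beta1 * m_w[l] + (1 - beta1) * gw
                v_w[l] = beta2 * v_w[l] + (1 - beta2) * gw * gw
                m_b[l] = beta1 * m_b[l] + (1 - beta1) * gb
                v_b[l] = beta2 * v_b[l] + (1 - beta2) * gb * gb
                mw_hat = m_w[l] / (1 - beta1**t)
                vw_hat = v_w[l] / (1 - beta2**t)
                mb_hat = m_b[l] / (1 - beta1**t)
                vb_hat = v_b[l] / (1 - beta2**t)
                model.weights[l] -= cfg.learning_rate * mw_hat / (np.sqrt(vw_hat) + eps)
                model.biases[l] -= cfg.learning_rate * mb_hat / (np.sqrt(vb_hat) + eps)
        auc = float(roc_auc_score(yv, model.predict_proba(Xv)))
        history.append((epoch, auc))
        if auc > best_auc:  # strict: ties keep the earlier epoch
            best_auc, best_epoch = auc, epoch
            best_weights = [w.copy() for w in model.weights]
            best_biases = [b.copy() for b in model.biases]
    model.weights = best_weights
    model.biases = best_biases
    model.best_epoch = best_epoch
    model.val_history = history
    return model


# ---------------------------------------------------------------------------
# White-box accessors
# ---------------------------------------------------------------------------


def predict(model: TrainedModel, fp) -> float:
    """Output probability for a single compound (positive class iff >= 0.5)."""
    return float(model.predict_proba(fp)[0])


def hidden_activations(model: TrainedModel, fp, layer: int) -> np.ndarray:
    """Rectified activation vector of one hidden layer (dropout disabled).

    ``layer`` is 1-based; accepts a single fingerprint (returns a vector) or a
    batch (returns a matrix).
    """
    n_hidden = model.n_layers - 1
    if not 1 <= layer <= n_hidden:
        raise ValueError(f"layer must be in 1..{n_hidden}")
    out = model.forward(fp)["act"][layer]
    return out[0] if out.shape[0] == 1 and not _is_batch(fp) else out


def _is_batch(fp) -> bool:
    if isinstance(fp, Fingerprint):
        return False
    if isinstance(fp, np.ndarray):
        return fp.ndim == 2
    return True


def input_weights(model: TrainedModel, layer: int, neuron: int) -> np.ndarray:
    """Learned weights feeding one neuron (length = size of the previous layer)."""
    n_hidden = model.n_layers - 1
    if not 1 <= layer <= n_hidden:
        raise ValueError(f"layer must be in 1..{n_hidden}")
    W = model.weights[layer - 1]
    if not 0 <= neuron < W.shape[1]:
        raise ValueError(f"neuron index {neuron} out of range")
    return W[:, neuron].copy()
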