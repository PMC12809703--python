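"""Seeded feed-forward network for multi-output EES regression.

One network maps a selected subset of autoscaled molecular descriptors
to the autoscaled 9-component EES profile.  Architectures have one or
two tanh hidden layers (n2 = 0 means a single hidden layer) and a
linear output.  Training minimizes mean squared error on the training
rows with full-batch Adam; the validation subset drives early stopping
(best-validation weights are restored), and the internal-test subset
never influences fitting.  Everything is seeded and deterministic.

The trainer is implemented directly on numpy because the contract —
an externally supplied validation subset for early stopping, exact
weight restoration, and bit-for-bit reproducibility from a seed — is
the point, and the networks involved are tiny (at most two 30-neuron
layers on fewer than a hundred rows).

Serialization is plain text: a JSON metadata file plus JSON-encoded
weight arrays, one directory per model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import DescriptorMatrix, ScalerParams, SubsetSplit, descale

__all__ = [
    "ANNTopology",
    "TrainingConfig",
    "TrainedANN",
    "train_ann",
    "predict_ann",
    "save_model",
    "load_model",
]

SERIALIZATION_VERSION = 1

N1_MAX = 30
N2_MAX = 30


@dataclass(frozen=True)
class ANNTopology:
    """Hidden-layer sizes: 1 <= n1 <= 30, 0 <= n2 <= 30 (0 = one layer)."""

    n1: int
    n2: int = 0

    def __post_init__(self):
        if not (isinstance(self.n1, (int, np.integer)) and 1 <= self.n1 <= N1_MAX):
            raise ValueError(f"n1 must be an integer in 1..{N1_MAX}, got {self.n1}")
        if not (isinstance(self.n2, (int, np.integer)) and 0 <= self.n2 <= N2_MAX):
            raise ValueError(f"n2 must be an integer in 0..{N2_MAX}, got {self.n2}")
        object.__setattr__(self, "n1", int(self.n1))
        object.__setattr__(self, "n2", int(self.n2))


@dataclass(frozen=True)
class TrainingConfig:
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0
    learning_rate: float = 0.02
    hidden_activation: str = "tanh"
    optimizer_tag: str = "adam"

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.hidden_activation != "tanh":
            raise ValueError(f"unsupported hidden activation {self.hidden_activation!r}")
        if self.optimizer_tag != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_tag!r}")


@dataclass
class TrainedANN:
    """One fitted network with its selection context.

    Carries the feature mask over the full descriptor set, the subset
    split it was trained under, the scalers needed to map raw inputs
    to network space and network outputs back to EES units, and a
    metrics dictionary filled in by the objective evaluation.
    """

    topology: ANNTopology
    feature_mask: np.ndarray
    split: SubsetSplit
    weights: list            # [(W, b), ...] per layer
    x_scaler: ScalerParams
    t_scaler: ScalerParams
    seed: int
    metrics: dict = field(default_factory=dict)
    training_history: dict = field(default_factory=dict)

    @property
    def nv(self) -> int:
        return int(np.count_nonzero(self.feature_mask))


def _init_weights(layer_sizes: list[int], rng: np.random.Generator) -> list:
    """Glorot-uniform initialization, deterministic for a given generator."""
    weights = []
    for fan_in, fan_out in zip(layer_sizes, layer_sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((w, b))
    return weights


def _forward(x: np.ndarray, weights: list) -> np.ndarray:
    """Forward pass: tanh hidden layers, linear output."""
    h = x
    for w, b in weights[:-1]:
        h = np.tanh(h @ w + b)
    w, b = weights[-1]
    return h @ w + b


def _forward_backward(x, t, weights):
    """MSE loss and its gradients for tanh hidden layers + linear output."""
    acts = [x]
    h = x
    for w, b in weights[:-1]:
        h = np.tanh(h @ w + b)
        acts.append(h)
    w_out, b_out = weights[-1]
    y = h @ w_out + b_out
    n = x.shape[0]
    resid = y - t
    loss = float(np.mean(resid ** 2))
    # d loss / d y, averaged over rows and outputs
    delta = 2.0 * resid / resid.size
    grads = [None] * len(weights)
    for li in range(len(weights) - 1, -1, -1):
        w, _ = weights[li]
        a_in = acts[li]
        grads[li] = (a_in.T @ delta, delta.sum(axis=0))
        if li > 0:
            delta = (delta @ w.T) * (1.0 - acts[li] ** 2)  # tanh'
    return loss, grads


def train_ann(
    x: np.ndarray,
    t: np.ndarray,
    split: SubsetSplit,
    topology: ANNTopology,
    cfg: TrainingConfig = TrainingConfig(),
    *,
    feature_mask: np.ndarray | None = None,
    x_scaler: ScalerParams | None = None,
    t_scaler: ScalerParams | None = None,
) -> TrainedANN:
    """Fit one network on autoscaled data.

    ``x`` must already be restricted to the selected descriptors (one
    column per active feature) and autoscaled; ``t`` is the autoscaled
    target matrix.  Weights are fitted by full-batch Adam on the
    training rows; after each epoch the validation MSE is evaluated and
    training halts once it has not improved for ``cfg.patience``
    epochs, restoring the best-validation weights.  Internal-test rows
    are never touched.

    The optional keyword arguments attach the selection context (mask
    and scalers) so the returned model can predict from raw,
    full-width descriptor input via :func:`predict_ann`.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.ndim != 2 or t.ndim != 2 or x.shape[0] != t.shape[0]:
        raise ValueError("x and t must be row-aligned 2-D matrices")
    if x.shape[1] < 1:
        raise ValueError("at least one input feature is required")
    if len(split.tr) < 2 or len(split.va) < 1:
        raise ValueError("degenerate split: need >= 2 training and >= 1 validation rows")

    tr = list(split.tr)
    va = list(split.va)
    x_tr, t_tr = x[tr], t[tr]
    x_va, t_va = x[va], t[va]

    layers = [x.shape[1], topology.n1] + ([topology.n2] if topology.n2 > 0 else []) + [t.shape[1]]
    rng = np.random.default_rng(cfg.seed)
    weights = _init_weights(layers, rng)

    # Adam state
    m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = cfg.learning_rate

    def va_mse(ws):
        r = _forward(x_va, ws) - t_va
        return float(np.mean(r ** 2))

    best_va = va_mse(weights)
    best_weights = [(w.copy(), b.copy()) for w, b in weights]
    best_epoch = 0
    wait = 0
    tr_losses = []

    for epoch in range(1, cfg.max_epochs + 1):
        loss, grads = _forward_backward(x_tr, t_tr, weights)
        tr_losses.append(loss)
        c1 = 1.0 - beta1 ** epoch
        c2 = 1.0 - beta2 ** epoch
        for li, ((gw, gb), (mw, mb), (vw, vb)) in enumerate(zip(grads, m, v)):
            mw = beta1 * mw + (1 - beta1) * gw
            mb = beta1 * mb + (1 - beta1) * gb
            vw = beta2 * vw + (1 - beta2) * gw ** 2
            vb = beta2 * vb + (1 - beta2) * gb ** 2
            m[li] = (mw, mb)
            v[li] = (vw, vb)
            w, b = weights[li]
            weights[li] = (
                w - lr * (mw / c1) / (np.sqrt(vw / c2) + eps),
                b - lr * (mb / c1) / (np.sqrt(vb / c2) + eps),
            )
        cur_va = va_mse(weights)
        if cur_va < best_va - 1e-12:
            best_va = cur_va
            best_weights = [(w.copy(), b.copy()) for w, b in weights]
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break

    n_features_total = len(feature_mask) if feature_mask is not None else x.shape[1]
    if feature_mask is None:
        feature_mask = np.ones(x.shape[1], dtype=bool)
    feature_mask = np.asarray(feature_mask, dtype=bool)
    if int(feature_mask.sum()) != x.shape[1]:
        raise ValueError(
            f"feature_mask selects {int(feature_mask.sum())} columns but x has {x.shape[1]}"
        )
    if x_scaler is None:
        x_scaler = ScalerParams(np.zeros(n_features_total), np.ones(n_features_total))
    if t_scaler is None:
        t_scaler = ScalerParams(np.zeros(t.shape[1]), np.ones(t.shape[1]))

    tr_resid = _forward(x_tr, best_weights) - t_tr
    return TrainedANN(
        topology=topology,
        feature_mask=feature_mask,
        split=split,
        weights=best_weights,
        x_scaler=x_scaler,
        t_scaler=t_scaler,
        seed=cfg.seed,
        training_history={
            "epochs_run": len(tr_losses),
            "best_epoch": best_epoch,
            "best_va_mse": best_va,
            "final_tr_mse": float(np.mean(tr_resid ** 2)),
        },
    )


def predict_scaled(model: TrainedANN, x_scaled_masked: np.ndarray) -> np.ndarray:
    """Forward pass on already-scaled, already-masked input; scaled output."""
    return _forward(np.asarray(x_scaled_masked, dtype=float), model.weights)


def predict_ann(model: TrainedANN, x_new, clip: bool = True, clip_range=(-1.0, 6.0)) -> np.ndarray:
    """Predict EES profiles (original units) from raw descriptor input.

    ``x_new`` is a :class:`DescriptorMatrix` or array carrying *all*
    descriptor columns in training order; the stored scaler and feature
    mask are applied internally and the network output is
    back-transformed to EES units.  With ``clip`` (default on for
    user-facing profiles) predictions are clamped to the practical EES
    range.
    """
    if isinstance(x_new, DescriptorMatrix):
        x_arr = x_new.values
    else:
        x_arr = np.asarray(x_new, dtype=float)
    single = x_arr.ndim == 1
    if single:
        x_arr = x_arr[None, :]
    n_total = model.feature_mask.size
    if x_arr.shape[1] != n_total:
        raise ValueError(
            f"input has {x_arr.shape[1]} descriptor columns, model expects {n_total}"
        )
    scale = np.where(model.x_scaler.scale > 0, model.x_scaler.scale, 1.0)
    x_scaled = (x_arr - model.x_scaler.center) / scale
    x_scaled[:, model.x_scaler.scale == 0] = 0.0
    y_scaled = _forward(x_scaled[:, model.feature_mask], model.weights)
    y = descale(y_scaled, model.t_scaler)
    if clip:
        y = np.clip(y, clip_range[0], clip_range[1])
    return y


# ---------------------------------------------------------------------------
# text serialization


def save_model(model: TrainedANN, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": SERIALIZATION_VERSION,
        "topology": {"n1": model.topology.n1, "n2": model.topology.n2},
        "feature_mask": model.feature_mask.astype(int).tolist(),
        "split": {"tr": list(model.split.tr), "va": list(model.split.va), "it": list(model.split.it)},
        "seed": model.seed,
        "nv": model.nv,
        "metrics": model.metrics,
        "training_history": model.training_history,
        "x_scaler": {"center": model.x_scaler.center.tolist(), "scale": model.x_scaler.scale.tolist()},
        "t_scaler": {"center": model.t_scaler.center.tolist(), "scale": model.t_scaler.scale.tolist()},
    }
    (d / "model.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    arrays = {"n_layers": len(model.weights)}
    for i, (w, b) in enumerate(model.weights):
        arrays[f"w{i}"] = w.tolist()
        arrays[f"b{i}"] = b.tolist()
    (d / "weights.json").write_text(json.dumps(arrays, sort_keys=True))


def load_model(directory) -> TrainedANN:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    if meta.get("format_version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model format version {meta.get('format_version')}")
    arrays = json.loads((d / "weights.json").read_text())
    weights = [
        (np.asarray(arrays[f"w{i}"], dtype=float), np.asarray(arrays[f"b{i}"], dtype=float))
        for i in range(arrays["n_layers"])
    ]
    return TrainedANN(
        topology=ANNTopology(**meta["topology"]),
        feature_mask=np.asarray(meta["feature_mask"], dtype=bool),
        split=SubsetSplit(**meta["split"]),
        weights=weights,
        x_scaler=ScalerParams(np.asarray(meta["x_scaler"]["center"]), np.asarray(meta["x_scaler"]["scale"])),
        t_scaler=ScalerParams(np.asarray(meta["t_scaler"]["center"]), np.asarray(meta["t_scaler"]["scale"])),
        seed=meta["seed"],
        metrics=meta["metrics"],
        training_history=meta["training_history"],
    )
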