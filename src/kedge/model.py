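"""Multilayer perceptron mapping feature vectors to discretised spectra.

The network is a plain feed-forward stack of dense layers: the input
dimension is fixed by the representation, the first hidden layer has
1200 neurons, each subsequent hidden layer shrinks by 30% (floor), four
hidden layers in total, tanh activations on hidden layers and a linear
output (targets are unbounded cross-sections).  Training minimises the
mean-squared-error cost with ADAM over shuffled minibatches of 100
samples at learning rate 3e-4, with 15% dropout on hidden activations
during training only.  At the default RDC input length (800) and a
300-point output grid this comes to about 2.8 million trainable
weights.

Everything is deterministic given the configuration seed: weight
initialisation, minibatch shuffling and dropout masks are all drawn
from one seeded generator, so rebuilding and retraining reproduces the
history bit for bit.

Features are standardised internally (per-feature z-score computed on
the training set, stored with the model and reapplied at prediction
time); without this, raw charge-weighted features saturate the first
tanh layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MLPConfig",
    "MLPModel",
    "build",
    "train",
    "predict",
    "mse",
    "loss_and_gradients",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and optimiser hyperparameters."""

    input_dim: int
    output_dim: int
    first_hidden: int = 1200
    shrink: float = 0.70
    n_hidden: int = 4
    activation: str = "tanh"
    dropout_fraction: float = 0.15
    learning_rate: float = 3e-4
    minibatch: int = 100
    max_epochs: int = 500
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    patience: int | None = None  # optional early stopping on validation MSE
    standardise: bool = True

    def __post_init__(self) -> None:
        if min(self.input_dim, self.output_dim, self.first_hidden, self.n_hidden) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout fraction must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.activation != "tanh":
            raise ValueError("only tanh hidden activations are supported")
        if min(self.hidden_sizes) < 1:
            raise ValueError(
                f"hidden sizes {self.hidden_sizes} shrink to zero; increase "
                "first_hidden or reduce n_hidden"
            )

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        sizes = [self.first_hidden]
        for _ in range(self.n_hidden - 1):
            sizes.append(math.floor(sizes[-1] * self.shrink))
        return tuple(sizes)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_sizes, self.output_dim)

    @property
    def n_weights(self) -> int:
        """Trainable weight count (biases excluded)."""
        s = self.layer_sizes
        return int(sum(a * b for a, b in zip(s[:-1], s[1:])))


@dataclass
class MLPModel:
    """Weights, biases and training history of one network."""

    config: MLPConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    history: dict = field(default_factory=lambda: {"train_mse": [], "val_mse": []})
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    rng: np.random.Generator | None = None
    init_scheme: str = "uniform-fan-in"

    @property
    def n_layers(self) -> int:
        return len(self.weights)


def build(config: MLPConfig) -> MLPModel:
    """Initialise a network from its seeded generator.

    Weights are drawn uniformly from +/- sqrt(1/fan_in) (symmetric
    fan-in scheme); biases start at zero.  The same seed yields
    bit-identical initial weights.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(1.0 / fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(config, weights, biases, rng=rng)


def _standardise_fit(model: MLPModel, x: np.ndarray) -> None:
    if model.config.standardise:
        model.feature_mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0] = 1.0
        model.feature_scale = scale
    else:
        model.feature_mean = np.zeros(x.shape[1])
        model.feature_scale = np.ones(x.shape[1])


def _standardise_apply(model: MLPModel, x: np.ndarray) -> np.ndarray:
    if model.feature_mean is None:
        return x
    return (x - model.feature_mean) / model.feature_scale


def _forward(
    model: MLPModel,
    x: np.ndarray,
    dropout_rng: np.random.Generator | None = None,
):
    """Feed-forward pass; returns output, per-layer activations and masks.

    When ``dropout_rng`` is given, hidden activations are dropped with
    probability ``dropout_fraction`` and survivors rescaled by
    1/(1 - p) (inverted dropout), so inference needs no rescaling.
    """
    p = model.config.dropout_fraction
    activations = [x]
    masks: list[np.ndarray | None] = []
    tanhs: list[np.ndarray] = []
    a = x
    n_hidden = model.n_layers - 1
    for k in range(n_hidden):
        z = a @ model.weights[k] + model.biases[k]
        t = np.tanh(z)
        tanhs.append(t)
        if dropout_rng is not None and p > 0:
            mask = (dropout_rng.random(t.shape) >= p) / (1.0 - p)
            a = t * mask
        else:
            mask = None
            a = t
        masks.append(mask)
        activations.append(a)
    out = a @ model.weights[-1] + model.biases[-1]
    return out, activations, masks, tanhs


def _backward(model: MLPModel, out, y, activations, masks, tanhs):
    """Gradients of the MSE cost (mean over samples and output points)."""
    n, d = y.shape
    grad_w = [None] * model.n_layers
    grad_b = [None] * model.n_layers
    delta = 2.0 * (out - y) / (n * d)
    for k in range(model.n_layers - 1, -1, -1):
        grad_w[k] = activations[k].T @ delta
        grad_b[k] = delta.sum(axis=0)
        if k > 0:
            delta = delta @ model.weights[k].T
            if masks[k - 1] is not None:
                delta = delta * masks[k - 1]
            delta = delta * (1.0 - tanhs[k - 1] ** 2)
    return grad_w, grad_b


def loss_and_gradients(model: MLPModel, x: np.ndarray, y: np.ndarray):
    """Cost and analytic weight/bias gradients, dropout disabled.

    Exposed so the backpropagation can be checked against finite
    differences on small networks.
    """
    out, activations, masks, tanhs = _forward(model, x, dropout_rng=None)
    loss = float(np.mean((out - y) ** 2))
    grad_w, grad_b = _backward(model, out, y, activations, masks, tanhs)
    return loss, grad_w, grad_b


def mse(predicted: np.ndarray, target: np.ndarray):
    """Per-sample mean squared error and its aggregate mean."""
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != target.shape:
        raise ValueError(
            f"shape mismatch: {predicted.shape} vs {target.shape}"
        )
    if predicted.ndim == 1:
        predicted = predicted[None, :]
        target = target[None, :]
    per_sample = np.mean((predicted - target) ** 2, axis=1)
    return per_sample, float(per_sample.mean())


def train(
    model: MLPModel,
    features: np.ndarray,
    targets: np.ndarray,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    epochs: int | None = None,
) -> MLPModel:
    """ADAM training over shuffled minibatches; mutates and returns the model.

    Dropout is active only here; the per-epoch history records the
    training MSE (and validation MSE when a validation pair is given)
    with dropout off.  With ``patience`` set in the config, training
    stops once the validation MSE has not improved for that many epochs.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features and targets must be 2-D with matching rows")
    if x.shape[1] != model.config.input_dim:
        raise ValueError(
            f"feature dim {x.shape[1]} != input_dim {model.config.input_dim}"
        )
    if y.shape[1] != model.config.output_dim:
        raise ValueError(
            f"target dim {y.shape[1]} != output_dim {model.config.output_dim}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")

    cfg = model.config
    rng = model.rng if model.rng is not None else np.random.default_rng(cfg.seed)
    model.rng = rng
    if model.feature_mean is None:
        _standardise_fit(model, x)
    xs = _standardise_apply(model, x)

    # ADAM state
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    t = 0
    n = x.shape[0]
    n_epochs = cfg.max_epochs if epochs is None else epochs
    best_val, since_best = np.inf, 0
    for _ in range(n_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.minibatch):
            idx = perm[start : start + cfg.minibatch]
            out, acts, masks, tanhs = _forward(model, xs[idx], dropout_rng=rng)
            grad_w, grad_b = _backward(model, out, y[idx], acts, masks, tanhs)
            t += 1
            corr1 = 1.0 - cfg.beta1**t
            corr2 = 1.0 - cfg.beta2**t
            for k in range(model.n_layers):
                m_w[k] = cfg.beta1 * m_w[k] + (1 - cfg.beta1) * grad_w[k]
                v_w[k] = cfg.beta2 * v_w[k] + (1 - cfg.beta2) * grad_w[k] ** 2
                model.weights[k] -= cfg.learning_rate * (m_w[k] / corr1) / (
                    np.sqrt(v_w[k] / corr2) + cfg.eps
                )
                m_b[k] = cfg.beta1 * m_b[k] + (1 - cfg.beta1) * grad_b[k]
                v_b[k] = cfg.beta2 * v_b[k] + (1 - cfg.beta2) * grad_b[k] ** 2
                model.biases[k] -= cfg.learning_rate * (m_b[k] / corr1) / (
                    np.sqrt(v_b[k] / corr2) + cfg.eps
                )
        out, _, _, _ = _forward(model, xs, dropout_rng=None)
        _, epoch_mse = mse(out, y)
        model.history["train_mse"].append(epoch_mse)
        if validation is not None:
            val_pred = predict(model, validation[0])
            _, val_mse = mse(val_pred, np.asarray(validation[1], dtype=float))
            model.history["val_mse"].append(val_mse)
            if cfg.patience is not None:
                if val_mse < best_val - 1e-12:
                    best_val, since_best = val_mse, 0
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
    return model


def predict(model: MLPModel, features: np.ndarray) -> np.ndarray:
    """Feed-forward with dropout disabled; one output row per input row."""
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.config.input_dim:
        raise ValueError(
            f"feature dim {x.shape[1]} != input_dim {model.config.input_dim}"
        )
    out, _, _, _ = _forward(model, _standardise_apply(model, x), dropout_rng=None)
    return out[0] if single else out


def save_model(model: MLPModel, path: str | Path) -> None:
    """Serialise config, weights, history and metadata to one .npz archive."""
    path = Path(path)
    arrays = {
        f"w{k}": w for k, w in enumerate(model.weights)
    } | {f"b{k}": b for k, b in enumerate(model.biases)}
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_scale"] = model.feature_scale
    meta = {
        "format_version": FORMAT_VERSION,
        "config": asdict(model.config),
        "history": model.history,
        "init_scheme": model.init_scheme,
        "n_layers": model.n_layers,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path: str | Path) -> MLPModel:
    """Restore a model saved by :func:`save_model` (bit-identical predictions)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta["format_version"] != FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {meta['format_version']}"
            )
        config = MLPConfig(**meta["config"])
        n = meta["n_layers"]
        weights = [data[f"w{k}"] for k in range(n)]
        biases = [data[f"b{k}"] for k in range(n)]
        model = MLPModel(
            config, weights, biases, history=meta["history"],
            init_scheme=meta["init_scheme"],
        )
        if "feature_mean" in data:
            model.feature_mean = data["feature_mean"]
            model.feature_scale = data["feature_scale"]
    return model
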