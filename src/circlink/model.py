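"""Two-layer convolutional pair classifier, implemented directly in numpy.

The network mirrors the shape of the pair feature matrix: a first valid
convolution with 2 x n_l1 filters spans both feature rows at once and slides
along the concatenated similarity/association/miRNA-score axis; a second
1 x n_l2 convolution composes those detections; a global max pool keeps one
activation per filter; dropout and a softmax head produce the two class
probabilities.

    input 2 x W -> conv(2 x n_l1, F filters) -> relu
                -> conv(1 x n_l2, F filters) -> relu
                -> global max pool (F values) -> dropout -> dense -> softmax

Forward, backward (exact analytic gradients, verified against numerical
differentiation in the test suite) and Adam are all written against plain
ndarrays, so training is bit-reproducible from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, ShapeError, TrainingError


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training hyperparameters of the pair classifier."""

    n_filters: int = 8
    kernel1: tuple[int, int] = (2, 32)
    kernel2: tuple[int, int] = (1, 16)
    dropout: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.kernel1[0] > 2 or self.kernel2[0] != 1:
            raise ConfigurationError(
                "first kernel height must be <= 2 and second exactly 1"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError(f"dropout must be in [0,1), got {self.dropout}")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


def layer_shapes(config: CnnConfig, feature_width: int) -> dict[str, tuple[int, ...]]:
    """Output shapes (height, length, filters) of each stage for one sample."""
    h1 = 2 - config.kernel1[0] + 1
    l1 = feature_width - config.kernel1[1] + 1
    l2 = l1 - config.kernel2[1] + 1
    if l2 < 1 or h1 < 1:
        raise ShapeError(
            f"feature width {feature_width} too small for kernels "
            f"{config.kernel1} then {config.kernel2}"
        )
    return {
        "conv1": (h1, l1, config.n_filters),
        "conv2": (h1, l2, config.n_filters),
        "pool": (config.n_filters,),
        "output": (2,),
    }


@dataclass
class TrainedModel:
    """Learned parameters plus the config and training-loss trace."""

    params: dict[str, np.ndarray]
    config: CnnConfig
    feature_width: int
    loss_trace: list[float] = field(default_factory=list)


def build_cnn(config: CnnConfig, feature_width: int) -> TrainedModel:
    """Initialize an untrained model (He-scaled Gaussian weights, zero biases)."""
    layer_shapes(config, feature_width)  # validates the width
    rng = np.random.default_rng(config.seed)
    F = config.n_filters
    h1, l1 = config.kernel1
    l2 = config.kernel2[1]
    params = {
        "W1": rng.normal(0.0, np.sqrt(2.0 / (h1 * l1)), size=(F, h1, l1)),
        "b1": np.zeros(F),
        "W2": rng.normal(0.0, np.sqrt(2.0 / (F * l2)), size=(F, F, l2)),
        "b2": np.zeros(F),
        "Wd": rng.normal(0.0, np.sqrt(2.0 / F), size=(F, 2)),
        "bd": np.zeros(2),
    }
    return TrainedModel(params=params, config=config, feature_width=feature_width)


# ---------------------------------------------------------------------------
# forward / backward


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 1-d convolution along the last axis, summing over channels.

    x: (B, C, L); W: (F, C, w); returns (B, F, L - w + 1).
    """
    windows = sliding_window_view(x, W.shape[2], axis=2)  # (B, C, L-w+1, w)
    return np.einsum("bclw,fcw->bfl", windows, W, optimize=True) + b[None, :, None]


def _conv_backward(
    x: np.ndarray, W: np.ndarray, dz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a valid 1-d convolution: returns (dx, dW, db)."""
    windows = sliding_window_view(x, W.shape[2], axis=2)
    dW = np.einsum("bfl,bclw->fcw", dz, windows, optimize=True)
    db = dz.sum(axis=(0, 2))
    dx = np.zeros_like(x)
    L_out = dz.shape[2]
    for w in range(W.shape[2]):
        dx[:, :, w : w + L_out] += np.einsum("bfl,fc->bcl", dz, W[:, :, w])
    return dx, dW, db


def _forward(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    dropout_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Full forward pass; X is (B, 2, W).  Returns all intermediates."""
    z1 = _conv_forward(X, params["W1"], params["b1"])
    a1 = np.maximum(z1, 0.0)
    z2 = _conv_forward(a1, params["W2"], params["b2"])
    a2 = np.maximum(z2, 0.0)
    pool_idx = a2.argmax(axis=2)
    pooled = np.take_along_axis(a2, pool_idx[:, :, None], axis=2)[:, :, 0]
    dropped = pooled if dropout_mask is None else pooled * dropout_mask
    logits = dropped @ params["Wd"] + params["bd"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(shifted)
    probs = expl / expl.sum(axis=1, keepdims=True)
    return {
        "X": X, "z1": z1, "a1": a1, "z2": z2, "a2": a2,
        "pool_idx": pool_idx, "pooled": pooled, "dropped": dropped,
        "logits": logits, "probs": probs,
    }


def _loss_and_grads(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    dropout_mask: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy loss and its exact gradients."""
    cache = _forward(params, X, dropout_mask)
    B = X.shape[0]
    probs = cache["probs"]
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(B), y] + eps).mean())

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = {
        "Wd": cache["dropped"].T @ dlogits,
        "bd": dlogits.sum(axis=0),
    }
    dpool = dlogits @ params["Wd"].T
    if dropout_mask is not None:
        dpool = dpool * dropout_mask
    da2 = np.zeros_like(cache["a2"])
    np.put_along_axis(da2, cache["pool_idx"][:, :, None], dpool[:, :, None], axis=2)
    dz2 = da2 * (cache["z2"] > 0)
    da1, grads["W2"], grads["b2"] = _conv_backward(cache["a1"], params["W2"], dz2)
    dz1 = da1 * (cache["z1"] > 0)
    _, grads["W1"], grads["b1"] = _conv_backward(cache["X"], params["W1"], dz1)
    return loss, grads


# ---------------------------------------------------------------------------
# training and scoring


def train(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    config: CnnConfig | None = None,
) -> TrainedModel:
    """Train with minibatch Adam (or plain SGD) and inverted dropout.

    Deterministic given the config seed: shuffling, dropout masks and
    initialization all derive from one ``numpy`` Generator.  Returns a new
    model; the input model's parameters are not mutated.
    """
    config = config or model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 3 or X.shape[1] != 2 or X.shape[2] != model.feature_width:
        raise ShapeError(
            f"expected features of shape (n, 2, {model.feature_width}), got {X.shape}"
        )
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all() or classes.size < 2:
        raise TrainingError(
            f"training needs both classes with labels in {{0,1}}; saw {classes.tolist()}"
        )

    rng = np.random.default_rng(config.seed)
    params = {k: v.copy() for k, v in model.params.items()}
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    keep = 1.0 - config.dropout
    step = 0
    losses: list[float] = []

    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        for start in range(0, len(X), config.batch_size):
            batch = order[start : start + config.batch_size]
            if config.dropout > 0:
                mask = (
                    rng.random((len(batch), config.n_filters)) < keep
                ).astype(float) / keep
            else:
                mask = None
            loss, grads = _loss_and_grads(params, X[batch], y[batch], mask)
            epoch_loss += loss * len(batch)
            step += 1
            for key, g in grads.items():
                if config.optimizer == "sgd":
                    params[key] -= config.learning_rate * g
                    continue
                m_state[key] = beta1 * m_state[key] + (1 - beta1) * g
                v_state[key] = beta2 * v_state[key] + (1 - beta2) * g * g
                m_hat = m_state[key] / (1 - beta1**step)
                v_hat = v_state[key] / (1 - beta2**step)
                params[key] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        losses.append(epoch_loss / len(X))
    return TrainedModel(
        params=params,
        config=config,
        feature_width=model.feature_width,
        loss_trace=losses,
    )


def score(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Positive-class probability per pair; dropout disabled (deterministic)."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[1] != 2 or X.shape[2] != model.feature_width:
        raise ShapeError(
            f"expected features of shape (n, 2, {model.feature_width}), got {X.shape}"
        )
    probs = _forward(model.params, X)["probs"][:, 1]
    return probs[0] if single else probs


def save_model(model: TrainedModel, path) -> None:
    """Checkpoint parameters + config to an .npz file."""
    import json
    from pathlib import Path

    from dataclasses import asdict

    path = Path(path)
    np.savez_compressed(path, **model.params)
    meta = {
        "config": asdict(model.config),
        "feature_width": model.feature_width,
        "loss_trace": model.loss_trace,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_model(path) -> TrainedModel:
    """Inverse of :func:`save_model`."""
    import json
    from pathlib import Path

    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz) as data:
        params = {k: data[k] for k in data.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = meta["config"]
    cfg["kernel1"] = tuple(cfg["kernel1"])
    cfg["kernel2"] = tuple(cfg["kernel2"])
    return TrainedModel(
        params=params,
        config=CnnConfig(**cfg),
        feature_width=meta["feature_width"],
        loss_trace=meta["loss_trace"],
    )
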