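"""Per-cell encoding models: the CNN and Lasso/Ridge/SVR baselines.

The CNN predicts a cell's (scaled, trial-averaged) response to a 10x10
stimulus through 4 valid 3x3 convolutional layers (32 filters, ReLU), one
2x2 max-pooling layer, a fully connected ReLU layer with dropout 0.5, and a
sigmoid output.  Training minimises mean squared error by momentum SGD
(momentum 0.9, initial learning rate 0.1, multiplicative decay 5e-5 per
update) on a 90/10 train/validation split, stopping when the validation
prediction similarity (Pearson r) has not improved for ``patience`` epochs
and restoring the best-epoch parameters.

Baselines are fitted with fixed hyperparameters: Lasso alpha 0.01, Ridge
alpha 1e4, RBF-kernel SVR with gamma and C both 0.01.

Prediction quality is always the Pearson correlation between predicted and
actual responses ("prediction similarity"), evaluated by seeded k-fold
cross-validation.  The nonlinearity index of a cell is
``1 - r_lasso / r_cnn``: the relative prediction gain of the CNN over the
best linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from ._nn import ConvNet, sgd_momentum_step
from ._seeds import derive_seed, rng_from
from .stimuli import StimulusSet

__all__ = [
    "CNNConfig",
    "TrainResult",
    "EncodingModel",
    "CNNEncoder",
    "build_cnn",
    "train",
    "crossval_similarity",
    "fit_baseline",
    "nonlinearity_index",
    "safe_pearson",
]


def safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 (with a warning) when either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # numerically constant counts as constant (e.g. an intercept-only model)
    tol_a = 1e-12 * (np.abs(a).max() + 1.0)
    tol_b = 1e-12 * (np.abs(b).max() + 1.0)
    if a.std() <= tol_a or b.std() <= tol_b:
        warnings.warn("Pearson similarity of a constant vector reported as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters of the CNN encoder."""

    n_conv_layers: int = 4
    filters_per_layer: int = 32
    kernel_size: int = 3
    pool_size: int = 2
    fc_units: int = 32
    dropout_rate: float = 0.5
    optimizer: str = "sgd"
    learning_rate: float = 0.1
    momentum: float = 0.9
    lr_decay: float = 5e-5
    batch_size: int | None = None  # None -> 5 if n_stim <= 400 else 30
    val_fraction: float = 0.1
    patience: int = 10
    max_epochs: int = 100

    def resolve_batch_size(self, n_train: int) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return 5 if n_train <= 400 else 30


@dataclass
class TrainResult:
    """Outcome of fitting an encoding model."""

    model_ref: object
    prediction_similarity: float
    fold_similarities: list = field(default_factory=list)
    loss_history: list = field(default_factory=list)  # (epoch, train_mse, val_r)


class EncodingModel:
    """Contract: frozen-parameter prediction of responses from images."""

    def predict(self, images: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class CNNEncoder(EncodingModel):
    """The convolutional encoding model (thin wrapper over the numpy net)."""

    def __init__(self, config: CNNConfig, input_size: int = 10):
        self.config = config
        self.net = ConvNet(
            input_size=input_size,
            n_conv=config.n_conv_layers,
            n_filters=config.filters_per_layer,
            kernel=config.kernel_size,
            pool=config.pool_size,
            fc_units=config.fc_units,
            dropout_rate=config.dropout_rate,
        )
        self.input_size = input_size

    def predict(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images)
        if images.ndim == 2:
            images = images[None]
        return self.net.predict(images)

    def output_and_input_grad(self, image: np.ndarray):
        return self.net.output_and_input_grad(np.asarray(image))


class BaselineEncoder(EncodingModel):
    """sklearn regressor on flattened pixels, behind the common contract."""

    def __init__(self, estimator):
        self.estimator = estimator

    def predict(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images)
        if images.ndim == 2:
            images = images[None]
        return self.estimator.predict(images.reshape(images.shape[0], -1))


def build_cnn(config: CNNConfig | None = None, input_size: int = 10) -> CNNEncoder:
    """Construct an (uninitialised) CNN encoder; parameters are drawn at
    training time from the Glorot-uniform scheme."""
    return CNNEncoder(config or CNNConfig(), input_size=input_size)


def _adam_step(w, state, grad, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    m, v = state
    m[:] = beta1 * m + (1 - beta1) * grad
    v[:] = beta2 * v + (1 - beta2) * grad * grad
    mhat = m / (1 - beta1**t)
    vhat = v / (1 - beta2**t)
    w -= lr * mhat / (np.sqrt(vhat) + eps)


def train(
    model: CNNEncoder,
    stimuli: StimulusSet | np.ndarray,
    responses: np.ndarray,
    config: CNNConfig | None = None,
    seed: int = 0,
) -> TrainResult:
    """Fit the CNN to one cell's responses by minibatch momentum SGD.

    A 90/10 train/validation split monitors the validation prediction
    similarity; training stops after ``patience`` epochs without improvement
    (``patience <= 0`` disables early stopping) and the best-validation-epoch
    parameters are restored.
    """
    cfg = config or model.config
    images = stimuli.images if isinstance(stimuli, StimulusSet) else np.asarray(stimuli)
    responses = np.asarray(responses, dtype=float)
    if len(responses) != images.shape[0]:
        raise ValueError("len(responses) must equal the number of stimuli")
    if responses.std() == 0:
        warnings.warn("constant responses: validation similarity will be reported as 0")

    rng = rng_from(seed, 301)
    net = model.net
    net.init_params(derive_seed(seed, 302))

    n = images.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if cfg.val_fraction > 0 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    x_tr = images[tr_idx].astype(np.float32)
    y_tr = responses[tr_idx].astype(np.float32)
    x_val, y_val = images[val_idx].astype(np.float32), responses[val_idx]

    batch = cfg.resolve_batch_size(len(tr_idx))
    velocity = {k: np.zeros_like(v) for k, v in net.params.items()}
    adam_state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in net.params.items()}
    t_update = 0
    best_r, best_params, best_epoch = -np.inf, net.copy_params(), -1
    history = []

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(tr_idx))
        epoch_loss = 0.0
        for start in range(0, len(order), batch):
            idx = order[start : start + batch]
            xb, yb = x_tr[idx], y_tr[idx]
            y_hat, cache = net.forward(xb, train=True, rng=rng)
            err = y_hat - yb
            epoch_loss += float(np.sum(err**2))
            dy = (2.0 / len(idx)) * err
            grads, _ = net.backward(cache, dy)
            t_update += 1
            if cfg.optimizer == "sgd":
                lr_t = cfg.learning_rate / (1.0 + cfg.lr_decay * t_update)
                for k in net.params:
                    sgd_momentum_step(net.params[k], velocity[k], grads[k].reshape(net.params[k].shape), lr_t, cfg.momentum)
            elif cfg.optimizer == "adam":
                for k in net.params:
                    _adam_step(net.params[k], adam_state[k], grads[k].reshape(net.params[k].shape), cfg.learning_rate, t_update)
            else:
                raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
        train_mse = epoch_loss / len(tr_idx)
        if n_val:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val_r = safe_pearson(net.predict(x_val), y_val)
        else:
            val_r = np.nan
        history.append((epoch, train_mse, val_r))
        monitor = val_r if n_val else -train_mse
        if monitor > best_r:
            best_r, best_params, best_epoch = monitor, net.copy_params(), epoch
        if cfg.patience > 0 and epoch - best_epoch >= cfg.patience:
            break
    net.set_params(best_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final_r = safe_pearson(net.predict(x_val), y_val) if n_val else np.nan
    return TrainResult(model_ref=model, prediction_similarity=float(final_r), loss_history=history)


def crossval_similarity(
    model_factory,
    stimuli: StimulusSet | np.ndarray,
    responses: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> TrainResult:
    """k-fold cross-validated prediction similarity of an encoding model.

    ``model_factory(train_images, train_responses, fold_seed)`` must return a
    fitted :class:`EncodingModel`.  Held-out predictions are scored per fold
    by Pearson r and averaged.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    images = stimuli.images if isinstance(stimuli, StimulusSet) else np.asarray(stimuli)
    responses = np.asarray(responses, dtype=float)
    if images.shape[0] < k:
        raise ValueError(f"cannot make {k} folds from {images.shape[0]} stimuli")
    kf = KFold(n_splits=k, shuffle=True, random_state=derive_seed(seed, 303))
    fold_rs, last_model = [], None
    for fold, (tr, te) in enumerate(kf.split(images)):
        m = model_factory(images[tr], responses[tr], derive_seed(seed, 304, fold))
        pred = m.predict(images[te])
        fold_rs.append(safe_pearson(pred, responses[te]))
        last_model = m
    return TrainResult(
        model_ref=last_model,
        prediction_similarity=float(np.mean(fold_rs)),
        fold_similarities=fold_rs,
    )


BASELINE_HYPERPARAMS = {
    "lasso": {"alpha": 0.01},
    "ridge": {"alpha": 1e4},
    "svr": {"gamma": 0.01, "C": 0.01},
}


def make_baseline(kind: str) -> BaselineEncoder:
    from sklearn.linear_model import Lasso, Ridge
    from sklearn.svm import SVR

    if kind == "lasso":
        est = Lasso(alpha=BASELINE_HYPERPARAMS["lasso"]["alpha"], max_iter=5000)
    elif kind == "ridge":
        est = Ridge(alpha=BASELINE_HYPERPARAMS["ridge"]["alpha"])
    elif kind == "svr":
        est = SVR(kernel="rbf", gamma=BASELINE_HYPERPARAMS["svr"]["gamma"], C=BASELINE_HYPERPARAMS["svr"]["C"])
    else:
        raise ValueError(f"unknown baseline kind {kind!r} (expected lasso, ridge, or svr)")
    return BaselineEncoder(est)


def fit_baseline(
    kind: str,
    stimuli: StimulusSet | np.ndarray,
    responses: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> TrainResult:
    """Cross-validated baseline fit with the fixed hyperparameters."""

    def factory(x, y, fold_seed):
        m = make_baseline(kind)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.estimator.fit(x.reshape(x.shape[0], -1), y)
        return m

    return crossval_similarity(factory, stimuli, responses, k=k, seed=seed)


def nonlinearity_index(r_lasso: float, r_cnn: float) -> float:
    """1 - r_lasso / r_cnn; nan (flagged) when r_cnn <= 0."""
    if r_cnn <= 0:
        warnings.warn("nonlinearity index undefined for r_cnn <= 0; reporting nan")
        return float("nan")
    return 1.0 - r_lasso / r_cnn
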