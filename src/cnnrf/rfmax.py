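"""Receptive-field synthesis by regularised activation maximisation.

Starting from a standard-normal random image, the input is updated by
RMSprop gradient ascent on

    E(I) = f(I; W*) - (lambda1 / M) * sum |I|^alpha
                    - (lambda2 / M) * sum ((dI/dx)^2 + (dI/dy)^2)^(beta/2)

where f is the trained encoding model with frozen parameters W*, M is the
pixel count, the second term is an alpha-norm penalty (alpha = 6) and the
third a total-variation penalty (beta = 1) computed with forward differences
and replicate boundary.  lambda1 = 10 and lambda2 = 2 by default.

RMSprop (decay 0.95):

    r <- gamma * r + (1 - gamma) * g^2
    I <- I + lr * g / sqrt(r + 1e-7)

The default schedule runs 300 steps at learning rate 0.05: because RMSprop
normalises each pixel's step to roughly +/- lr, the learning rate sets the
per-step displacement in (standardised) pixel units, and the ascent needs
many sub-pixel steps to settle into the penalty-bounded optimum.  A handful
of unit-size steps moves each pixel by its gradient sign only and does not
converge on these networks.

The ascended image is standardised to mean 0 / SD 1 (the "RF image") and
accepted when the model's predicted response to it reaches at least
``accept_fraction`` of the cell's maximum actual response; otherwise the
whole process retries from a fresh random image.  An ensemble repeats the
estimation independently (100 times for simple/complex-cell analyses, 1,000
for rotation-invariant cells); repeats are batched through the network for
speed but use per-repeat derived seeds, so results are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed, rng_from

__all__ = [
    "RFEstimConfig",
    "RFImage",
    "RFEnsemble",
    "rf_objective",
    "rmsprop_ascend",
    "estimate_rf",
    "estimate_rf_ensemble",
]

_RMSPROP_EPS = 1e-7


@dataclass(frozen=True)
class RFEstimConfig:
    """Regularisation and ascent settings for RF synthesis."""

    lambda1: float = 10.0
    lambda2: float = 2.0
    norm_exponent: float = 6.0  # alpha in the norm penalty
    tv_exponent: float = 1.0  # beta in the total-variation penalty
    n_steps: int = 300
    rmsprop_gamma: float = 0.95
    rmsprop_lr: float = 0.05
    accept_fraction: float = 0.95
    max_attempts: int = 20

    def __post_init__(self):
        if not (0 < self.accept_fraction <= 1):
            raise ValueError("accept_fraction must be in (0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class RFImage:
    """One synthesised RF image (standardised to mean 0 / SD 1)."""

    image: np.ndarray
    predicted_response: float
    activation_fraction: float
    accepted: bool = True
    seed: int | None = None
    n_attempts: int = 1


@dataclass
class RFEnsemble:
    """Independently synthesised RF images for one cell."""

    cell_id: object
    rf_images: list
    seeds: list = field(default_factory=list)

    def __len__(self):
        return len(self.rf_images)

    @property
    def images(self) -> np.ndarray:
        return np.stack([r.image for r in self.rf_images])

    @property
    def activation_fractions(self) -> np.ndarray:
        return np.array([r.activation_fraction for r in self.rf_images])

    @property
    def accepted_mask(self) -> np.ndarray:
        return np.array([r.accepted for r in self.rf_images])

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("rf_images", data=self.images)
            f.create_dataset("activation_fraction", data=self.activation_fractions)
            f.create_dataset("accepted", data=self.accepted_mask.astype(np.int8))
            f.create_dataset("seeds", data=np.asarray(self.seeds, dtype=np.int64))
            f.attrs["cell_id"] = str(self.cell_id)


# -- objective and its pieces ---------------------------------------------

def _forward_diffs(image: np.ndarray):
    """Forward differences with replicate boundary (last row/col diff 0)."""
    gx = np.zeros_like(image)
    gy = np.zeros_like(image)
    gx[:, :-1] = image[:, 1:] - image[:, :-1]
    gy[:-1, :] = image[1:, :] - image[:-1, :]
    return gx, gy


def regulariser_value(image: np.ndarray, config: RFEstimConfig) -> float:
    """The two penalty terms of the objective (to be subtracted)."""
    m = image.size
    norm_term = (config.lambda1 / m) * np.sum(np.abs(image) ** config.norm_exponent)
    gx, gy = _forward_diffs(image)
    tv_term = (config.lambda2 / m) * np.sum((gx**2 + gy**2) ** (config.tv_exponent / 2.0))
    return float(norm_term + tv_term)


def regulariser_gradient(image: np.ndarray, config: RFEstimConfig) -> np.ndarray:
    """Analytic gradient of the penalty terms with respect to the image.

    Accepts a single image (H, W) or a batch (N, H, W); the penalty is
    separable over batch members.
    """
    m = image.shape[-1] * image.shape[-2]
    a = config.norm_exponent
    g_norm = (config.lambda1 / m) * a * np.abs(image) ** (a - 1) * np.sign(image)
    gx = np.zeros_like(image)
    gy = np.zeros_like(image)
    gx[..., :, :-1] = image[..., :, 1:] - image[..., :, :-1]
    gy[..., :-1, :] = image[..., 1:, :] - image[..., :-1, :]
    b = config.tv_exponent
    mag2 = gx**2 + gy**2
    w = b * (mag2 + 1e-12) ** (b / 2.0 - 1.0)
    dgx = w * gx
    dgy = w * gy
    g_tv = np.zeros_like(image)
    g_tv[..., :, :-1] -= dgx[..., :, :-1]
    g_tv[..., :, 1:] += dgx[..., :, :-1]
    g_tv[..., :-1, :] -= dgy[..., :-1, :]
    g_tv[..., 1:, :] += dgy[..., :-1, :]
    g_tv *= config.lambda2 / m
    return g_norm + g_tv


def rf_objective(image: np.ndarray, model, config: RFEstimConfig | None = None) -> float:
    """Model output minus the norm and total-variation penalties."""
    config = config or RFEstimConfig()
    image = np.asarray(image, dtype=float)
    out = float(np.asarray(model.predict(image[None])).ravel()[0])
    return out - regulariser_value(image, config)


def rmsprop_ascend(image: np.ndarray, gradient_fn, config: RFEstimConfig | None = None) -> np.ndarray:
    """``n_steps`` RMSprop ascent updates of the image.

    ``gradient_fn(image)`` must return dE/dI with the image's shape.  A
    non-finite gradient raises ``FloatingPointError`` (the ensemble driver
    catches it and retries with a fresh seed).
    """
    config = config or RFEstimConfig()
    image = np.asarray(image, dtype=float).copy()
    r = np.zeros_like(image)
    for _ in range(config.n_steps):
        g = np.asarray(gradient_fn(image), dtype=float)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient during RF ascent")
        r = config.rmsprop_gamma * r + (1.0 - config.rmsprop_gamma) * g**2
        image = image + config.rmsprop_lr * g / np.sqrt(r + _RMSPROP_EPS)
    return image


def _standardise_image(image: np.ndarray) -> np.ndarray:
    sd = image.std()
    if sd == 0:
        raise FloatingPointError("degenerate (constant) image after ascent")
    return (image - image.mean()) / sd


def _objective_gradient(model, config):
    def grad(image):
        _, dmodel = model.output_and_input_grad(image)
        return dmodel - regulariser_gradient(image, config)

    return grad


def estimate_rf(
    model,
    max_actual_response: float,
    config: RFEstimConfig | None = None,
    seed: int = 0,
) -> RFImage:
    """Synthesise one RF image, retrying until the acceptance gate passes.

    The gate compares the model's predicted response to the *standardised*
    image against ``accept_fraction * max_actual_response``.  If all
    ``max_attempts`` fail, the best attempt is returned with
    ``accepted=False``.
    """
    if max_actual_response <= 0:
        raise ValueError("max_actual_response must be > 0")
    config = config or RFEstimConfig()
    grad = _objective_gradient(model, config)
    size = model.input_size
    best: RFImage | None = None
    for attempt in range(config.max_attempts):
        rng = rng_from(seed, 401, attempt)
        init = rng.standard_normal((size, size))
        try:
            final = rmsprop_ascend(init, grad, config)
            rf = _standardise_image(final)
        except FloatingPointError as exc:
            warnings.warn(f"RF attempt {attempt} aborted ({exc}); retrying with a new seed")
            continue
        pred = float(np.asarray(model.predict(rf[None])).ravel()[0])
        frac = pred / max_actual_response
        cand = RFImage(rf, pred, frac, accepted=frac >= config.accept_fraction, seed=seed, n_attempts=attempt + 1)
        if cand.accepted:
            return cand
        if best is None or cand.activation_fraction > best.activation_fraction:
            best = cand
    warnings.warn("max_attempts exhausted; returning best below-threshold RF image")
    return best


def _ascend_batch(inits: np.ndarray, model, config: RFEstimConfig) -> np.ndarray:
    """Batched RMSprop ascent (one image per row; outputs are independent,
    so a single backward pass yields every image's own gradient)."""
    images = inits.astype(float).copy()
    r = np.zeros_like(images)
    n = images.shape[0]
    has_net = hasattr(model, "net")
    for _ in range(config.n_steps):
        if has_net:
            _, cache = model.net.forward(images, train=False)
            _, dmodel = model.net.backward(cache, np.ones(n, dtype=np.float32))
            g = dmodel.astype(float)
        else:
            g = np.stack([model.output_and_input_grad(im)[1] for im in images])
        g -= regulariser_gradient(images, config)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient during batched RF ascent")
        r = config.rmsprop_gamma * r + (1.0 - config.rmsprop_gamma) * g**2
        images = images + config.rmsprop_lr * g / np.sqrt(r + _RMSPROP_EPS)
    return images


def estimate_rf_ensemble(
    model,
    max_actual_response: float,
    n_repeats: int = 100,
    config: RFEstimConfig | None = None,
    seed: int = 0,
    cell_id: object = None,
) -> RFEnsemble:
    """``n_repeats`` independent RF estimations with derived per-repeat seeds.

    Repeats are batched through the network per attempt round; each repeat's
    initial image comes from its own derived seed, so the ensemble is
    reproducible for a fixed master seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if max_actual_response <= 0:
        raise ValueError("max_actual_response must be > 0")
    config = config or RFEstimConfig()
    size = model.input_size
    rep_seeds = [derive_seed(seed, 402, i) for i in range(n_repeats)]
    results: dict[int, RFImage] = {}
    best: dict[int, RFImage] = {}
    active = list(range(n_repeats))
    for attempt in range(config.max_attempts):
        if not active:
            break
        inits = np.stack(
            [rng_from(rep_seeds[i], 401, attempt).standard_normal((size, size)) for i in active]
        )
        finals = _ascend_batch(inits, model, config)
        preds_images = []
        kept = []
        for row, i in enumerate(active):
            sd = finals[row].std()
            if sd == 0 or not np.all(np.isfinite(finals[row])):
                continue
            preds_images.append((finals[row] - finals[row].mean()) / sd)
            kept.append(i)
        if not kept:
            continue
        preds = np.asarray(model.predict(np.stack(preds_images))).ravel()
        still_active = [i for i in active if i not in kept]
        for rf, i, pred in zip(preds_images, kept, preds):
            frac = float(pred) / max_actual_response
            cand = RFImage(rf, float(pred), frac, accepted=frac >= config.accept_fraction,
                           seed=rep_seeds[i], n_attempts=attempt + 1)
            if cand.accepted:
                results[i] = cand
            else:
                if i not in best or cand.activation_fraction > best[i].activation_fraction:
                    best[i] = cand
                still_active.append(i)
        active = sorted(still_active)
    for i in active:
        warnings.warn(f"RF repeat {i}: max_attempts exhausted; keeping best below-threshold image")
        results[i] = best[i]
    ensemble = RFEnsemble(cell_id=cell_id, rf_images=[results[i] for i in range(n_repeats)], seeds=rep_seeds)
    return ensemble
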