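"""A small convolutional network implemented on numpy.

The architecture mirrors the encoding model used throughout the package:
``n_conv`` valid 3x3 convolutional layers (ReLU), one 2x2 max-pooling layer,
one fully connected ReLU layer with dropout at training time, and a scalar
sigmoid output.  On a 10x10 input with four convolutional layers the feature
maps shrink 8 -> 6 -> 4 -> 2 and pooling leaves a 1x1x32 tensor.

Everything is float32.  Convolutions use im2col + matmul; the backward pass
returns both parameter gradients and the gradient with respect to the input
image, which activation maximisation consumes directly.

Optimisers:

* momentum SGD  —  v <- m*v + eps_t*g ;  w <- w - v,  with the learning rate
  annealed as eps_t = eps0 / (1 + decay * t) per update (t counts updates).
* Adam with its published defaults (beta1=0.9, beta2=0.999, eps=1e-8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet", "sgd_momentum_step", "glorot_uniform"]


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def sgd_momentum_step(w, v, grad, lr, momentum):
    """One momentum-SGD update: v <- m*v + lr*g ; w <- w - v (in place)."""
    v *= momentum
    v += lr * grad
    w -= v
    return w, v


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (N, H, W, C) -> (N, oh, ow, k*k*C), patch order (ki, kj, c)
    n, h, w, c = x.shape
    v = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, oh, ow, C, k, k)
    v = v.transpose(0, 1, 2, 4, 5, 3)  # (N, oh, ow, k, k, C)
    return np.ascontiguousarray(v).reshape(n, h - k + 1, w - k + 1, k * k * c)


def _col2im(dcols: np.ndarray, h: int, w: int, c: int, k: int) -> np.ndarray:
    # dcols: (N, oh, ow, k*k*C) -> dx (N, H, W, C)
    n, oh, ow, _ = dcols.shape
    d = dcols.reshape(n, oh, ow, k, k, c)
    dx = np.zeros((n, h, w, c), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, i : i + oh, j : j + ow, :] += d[:, :, :, i, j, :]
    return dx


@dataclass
class ConvNet:
    """Conv stack -> max-pool -> FC(ReLU, dropout) -> sigmoid scalar."""

    input_size: int
    n_conv: int = 4
    n_filters: int = 32
    kernel: int = 3
    pool: int = 2
    fc_units: int = 32
    dropout_rate: float = 0.5
    params: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        size = self.input_size
        for _ in range(self.n_conv):
            size -= self.kernel - 1
            if size < 1:
                raise ValueError(
                    f"input size {self.input_size} too small for {self.n_conv} "
                    f"valid {self.kernel}x{self.kernel} convolutions "
                    f"(spatial size reaches {size})"
                )
        if size % self.pool != 0:
            raise ValueError(
                f"feature map size {size} after convolutions is not divisible "
                f"by pool size {self.pool}"
            )
        self._conv_out = size
        self._pooled = size // self.pool
        self._flat = self._pooled * self._pooled * self.n_filters

    # -- initialisation -------------------------------------------------
    def init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        k, nf = self.kernel, self.n_filters
        p = {}
        c_in = 1
        for li in range(self.n_conv):
            fan_in, fan_out = k * k * c_in, k * k * nf
            p[f"W{li}"] = glorot_uniform(rng, (k * k * c_in, nf), fan_in, fan_out)
            p[f"b{li}"] = np.zeros(nf, dtype=np.float32)
            c_in = nf
        p["Wfc"] = glorot_uniform(rng, (self._flat, self.fc_units), self._flat, self.fc_units)
        p["bfc"] = np.zeros(self.fc_units, dtype=np.float32)
        p["Wout"] = glorot_uniform(rng, (self.fc_units, 1), self.fc_units, 1)
        p["bout"] = np.zeros(1, dtype=np.float32)
        self.params = p

    def param_names(self):
        return list(self.params.keys())

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """x: (N, H, W) -> (y (N,), cache)."""
        p = self.params
        a = x.astype(np.float32, copy=False)[..., None]  # (N,H,W,1)
        cache: dict = {"x_shapes": [], "cols": [], "relu": []}
        k = self.kernel
        for li in range(self.n_conv):
            cols = _im2col(a, k)
            z = cols @ p[f"W{li}"] + p[f"b{li}"]
            mask = z > 0
            a_next = z * mask
            cache["x_shapes"].append(a.shape)
            cache["cols"].append(cols)
            cache["relu"].append(mask)
            a = a_next
        # max pool over the full remaining spatial extent in pool x pool tiles
        n = a.shape[0]
        s, pl = self._conv_out, self.pool
        tiles = a.reshape(n, s // pl, pl, s // pl, pl, self.n_filters)
        tiles = tiles.transpose(0, 1, 3, 2, 4, 5).reshape(n, s // pl, s // pl, pl * pl, self.n_filters)
        argmax = tiles.argmax(axis=3)
        pooled = np.take_along_axis(tiles, argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        cache["pool_argmax"] = argmax
        flat = pooled.reshape(n, self._flat)
        zfc = flat @ p["Wfc"] + p["bfc"]
        fc_mask = zfc > 0
        h = zfc * fc_mask
        if train and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("training forward pass with dropout requires an rng")
            drop = (rng.random(h.shape) >= self.dropout_rate).astype(np.float32)
            h = h * drop / (1.0 - self.dropout_rate)
            cache["drop"] = drop
        else:
            cache["drop"] = None
        zout = h @ p["Wout"] + p["bout"]
        y = 1.0 / (1.0 + np.exp(-zout[:, 0]))
        cache.update(flat=flat, fc_mask=fc_mask, h=h, y=y)
        return y, cache

    def backward(self, cache: dict, dy: np.ndarray):
        """Backprop from dE/dy.  Returns (grads dict, dE/dx (N,H,W))."""
        p = self.params
        y = cache["y"]
        dz = (dy * y * (1.0 - y))[:, None].astype(np.float32)  # sigmoid
        grads = {}
        grads["Wout"] = cache["h"].T @ dz
        grads["bout"] = dz.sum(axis=0)
        dh = dz @ p["Wout"].T
        if cache["drop"] is not None:
            dh = dh * cache["drop"] / (1.0 - self.dropout_rate)
        dzfc = dh * cache["fc_mask"]
        grads["Wfc"] = cache["flat"].T @ dzfc
        grads["bfc"] = dzfc.sum(axis=0)
        dflat = dzfc @ p["Wfc"].T
        n = dflat.shape[0]
        s, pl = self._conv_out, self.pool
        dpooled = dflat.reshape(n, s // pl, s // pl, self.n_filters)
        dtiles = np.zeros((n, s // pl, s // pl, pl * pl, self.n_filters), dtype=np.float32)
        np.put_along_axis(dtiles, cache["pool_argmax"][:, :, :, None, :], dpooled[:, :, :, None, :], axis=3)
        da = (
            dtiles.reshape(n, s // pl, s // pl, pl, pl, self.n_filters)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, s, s, self.n_filters)
        )
        k = self.kernel
        for li in range(self.n_conv - 1, -1, -1):
            dzc = da * cache["relu"][li]
            cols = cache["cols"][li]
            oh = cols.shape[1]
            dz2 = dzc.reshape(-1, self.n_filters)
            grads[f"W{li}"] = cols.reshape(-1, cols.shape[-1]).T @ dz2
            grads[f"b{li}"] = dz2.sum(axis=0)
            dcols = dzc @ p[f"W{li}"].T
            nshape = cache["x_shapes"][li]
            da = _col2im(dcols.reshape(cols.shape), nshape[1], nshape[2], nshape[3], k)
        return grads, da[..., 0]

    # -- inference helpers ----------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.forward(np.asarray(x), train=False)
        return y

    def output_and_input_grad(self, image: np.ndarray):
        """Model output for one image and d(output)/d(image)."""
        y, cache = self.forward(image[None], train=False)
        _, dx = self.backward(cache, np.ones(1, dtype=np.float32))
        return float(y[0]), dx[0].astype(np.float64)
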