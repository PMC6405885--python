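"""RF-image analysis: Gabor fitting, linear RFs, and similarity metrics.

Gabor fitting minimises the pixelwise absolute error between an RF image and
a Gabor kernel by bounded SLSQP, multistarted from a 7x7 grid of initial
centres (at L * {1/8 .. 7/8}); the initial orientation and carrier frequency
come from the image's spectral peak.  Bounds follow the kernel-sanity
constraints 0 <= x0/Lx <= 1, 0 < sigma1/Lx <= 0.2, pi/3 <= k0 <= pi (and the
y counterparts).  Fit quality is the pixelwise Pearson correlation between
the image and the fitted kernel.

The linear RF uses the regularised-pseudoinverse (ridge) estimator
w = (S^T S + lambda I)^-1 S^T r with lambda chosen by exhaustive grid search
under 10-fold cross-validation on the Pearson prediction similarity.

Similarity between two RFs (or an RF and a generator filter) is the
normalised pixelwise dot product (cosine); the orientation agreement between
two sets of axial angles is the Fisher-Lee circular correlation computed on
doubled angles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import KFold

from ._seeds import derive_seed
from .encoders import safe_pearson
from .simcells import GaborParams, gabor_kernel
from .stimuli import StimulusSet

__all__ = [
    "GaborFit",
    "LinearRF",
    "fit_gabor",
    "estimate_linear_rf",
    "rf_dot_similarity",
    "max_ensemble_similarity",
    "circular_orientation_correlation",
]


@dataclass
class GaborFit:
    """Best Gabor kernel for an RF image."""

    params: GaborParams
    fit_similarity: float
    fit_error: float  # summed pixelwise absolute error

    @property
    def kernel(self) -> np.ndarray:
        return gabor_kernel(self.params)


@dataclass
class LinearRF:
    """Regularised-pseudoinverse RF with its CV-selected penalty."""

    image: np.ndarray
    reg_parameter: float
    cv_similarity: float


def _canonicalise(p: np.ndarray) -> np.ndarray:
    """Resolve Gabor parameter degeneracies: A >= 0, theta in [0, pi),
    tau in [0, 2*pi).  (theta + pi, tau) and (theta, -tau) give the same
    kernel, as do (A, tau) and (-A, tau + pi)."""
    a, s1, s2, k0, tau, x0, y0, th = p
    if a < 0:
        a, tau = -a, tau + np.pi
    th = th % (2 * np.pi)
    if th >= np.pi:
        th -= np.pi
        tau = -tau
    return np.array([a, s1, s2, k0, tau % (2 * np.pi), x0, y0, th])


def _spectral_init(rf: np.ndarray) -> tuple[float, float]:
    """Initial (theta, k0) from the image's dominant spatial frequency."""
    ly, lx = rf.shape
    spec = np.abs(np.fft.fft2(rf))
    fx = np.fft.fftfreq(lx)[None, :]
    fy = np.fft.fftfreq(ly)[:, None]
    spec = spec * (np.hypot(np.broadcast_to(fx, spec.shape), np.broadcast_to(fy, spec.shape)) > 0)
    iy, ix = np.unravel_index(np.argmax(spec), spec.shape)
    kx, ky = 2 * np.pi * fx[0, ix], 2 * np.pi * fy[iy, 0]
    k = float(np.hypot(kx, ky))
    # carrier direction (-sin theta, cos theta) is parallel to (kx, ky)
    theta = float(np.arctan2(-kx, ky)) % np.pi
    return theta, k


def fit_gabor(rf_image: np.ndarray, n_centre_starts: int = 7, maxiter: int = 60) -> GaborFit:
    """Bounded least-absolute-error Gabor fit with a 7x7 multistart grid."""
    rf = np.asarray(rf_image, dtype=float)
    ly, lx = rf.shape
    theta0, k0_init = _spectral_init(rf)
    k0_init = float(np.clip(k0_init, np.pi / 3, np.pi))
    amp0 = float(np.abs(rf).max())
    bounds = [
        (0.0, 10.0 * max(amp0, 1e-6)),  # A
        (0.02 * lx, 0.2 * lx),  # sigma1
        (0.02 * ly, 0.2 * ly),  # sigma2
        (np.pi / 3, np.pi),  # k0
        (-2 * np.pi, 4 * np.pi),  # tau (canonicalised afterwards)
        (0.0, float(lx)),  # x0
        (0.0, float(ly)),  # y0
        (-np.pi, 2 * np.pi),  # theta (canonicalised afterwards)
    ]

    def objective(p):
        g = gabor_kernel(GaborParams(
            A=max(p[0], 0.0), sigma1=max(p[1], 1e-6), sigma2=max(p[2], 1e-6),
            k0=p[3], tau=p[4], x0=np.clip(p[5], 0, lx), y0=np.clip(p[6], 0, ly),
            theta=p[7], Lx=lx, Ly=ly))
        return float(np.abs(rf - g).sum())

    centres = np.linspace(1.0 / 8.0, 7.0 / 8.0, n_centre_starts)
    best_p, best_err = None, np.inf
    for cx in centres:
        for cy in centres:
            p0 = np.array([amp0, 0.15 * lx, 0.15 * ly, k0_init, 0.0, cx * lx, cy * ly, theta0])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = minimize(objective, p0, method="SLSQP", bounds=bounds,
                                   options={"maxiter": maxiter, "ftol": 1e-6})
            except Exception:
                continue
            if np.all(np.isfinite(res.x)) and res.fun < best_err:
                best_err, best_p = float(res.fun), res.x
    if best_p is None:
        warnings.warn("Gabor fit failed on all starts; flagging unfit")
        return GaborFit(
            params=GaborParams(A=0, sigma1=1, sigma2=1, k0=np.pi / 3, tau=0, x0=lx / 2, y0=ly / 2, theta=0, Lx=lx, Ly=ly),
            fit_similarity=-1.0,
            fit_error=float("inf"),
        )
    c = _canonicalise(best_p)
    params = GaborParams(A=c[0], sigma1=c[1], sigma2=c[2], k0=c[3], tau=c[4],
                         x0=float(np.clip(c[5], 0, lx)), y0=float(np.clip(c[6], 0, ly)),
                         theta=c[7], Lx=lx, Ly=ly)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = safe_pearson(rf.ravel(), gabor_kernel(params).ravel())
    return GaborFit(params=params, fit_similarity=sim, fit_error=best_err)


def estimate_linear_rf(
    stimuli: StimulusSet | np.ndarray,
    responses: np.ndarray,
    grid: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
) -> LinearRF:
    """Ridge-form regularised pseudoinverse RF with grid-searched penalty."""
    images = stimuli.images if isinstance(stimuli, StimulusSet) else np.asarray(stimuli)
    n = images.shape[0]
    shape = images.shape[1:]
    if n <= k:
        raise ValueError(f"need more than k={k} stimuli (got {n})")
    s = images.reshape(n, -1)
    r = np.asarray(responses, dtype=float)
    grid = np.logspace(-3, 3, 13) if grid is None else np.asarray(grid, dtype=float)
    kf = KFold(n_splits=k, shuffle=True, random_state=derive_seed(seed, 501))
    scores = np.zeros(len(grid))
    counts = np.zeros(len(grid))
    for tr, te in kf.split(s):
        u, sv, vt = np.linalg.svd(s[tr], full_matrices=False)
        utr = u.T @ r[tr]
        for gi, lam in enumerate(grid):
            if lam == 0 and np.any(sv < 1e-12):
                warnings.warn("singular system at lambda=0; grid point skipped")
                continue
            w = vt.T @ (sv / (sv**2 + lam) * utr)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores[gi] += safe_pearson(s[te] @ w, r[te])
            counts[gi] += 1
    valid = counts > 0
    mean_scores = np.full(len(grid), -np.inf)
    mean_scores[valid] = scores[valid] / counts[valid]
    best = int(np.argmax(mean_scores))
    lam = float(grid[best])
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    w = vt.T @ (sv / (sv**2 + lam) * (u.T @ r))
    return LinearRF(image=w.reshape(shape), reg_parameter=lam, cv_similarity=float(mean_scores[best]))


def rf_dot_similarity(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Normalised pixelwise dot product (cosine) of two images."""
    a = np.asarray(image_a, dtype=float).ravel()
    b = np.asarray(image_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero-norm image in dot similarity; reporting nan")
        return float("nan")
    return float(a @ b / (na * nb))


def max_ensemble_similarity(reference: np.ndarray, ensemble) -> float:
    """Max over ensemble members of |cosine| with the reference image.

    The larger of the +/- member similarities absorbs the contrast-polarity
    sign ambiguity of synthesised RF images.
    """
    images = ensemble.images if hasattr(ensemble, "images") else np.asarray(ensemble)
    if len(images) == 0:
        raise ValueError("empty ensemble")
    sims = [abs(rf_dot_similarity(reference, img)) for img in images]
    return float(np.nanmax(sims))


def circular_orientation_correlation(angles_a: np.ndarray, angles_b: np.ndarray) -> float:
    """Fisher-Lee circular correlation of two axial-angle samples.

    Orientations have period pi, so angles are doubled before applying the
    Fisher-Lee statistic

        r = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j)
            / sqrt(sum_{i<j} sin^2(a_i - a_j) * sum_{i<j} sin^2(b_i - b_j)).
    """
    a = 2.0 * np.asarray(angles_a, dtype=float)
    b = 2.0 * np.asarray(angles_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("angle vectors must be 1-D with equal lengths")
    if len(a) < 3:
        raise ValueError("need at least 3 angle pairs")
    da = np.sin(a[:, None] - a[None, :])
    db = np.sin(b[:, None] - b[None, :])
    iu = np.triu_indices(len(a), 1)
    num = float(np.sum(da[iu] * db[iu]))
    den = float(np.sqrt(np.sum(da[iu] ** 2) * np.sum(db[iu] ** 2)))
    if den == 0:
        warnings.warn("zero angular variance; circular correlation undefined (nan)")
        return float("nan")
    return num / den
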