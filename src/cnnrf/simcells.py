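"""Ground-truth simulated cells and their noisy trial responses.

Three cell models, each built from Gabor-shaped linear filters:

* simple cell  — linear-nonlinear cascade,  R = max(s . f1, 0) + noise
* complex cell — energy model,  R = sqrt((s . f1)^2 + (s . f2)^2) + noise,
  where f2 equals f1 with the sinusoid phase shifted by 90 degrees
* rotation-invariant cell — R = max_i(s . f_i) + noise over 36 subunit
  filters whose orientations step by 5 degrees

The Gabor kernel is the product of a 2-D Gaussian envelope and a sinusoidal
carrier,

    G(x, y) = A exp(-(x'^2 / 2 sigma1^2 + y'^2 / 2 sigma2^2)) cos(k0 y' + tau)
    (x', y') = R(theta) (x - x0, y - y0)

with pixel coordinates (x, y) = (column, row), 0-based integer centres, and
theta measured counter-clockwise from the x-axis.  The carrier varies along
y', so the stripe (orientation) axis is x'.

Noise is additive Gaussian (SD 1 by default), drawn independently per trial
and per stimulus; the trial-averaged response is min-max scaled to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np

from ._seeds import rng_from
from .stimuli import StimulusSet

__all__ = [
    "GaborParams",
    "SimCellSpec",
    "ResponseRecord",
    "gabor_kernel",
    "sample_cell",
    "simulate_responses",
    "calibrate_noise",
    "N_ROTINV_SUBUNITS",
]

N_ROTINV_SUBUNITS = 36
CELL_TYPES = ("simple", "complex", "rotation_invariant")


@dataclass
class GaborParams:
    """Parameters of a Gabor kernel on an Lx x Ly pixel field."""

    A: float
    sigma1: float
    sigma2: float
    k0: float
    tau: float
    x0: float
    y0: float
    theta: float
    Lx: int = 10
    Ly: int = 10

    def __post_init__(self):
        if self.A < 0:
            raise ValueError("amplitude A must be >= 0")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("envelope SDs sigma1, sigma2 must be > 0")
        if not (0 <= self.x0 <= self.Lx and 0 <= self.y0 <= self.Ly):
            raise ValueError("centre (x0, y0) must lie within the field")

    def with_(self, **kw) -> "GaborParams":
        d = asdict(self)
        d.update(kw)
        return GaborParams(**d)


def gabor_kernel(params: GaborParams) -> np.ndarray:
    """Evaluate the Gabor kernel at integer pixel centres.

    Returns an (Ly, Lx) array indexed [row=y, col=x] so that
    ``kernel[y, x] == G(x, y)``.
    """
    p = params
    x = np.arange(p.Lx)[None, :].astype(float)
    y = np.arange(p.Ly)[:, None].astype(float)
    ct, st = np.cos(p.theta), np.sin(p.theta)
    xp = ct * (x - p.x0) + st * (y - p.y0)
    yp = -st * (x - p.x0) + ct * (y - p.y0)
    env = np.exp(-(xp**2 / (2 * p.sigma1**2) + yp**2 / (2 * p.sigma2**2)))
    return p.A * env * np.cos(p.k0 * yp + p.tau)


@dataclass
class SimCellSpec:
    """A simulated cell: its type, filters, and noise/trial settings."""

    cell_type: str
    filter_params: list
    noise_sd: float = 1.0
    n_trials: int = 4
    seed: int | None = None
    filters: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        expected = {"simple": 1, "complex": 2, "rotation_invariant": N_ROTINV_SUBUNITS}
        if len(self.filter_params) != expected[self.cell_type]:
            raise ValueError(
                f"{self.cell_type} cell requires {expected[self.cell_type]} filters, "
                f"got {len(self.filter_params)}"
            )
        if not self.filters:
            self.filters = [gabor_kernel(p) for p in self.filter_params]

    def to_json(self) -> str:
        return json.dumps(
            {
                "cell_type": self.cell_type,
                "noise_sd": self.noise_sd,
                "n_trials": self.n_trials,
                "seed": self.seed,
                "filter_params": [asdict(p) for p in self.filter_params],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SimCellSpec":
        d = json.loads(text)
        return cls(
            cell_type=d["cell_type"],
            filter_params=[GaborParams(**p) for p in d["filter_params"]],
            noise_sd=d["noise_sd"],
            n_trials=d["n_trials"],
            seed=d["seed"],
        )


@dataclass
class ResponseRecord:
    """Per-trial responses and the scaled trial average of one cell."""

    per_trial: np.ndarray  # (n_trials, n_stim)
    averaged: np.ndarray  # (n_stim,), min-max scaled to [0, 1]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("per_trial", data=self.per_trial)
            f.create_dataset("averaged", data=self.averaged)


# -- sampling -------------------------------------------------------------

def sample_cell(cell_type: str, Lx: int = 10, Ly: int = 10, seed: int = 0) -> SimCellSpec:
    """Draw a cell's Gabor parameters uniformly from the model ranges.

    Simple/complex: x0/Lx, y0/Ly ~ U(0.1, 0.9); A ~ U(0, 1);
    sigma1/Lx, sigma2/Ly ~ U(0.1, 0.2); k0 ~ U(pi/3, pi); theta, tau ~ U(0, 2pi).
    The complex cell's second filter shares every parameter with the first,
    with tau offset by pi/2 (a 90-degree phase shift).

    Rotation-invariant: A ~ U(0, 1); sigma/L ~ U(0.15, 0.2);
    k0 ~ U(pi/3, 2pi/3); tau ~ U(0, 2pi); centre fixed at (Lx/2, Ly/2);
    the i-th of 36 subunits has theta = 5*(i-1) degrees.
    """
    rng = rng_from(seed, 201)
    if cell_type in ("simple", "complex"):
        base = GaborParams(
            A=rng.uniform(0, 1),
            sigma1=rng.uniform(0.1, 0.2) * Lx,
            sigma2=rng.uniform(0.1, 0.2) * Ly,
            k0=rng.uniform(np.pi / 3, np.pi),
            tau=rng.uniform(0, 2 * np.pi),
            x0=rng.uniform(0.1, 0.9) * Lx,
            y0=rng.uniform(0.1, 0.9) * Ly,
            theta=rng.uniform(0, 2 * np.pi),
            Lx=Lx,
            Ly=Ly,
        )
        if cell_type == "simple":
            fparams = [base]
        else:
            fparams = [base, base.with_(tau=base.tau + np.pi / 2)]
    elif cell_type == "rotation_invariant":
        base = GaborParams(
            A=rng.uniform(0, 1),
            sigma1=rng.uniform(0.15, 0.2) * Lx,
            sigma2=rng.uniform(0.15, 0.2) * Ly,
            k0=rng.uniform(np.pi / 3, 2 * np.pi / 3),
            tau=rng.uniform(0, 2 * np.pi),
            x0=Lx / 2,
            y0=Ly / 2,
            theta=0.0,
            Lx=Lx,
            Ly=Ly,
        )
        fparams = [base.with_(theta=np.deg2rad(5.0 * i)) for i in range(N_ROTINV_SUBUNITS)]
    else:
        raise ValueError(f"unknown cell_type {cell_type!r}")
    return SimCellSpec(cell_type=cell_type, filter_params=fparams, seed=seed)


# -- response generation ---------------------------------------------------

def raw_response(spec: SimCellSpec, stimuli_flat: np.ndarray) -> np.ndarray:
    """Noise-free model output for flattened stimuli (n_stim, Lx*Ly)."""
    proj = stimuli_flat @ np.stack([f.ravel() for f in spec.filters], axis=1)
    if spec.cell_type == "simple":
        return np.maximum(proj[:, 0], 0.0)
    if spec.cell_type == "complex":
        return np.sqrt(proj[:, 0] ** 2 + proj[:, 1] ** 2)
    # rotation-invariant: subunit outputs are not rectified before the max
    return proj.max(axis=1)


def simulate_responses(spec: SimCellSpec, stimuli: StimulusSet, seed: int = 0) -> ResponseRecord:
    """Noisy per-trial responses plus the [0, 1]-scaled trial average.

    Noise is added per trial and stimulus before averaging; the trial mean is
    then min-max scaled over the full stimulus set.
    """
    lx, ly = stimuli.shape
    fy, fx = spec.filters[0].shape
    if (fx, fy) != (lx, ly):
        raise ValueError(f"stimulus field {lx}x{ly} does not match filter field {fx}x{fy}")
    clean = raw_response(spec, stimuli.flat)
    rng = rng_from(seed, 202)
    noise = spec.noise_sd * rng.standard_normal((spec.n_trials, stimuli.n_stim))
    per_trial = clean[None, :] + noise
    mean = per_trial.mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi == lo:
        raise ValueError("constant trial-mean response: [0, 1] scaling is undefined")
    return ResponseRecord(per_trial=per_trial, averaged=(mean - lo) / (hi - lo))


def calibrate_noise(
    spec: SimCellSpec,
    stimuli: StimulusSet,
    target_variability: float | None = None,
) -> float:
    """Noise SD for the simulator.

    With no target this returns the default SD of 1.0 (which gives
    trial-to-trial variability comparable to calcium-imaging data for these
    response magnitudes).  Given a target trial-to-trial variability — the
    ratio of the across-trial SD to the SD of the noise-free response across
    stimuli — the matching noise SD is found by bisection.
    """
    if target_variability is None:
        return 1.0
    if target_variability < 0:
        raise ValueError("target variability must be >= 0")
    clean = raw_response(spec, stimuli.flat)
    signal_sd = float(clean.std())
    if signal_sd == 0:
        warnings.warn("noise-free response is constant; variability target is unattainable")
        return 0.0
    if target_variability == 0:
        return 0.0
    from scipy.optimize import brentq

    def gap(sd):  # across-trial SD of an additive Gaussian equals sd exactly
        return sd / signal_sd - target_variability

    hi = max(1.0, 10 * target_variability * signal_sd)
    while gap(hi) < 0:
        hi *= 2
    return float(brentq(gap, 0.0, hi, xtol=1e-9))
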