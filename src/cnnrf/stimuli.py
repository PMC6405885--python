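"""Stimulus image sets: generation, preprocessing, and I/O.

The encoding models in this package operate on small grey-scale images that
are (i) down-sampled to a common size (10x10 pixels by default) and (ii)
standardised per pixel position — each pixel has mean 0 and SD 1 across the
stimulus set.  Two synthetic generators are provided:

* white-noise stimuli (independent standard-normal pixels), and
* "natural-surrogate" stimuli with approximately 1/f^exponent amplitude
  spectra, a stand-in for calibrated natural-image databases that captures
  the long-range spatial correlations of natural scenes.

Both return a :class:`StimulusSet` whose stored per-pixel statistics make the
standardisation invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import rng_from

__all__ = [
    "StimulusSet",
    "make_white_noise_stimuli",
    "make_natural_surrogate_stimuli",
    "preprocess_stimuli",
]


@dataclass
class StimulusSet:
    """A preprocessed stimulus set.

    Attributes
    ----------
    images : (n_stim, Lx, Ly) array
        Standardised images; each pixel position has mean 0 / SD 1 across
        stimuli.
    pixel_mean, pixel_sd : (Lx, Ly) arrays
        Raw-unit per-pixel statistics; ``raw = images * pixel_sd + pixel_mean``.
    source_tag : str
        One of ``white_noise``, ``natural_surrogate``, ``external``.
    seed : int | None
        Seed used by the generator, if any.
    """

    images: np.ndarray
    pixel_mean: np.ndarray
    pixel_sd: np.ndarray
    source_tag: str = "external"
    seed: int | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be (n_stim, Lx, Ly)")
        if self.images.shape[0] < 2:
            raise ValueError(
                "a stimulus set needs n_stim >= 2 (per-pixel standardisation "
                "is undefined for a single image)"
            )

    @property
    def n_stim(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    @property
    def flat(self) -> np.ndarray:
        """(n_stim, Lx*Ly) row-major flattened view of the images."""
        return self.images.reshape(self.n_stim, -1)

    def unstandardised(self) -> np.ndarray:
        """Map images back to raw units via the stored statistics."""
        return self.images * self.pixel_sd + self.pixel_mean

    # -- persistence ------------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images)
            f.create_dataset("pixel_mean", data=self.pixel_mean)
            f.create_dataset("pixel_sd", data=self.pixel_sd)
            f.attrs["source_tag"] = self.source_tag
            if self.seed is not None:
                f.attrs["seed"] = int(self.seed)

    @classmethod
    def from_hdf5(cls, path) -> "StimulusSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                images=f["images"][()],
                pixel_mean=f["pixel_mean"][()],
                pixel_sd=f["pixel_sd"][()],
                source_tag=str(f.attrs.get("source_tag", "external")),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )

    def to_csv(self, path) -> None:
        """One row per stimulus, flattened row-major."""
        np.savetxt(path, self.flat, delimiter=",")


def _standardise(images: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = images.mean(axis=0)
    sd = images.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(
            "degenerate stimulus set: at least one pixel position has zero "
            "standard deviation across stimuli"
        )
    return (images - mean) / sd, mean, sd


def make_white_noise_stimuli(n_stim: int, size: int = 10, seed: int = 0) -> StimulusSet:
    """Independent standard-normal pixel images, standardised per pixel."""
    if n_stim < 2:
        raise ValueError("n_stim must be >= 2: per-pixel standardisation is undefined otherwise")
    if size < 2:
        raise ValueError("size must be >= 2")
    rng = rng_from(seed, 101)
    raw = rng.standard_normal((n_stim, size, size))
    images, mean, sd = _standardise(raw)
    return StimulusSet(images, mean, sd, source_tag="white_noise", seed=seed)


def make_natural_surrogate_stimuli(
    n_stim: int,
    size: int = 10,
    spectral_exponent: float = 1.0,
    seed: int = 0,
) -> StimulusSet:
    """Images with approximately 1/f^exponent amplitude spectra.

    Gaussian noise is shaped in the Fourier domain by ``1/f**spectral_exponent``
    (so the *power* spectrum falls as ``1/f**(2*exponent)``; natural scenes
    correspond to an exponent near 1).  ``spectral_exponent=0`` reduces to
    white noise.
    """
    if not np.isfinite(spectral_exponent):
        raise ValueError("spectral_exponent must be finite")
    if n_stim < 2:
        raise ValueError("n_stim must be >= 2")
    if size < 2:
        raise ValueError("size must be >= 2")
    rng = rng_from(seed, 102)
    fx = np.fft.fftfreq(size)[:, None]
    fy = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fx, fy)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-spectral_exponent)
    spec = rng.standard_normal((n_stim, size, size)) + 1j * rng.standard_normal((n_stim, size, size))
    raw = np.fft.ifft2(spec * amp).real
    images, mean, sd = _standardise(raw)
    return StimulusSet(images, mean, sd, source_tag="natural_surrogate", seed=seed)


def _block_average_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Area-weighted averaging operator mapping length n_in to n_out.

    Exact block means when n_in is an integer multiple of n_out; otherwise the
    overlap of each output interval with each input pixel is used as weight.
    """
    edges_out = np.linspace(0.0, n_in, n_out + 1)
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = edges_out[i], edges_out[i + 1]
        for j in range(int(np.floor(lo)), int(np.ceil(hi))):
            w[i, j] = min(hi, j + 1) - max(lo, j)
        w[i] /= w[i].sum()
    return w


def preprocess_stimuli(raw_images: np.ndarray, target_size: int = 10) -> StimulusSet:
    """Block-average down-sampling followed by per-pixel standardisation."""
    raw_images = np.asarray(raw_images, dtype=np.float64)
    if raw_images.ndim != 3:
        raise ValueError("raw_images must be (n, H, W)")
    n, h, w = raw_images.shape
    if h < target_size or w < target_size:
        raise ValueError(f"input images ({h}x{w}) smaller than target size {target_size}")
    rx = _block_average_matrix(h, target_size)
    ry = _block_average_matrix(w, target_size)
    small = np.einsum("ih,nhw,jw->nij", rx, raw_images, ry)
    images, mean, sd = _standardise(small)
    return StimulusSet(images, mean, sd, source_tag="external")
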