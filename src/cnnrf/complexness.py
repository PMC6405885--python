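"""Shift-invariance quantification ("complexness") from RF ensembles.

Two RF images are "shifted" when their zero-mean normalised cross-correlation
(ZNCC) exceeds a threshold (0.95 by default; 0.7 is the variant used for the
population shifted-pair statistic) at some non-zero pixel shift (u, v).  The
ZNCC at shift (u, v),

    ZNCC(u, v) = sum (I1(x+u, y+v) - m1)(I2(x, y) - m2)
                 / sqrt(sum (I1 - m1)^2) / sqrt(sum (I2 - m2)^2),

is evaluated over the overlap region only, with means and norms computed on
that region.  The search window keeps |u|, |v| <= L/2 with at least 50% area
overlap.

From the detected shifts a "shifted image set" is grown greedily: seeded by
the pair with the largest shift distance orthogonal to the cell's Gabor
stripe orientation, images shifted with respect to any collected image are
added until closure.  Two predictive models then score the cell:

* simple model  — response ~ cosine(stimulus, one best RF image);
* complex model — response ~ max over the set of cosines (identical to the
  simple model when the set has a single image).

Complexness = 1 - R_simple / R_complex, where each R is the Pearson
similarity between predictions and actual responses.  Cells are labelled
simple (complexness <= 0) or complex-like (> 0); cells whose best Gabor fit
is poor (similarity <= 0.6) or with a negative model similarity stay
unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoders import safe_pearson
from .stimuli import StimulusSet

__all__ = [
    "ShiftRecord",
    "ComplexnessRecord",
    "zncc",
    "detect_shifts",
    "pairwise_peak_zncc",
    "orthogonal_shift_distance",
    "build_shifted_image_set",
    "simple_model_similarity",
    "complex_model_similarity",
    "complexness_index",
    "classify_cell",
]


@dataclass
class ShiftRecord:
    """A detected shift between two ensemble members."""

    pair: tuple
    shift: tuple  # (u, v), pixels
    zncc: float


@dataclass
class ComplexnessRecord:
    """Per-cell shift-invariance summary."""

    cell_id: object
    r_simple: float
    r_complex: float
    complexness: float
    gabor_fit_similarity: float
    label: str = "unclassified"
    fraction_shifted_pairs: float = float("nan")
    max_orthogonal_shift: float = float("nan")


def _overlap_slices(u: int, v: int, lx: int, ly: int):
    """Index ranges of the overlap for I1 shifted by (u, v) against I2.

    Matching I1(x+u, y+v) with I2(x, y): I2 is indexed at x in
    [max(0,-u), min(lx, lx-u)) and I1 at x+u (same for y/v).
    """
    x0, x1 = max(0, -u), min(lx, lx - u)
    y0, y1 = max(0, -v), min(ly, ly - v)
    return x0, x1, y0, y1


def zncc(image_a: np.ndarray, image_b: np.ndarray, u: int = 0, v: int = 0) -> float:
    """Zero-mean normalised cross-correlation of a against b at shift (u, v).

    ``image_a`` plays the role of I1 (sampled at (x+u, y+v)); statistics are
    computed over the overlap region.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    ly, lx = b.shape
    x0, x1, y0, y1 = _overlap_slices(int(u), int(v), lx, ly)
    if (x1 - x0) * (y1 - y0) < 4:
        raise ValueError("overlap region must contain at least 4 pixels")
    pa = a[y0 + v : y1 + v, x0 + u : x1 + u]
    pb = b[y0:y1, x0:x1]
    pa = pa - pa.mean()
    pb = pb - pb.mean()
    na, nb = np.linalg.norm(pa), np.linalg.norm(pb)
    if na == 0 or nb == 0:
        warnings.warn("zero variance in overlap patch; ZNCC undefined, treated as no-match")
        return float("nan")
    return float((pa * pb).sum() / (na * nb))


def _search_window(lx: int, ly: int, min_overlap: float = 0.5):
    """Admissible non-zero (u, v) shifts: |u|,|v| <= L/2, overlap >= 50%."""
    area = lx * ly
    out = []
    for u in range(-(lx // 2), lx // 2 + 1):
        for v in range(-(ly // 2), ly // 2 + 1):
            if (u, v) == (0, 0):
                continue
            if (lx - abs(u)) * (ly - abs(v)) >= min_overlap * area:
                out.append((u, v))
    return out


def detect_shifts(ensemble, zncc_threshold: float = 0.95) -> list:
    """All above-threshold shifts for every unordered image pair (i < j).

    Each record stores I_i shifted by (u, v) matching I_j.  The relation is
    symmetric: (i, j, u, v) is detected iff (j, i, -u, -v) would be.
    """
    images = ensemble.images if hasattr(ensemble, "images") else np.stack(ensemble)
    n = images.shape[0]
    if n < 2:
        raise ValueError("ensemble must contain at least 2 images")
    ly, lx = images.shape[1:]
    records = []
    flat_pairs = np.triu_indices(n, 1)
    for (u, v) in _search_window(lx, ly):
        x0, x1, y0, y1 = _overlap_slices(u, v, lx, ly)
        pa = images[:, y0 + v : y1 + v, x0 + u : x1 + u].reshape(n, -1)
        pb = images[:, y0:y1, x0:x1].reshape(n, -1)
        pa = pa - pa.mean(axis=1, keepdims=True)
        pb = pb - pb.mean(axis=1, keepdims=True)
        na = np.linalg.norm(pa, axis=1)
        nb = np.linalg.norm(pb, axis=1)
        na[na == 0] = np.inf  # zero-variance patch -> correlation 0 (no match)
        nb[nb == 0] = np.inf
        corr = (pa / na[:, None]) @ (pb / nb[:, None]).T  # corr[i, j]: I_i shifted vs I_j
        ii, jj = flat_pairs
        hit = corr[ii, jj] > zncc_threshold
        for i, j, c in zip(ii[hit], jj[hit], corr[ii, jj][hit]):
            records.append(ShiftRecord(pair=(int(i), int(j)), shift=(u, v), zncc=float(c)))
    return records


def pairwise_peak_zncc(ensemble) -> np.ndarray:
    """Matrix of each pair's maximum ZNCC over the shift window (incl. (0,0))."""
    images = ensemble.images if hasattr(ensemble, "images") else np.stack(ensemble)
    n = images.shape[0]
    ly, lx = images.shape[1:]
    peak = np.full((n, n), -np.inf)
    np.fill_diagonal(peak, 1.0)
    for (u, v) in _search_window(lx, ly) + [(0, 0)]:
        x0, x1, y0, y1 = _overlap_slices(u, v, lx, ly)
        pa = images[:, y0 + v : y1 + v, x0 + u : x1 + u].reshape(n, -1)
        pb = images[:, y0:y1, x0:x1].reshape(n, -1)
        pa = pa - pa.mean(axis=1, keepdims=True)
        pb = pb - pb.mean(axis=1, keepdims=True)
        na = np.linalg.norm(pa, axis=1)
        nb = np.linalg.norm(pb, axis=1)
        na[na == 0] = np.inf
        nb[nb == 0] = np.inf
        corr = (pa / na[:, None]) @ (pb / nb[:, None]).T
        peak = np.maximum(peak, np.maximum(corr, corr.T))
    return peak


def orthogonal_shift_distance(shifts, theta: float) -> float:
    """Max length of (u, v) projected orthogonally to the Gabor stripe axis.

    The stripe (orientation) axis is x' = (cos theta, sin theta); the
    orthogonal direction is the carrier axis (-sin theta, cos theta).
    """
    if len(shifts) == 0:
        return 0.0
    uv = np.array([s.shift if isinstance(s, ShiftRecord) else s for s in shifts], dtype=float)
    n_hat = np.array([-np.sin(theta), np.cos(theta)])
    return float(np.abs(uv @ n_hat).max())


def _pair_distances(records, theta):
    dist: dict[tuple, float] = {}
    for rec in records:
        d = orthogonal_shift_distance([rec], theta)
        key = rec.pair
        dist[key] = max(dist.get(key, -np.inf), d)
    return dist


def build_shifted_image_set(ensemble, shifts, theta: float) -> list[int]:
    """Greedy closure over the shift relation; returns member indices.

    Seeded by the pair with the largest orthogonal shift distance (ties
    broken towards the higher summed activation fraction), then any image
    shifted relative to an already-collected image joins, to closure.  With
    no shifted pair at all, the single RF image with the highest predicted
    response is returned.
    """
    rf_images = getattr(ensemble, "rf_images", None)
    n = len(rf_images) if rf_images is not None else len(ensemble)
    if not shifts:
        if rf_images is not None:
            preds = [r.predicted_response for r in rf_images]
            return [int(np.argmax(preds))]
        return [0]
    dist = _pair_distances(shifts, theta)

    def tiebreak(pair):
        if rf_images is None:
            return 0.0
        return rf_images[pair[0]].activation_fraction + rf_images[pair[1]].activation_fraction

    seed_pair = max(dist, key=lambda p: (dist[p], tiebreak(p)))
    collected = set(seed_pair)
    neighbours: dict[int, set] = {i: set() for i in range(n)}
    for rec in shifts:
        i, j = rec.pair
        neighbours[i].add(j)
        neighbours[j].add(i)
    grew = True
    while grew:
        grew = False
        for i in list(collected):
            new = neighbours[i] - collected
            if new:
                collected |= new
                grew = True
    return sorted(collected)


def _cosine_predictions(stim_flat: np.ndarray, rf_flat: np.ndarray) -> np.ndarray:
    """Cosine of every stimulus against every RF: (n_stim, n_rf)."""
    sn = np.linalg.norm(stim_flat, axis=1)
    zero = sn == 0
    if np.any(zero):
        warnings.warn("zero-norm stimulus; its prediction is set to 0")
    sn[zero] = np.inf
    rn = np.linalg.norm(rf_flat, axis=1)
    rn[rn == 0] = np.inf
    return (stim_flat / sn[:, None]) @ (rf_flat / rn[:, None]).T


def simple_model_similarity(stimuli, responses, image_set) -> tuple[float, int]:
    """Best single-RF cosine predictor: returns (Pearson r, chosen index)."""
    if len(image_set) == 0:
        raise ValueError("image_set must be non-empty")
    images = _as_image_array(image_set)
    flat = images.reshape(len(images), -1)
    stim_flat = stimuli.flat if isinstance(stimuli, StimulusSet) else np.asarray(stimuli).reshape(len(responses), -1)
    preds = _cosine_predictions(stim_flat, flat)
    rs = [safe_pearson(preds[:, i], responses) for i in range(preds.shape[1])]
    best = int(np.argmax(rs))
    return float(rs[best]), best


def complex_model_similarity(stimuli, responses, image_set) -> float:
    """Max-over-RFs cosine predictor similarity."""
    if len(image_set) == 0:
        raise ValueError("image_set must be non-empty")
    images = _as_image_array(image_set)
    flat = images.reshape(len(images), -1)
    stim_flat = stimuli.flat if isinstance(stimuli, StimulusSet) else np.asarray(stimuli).reshape(len(responses), -1)
    preds = _cosine_predictions(stim_flat, flat).max(axis=1)
    return float(safe_pearson(preds, responses))


def _as_image_array(image_set) -> np.ndarray:
    if hasattr(image_set, "images"):
        return image_set.images
    first = image_set[0]
    if hasattr(first, "image"):
        return np.stack([r.image for r in image_set])
    return np.stack(image_set)


def complexness_index(r_simple: float, r_complex: float) -> float:
    """1 - R_simple / R_complex."""
    if r_complex == 0:
        return float("nan")
    return 1.0 - r_simple / r_complex


def classify_cell(record: ComplexnessRecord, gabor_threshold: float = 0.6) -> str:
    """simple (complexness <= 0) / complex_like (> 0) / unclassified.

    Unclassified when the Gabor fit similarity is <= ``gabor_threshold`` or
    either model similarity is negative.
    """
    if (
        record.gabor_fit_similarity <= gabor_threshold
        or record.r_simple < 0
        or record.r_complex < 0
        or not np.isfinite(record.complexness)
    ):
        return "unclassified"
    return "simple" if record.complexness <= 0 else "complex_like"


def fraction_shifted_pairs(
    ensemble,
    zncc_threshold: float = 0.7,
    include_zero_shift: bool = True,
    shifts=None,
) -> float:
    """Fraction of unordered image pairs related by a pixel shift.

    By default a pair counts when its peak ZNCC over the admissible search
    window *including* (0, 0) exceeds the threshold — identical images are
    trivially explained by a (zero) shift, and only pairs whose structure
    differs beyond any translation are excluded.  With
    ``include_zero_shift=False`` (or an explicit ``shifts`` record list)
    only non-zero shifts count, the criterion used for shifted-image-set
    construction.
    """
    n = len(ensemble.rf_images) if hasattr(ensemble, "rf_images") else len(ensemble)
    if n < 2:
        return float("nan")
    if shifts is not None:
        pairs = {rec.pair for rec in shifts}
        return len(pairs) / (n * (n - 1) / 2)
    if include_zero_shift:
        peak = pairwise_peak_zncc(ensemble)
        iu = np.triu_indices(n, 1)
        return float(np.mean(peak[iu] > zncc_threshold))
    return fraction_shifted_pairs(ensemble, shifts=detect_shifts(ensemble, zncc_threshold))


__all__.append("fraction_shifted_pairs")
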