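"""Spatial organisation of complexness across an imaging plane.

Two complementary tests on cells with known cortical positions (micrometres)
and simple / complex-like labels:

* the Pearson correlation between pairwise cortical distance and the
  absolute complexness difference over all unordered cell pairs, and
* a position-permutation test of label clustering: the cumulative
  distribution of within-class pair distances (area-normalised) is compared
  with the 1st/99th-percentile envelope from label assignments permuted
  uniformly over the observed positions (1,000 permutations by default).

An observed curve leaving the envelope indicates spatial clustering of that
label; curves inside the envelope are consistent with no organisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import rng_from
from .encoders import safe_pearson

__all__ = [
    "PlaneMap",
    "pairwise_distance_vs_complexness",
    "permutation_cluster_test",
    "make_synthetic_plane",
]

LABELS = ("simple", "complex_like")


@dataclass
class PlaneMap:
    """Cells on one imaging plane: positions (um), complexness, labels."""

    cell_ids: list
    positions: np.ndarray  # (n, 2), micrometres
    complexness: np.ndarray
    labels: list

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.complexness = np.asarray(self.complexness, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"labels must be drawn from {LABELS}; got {bad}")

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @classmethod
    def from_csv(cls, path) -> "PlaneMap":
        df = pd.read_csv(path)
        return cls(
            cell_ids=df["cell_id"].tolist(),
            positions=df[["x_um", "y_um"]].to_numpy(),
            complexness=df["complexness"].to_numpy(),
            labels=df["label"].tolist(),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "complexness": self.complexness,
                "label": self.labels,
            }
        ).to_csv(path, index=False)


def _pairwise_distances(positions: np.ndarray) -> np.ndarray:
    d = positions[:, None, :] - positions[None, :, :]
    return np.sqrt((d**2).sum(-1))


def pairwise_distance_vs_complexness(plane: PlaneMap) -> tuple[pd.DataFrame, float]:
    """(distance um, |delta complexness|) for all unordered pairs + Pearson r."""
    if plane.n < 3:
        raise ValueError("need at least 3 cells")
    iu = np.triu_indices(plane.n, 1)
    dists = _pairwise_distances(plane.positions)[iu]
    dcomp = np.abs(plane.complexness[:, None] - plane.complexness[None, :])[iu]
    table = pd.DataFrame({"distance_um": dists, "abs_delta_complexness": dcomp})
    if dcomp.std() == 0:
        warnings.warn("all cells share one complexness value; correlation undefined (nan)")
        return table, float("nan")
    return table, safe_pearson(dists, dcomp)


@dataclass
class ClusterEnvelope:
    """Observed within-class distance curves and their permutation envelope."""

    bin_edges: np.ndarray
    observed: dict = field(default_factory=dict)  # label -> curve
    lower: dict = field(default_factory=dict)  # 1st percentile
    upper: dict = field(default_factory=dict)  # 99th percentile
    exits_envelope: dict = field(default_factory=dict)
    normalisation: str = "area"

    def to_csv(self, path) -> None:
        rows = {"bin_upper_um": self.bin_edges[1:]}
        for lab in self.observed:
            rows[f"{lab}_observed"] = self.observed[lab]
            rows[f"{lab}_p01"] = self.lower[lab]
            rows[f"{lab}_p99"] = self.upper[lab]
        pd.DataFrame(rows).to_csv(path, index=False)


def _cumulative_curve(dists: np.ndarray, edges: np.ndarray, normalisation: str) -> np.ndarray:
    """Cumulative count of pair distances per bin upper edge.

    ``area`` divides the cumulative count at distance d by the disc area
    pi*d^2 (a pair-density correction for the growing annulus area);
    ``cdf`` normalises the final count to 1.
    """
    counts = np.searchsorted(np.sort(dists), edges[1:], side="right").astype(float)
    if normalisation == "area":
        return counts / (np.pi * edges[1:] ** 2)
    if normalisation == "cdf":
        total = counts[-1] if counts[-1] > 0 else 1.0
        return counts / total
    raise ValueError("normalisation must be 'area' or 'cdf'")


def permutation_cluster_test(
    plane: PlaneMap,
    n_perm: int = 1000,
    seed: int = 0,
    n_bins: int = 50,
    normalisation: str = "area",
) -> ClusterEnvelope:
    """Label-permutation envelope test for spatial clustering.

    For each permutation the simple-cell positions are re-sampled uniformly
    from all observed positions (the rest become complex-like), the
    within-class cumulative distance curves are recomputed, and per-bin
    1st/99th percentiles form the envelope.
    """
    labels = np.asarray(plane.labels)
    present = [lab for lab in LABELS if (labels == lab).sum() >= 2]
    for lab in set(LABELS) - set(present):
        warnings.warn(f"label class {lab!r} has fewer than 2 cells; its curve is skipped")
    if not present:
        raise ValueError("no label class with at least 2 cells")
    dmat = _pairwise_distances(plane.positions)
    diameter = float(dmat.max())
    edges = np.linspace(0.0, diameter, n_bins + 1)
    iu = np.triu_indices(plane.n, 1)
    env = ClusterEnvelope(bin_edges=edges, normalisation=normalisation)
    rng = rng_from(seed, 601)
    n_simple = int((labels == "simple").sum())
    perm_curves = {lab: np.empty((n_perm, n_bins)) for lab in present}
    for p in range(n_perm):
        order = rng.permutation(plane.n)
        perm_labels = np.empty(plane.n, dtype=object)
        perm_labels[order[:n_simple]] = "simple"
        perm_labels[order[n_simple:]] = "complex_like"
        for lab in present:
            mask = perm_labels == lab
            sub = dmat[np.ix_(mask, mask)]
            dd = sub[np.triu_indices(mask.sum(), 1)]
            perm_curves[lab][p] = _cumulative_curve(dd, edges, normalisation)
    for lab in present:
        mask = labels == lab
        sub = dmat[np.ix_(mask, mask)]
        dd = sub[np.triu_indices(mask.sum(), 1)]
        env.observed[lab] = _cumulative_curve(dd, edges, normalisation)
        env.lower[lab] = np.percentile(perm_curves[lab], 1, axis=0)
        env.upper[lab] = np.percentile(perm_curves[lab], 99, axis=0)
        env.exits_envelope[lab] = bool(
            np.any(env.observed[lab] < env.lower[lab]) or np.any(env.observed[lab] > env.upper[lab])
        )
    return env


def make_synthetic_plane(
    n_cells: int,
    plane_size_um: float = 500.0,
    complex_fraction: float = 0.26,
    cluster_radius_um: float | None = None,
    seed: int = 0,
) -> PlaneMap:
    """Synthetic imaging plane for end-to-end tests.

    Positions are uniform over a square plane.  With ``cluster_radius_um``
    set, all complex-like cells are planted inside a disc of that radius at
    the plane centre (a positive control for the cluster test).
    """
    rng = rng_from(seed, 602)
    pos = rng.uniform(0, plane_size_um, size=(n_cells, 2))
    n_complex = int(round(complex_fraction * n_cells))
    labels = ["simple"] * (n_cells - n_complex) + ["complex_like"] * n_complex
    if cluster_radius_um is not None:
        centre = np.array([plane_size_um / 2, plane_size_um / 2])
        for i in range(n_cells - n_complex, n_cells):
            r = cluster_radius_um * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            pos[i] = centre + r * np.array([np.cos(ang), np.sin(ang)])
    comp = np.where(np.arange(n_cells) < n_cells - n_complex,
                    rng.uniform(-0.5, 0.0, n_cells), rng.uniform(0.0, 0.8, n_cells))
    return PlaneMap(cell_ids=list(range(n_cells)), positions=pos, complexness=comp, labels=labels)
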