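"""Principal coordinates analysis and ordination-space centroids.

Multiple biopsies from one patient at one time are pseudo-replicates;
the analysis collapses them to their centroid (per-axis arithmetic mean)
in the PCoA embedding before any between-patient comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import DistanceMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = ["Ordination", "CentroidSet", "pcoa", "collapse_to_centroids", "centroid_distance"]


@dataclass
class Ordination:
    """PCoA embedding: per-sample coordinates on positive-eigenvalue axes.

    Negative eigenvalues (possible for non-Euclidean distance matrices
    such as UniFrac) are dropped; their absolute-value share of the total
    eigenvalue mass is recorded in ``negative_fraction``.
    """

    ids: list[str]
    coordinates: np.ndarray          # samples x axes
    eigenvalues: np.ndarray          # positive, non-increasing
    proportion_explained: np.ndarray
    negative_fraction: float

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def coords_for(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.ids)}
        return self.coordinates[[pos[s] for s in ids]]

    def to_tsv(self, path) -> None:
        cols = [f"PC{k + 1}" for k in range(self.n_axes)]
        df = pd.DataFrame(self.coordinates, index=self.ids, columns=cols)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


def pcoa(D: DistanceMatrix, eig_tol: float = 1e-10) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower double-centering of -0.5 * D^2, symmetric eigendecomposition,
    coordinates = eigenvectors scaled by sqrt(eigenvalue) on the axes
    with positive eigenvalues, ordered by decreasing eigenvalue.
    """
    d = D.data
    n = d.shape[0]
    if n == 0:
        raise ValueError("empty distance matrix")
    a = -0.5 * d ** 2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigvals, eigvecs = np.linalg.eigh(centered)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0)
    pos = eigvals > eig_tol * scale
    neg_mass = float(np.abs(eigvals[eigvals < 0]).sum())
    total_mass = float(np.abs(eigvals).sum())
    negative_fraction = neg_mass / total_mass if total_mass > 0 else 0.0
    if negative_fraction > 0:
        logger.info("pcoa: dropped negative eigenvalue mass fraction %.4f", negative_fraction)
    lam = eigvals[pos]
    if lam.size == 0:
        return Ordination(
            list(D.ids), np.zeros((n, 1)), np.zeros(1), np.zeros(1), negative_fraction
        )
    coords = eigvecs[:, pos] * np.sqrt(lam)
    prop = lam / lam.sum()
    return Ordination(list(D.ids), coords, lam, prop, negative_fraction)


@dataclass
class CentroidSet:
    """Group centroids in ordination space, keyed by grouping tuple."""

    keys: list[tuple]
    coordinates: np.ndarray   # groups x axes
    key_columns: tuple[str, ...]

    def coords_for(self, key: tuple) -> np.ndarray:
        return self.coordinates[self.keys.index(key)]

    def to_tsv(self, path) -> None:
        cols = [f"PC{k + 1}" for k in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, columns=cols)
        for j, name in enumerate(reversed(self.key_columns)):
            df.insert(0, name, [k[len(self.key_columns) - 1 - j] for k in self.keys])
        df.to_csv(path, sep="\t", index=False)


def collapse_to_centroids(
    ordn: Ordination,
    meta: SampleMetadata,
    key: tuple[str, ...] = ("patient_id", "timepoint"),
) -> CentroidSet:
    """Arithmetic-mean centroid per metadata group (default patient x time).

    Every ordinated sample must carry metadata; centroids use all
    positive-eigenvalue axes, not just the plotted ones.
    """
    meta_df = meta.df.set_index("sample_id")
    missing = [s for s in ordn.ids if s not in meta_df.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    rows = meta_df.loc[ordn.ids, list(key)]
    frame = pd.DataFrame(ordn.coordinates, index=ordn.ids)
    grouped = frame.groupby([rows[c].to_numpy() for c in key], sort=True).mean()
    keys = [k if isinstance(k, tuple) else (k,) for k in grouped.index]
    return CentroidSet(keys, grouped.to_numpy(), tuple(key))


def centroid_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two points in the retained ordination space."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
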