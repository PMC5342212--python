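"""Generalized Procrustes superimposition and tangent-space shape statistics.

Implements the iterative generalized least-squares superimposition (proper
rotations only), partial Procrustes distances on aligned unit-size
configurations, orthogonal projection into the linear space tangent to shape
space at the consensus, centroid size, the tangent-adequacy diagnostic
(through-origin slope and correlation between Procrustes and tangent
distances), and principal coordinates analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import DistanceMatrix
from .landmark_io import LandmarkConfiguration

__all__ = [
    "AlignedDataset",
    "gpa_align",
    "procrustes_distance_matrix",
    "tangent_coordinates",
    "tangent_distance_matrix",
    "centroid_size",
    "centroid_sizes",
    "tangent_space_check",
    "pcoa",
]

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


@dataclass
class AlignedDataset:
    """Result of generalized Procrustes alignment.

    ``aligned`` configurations are centered, unit-centroid-size and rotated
    onto the consensus; ``centroid_sizes`` are recorded before scaling, in
    original landmark units.  ``tangent`` is filled by
    :func:`tangent_coordinates`.
    """

    specimen_ids: list[str]
    consensus: np.ndarray  # (k, 2), unit centroid size
    aligned: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool
    tangent: np.ndarray | None = None  # (n, 2k)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark-to-centroid distances."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def centroid_sizes(configs: Sequence[LandmarkConfiguration]) -> np.ndarray:
    """Centroid size per configuration, in original (scale-applied) units."""
    return np.array([centroid_size(c.coords) for c in configs])


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det=+1) minimizing ||source @ R - target||."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def gpa_align(
    configs: Sequence[LandmarkConfiguration],
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
) -> AlignedDataset:
    """Iterative GLS Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size, and rotated
    (proper rotation) onto the running consensus; the consensus is the mean of
    aligned configurations rescaled to unit size.  Iterates until the maximum
    consensus coordinate change falls below ``tol``.

    Raises
    ------
    ValueError
        For fewer than 2 configurations, mixed landmark counts, or a
        degenerate (zero centroid size) configuration.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("GPA requires at least 2 configurations")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ValueError(f"mixed landmark counts: {sorted(ks)}")
    k = ks.pop()
    if k < 3:
        raise ValueError("GPA requires at least 3 landmarks")

    n = len(configs)
    shapes = np.empty((n, k, 2))
    sizes = np.empty(n)
    for i, c in enumerate(configs):
        centered = c.coords - c.coords.mean(axis=0)
        cs = np.sqrt(np.sum(centered**2))
        if cs <= 0.0:
            raise ValueError(
                f"degenerate configuration (zero centroid size): {c.specimen_id!r}"
            )
        sizes[i] = cs
        shapes[i] = centered / cs

    consensus = shapes[0].copy()
    consensus /= np.sqrt(np.sum(consensus**2))
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = shapes.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        # consensus orientation is arbitrary; align the update to the old one
        new_consensus = new_consensus @ _optimal_rotation(new_consensus, consensus)
        change = np.max(np.abs(new_consensus - consensus))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    # final rotation pass against the converged consensus
    for i in range(n):
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)

    return AlignedDataset(
        specimen_ids=[c.specimen_id for c in configs],
        consensus=consensus,
        aligned=shapes,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
    )


def procrustes_distance_matrix(a: AlignedDataset) -> DistanceMatrix:
    """Pairwise Procrustes distances on GPA-aligned configurations.

    d(i, j) = sqrt(sum over landmarks of squared coordinate differences),
    i.e. the Euclidean distance between flattened aligned configurations
    (partial Procrustes distance).
    """
    flat = a.aligned.reshape(a.n, -1)
    d = squareform(pdist(flat, metric="euclidean"))
    return DistanceMatrix(a.specimen_ids, d, "procrustes")


def tangent_coordinates(a: AlignedDataset) -> AlignedDataset:
    """Project aligned configurations into the tangent space at the consensus.

    Each flattened aligned configuration x (||consensus vector c|| = 1) is
    projected orthogonally onto the hyperplane through c normal to c:
    t = x - (x . c) c.  The resulting 2k-vectors satisfy t . c = x . c - x . c
    = 0 up to the anchoring constant; deviations from the consensus are
    exactly orthogonal to c.
    """
    flat = a.aligned.reshape(a.n, -1)
    c = a.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    t = flat - np.outer(flat @ c, c)
    a.tangent = t
    return a


def tangent_distance_matrix(a: AlignedDataset) -> DistanceMatrix:
    """Euclidean distances among tangent-space coordinates."""
    if a.tangent is None:
        tangent_coordinates(a)
    d = squareform(pdist(a.tangent, metric="euclidean"))
    return DistanceMatrix(a.specimen_ids, d, "tangent")


def tangent_space_check(a: AlignedDataset) -> tuple[float, float]:
    """Tangent-space adequacy diagnostic.

    Over all specimen pairs, regresses tangent (Euclidean) distance on
    Procrustes distance through the origin and computes the Pearson
    correlation between the two distance sets.

    Returns
    -------
    (slope, correlation)

    Raises
    ------
    ValueError
        With fewer than 3 configurations or when all distances are zero
        (correlation undefined).
    """
    if a.n < 3:
        raise ValueError("tangent-space check requires at least 3 configurations")
    dp = procrustes_distance_matrix(a).condensed()
    dt = tangent_distance_matrix(a).condensed()
    denom = float(dp @ dp)
    if denom == 0.0:
        raise ValueError("all Procrustes distances are zero; diagnostic undefined")
    slope = float(dp @ dt) / denom
    sp = dp.std()
    st = dt.std()
    if sp == 0.0 or st == 0.0:
        raise ValueError("zero variance in distances; correlation undefined")
    correlation = float(np.corrcoef(dp, dt)[0, 1])
    return slope, correlation


def pcoa(d: DistanceMatrix, n_axes: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates analysis (Gower double-centering).

    Returns
    -------
    coordinates : (n, n_axes) ndarray
        Scores on the first ``n_axes`` axes ordered by decreasing eigenvalue.
        Axes with non-positive eigenvalues are never returned as coordinates.
    eigenvalues : (n,) ndarray
        All eigenvalues in decreasing order (negatives included, reported).
    """
    n = d.n
    if n < 3:
        raise ValueError("PCoA requires at least 3 objects")
    if n_axes > n - 1:
        raise ValueError(f"n_axes={n_axes} exceeds n-1={n - 1}")
    a = -0.5 * d.values**2
    row_means = a.mean(axis=1, keepdims=True)
    g = a - row_means - row_means.T + a.mean()
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    n_pos = int(np.sum(eigvals > 1e-12))
    usable = min(n_axes, n_pos)
    coords = eigvecs[:, :usable] * np.sqrt(eigvals[:usable])
    return coords, eigvals
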