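"""Conformational ensemble analysis.

Rigid-body superposition (Kabsch), RMSD, radius-limited k-means
clustering of conformers, per-atom RMSF about the iterated mean
structure, gyration-tensor shape descriptors, and population-weighted
CCS distributions assembled from per-cluster medoid CCS values.

Unless a mask is given, superposition, clustering, RMSF and shape use
heavy atoms only — hydrogen positions are comparatively noisy and the
observables of interest (CCS, fold) are set by the heavy-atom skeleton.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ccs import CCSResult
from .ensemble import ConformerEnsemble
from .errors import ConfigError, GeometryError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSet", "Cluster", "CCSDistribution", "RMSFProfile", "ShapeDescriptor",
    "superpose", "rmsd", "cluster_ensemble", "rmsf", "weighted_ccs_distribution",
    "major_conformers", "shape_descriptor",
]

#: Fine clustering is capped at this many clusters (warning when it binds).
MAX_CLUSTERS = 2625


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _resolve_mask(n: int, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.ones(n, dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape[0] != n:
            raise GeometryError("boolean mask length must equal atom count")
        return mask
    out = np.zeros(n, dtype=bool)
    out[mask] = True
    return out


def superpose(reference: np.ndarray, mobile: np.ndarray,
              mask: np.ndarray | None = None,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kabsch least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, aligned)`` such that
    ``aligned = mobile @ rotation.T + translation`` minimizes the masked
    RMSD.  The rotation is proper (det = +1).  Raises
    :class:`GeometryError` for fewer than 3 masked atoms or a collinear
    masked set, where the rotation is not uniquely determined.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.shape != mobile.shape:
        raise GeometryError("reference and mobile coordinate sets must be conformable")
    m = _resolve_mask(reference.shape[0], mask)
    a = reference[m]
    b = mobile[m]
    if a.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 masked atoms")
    a_cm = a.mean(axis=0)
    b_cm = b.mean(axis=0)
    a0, b0 = a - a_cm, b - b_cm
    if np.linalg.matrix_rank(b0, tol=1e-8) < 2 or np.linalg.matrix_rank(a0, tol=1e-8) < 2:
        raise GeometryError("masked atoms are collinear; rotation is degenerate")
    if np.array_equal(a, b):  # exact identity: no numerical noise on aligned coords
        return np.eye(3), np.zeros(3), mobile.copy()
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = a_cm - rot @ b_cm
    aligned = mobile @ rot.T + trans
    return rot, trans, aligned


def rmsd(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None,
         fit: bool = True) -> float:
    """Root-mean-square deviation over masked atoms, optionally after superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError("coordinate sets must be conformable")
    m = _resolve_mask(a.shape[0], mask)
    if fit:
        _, _, b = superpose(a, b, m)
    diff = a[m] - b[m]
    return float(np.sqrt((diff ** 2).sum() / m.sum()))


# ---------------------------------------------------------------------------
# Radius-limited k-means clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    members: tuple[int, ...]
    medoid: int
    weight: float


@dataclass(frozen=True)
class ClusterSet:
    """An RMSD-threshold partition of the conformers of one ensemble."""

    threshold: float
    clusters: tuple[Cluster, ...]
    n_conformers: int

    def __post_init__(self) -> None:
        seen = sorted(i for c in self.clusters for i in c.members)
        if seen != list(range(self.n_conformers)):
            raise ConfigError("clusters must partition the conformer indices")
        if abs(sum(c.weight for c in self.clusters) - 1.0) > 1e-12:
            raise ConfigError("cluster weights must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.clusters])

    @property
    def medoids(self) -> list[int]:
        return [c.medoid for c in self.clusters]

    def assignments(self) -> np.ndarray:
        out = np.empty(self.n_conformers, dtype=int)
        for k, c in enumerate(self.clusters):
            out[list(c.members)] = k
        return out


def _lloyd(x: np.ndarray, centroids: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic Lloyd iteration; empty clusters are dropped."""
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        keep = np.unique(labels)
        new = np.stack([x[labels == k].mean(axis=0) for k in keep])
        relabel = {k: i for i, k in enumerate(keep)}
        labels = np.array([relabel[k] for k in labels])
        if new.shape == centroids.shape and np.allclose(new, centroids, atol=1e-12):
            return labels, new
        centroids = new
    return labels, centroids


def cluster_ensemble(ensemble: ConformerEnsemble, threshold: float,
                     seed: int = 0, max_iter: int = 200,
                     mask: np.ndarray | None = None,
                     max_clusters: int = MAX_CLUSTERS) -> ClusterSet:
    """Radius-limited k-means clustering of conformers at an RMSD threshold.

    All conformers are first superposed onto the first one (heavy atoms
    by default); k-means then runs on the flattened coordinates, with k
    grown by splitting — the cluster with the largest member-to-centroid
    RMSD is reseeded at its two most distant members — until every
    member lies within ``threshold`` RMSD of its cluster centroid.  The
    representative of each cluster is its medoid (the actual conformer
    with minimal mean pairwise fitted RMSD to its co-members), since a
    physical structure is needed for CCS computation.

    The algorithm is deterministic; ``seed`` is accepted for interface
    stability but not consumed.
    """
    del seed
    m_conf = ensemble.n_conformers
    amask = _resolve_mask(ensemble.n_atoms, mask if mask is not None else ensemble.heavy_mask)
    if amask.sum() == 0:
        raise GeometryError("empty atom mask")
    n_sel = int(amask.sum())

    aligned = np.empty((m_conf, n_sel, 3))
    aligned[0] = ensemble.coords[0][amask]
    ref = ensemble.coords[0]
    for i in range(1, m_conf):
        _, _, fit_coords = superpose(ref, ensemble.coords[i], amask)
        aligned[i] = fit_coords[amask]
    x = aligned.reshape(m_conf, -1)
    scale = math.sqrt(n_sel)  # Euclidean distance on x = RMSD * sqrt(n_sel)

    centroids = x.mean(axis=0, keepdims=True)
    labels = np.zeros(m_conf, dtype=int)
    capped = False
    while True:
        labels, centroids = _lloyd(x, centroids, max_iter)
        worst_k, worst_r = -1, threshold
        for k in range(centroids.shape[0]):
            idx = np.where(labels == k)[0]
            r = np.linalg.norm(x[idx] - centroids[k], axis=1).max() / scale
            if r > worst_r:
                worst_k, worst_r = k, r
        if worst_k < 0:
            break
        if centroids.shape[0] >= max_clusters:
            capped = True
            break
        idx = np.where(labels == worst_k)[0]
        d2 = ((x[idx, None, :] - x[None, idx, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(int(d2.argmax()), d2.shape)
        centroids = np.vstack([np.delete(centroids, worst_k, axis=0),
                               x[idx[i]], x[idx[j]]])
    if capped:
        warnings.warn(f"cluster cap of {max_clusters} reached before the radius "
                      f"criterion was satisfied", stacklevel=2)

    clusters = []
    for k in range(centroids.shape[0]):
        idx = np.where(labels == k)[0]
        if idx.size == 0:
            continue
        medoid = _medoid(aligned, idx)
        clusters.append(Cluster(members=tuple(int(i) for i in idx), medoid=medoid,
                                weight=idx.size / m_conf))
    clusters.sort(key=lambda c: (-c.weight, c.medoid))
    return ClusterSet(threshold=float(threshold), clusters=tuple(clusters),
                      n_conformers=m_conf)


def _medoid(aligned: np.ndarray, idx: np.ndarray) -> int:
    """Member with minimal mean pairwise fitted RMSD to its co-members."""
    if idx.size == 1:
        return int(idx[0])
    k = idx.size
    dm = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            dm[a, b] = dm[b, a] = rmsd(aligned[idx[a]], aligned[idx[b]], fit=True)
    return int(idx[int(dm.mean(axis=1).argmin())])


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RMSFProfile:
    """Per-atom root-mean-square fluctuation (Å) over the masked atoms."""

    values: np.ndarray
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise GeometryError("RMSF values must be non-negative")


def rmsf(ensemble: ConformerEnsemble, mask: np.ndarray | None = None,
         tol: float = 1e-6, max_iter: int = 50) -> RMSFProfile:
    """RMSF about the ensemble-mean structure, with iterated mean-fitting.

    Conformers are superposed onto the running mean structure and the
    mean recomputed until it moves less than ``tol`` Å (RMS).  Then
    RMSF_i = sqrt(⟨|x_i − x̄_i|²⟩ over conformers) for each masked atom.
    """
    if ensemble.n_conformers < 2:
        raise GeometryError("RMSF needs at least 2 conformers")
    amask = _resolve_mask(ensemble.n_atoms, mask if mask is not None else ensemble.heavy_mask)
    coords = ensemble.coords[:, amask, :].copy()
    if all(np.array_equal(coords[i], coords[0]) for i in range(1, coords.shape[0])):
        # identical frames fluctuate exactly zero; skip the fit entirely so
        # no floating-point noise leaks in
        return RMSFProfile(values=np.zeros(coords.shape[1]),
                           atom_indices=np.where(amask)[0])
    mean = coords[0].copy()
    for _ in range(max_iter):
        for i in range(coords.shape[0]):
            _, _, coords[i] = superpose(mean, coords[i])
        new_mean = coords.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum() / mean.shape[0]))
        mean = new_mean
        if shift < tol:
            break
    fluct = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    return RMSFProfile(values=fluct, atom_indices=np.where(amask)[0])


# ---------------------------------------------------------------------------
# Weighted CCS distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CCSDistribution:
    """Population-weighted CCS support points, histogram and mean."""

    support: tuple[tuple[float, float], ...]   # (omega, weight)
    bin_edges: np.ndarray
    bin_masses: np.ndarray
    weighted_mean: float


def weighted_ccs_distribution(clusterset: ClusterSet,
                              medoid_ccs: Mapping[int, CCSResult | float],
                              bin_width: float = 2.0) -> CCSDistribution:
    """Weight each cluster's medoid CCS by its population fraction.

    ``medoid_ccs`` maps the cluster position (index into
    ``clusterset.clusters``) to that cluster's representative-structure
    CCS.  Every cluster must be covered.
    """
    omegas, weights = [], []
    for k, cluster in enumerate(clusterset.clusters):
        if k not in medoid_ccs:
            raise ConfigError(f"no CCS provided for cluster {k}")
        val = medoid_ccs[k]
        omegas.append(float(val.omega if isinstance(val, CCSResult) else val))
        weights.append(cluster.weight)
    omegas_arr = np.array(omegas)
    weights_arr = np.array(weights)
    mean = float(np.average(omegas_arr, weights=weights_arr))
    lo = math.floor(omegas_arr.min() / bin_width) * bin_width
    hi = math.ceil(omegas_arr.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    masses, _ = np.histogram(omegas_arr, bins=edges, weights=weights_arr)
    return CCSDistribution(support=tuple(zip(omegas, weights)), bin_edges=edges,
                           bin_masses=masses, weighted_mean=mean)


def major_conformers(clusterset: ClusterSet, min_fraction: float = 0.10,
                     ) -> list[tuple[int, float]]:
    """(medoid index, weight) of clusters holding more than ``min_fraction``
    of the population, sorted by descending weight."""
    out = [(c.medoid, c.weight) for c in clusterset.clusters if c.weight > min_fraction]
    out.sort(key=lambda t: -t[1])
    return out


# ---------------------------------------------------------------------------
# Shape descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeDescriptor:
    """Gyration-tensor summary of one conformer.

    κ² (relative shape anisotropy) is 0 for an isotropic mass
    distribution and 1 for a strictly collinear one; the rod/globular
    class label uses a configurable κ² threshold (a package convention —
    visual classification is not reproducible).
    """

    gyration_radius: float
    eigenvalues: tuple[float, float, float]   # λ1 ≥ λ2 ≥ λ3, Å²
    kappa_squared: float
    label: str                                # 'globular' | 'rod-like'


def shape_descriptor(coords: np.ndarray, mask: np.ndarray | None = None,
                     rod_threshold: float = 0.4) -> ShapeDescriptor:
    """Gyration radius, gyration-tensor eigenvalues and κ² of one structure."""
    coords = np.asarray(coords, dtype=float)
    m = _resolve_mask(coords.shape[0], mask)
    pts = coords[m]
    if pts.shape[0] < 2:
        raise GeometryError("shape descriptor needs at least 2 atoms")
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise GeometryError("all masked atoms coincide; gyration tensor degenerate")
    gyr = centered.T @ centered / pts.shape[0]
    lam = np.linalg.eigvalsh(gyr)[::-1]
    lam = np.clip(lam, 0.0, None)
    tr = float(lam.sum())
    kappa2 = 1.0 - 3.0 * float(lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / tr ** 2
    kappa2 = min(max(kappa2, 0.0), 1.0)
    label = "rod-like" if kappa2 >= rod_threshold else "globular"
    return ShapeDescriptor(gyration_radius=math.sqrt(tr),
                           eigenvalues=(float(lam[0]), float(lam[1]), float(lam[2])),
                           kappa_squared=kappa2, label=label)
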