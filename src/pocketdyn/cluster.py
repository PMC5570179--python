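"""Clustering of binding-site conformations.

Two methods mirror the two refinement stages of the workflow: a simplified
single-linkage clustering at an RMSD threshold (default 3 A), realized exactly
as connected components of the thresholded distance graph, and a
threshold-driven k-means on concatenated side-chain center coordinates that
picks the smallest k whose clusters are all tighter than the threshold
(default 1.5 A on the per-residue RMSD scale). Each cluster is summarized by
its medoid representative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ClusteringResult",
    "single_linkage_cluster",
    "kmeans_threshold_cluster",
    "cluster_report",
]

DEFAULT_SINGLE_LINKAGE_THRESHOLD = 3.0  # Angstrom
DEFAULT_SEED = 17


@dataclass
class ClusteringResult:
    labels: np.ndarray  # (n,) int, 0-based, ordered by first occurrence
    representatives: List[int]  # one medoid index per cluster
    method: str  # "single_linkage" | "kmeans"
    threshold: float
    seed: Optional[int] = None
    converged: bool = True  # False if k-means hit max_k without satisfying the threshold

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members_of(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first occurrence (order-stable)."""
    mapping: dict = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _medoid(indices: np.ndarray, matrix: np.ndarray) -> int:
    """Member minimizing summed intra-cluster distance; ties -> lowest index."""
    sums = matrix[np.ix_(indices, indices)].sum(axis=1)
    return int(indices[int(np.argmin(sums))])  # argmin takes the first minimum


def single_linkage_cluster(matrix: np.ndarray, threshold: float = DEFAULT_SINGLE_LINKAGE_THRESHOLD) -> ClusteringResult:
    """Cluster members by connected components of the RMSD threshold graph.

    Members i and j share a cluster iff they are connected by a chain of pairs
    each within ``threshold`` — the closure of single-linkage clustering cut at
    that height, computed exactly and order-independently.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.abs(np.diag(matrix)) > 1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    adjacency = csr_matrix((matrix <= threshold).astype(np.int8))
    _, raw = connected_components(adjacency, directed=False)
    labels = _canonical_labels(raw)
    reps = [_medoid(np.flatnonzero(labels == c), matrix) for c in range(labels.max() + 1)]
    return ClusteringResult(labels=labels, representatives=reps,
                            method="single_linkage", threshold=float(threshold))


def _farthest_point_init(features: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic-given-seed farthest-point (k-center) initialization."""
    n = features.shape[0]
    centers = [int(rng.integers(n))]
    for _ in range(1, k):
        d = np.min(
            np.linalg.norm(features[:, None, :] - features[centers][None, :, :], axis=-1),
            axis=1,
        )
        d[centers] = -1.0
        centers.append(int(np.argmax(d)))
    return features[centers].copy()


def _lloyd(features: np.ndarray, centers: np.ndarray, max_iter: int = 100):
    for _ in range(max_iter):
        d = np.linalg.norm(features[:, None, :] - centers[None, :, :], axis=-1)
        labels = np.argmin(d, axis=1)
        new_centers = centers.copy()
        for c in range(centers.shape[0]):
            pts = features[labels == c]
            if len(pts):
                new_centers[c] = pts.mean(axis=0)
        if np.allclose(new_centers, centers):
            centers = new_centers
            break
        centers = new_centers
    d = np.linalg.norm(features[:, None, :] - centers[None, :, :], axis=-1)
    labels = np.argmin(d, axis=1)
    return labels, centers, d[np.arange(len(labels)), labels]


def kmeans_threshold_cluster(features: np.ndarray, threshold: float,
                             seed: int = DEFAULT_SEED, max_k: Optional[int] = None,
                             n_residues: Optional[int] = None) -> ClusteringResult:
    """k-means with k chosen as the smallest value meeting an RMSD threshold.

    ``features`` is the member x (3*R) matrix of concatenated per-residue
    side-chain geometric centers; Euclidean distances in that space are
    converted to the per-residue RMSD scale by dividing by sqrt(R) (``R``
    defaults to ``features.shape[1] / 3``). The smallest k in 1..max_k whose
    clusters all lie within ``threshold`` of their centroid is returned; if no
    k satisfies the bound the result carries ``converged=False`` at
    ``k = max_k``.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValueError("features must be a non-empty member x d matrix")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    n = features.shape[0]
    if max_k is None:
        max_k = n
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    if n_residues is None:
        n_residues = max(features.shape[1] // 3, 1)
    scale = np.sqrt(n_residues)

    best = None
    for k in range(1, min(max_k, n) + 1):
        rng = np.random.default_rng(seed)
        centers = _farthest_point_init(features, k, rng)
        labels, centers, dist = _lloyd(features, centers)
        labels = _canonical_labels(labels)
        rmsd_dist = dist / scale
        best = (labels, rmsd_dist)
        if rmsd_dist.max() <= threshold:
            break
    labels, _ = best  # type: ignore[misc]
    # medoids in the RMSD-scaled feature space
    dmat = np.linalg.norm(features[:, None, :] - features[None, :, :], axis=-1) / scale
    reps = [_medoid(np.flatnonzero(labels == c), dmat) for c in range(labels.max() + 1)]
    converged = bool((best[1] <= threshold).all())
    return ClusteringResult(labels=labels, representatives=reps, method="kmeans",
                            threshold=float(threshold), seed=seed, converged=converged)


def cluster_report(result: ClusteringResult, matrix: np.ndarray,
                   member_labels: Optional[List[str]] = None,
                   rmsd_to_reference: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-cluster summary: size, medoid representative, representative RMSD.

    ``rmsd_to_reference`` (optional, one value per member) fills the
    representative-vs-reference column that backs the per-cluster overlay
    plots.
    """
    rows = []
    for c in range(result.n_clusters):
        members = result.members_of(c)
        rep = result.representatives[c]
        rows.append({
            "cluster": c,
            "size": len(members),
            "representative": rep,
            "representative_id": member_labels[rep] if member_labels else str(rep),
            "representative_rmsd_to_reference": (
                float(rmsd_to_reference[rep]) if rmsd_to_reference is not None else np.nan
            ),
            "mean_intra_rmsd": float(matrix[np.ix_(members, members)].mean()) if len(members) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
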