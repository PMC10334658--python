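"""DBSCAN module detection on taxon abundance profiles.

Each taxon is a point whose coordinates are its relative abundances
across all samples; modules are dense groups of taxa under Euclidean
distance, found with DBSCAN (named with letters in discovery order, as
Module A, B, ...).  The epsilon radius can be chosen from the knee of
the sorted k-th-nearest-neighbor distance profile.

The clustering itself is implemented here rather than delegated so that
border-point assignment is deterministic under the documented point
order (first-discovering cluster wins, points processed in input
order); equivalence with library and brute-force references is asserted
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .feature_table import FeatureTable

NOISE = "NOISE"


def taxon_profiles(ft: FeatureTable, scale: bool = False) -> pd.DataFrame:
    """Taxa x samples coordinate matrix for clustering.

    With ``scale=True`` each taxon's profile is standardized to zero
    mean and unit variance across samples, which makes Euclidean
    distance a monotone function of (one minus) the profile correlation;
    constant profiles scale to the zero vector.
    """
    if ft.mode != "relative":
        raise ValueError("taxon_profiles requires a relative-mode table")
    x = ft.data.astype(float).copy()
    if scale:
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=0)
        sd = sd.replace(0.0, 1.0)
        x = x.sub(mu, axis=0).div(sd, axis=0)
    return x


def dbscan_labels(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Standard DBSCAN; returns integer labels (-1 = noise) in input order.

    A core point has at least ``min_pts`` neighbors within ``eps``
    (itself included).  Clusters are maximal density-connected sets;
    border points join the first cluster that discovers them, which is
    deterministic for a fixed point order.
    """
    points = np.asarray(points, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    n = points.shape[0]
    d = cdist(points, points)
    neighbors = [np.where(d[i] <= eps)[0] for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    cluster = -1
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        cluster += 1
        labels[i] = cluster
        stack = [i]
        while stack:
            j = stack.pop()
            for nb in neighbors[j]:
                if labels[nb] == -1:
                    labels[nb] = cluster
                    if core[nb]:
                        stack.append(nb)
    return labels


@dataclass
class ClusterAssignment:
    """Taxon -> module letter (discovery order) or NOISE."""

    assignments: dict[str, str]
    eps: float
    min_pts: int

    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for taxon, mod in self.assignments.items():
            if mod != NOISE:
                out.setdefault(mod, []).append(taxon)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"module": pd.Series(self.assignments)}
        ).rename_axis("taxon")


def dbscan(points: pd.DataFrame | np.ndarray, eps: float,
           min_pts: int) -> ClusterAssignment:
    """Cluster labeled points (rows) and name modules A, B, C, ...

    Rows are processed in a fixed sorted order of their labels so the
    border-point tie-break, and hence the whole assignment, is
    reproducible.
    """
    if isinstance(points, np.ndarray):
        # bare arrays keep their input order
        width = len(str(max(len(points) - 1, 0)))
        points = pd.DataFrame(
            points, index=[f"p{i:0{width}d}" for i in range(len(points))])
    order = sorted(points.index)
    mat = points.loc[order].to_numpy(dtype=float)
    labels = dbscan_labels(mat, eps, min_pts)
    assignments = {}
    for name, lab in zip(order, labels):
        assignments[name] = NOISE if lab < 0 else chr(ord("A") + lab)
    return ClusterAssignment(assignments, eps=eps, min_pts=min_pts)


def knn_distance_profile(points: pd.DataFrame | np.ndarray,
                         k: int) -> np.ndarray:
    """Sorted (ascending) distances to each point's k-th nearest neighbor."""
    mat = np.asarray(points, dtype=float)
    n = mat.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}]")
    d = cdist(mat, mat)
    d_sorted = np.sort(d, axis=1)  # column 0 is the self-distance 0
    return np.sort(d_sorted[:, k])


def suggest_eps(profile: np.ndarray) -> float:
    """Knee of a sorted k-NN distance profile (max deviation below the chord).

    For the typical profile — a flat plateau of within-module distances
    followed by a jump to between-module scales — this returns a radius
    at the top of the plateau, just before the jump.
    """
    y = np.asarray(profile, dtype=float)
    n = y.size
    if n < 3 or np.ptp(y) == 0:
        return float(y[-1]) if n else 0.0
    x = np.linspace(0.0, 1.0, n)
    yn = (y - y[0]) / (y[-1] - y[0])
    knee = int(np.argmax(x - yn))
    return float(y[knee])


def cluster_taxa(ft: FeatureTable, eps: float | None = None,
                 min_pts: int = 4, scale: bool = False) -> ClusterAssignment:
    """Detect taxon modules in a feature table with DBSCAN.

    When ``eps`` is None it is chosen from the knee of the
    ``(min_pts - 1)``-NN distance profile.
    """
    profiles = taxon_profiles(ft, scale=scale)
    if eps is None:
        k = max(min_pts - 1, 1)
        eps = suggest_eps(knn_distance_profile(profiles, k))
        if eps <= 0:
            raise ValueError("could not derive a positive eps from the "
                             "k-NN profile; set eps explicitly")
    return dbscan(profiles, eps=eps, min_pts=min_pts)
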