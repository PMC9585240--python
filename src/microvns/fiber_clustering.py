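"""Weighted cityblock k-means for large myelinated fibers.

Large fibers (outer diameter above the selection threshold, 2.97 µm in
the reference analysis) are clustered by their cross-section location
under the L1 (cityblock) distance with integer diameter-bin weights.
Weights act as point multiplicities; the L1 centroid update is the
weighted per-coordinate median, the exact minimizer of the cityblock
cost.  The best of several random k-means++-style initializations is
kept.  Clusters are then classified as central or peripheral by how
close their centroid sits to the epineurium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "ClusterResult",
    "assign_weights",
    "weighted_kmeans",
    "classify_cluster_location",
    "cityblock_cost",
]

# half-open diameter bins (µm) -> integer weight; the lowest bin extends
# down to the large-fiber selection threshold
WEIGHT_BIN_EDGES = (6.0, 9.0, 12.0, 15.0)


@dataclass
class ClusterResult:
    labels: np.ndarray  # (n,) cluster index in [0, k)
    centroids: np.ndarray  # (k, 2) µm
    total_cost: float  # weighted sum of L1 distances
    k: int
    replicates: int
    seed: int
    location_class: Optional[list] = None  # per-cluster "central"/"peripheral"


def assign_weights(records: pd.DataFrame) -> np.ndarray:
    """Integer k-means weights from outer diameters.

    Half-open bins: [threshold, 6) → 1, [6, 9) → 2, [9, 12) → 3,
    [12, 15) → 4, [15, ∞) → 5.
    """
    d = records["diameter_um"].to_numpy(float)
    return 1 + np.digitize(d, WEIGHT_BIN_EDGES, right=False)


def cityblock_cost(
    points: np.ndarray, weights: np.ndarray, labels: np.ndarray, centroids: np.ndarray
) -> float:
    """Independent recomputation of the weighted L1 cost."""
    return float(
        np.sum(weights * np.abs(points - centroids[labels]).sum(axis=1))
    )


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    """Weighted median; even-multiplicity ties take the lower middle value."""
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws)
    half = cum[-1] / 2.0
    return float(xs[np.searchsorted(cum, half, side="left")])


def _kmeanspp_init(
    points: np.ndarray, weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(points)
    centroids = np.empty((k, points.shape[1]))
    i0 = rng.choice(n, p=weights / weights.sum())
    centroids[0] = points[i0]
    d2 = np.abs(points - centroids[0]).sum(axis=1) ** 2
    for j in range(1, k):
        p = weights * d2
        if p.sum() <= 0:
            idx = rng.choice(n)
        else:
            idx = rng.choice(n, p=p / p.sum())
        centroids[j] = points[idx]
        d2 = np.minimum(d2, np.abs(points - centroids[j]).sum(axis=1) ** 2)
    return centroids


def weighted_kmeans(
    points: np.ndarray,
    weights: Optional[np.ndarray] = None,
    k: int = 11,
    replicates: int = 5,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterResult:
    """Lloyd-style k-means under the cityblock distance with multiplicities.

    Assignment minimizes L1 distance to the centroids; the update step is
    the weighted per-coordinate median.  Ties in assignment go to the
    lowest cluster index.  An emptied cluster is re-seeded at the point
    farthest (weighted L1) from its centroid.  Deterministic for a fixed
    seed; points are put in canonical (lexicographic) order first so the
    result does not depend on input order.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 1):
        raise ValueError("weights must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points n={n}")

    order = np.lexsort(points.T[::-1])
    pts = points[order]
    w = weights[order]

    best = None
    rng = np.random.default_rng(seed)
    for rep in range(replicates):
        centroids = _kmeanspp_init(pts, w, k, rng)
        labels = np.zeros(n, dtype=int)
        prev_cost = np.inf
        for _ in range(max_iter):
            dist = np.abs(pts[:, None, :] - centroids[None, :, :]).sum(axis=2)
            labels = np.argmin(dist, axis=1)
            # re-seed empty clusters at the worst-served point
            for j in range(k):
                if not np.any(labels == j):
                    far = int(np.argmax(w * dist[np.arange(n), labels]))
                    centroids[j] = pts[far]
                    labels[far] = j
            for j in range(k):
                m = labels == j
                for c in range(pts.shape[1]):
                    centroids[j, c] = _weighted_median(pts[m, c], w[m])
            cost = cityblock_cost(pts, w, labels, centroids)
            if cost > prev_cost + 1e-9:
                raise AssertionError("k-means cost increased between iterations")
            if prev_cost - cost <= 1e-12:
                break
            prev_cost = cost
        if best is None or cost < best[0]:
            best = (cost, labels.copy(), centroids.copy())

    cost, labels_sorted, centroids = best
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return ClusterResult(
        labels=labels,
        centroids=centroids,
        total_cost=cost,
        k=k,
        replicates=replicates,
        seed=seed,
    )


def classify_cluster_location(
    result: ClusterResult, boundary: np.ndarray, margin: float = 0.25
) -> ClusterResult:
    """Label clusters central vs peripheral.

    A cluster is peripheral when its centroid lies within
    ``margin × area-equivalent nerve radius`` of the epineurium boundary.
    ``margin=1`` therefore makes every cluster peripheral.
    """
    poly = Polygon(boundary)
    radius = math.sqrt(poly.area / math.pi)
    ring = poly.exterior
    classes = []
    for c in result.centroids:
        dist = ring.distance(Point(c))
        classes.append("peripheral" if dist < margin * radius else "central")
    result.location_class = classes
    return result
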