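"""Cluster-count selection by the elbow (SSE) and silhouette criteria.

For each representation the number of clusters k is scanned over a grid
(default 2..10).  The elbow criterion takes the k whose point on the SSE
curve is farthest from the chord joining the curve's endpoints (computed on
axes normalized to [0, 1]; ties break toward smaller k).  The silhouette
criterion takes the k maximizing the mean silhouette coefficient
(b − a)/max(a, b), with singleton clusters contributing 0.

SSE curves use best-of-restarts k-means fits, with each k additionally
warm-started from the previous k's best solution (splitting the centroid of
the cluster with the largest within-cluster SSE), which makes the reported
curve non-increasing in k.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from ._seeds import derive_seed
from .clustering import KMeansResult, _as_matrix, _lloyd, kmeans
from .errors import InvalidInputError

__all__ = [
    "DEFAULT_K_GRID",
    "KSelectionResult",
    "sse_curve",
    "detect_elbow",
    "mean_silhouette",
    "choose_k",
    "selection_code",
]

DEFAULT_K_GRID = tuple(range(2, 11))

_CRITERION_INITIAL = {"elbow": "E", "silhouette": "S"}
_REPRESENTATION_INITIAL = {"grayscale": "G", "threshold": "T", "colored": "C"}


def selection_code(criterion: str, representation: str) -> str:
    """Two-letter run code, e.g. (elbow, grayscale) -> 'EG'."""
    try:
        return _CRITERION_INITIAL[criterion] + _REPRESENTATION_INITIAL[representation]
    except KeyError as exc:
        raise InvalidInputError(
            f"unknown criterion/representation pair ({criterion!r}, {representation!r})"
        ) from exc


@dataclasses.dataclass
class KSelectionResult:
    """Curves and chosen ks for one representation."""

    representation: str
    k_grid: tuple[int, ...]
    sse: np.ndarray
    silhouette: np.ndarray
    k_elbow: int
    k_silhouette: int

    def chosen_k(self, criterion: str) -> int:
        if criterion == "elbow":
            return self.k_elbow
        if criterion == "silhouette":
            return self.k_silhouette
        raise InvalidInputError(f"unknown criterion {criterion!r}")


def _validate_grid(k_grid) -> tuple[int, ...]:
    grid = tuple(int(k) for k in k_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise InvalidInputError("k_grid must be strictly increasing")
    return grid


def _scan(X: np.ndarray, k_grid: tuple[int, ...], restarts: int,
          seed: int) -> list[KMeansResult]:
    """Best k-means fit per k, warm-started along the grid."""
    fits: list[KMeansResult] = []
    prev: KMeansResult | None = None
    for k in k_grid:
        best = kmeans(X, k, init="k-means++", seed=derive_seed(seed, "scan", k),
                      restarts=restarts)
        if prev is not None and len(prev.centroids) < k:
            warm = _split_warm_start(X, prev, k)
            if warm.sse < best.sse:
                best = warm
        fits.append(best)
        prev = best
    return fits


def _split_warm_start(X: np.ndarray, prev: KMeansResult, k: int) -> KMeansResult:
    """Warm start at k by splitting the worst cluster of the (k-1) solution.

    The cluster with the largest within-cluster SSE donates its farthest
    point as an extra centroid; a Lloyd pass then refines.  Guarantees the
    best-of-k SSE never exceeds the best-of-(k-1) SSE.
    """
    centroids = prev.centroids
    labels = prev.labels
    per_point = ((X - centroids[labels]) ** 2).sum(axis=1)
    within = np.bincount(labels, weights=per_point, minlength=len(centroids))
    worst = int(within.argmax())
    members = np.nonzero(labels == worst)[0]
    farthest = members[per_point[members].argmax()]
    init = np.vstack([centroids, X[farthest]])
    while len(init) < k:  # grid gaps larger than 1
        d2 = cdist(X, init, "sqeuclidean").min(axis=1)
        init = np.vstack([init, X[int(d2.argmax())]])
    return _lloyd(X, init, max_iter=300)


def sse_curve(vectors, k_grid=DEFAULT_K_GRID, restarts: int = 10,
              seed: int = 0) -> np.ndarray:
    """Per-k SSE of the best seeded k-means fit (warm-started, non-increasing)."""
    X = _as_matrix(vectors)
    grid = _validate_grid(k_grid)
    if max(grid) > len(X):
        raise InvalidInputError(
            f"largest k ({max(grid)}) exceeds the number of points ({len(X)})"
        )
    return np.array([f.sse for f in _scan(X, grid, restarts, seed)])


def detect_elbow(k_grid, sse) -> int:
    """Elbow k: maximum distance from the normalized SSE curve to its chord.

    Both axes are rescaled to [0, 1]; only interior grid points are
    candidates (endpoints lie on the chord); ties break toward smaller k.
    """
    grid = _validate_grid(k_grid)
    y = np.asarray(sse, dtype=float)
    if len(grid) != len(y):
        raise InvalidInputError("k_grid and sse must have equal length")
    if len(grid) < 3:
        raise InvalidInputError("elbow detection needs at least 3 grid points")
    if not np.isfinite(y).all():
        raise InvalidInputError("sse values must be finite")
    x = np.asarray(grid, dtype=float)
    xs = (x - x[0]) / (x[-1] - x[0])
    span = y[0] - y[-1]
    ys = (y - y[-1]) / span if abs(span) > 1e-300 else np.zeros_like(y)
    # chord from (0, ys[0]=1) to (1, 0); distance ∝ |xs + ys - 1| when span>0
    chord = np.array([1.0, -(ys[0])])
    chord = chord / np.linalg.norm(chord)
    rel = np.column_stack([xs - xs[0], ys - ys[0]])
    proj = rel @ chord
    perp = rel - proj[:, None] * chord[None, :]
    dist = np.linalg.norm(perp, axis=1)
    interior = dist[1:-1]
    # first (smallest-k) interior point within numerical tolerance of the max
    best = interior.max()
    idx = int(np.flatnonzero(interior >= best - 1e-12)[0])
    return grid[1 + idx]


def mean_silhouette(vectors, labels) -> float:
    """Mean silhouette coefficient (singletons contribute 0)."""
    X = _as_matrix(vectors)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("silhouette requires at least 2 clusters")
    if len(np.unique(labels)) >= len(X):
        # all-singleton partition: every sample contributes the 0 convention
        return 0.0
    return float(silhouette_score(X, labels, metric="euclidean"))


def choose_k(vectors, k_grid=DEFAULT_K_GRID, restarts: int = 10, seed: int = 0,
             representation: str = "") -> KSelectionResult:
    """Scan the k grid once and record both criteria's choices."""
    X = _as_matrix(vectors)
    grid = _validate_grid(k_grid)
    if max(grid) > len(X):
        raise InvalidInputError(
            f"largest k ({max(grid)}) exceeds the number of points ({len(X)})"
        )
    fits = _scan(X, grid, restarts, seed)
    sse = np.array([f.sse for f in fits])
    sil = np.array([mean_silhouette(X, f.labels) if len(np.unique(f.labels)) > 1
                    else -1.0 for f in fits])
    k_elbow = detect_elbow(grid, sse)
    k_sil = grid[int(np.argmax(sil))]  # argmax takes the first (smallest k) tie
    return KSelectionResult(representation=representation, k_grid=grid,
                            sse=sse, silhouette=sil, k_elbow=k_elbow,
                            k_silhouette=k_sil)
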