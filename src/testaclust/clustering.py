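"""The five-method clustering battery.

Methods: K-means with random-point initialization (M1), K-means++ (M2),
Minibatch K-means (M3), Spectral clustering (M4) and Birch (M5).  The
k-means family and the spectral embedding are implemented here because the
pipeline's validation pins their algorithmic details (D² initialization
probabilities, farthest-point re-seeding of empty clusters, streaming
minibatch updates, the normalized-Laplacian / row-normalization recipe);
Birch's CF-tree stage is delegated to scikit-learn with a centroid-linkage
global merge.

Distances are Euclidean throughout.  Every public entry point is a pure
function of its inputs and seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import eigh
from scipy.spatial.distance import cdist
from sklearn.cluster import Birch

from ._seeds import derive_seed
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "METHODS",
    "METHOD_CODES",
    "PROPOSED_CODES",
    "BatteryConfig",
    "ClusteringRun",
    "KMeansResult",
    "d_squared_weights",
    "kmeanspp_init",
    "kmeans",
    "minibatch_kmeans",
    "spectral_cluster",
    "birch_cluster",
    "run_battery",
]

METHODS = ("kmeans", "kmeanspp", "minibatch", "spectral", "birch")
METHOD_CODES = {"kmeans": "M1", "kmeanspp": "M2", "minibatch": "M3",
                "spectral": "M4", "birch": "M5"}

#: Proposed-run codes: (criterion, representation) -> code.
PROPOSED_CODES = {
    ("elbow", "grayscale"): "EG",
    ("silhouette", "grayscale"): "SG",
    ("elbow", "threshold"): "ET",
    ("silhouette", "threshold"): "ST",
    ("elbow", "colored"): "EC",
    ("silhouette", "colored"): "SC",
}


@dataclasses.dataclass
class ClusteringRun:
    """One labelling of the image set by (method | criterion, representation, k)."""

    code: str
    method: str
    representation: str
    k: int
    labels: np.ndarray
    seed: int
    image_ids: tuple[str, ...] = ()
    criterion: str | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.k < 1:
            raise InvalidInputError("k must be >= 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise InvalidInputError("labels must lie in 0..k-1")
        if self.image_ids and len(self.image_ids) != len(self.labels):
            raise InvalidInputError("image_ids and labels length mismatch")


@dataclasses.dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    sse: float
    n_iter: int


def _as_matrix(vectors) -> np.ndarray:
    X = np.asarray(vectors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or not np.isfinite(X).all():
        raise InvalidInputError("vectors must form a finite 2-D matrix")
    return X


def d_squared_weights(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Normalized D² sampling weights given already-chosen centroids.

    Each point's weight is its squared distance to the nearest chosen
    centroid, normalized to sum to 1; a point coinciding with a centroid
    has weight 0.
    """
    X = _as_matrix(X)
    C = _as_matrix(centroids)
    d2 = cdist(X, C, "sqeuclidean").min(axis=1)
    total = d2.sum()
    if total <= 0:
        # all points coincide with centroids; fall back to uniform
        return np.full(len(X), 1.0 / len(X))
    return d2 / total


def kmeanspp_init(vectors, k: int, seed: int = 0) -> np.ndarray:
    """K-means++ initialization: first centroid uniform, then D² sampling."""
    X = _as_matrix(vectors)
    n = len(X)
    if k > n:
        raise InvalidInputError(f"k={k} exceeds the number of points n={n}")
    rng = np.random.default_rng(seed)
    centroids = [X[rng.integers(n)]]
    while len(centroids) < k:
        w = d_squared_weights(X, np.asarray(centroids))
        centroids.append(X[rng.choice(n, p=w)])
    return np.asarray(centroids)


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int) -> KMeansResult:
    """Lloyd iterations with farthest-point re-seeding of empty clusters."""
    k = len(centroids)
    centroids = centroids.copy()
    labels = np.full(len(X), -1)
    for it in range(1, max_iter + 1):
        dist = cdist(X, centroids, "sqeuclidean")
        new_labels = dist.argmin(axis=1)
        # re-seed empty clusters with the point farthest from its centroid
        for empty in range(k):
            if not (new_labels == empty).any():
                worst = int(dist[np.arange(len(X)), new_labels].argmax())
                new_labels[worst] = empty
                centroids[empty] = X[worst]
                dist[:, empty] = cdist(X, centroids[empty:empty + 1],
                                       "sqeuclidean")[:, 0]
        if (new_labels == labels).all():
            labels = new_labels
            break
        labels = new_labels
        for c in range(k):
            members = X[labels == c]
            if len(members):  # degenerate duplicate-point inputs
                centroids[c] = members.mean(axis=0)
    sse = float(((X - centroids[labels]) ** 2).sum())
    return KMeansResult(labels=labels, centroids=centroids, sse=sse, n_iter=it)


def kmeans(vectors, k: int, init="k-means++", max_iter: int = 300,
           seed: int = 0, restarts: int = 10) -> KMeansResult:
    """Best-of-restarts Lloyd k-means.

    ``init`` is "k-means++", "random" (random distinct points), or an
    explicit (k, d) centroid array (then a single run is performed).
    """
    X = _as_matrix(vectors)
    n = len(X)
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if k > n:
        raise InvalidInputError(f"k={k} exceeds the number of points n={n}")
    if isinstance(init, np.ndarray) or isinstance(init, (list, tuple)):
        return _lloyd(X, _as_matrix(init), max_iter)
    best: KMeansResult | None = None
    for r in range(restarts):
        run_seed = derive_seed(seed, "kmeans", r)
        if init == "k-means++":
            c0 = kmeanspp_init(X, k, seed=run_seed)
        elif init == "random":
            rng = np.random.default_rng(run_seed)
            c0 = X[rng.choice(n, size=k, replace=False)]
        else:
            raise InvalidInputError(f"unknown init {init!r}")
        result = _lloyd(X, c0, max_iter)
        if best is None or result.sse < best.sse:
            best = result
    return best


def minibatch_kmeans(vectors, k: int, batch_size: int = 32,
                     iterations: int = 200, seed: int = 0,
                     restarts: int = 5) -> KMeansResult:
    """Minibatch k-means with per-centroid streaming learning rates.

    Each iteration draws a random batch, assigns it to the nearest
    centroids, and moves each selected centroid toward its batch points
    with step size 1/count; final labels come from a nearest-centroid pass
    (with empty clusters refilled by farthest points).  The streaming pass
    cannot escape a bad initialization, so the whole procedure is restarted
    ``restarts`` times and the lowest-SSE labelling kept.
    """
    X = _as_matrix(vectors)
    n = len(X)
    if batch_size > n:
        raise InvalidInputError("batch_size must not exceed the number of points")
    if k > n:
        raise InvalidInputError(f"k={k} exceeds the number of points n={n}")
    best: KMeansResult | None = None
    for r in range(max(1, restarts)):
        rng = np.random.default_rng(derive_seed(seed, "mb-stream", r))
        centroids = kmeanspp_init(X, k, seed=derive_seed(seed, "mb-init", r))
        counts = np.zeros(k)
        for _ in range(iterations):
            batch = X[rng.choice(n, size=batch_size, replace=False)]
            assign = cdist(batch, centroids, "sqeuclidean").argmin(axis=1)
            for x, c in zip(batch, assign):
                counts[c] += 1
                eta = 1.0 / counts[c]
                centroids[c] = (1 - eta) * centroids[c] + eta * x
        labels = cdist(X, centroids, "sqeuclidean").argmin(axis=1)
        labels, centroids = _fill_empty_clusters(X, labels, centroids)
        sse = float(((X - centroids[labels]) ** 2).sum())
        result = KMeansResult(labels=labels, centroids=centroids, sse=sse,
                              n_iter=iterations)
        if best is None or result.sse < best.sse:
            best = result
    return best


def _fill_empty_clusters(X, labels, centroids):
    """Move farthest points into empty clusters so all of 0..k-1 are used."""
    k = len(centroids)
    labels = labels.copy()
    centroids = centroids.copy()
    for empty in range(k):
        if not (labels == empty).any():
            dist = ((X - centroids[labels]) ** 2).sum(axis=1)
            # avoid emptying a singleton cluster in turn
            sizes = np.bincount(labels, minlength=k)
            dist[sizes[labels] <= 1] = -1.0
            worst = int(dist.argmax())
            labels[worst] = empty
            centroids[empty] = X[worst]
    return labels, centroids


def default_rbf_gamma(X: np.ndarray) -> float:
    """Default RBF scale: 1 / (total feature variance × dimension)."""
    X = _as_matrix(X)
    var = float(X.var())
    d = X.shape[1]
    return 1.0 / max(var * d, 1e-12)


def spectral_cluster(vectors, k: int, rbf_gamma: float | None = None,
                     seed: int = 0, affinity: np.ndarray | None = None) -> np.ndarray:
    """Normalized-cut spectral clustering.

    RBF affinity (or a precomputed affinity matrix), symmetric normalized
    Laplacian, the k eigenvectors of smallest eigenvalue, row normalization,
    then k-means on the embedded rows.
    """
    X = _as_matrix(vectors)
    n = len(X)
    if k < 2:
        raise InvalidInputError("spectral clustering requires k >= 2")
    if n < k:
        raise InvalidInputError(f"k={k} exceeds the number of points n={n}")
    if affinity is None:
        gamma = default_rbf_gamma(X) if rbf_gamma is None else rbf_gamma
        A = np.exp(-gamma * cdist(X, X, "sqeuclidean"))
    else:
        A = np.asarray(affinity, dtype=float)
        if A.shape != (n, n):
            raise InvalidInputError("affinity must be n x n")
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    L = np.eye(n) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
    try:
        vals, vecs = eigh(L, subset_by_index=(0, k - 1))
    except Exception as exc:  # pragma: no cover - numerical failure path
        raise ConfigurationError(f"spectral eigendecomposition failed: {exc}") from exc
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    embedded = vecs / np.maximum(norms, 1e-12)
    return kmeans(embedded, k, seed=derive_seed(seed, "spectral-kmeans"),
                  restarts=10).labels


def birch_cluster(vectors, k: int, branching: int = 50,
                  radius_threshold: float = 0.5):
    """Birch: one-pass CF-tree summarization, then centroid-linkage merge to k.

    Returns ``(labels, n_subclusters)`` where ``n_subclusters`` is the number
    of CF-tree leaf entries before the global merge.
    """
    X = _as_matrix(vectors)
    if branching < 2:
        raise InvalidInputError("branching must be >= 2")
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    tree = Birch(threshold=radius_threshold, branching_factor=branching,
                 n_clusters=None)
    sub = tree.fit_predict(X)
    centers = tree.subcluster_centers_
    n_sub = len(centers)
    if n_sub <= k:
        # fewer summaries than clusters: each leaf entry is its own cluster
        labels = sub.copy()
    else:
        Z = linkage(centers, method="centroid")
        merged = fcluster(Z, t=k, criterion="maxclust") - 1
        labels = merged[sub]
    # compact to contiguous 0..k'-1 in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return labels.astype(int), n_sub


# ---------------------------------------------------------------------------
# Battery orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BatteryConfig:
    """Configuration of the five-method battery and the six proposed runs."""

    methods: tuple[str, ...] = METHODS
    representations: tuple[str, ...] = ("grayscale", "threshold", "colored")
    criteria: tuple[str, ...] = ("elbow", "silhouette")
    restarts: int = 10
    batch_size: int = 32
    minibatch_iterations: int = 200
    birch_branching: int = 50
    birch_threshold: float = 0.5
    rbf_gamma: float | None = None
    m_run_representation: str = "grayscale"
    m_run_criterion: str = "elbow"
    master_seed: int = 0

    def __post_init__(self):
        if self.restarts < 1:
            raise InvalidInputError("restarts must be >= 1")
        if self.batch_size < 1:
            raise InvalidInputError("batch_size must be >= 1")
        if self.birch_branching < 2:
            raise InvalidInputError("birch_branching must be >= 2")
        for m in self.methods:
            if m not in METHODS:
                raise InvalidInputError(f"unknown method {m!r}")


def standardize(X: np.ndarray) -> np.ndarray:
    """Per-dimension z-score; constant dimensions map to 0."""
    X = _as_matrix(X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def run_method(method: str, X: np.ndarray, k: int, config: BatteryConfig,
               seed: int) -> np.ndarray:
    """Dispatch one method on one feature matrix; returns a label vector."""
    if method == "kmeans":
        return kmeans(X, k, init="random", seed=seed,
                      restarts=config.restarts).labels
    if method == "kmeanspp":
        return kmeans(X, k, init="k-means++", seed=seed,
                      restarts=config.restarts).labels
    if method == "minibatch":
        return minibatch_kmeans(X, k, batch_size=min(config.batch_size, len(X)),
                                iterations=config.minibatch_iterations,
                                seed=seed).labels
    if method == "spectral":
        return spectral_cluster(standardize(X), k, rbf_gamma=config.rbf_gamma,
                                seed=seed)
    if method == "birch":
        labels, _ = birch_cluster(standardize(X), k,
                                  branching=config.birch_branching,
                                  radius_threshold=config.birch_threshold)
        return labels
    raise InvalidInputError(f"unknown method {method!r}")


def run_battery(image_ids: Sequence[str], features: dict[str, np.ndarray],
                config: BatteryConfig, selection: dict) -> list[ClusteringRun]:
    """Produce the M1..M5 method runs and the six proposed EG..SC runs.

    ``features`` maps representation name to an (n, d) matrix over the same
    image ordering as ``image_ids``; ``selection`` maps representation name
    to a :class:`~testaclust.model_selection.KSelectionResult`.
    """
    ids = tuple(image_ids)
    runs: list[ClusteringRun] = []

    # Method comparison runs M1..M5 on one representation/criterion.
    rep = config.m_run_representation
    if rep not in features:
        raise ConfigurationError(f"no features for representation {rep!r}")
    if rep not in selection:
        raise ConfigurationError(f"no k-selection for representation {rep!r}")
    k_m = selection[rep].chosen_k(config.m_run_criterion)
    for method in config.methods:
        seed = derive_seed(config.master_seed, "battery", method, rep)
        labels = run_method(method, features[rep], k_m, config, seed)
        runs.append(ClusteringRun(code=METHOD_CODES[method], method=method,
                                  representation=rep, k=k_m, labels=labels,
                                  seed=seed, image_ids=ids,
                                  criterion=config.m_run_criterion))

    # Proposed runs: one per (criterion, representation), K-means++ workhorse.
    for criterion in config.criteria:
        for rep in config.representations:
            if rep not in selection:
                raise ConfigurationError(f"no k-selection for representation {rep!r}")
            code = PROPOSED_CODES[(criterion, rep)]
            k = selection[rep].chosen_k(criterion)
            seed = derive_seed(config.master_seed, "battery", code)
            labels = kmeans(features[rep], k, init="k-means++", seed=seed,
                            restarts=config.restarts).labels
            runs.append(ClusteringRun(code=code, method="kmeanspp",
                                      representation=rep, k=k, labels=labels,
                                      seed=seed, image_ids=ids,
                                      criterion=criterion))
    return runs
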