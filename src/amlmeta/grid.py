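"""Grid search over transformation x dimensionality x clustering combinations.

The default registry pairs 11 embedding algorithms with 11 clustering
algorithms across target dimensionalities 2-6, i.e. 11 x 5 x 11 = 605
combinations. Each combination is executed for a fixed number of seeded
iterations; every run is scored with internal validation indices
(silhouette, Calinski-Harabasz, Davies-Bouldin, all Euclidean) and vetted
by a sanity check (cluster count between 2 and ``max_clusters``, every
cluster at least ``min_frac`` of the cohort). Incompatible algorithm
pairings fail gracefully: the failure is recorded, never raised.

Clusterers that need a preset cluster count sweep k over 2..max_clusters
inside the run and keep the partition with the best silhouette. Density
clusterers that emit noise points have those points reassigned to the
nearest cluster centroid before the sanity check.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.cluster import (
    DBSCAN,
    OPTICS,
    AffinityPropagation,
    AgglomerativeClustering,
    Birch,
    KMeans,
    MeanShift,
    MiniBatchKMeans,
    SpectralClustering,
    estimate_bandwidth,
)
from sklearn.decomposition import NMF, PCA, FactorAnalysis, FastICA, KernelPCA, TruncatedSVD
from sklearn.manifold import (
    MDS,
    TSNE,
    Isomap,
    LocallyLinearEmbedding,
    SpectralEmbedding,
)
from scipy.spatial.distance import cdist
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .preprocess import ClusteringMatrix

logger = logging.getLogger(__name__)

DEFAULT_DIMS = (2, 3, 4, 5, 6)
DEFAULT_MIN_FRAC = 0.10
DEFAULT_MAX_CLUSTERS = 10
DEFAULT_ITERATIONS = 10


class DegenerateClusteringError(ValueError):
    """Raised when quality metrics are undefined (<2 clusters, empty cluster)."""


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class TransformSpec:
    name: str
    make: Callable[[int, int], object]  # (dim, seed) -> estimator with fit_transform


@dataclass(frozen=True)
class ClustererSpec:
    name: str
    needs_k: bool
    # (X_embedded, seed, k) -> labels
    fit_predict: Callable[[np.ndarray, int, int | None], np.ndarray]


@dataclass(frozen=True)
class AlgorithmRegistry:
    transforms: tuple[TransformSpec, ...]
    dims: tuple[int, ...]
    clusterers: tuple[ClustererSpec, ...]

    def __post_init__(self) -> None:
        if not self.transforms or not self.dims or not self.clusterers:
            raise ValueError("registry components must be non-empty")

    @property
    def n_combinations(self) -> int:
        return len(self.transforms) * len(self.dims) * len(self.clusterers)


def _tsne(dim: int, seed: int):
    return TSNE(
        n_components=dim,
        random_state=seed,
        method="exact" if dim > 3 else "barnes_hut",
        init="pca",
        perplexity=30.0,
    )


class _ShiftedNMF:
    """NMF on data shifted to be non-negative (clustering data is z-scored)."""

    def __init__(self, dim: int, seed: int) -> None:
        self.nmf = NMF(n_components=dim, random_state=seed, init="nndsvda", max_iter=500)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.nmf.fit_transform(X - X.min())


_TRANSFORM_FACTORIES: dict[str, Callable[[int, int], object]] = {
    "pca": lambda d, s: PCA(n_components=d, svd_solver="full", random_state=s),
    "kernel_pca": lambda d, s: KernelPCA(n_components=d, kernel="rbf", random_state=s),
    "truncated_svd": lambda d, s: TruncatedSVD(n_components=d, random_state=s),
    "fast_ica": lambda d, s: FastICA(n_components=d, random_state=s, max_iter=1000, tol=1e-3),
    "factor_analysis": lambda d, s: FactorAnalysis(n_components=d, random_state=s),
    "nmf_shifted": lambda d, s: _ShiftedNMF(d, s),
    "mds": lambda d, s: MDS(n_components=d, random_state=s, n_init=1, normalized_stress="auto"),
    "isomap": lambda d, s: Isomap(n_components=d),
    "lle": lambda d, s: LocallyLinearEmbedding(n_components=d, random_state=s),
    "spectral_embedding": lambda d, s: SpectralEmbedding(n_components=d, random_state=s),
    "tsne": _tsne,
}


def _kmeans(X, seed, k):
    return KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)


def _minibatch_kmeans(X, seed, k):
    return MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)


def _ward(X, seed, k):
    return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)


def _average_link(X, seed, k):
    return AgglomerativeClustering(n_clusters=k, linkage="average").fit_predict(X)


def _birch(X, seed, k):
    return Birch(n_clusters=k).fit_predict(X)


def _gmm(X, seed, k):
    return GaussianMixture(n_components=k, random_state=seed).fit_predict(X)


def _spectral(X, seed, k):
    return SpectralClustering(
        n_clusters=k, random_state=seed, assign_labels="kmeans", n_neighbors=10
    ).fit_predict(X)


def _mean_shift(X, seed, k=None):
    bw = estimate_bandwidth(X, quantile=0.3, random_state=seed)
    if bw <= 0:
        bw = None
    return MeanShift(bandwidth=bw, bin_seeding=False).fit_predict(X)


def _knn_eps(X: np.ndarray, k: int = 5) -> float:
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(X)))
    dist, _ = nn.fit(X).kneighbors(X)
    eps = float(np.median(dist[:, -1]))
    return eps if eps > 0 else 0.5


def _dbscan(X, seed, k=None):
    return DBSCAN(eps=_knn_eps(X), min_samples=5).fit_predict(X)


def _optics(X, seed, k=None):
    return OPTICS(min_samples=max(5, len(X) // 100)).fit_predict(X)


def _affinity_propagation(X, seed, k=None):
    return AffinityPropagation(random_state=seed, damping=0.9, max_iter=300).fit_predict(X)


_CLUSTERERS: tuple[ClustererSpec, ...] = (
    ClustererSpec("kmeans", True, _kmeans),
    ClustererSpec("minibatch_kmeans", True, _minibatch_kmeans),
    ClustererSpec("agglomerative_ward", True, _ward),
    ClustererSpec("agglomerative_average", True, _average_link),
    ClustererSpec("birch", True, _birch),
    ClustererSpec("gaussian_mixture", True, _gmm),
    ClustererSpec("spectral", True, _spectral),
    ClustererSpec("mean_shift", False, _mean_shift),
    ClustererSpec("dbscan", False, _dbscan),
    ClustererSpec("optics", False, _optics),
    ClustererSpec("affinity_propagation", False, _affinity_propagation),
)


def default_registry() -> AlgorithmRegistry:
    """11 transforms x dims 2-6 x 11 clusterers = 605 combinations."""
    transforms = tuple(TransformSpec(n, f) for n, f in _TRANSFORM_FACTORIES.items())
    return AlgorithmRegistry(transforms, DEFAULT_DIMS, _CLUSTERERS)


def reduced_registry(
    transform_names: tuple[str, ...] = ("pca", "truncated_svd", "fast_ica", "factor_analysis"),
    dims: tuple[int, ...] = (2, 3),
    clusterer_names: tuple[str, ...] = (
        "kmeans",
        "minibatch_kmeans",
        "agglomerative_ward",
        "gaussian_mixture",
    ),
) -> AlgorithmRegistry:
    """Small fast registry for demos, smoke tests and recovery experiments."""
    transforms = tuple(
        TransformSpec(n, _TRANSFORM_FACTORIES[n]) for n in transform_names
    )
    by_name = {c.name: c for c in _CLUSTERERS}
    clusterers = tuple(by_name[n] for n in clusterer_names)
    return AlgorithmRegistry(transforms, tuple(dims), clusterers)


# ---------------------------------------------------------------------------
# grid enumeration and execution


@dataclass(frozen=True)
class GridRunSpec:
    combo_index: int
    transform: TransformSpec
    dim: int
    clusterer: ClustererSpec
    master_seed: int

    @property
    def combo_id(self) -> tuple[str, int, str]:
        return (self.transform.name, self.dim, self.clusterer.name)

    def seed_for(self, iteration: int) -> int:
        ss = np.random.SeedSequence(self.master_seed, spawn_key=(self.combo_index, iteration))
        return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class GridRunResult:
    combo_id: tuple[str, int, str]
    iteration: int
    seed: int
    labels: np.ndarray | None
    n_clusters: int
    silhouette: float | None
    calinski_harabasz: float | None
    davies_bouldin: float | None
    sanity_pass: bool
    failure_reason: str | None = None


def enumerate_grid(registry: AlgorithmRegistry, master_seed: int = 0) -> list[GridRunSpec]:
    """Cartesian product in deterministic (transform, dim, clusterer) order."""
    specs = []
    for i, (t, d, c) in enumerate(
        itertools.product(registry.transforms, registry.dims, registry.clusterers)
    ):
        specs.append(GridRunSpec(i, t, d, c, master_seed))
    return specs


def sanity_check(
    labels: np.ndarray,
    n_patients: int,
    min_frac: float = DEFAULT_MIN_FRAC,
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
) -> tuple[bool, str | None]:
    """Partition quality gate: 2..max_clusters clusters, and every cluster at
    least ``ceil(min_frac * n)`` patients (both boundaries inclusive)."""
    labels = np.asarray(labels)
    if len(labels) != n_patients:
        raise ValueError("labels length does not match n_patients")
    _, counts = np.unique(labels, return_counts=True)
    k = len(counts)
    if k < 2:
        return False, f"only {k} cluster(s)"
    if k > max_clusters:
        return False, f"{k} clusters exceeds maximum {max_clusters}"
    min_size = int(np.ceil(min_frac * n_patients))
    if counts.min() < min_size:
        return False, f"smallest cluster has {int(counts.min())} < {min_size} patients"
    return True, None


def compute_quality_metrics(
    X_embedded: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Silhouette, Calinski-Harabasz and Davies-Bouldin (Euclidean).

    Raises :class:`DegenerateClusteringError` when undefined: fewer than two
    clusters, or any cluster empty after relabelling.
    """
    labels = np.asarray(labels)
    if len(labels) != len(X_embedded):
        raise ValueError("labels length does not match matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or len(uniq) >= len(labels):
        raise DegenerateClusteringError(
            f"metrics undefined for {len(uniq)} clusters over {len(labels)} points"
        )
    sil = float(silhouette_score(X_embedded, labels, metric="euclidean"))
    ch = float(calinski_harabasz_score(X_embedded, labels))
    return sil, ch, _davies_bouldin(X_embedded, labels, uniq)


def _davies_bouldin(X: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    # direct difference-based distances: the expanded-form shortcut some
    # libraries use loses ~1e-8 of precision to cancellation
    X = np.asarray(X, dtype=float)
    centroids = np.vstack([X[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [np.linalg.norm(X[labels == u] - centroids[i], axis=1).mean() for i, u in enumerate(uniq)]
    )
    sep = cdist(centroids, centroids)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (scatter[:, None] + scatter[None, :]) / sep
    np.fill_diagonal(ratio, -np.inf)
    worst = ratio.max(axis=1)
    worst[~np.isfinite(worst)] = 0.0  # coincident centroids
    return float(worst.mean())


def _reassign_noise(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Map noise points (label -1) to the nearest cluster centroid."""
    labels = labels.copy()
    noise = labels == -1
    if not noise.any():
        return labels
    keep = ~noise
    if not keep.any():
        raise DegenerateClusteringError("all points labelled noise")
    uniq = np.unique(labels[keep])
    centroids = np.vstack([X[labels == u].mean(axis=0) for u in uniq])
    d = np.linalg.norm(X[noise][:, None, :] - centroids[None, :, :], axis=2)
    labels[noise] = uniq[d.argmin(axis=1)]
    return labels


def _best_k_partition(
    clusterer: ClustererSpec,
    X: np.ndarray,
    seed: int,
    max_clusters: int,
) -> np.ndarray:
    """Sweep k over 2..max_clusters, keep the silhouette-best partition."""
    best_labels, best_sil = None, -np.inf
    for k in range(2, max_clusters + 1):
        if k >= len(X):
            break
        try:
            labels = clusterer.fit_predict(X, seed, k)
            sil = float(silhouette_score(X, labels))
        except Exception:  # an individual k may legitimately fail
            continue
        if sil > best_sil:
            best_labels, best_sil = labels, sil
    if best_labels is None:
        raise DegenerateClusteringError("no k in sweep produced a scorable partition")
    return best_labels


def run_combination(
    spec: GridRunSpec,
    matrix: ClusteringMatrix | np.ndarray,
    n_iterations: int = DEFAULT_ITERATIONS,
    min_frac: float = DEFAULT_MIN_FRAC,
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
) -> list[GridRunResult]:
    """Execute one (transform, dim, clusterer) combination for all iterations.

    Failures of any kind (inapplicable pairing, non-convergence, degenerate
    partitions) are captured per-iteration in ``failure_reason``; nothing is
    raised.
    """
    X = matrix.matrix if isinstance(matrix, ClusteringMatrix) else np.asarray(matrix)
    results: list[GridRunResult] = []
    for it in range(n_iterations):
        seed = spec.seed_for(it)
        try:
            transformer = spec.transform.make(spec.dim, seed)
            X_emb = np.asarray(transformer.fit_transform(X), dtype=float)
            if not np.isfinite(X_emb).all():
                raise ValueError("embedding produced non-finite coordinates")
            if spec.clusterer.needs_k:
                labels = _best_k_partition(spec.clusterer, X_emb, seed, max_clusters)
            else:
                labels = np.asarray(spec.clusterer.fit_predict(X_emb, seed, None))
                labels = _reassign_noise(X_emb, labels)
            n_clusters = len(np.unique(labels))
            passed, reason = sanity_check(labels, len(X), min_frac, max_clusters)
            try:
                sil, ch, db = compute_quality_metrics(X_emb, labels)
            except DegenerateClusteringError:
                sil = ch = db = None
            results.append(
                GridRunResult(
                    spec.combo_id, it, seed, labels, n_clusters, sil, ch, db, passed, reason
                )
            )
        except Exception as exc:  # noqa: BLE001 — grid must survive any pairing
            logger.debug("combination %s iteration %d failed: %s", spec.combo_id, it, exc)
            results.append(
                GridRunResult(
                    spec.combo_id, it, seed, None, 0, None, None, None, False,
                    f"{type(exc).__name__}: {exc}",
                )
            )
    return results


def run_grid(
    registry: AlgorithmRegistry,
    matrix: ClusteringMatrix | np.ndarray,
    master_seed: int = 0,
    n_iterations: int = DEFAULT_ITERATIONS,
    min_frac: float = DEFAULT_MIN_FRAC,
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
    n_jobs: int = 1,
) -> list[GridRunResult]:
    """Execute the full grid; embarrassingly parallel, order-independent."""
    specs = enumerate_grid(registry, master_seed)
    if n_jobs == 1:
        chunks = [
            run_combination(s, matrix, n_iterations, min_frac, max_clusters) for s in specs
        ]
    else:
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(run_combination)(s, matrix, n_iterations, min_frac, max_clusters)
            for s in specs
        )
    return [r for chunk in chunks for r in chunk]


def collect_passing(results: list[GridRunResult]) -> list[GridRunResult]:
    """Sanity-passing runs, in input order."""
    passing = [r for r in results if r.sanity_pass]
    if not passing:
        logger.warning("no grid run passed the sanity check")
    return passing


def summarize_results(results: list[GridRunResult]) -> pd.DataFrame:
    """Per-run metric table plus pass verdicts (combination-level overview)."""
    rows = []
    for r in results:
        rows.append(
            {
                "transform": r.combo_id[0],
                "dim": r.combo_id[1],
                "clusterer": r.combo_id[2],
                "iteration": r.iteration,
                "n_clusters": r.n_clusters,
                "silhouette": r.silhouette,
                "calinski_harabasz": r.calinski_harabasz,
                "davies_bouldin": r.davies_bouldin,
                "sanity_pass": r.sanity_pass,
                "failure_reason": r.failure_reason,
            }
        )
    return pd.DataFrame(rows)


def metric_ranges(results: list[GridRunResult]) -> dict[str, tuple[float, float]]:
    """Min/max of each internal index over sanity-passing runs."""
    passing = [r for r in results if r.sanity_pass and r.silhouette is not None]
    if not passing:
        return {}
    return {
        "silhouette": (
            min(r.silhouette for r in passing),
            max(r.silhouette for r in passing),
        ),
        "calinski_harabasz": (
            min(r.calinski_harabasz for r in passing),
            max(r.calinski_harabasz for r in passing),
        ),
        "davies_bouldin": (
            min(r.davies_bouldin for r in passing),
            max(r.davies_bouldin for r in passing),
        ),
    }
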