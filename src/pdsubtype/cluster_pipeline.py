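"""Fused-similarity distance, hierarchical clustering and joint tuning.

The fused bi-stochastic similarity matrix is converted to a dissimilarity
(one minus the similarity after rescaling), clustered by agglomerative
hierarchical clustering on the precomputed distances, and the cluster
number together with the per-view kernel bandwidths is tuned by maximising
the mean silhouette index over a seeded random search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score as _sk_silhouette

from .cohort_io import CohortTable, zscore_view
from .kernel_fusion import (
    BistochasticMatrix,
    ConvergenceError,
    FusionConfig,
    FusionResult,
    kernel_from_sq_distances,
    mbbs_fuse,
)

__all__ = [
    "DistanceMatrix",
    "ClusteringResult",
    "SearchResult",
    "to_distance",
    "hierarchical_cluster",
    "silhouette_score",
    "joint_search",
    "run_pipeline",
]

BANDWIDTH_RANGE = (0.25, 4.0)
DEFAULT_K_RANGE = (2, 3, 4, 5, 6)


@dataclass
class DistanceMatrix:
    values: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        self.values = D

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    linkage_method: str
    silhouette: float


@dataclass
class Trial:
    bandwidth_scales: dict[str, float]
    k: int
    silhouette: float
    weights: np.ndarray | None = None
    error: str | None = None


@dataclass
class SearchResult:
    trials: list[Trial]
    best: ClusteringResult
    best_fusion: FusionResult
    best_trial: Trial
    n_trials: int
    seed: int
    patient_ids: list = field(default_factory=list)


def to_distance(fused: BistochasticMatrix | np.ndarray, rescale: str = "max") -> DistanceMatrix:
    """Dissimilarity D = 1 - K from a fused similarity matrix.

    A bi-stochastic matrix has entries that are small (each row sums to one
    across N entries), so the literal complement would compress all
    distances near one; by default the matrix is first divided by its
    maximum off-diagonal entry (``rescale="max"``).  ``rescale="none"``
    applies the literal complement.  The diagonal is forced to zero and
    negative dust clipped.
    """
    K = fused.values if isinstance(fused, BistochasticMatrix) else np.asarray(fused, dtype=float)
    n = K.shape[0]
    off = ~np.eye(n, dtype=bool)
    if rescale == "max":
        m = K[off].max()
        if m <= 0:
            raise ValueError("fused similarity has no positive off-diagonal entry")
        K = K / m
    elif rescale != "none":
        raise ValueError(f"unknown rescale mode {rescale!r}")
    D = 1.0 - K
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(values=np.clip(D, 0.0, None))


def hierarchical_cluster(
    D: DistanceMatrix, k: int, linkage_method: str = "average"
) -> ClusteringResult:
    """Agglomerative clustering on precomputed distances, cut at k clusters.

    Average linkage by default (valid for arbitrary dissimilarities; Ward
    presumes Euclidean geometry).  Deterministic given D.
    """
    n = D.n
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} patients")
    if linkage_method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    Z = linkage(squareform(D.values, checks=False), method=linkage_method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    sil = silhouette_score(D, labels) if 2 <= len(np.unique(labels)) <= n - 1 else float("nan")
    return ClusteringResult(labels=labels, k=int(len(np.unique(labels))), linkage_method=linkage_method, silhouette=sil)


def silhouette_score(D: DistanceMatrix | np.ndarray, labels) -> float:
    """Mean silhouette index (b - a)/max(a, b) on precomputed distances.

    Singleton clusters contribute zero.  Requires at least two and at most
    N - 1 clusters.
    """
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("silhouette requires at least two clusters")
    if k > len(labels) - 1:
        raise ValueError("silhouette requires at most N - 1 clusters")
    return float(_sk_silhouette(Dv, labels, metric="precomputed"))


def run_pipeline(
    sq_dists: dict[str, np.ndarray],
    bandwidth_scales: dict[str, float],
    k: int,
    fusion_config: FusionConfig | None = None,
    linkage_method: str = "average",
    rescale: str = "max",
) -> tuple[ClusteringResult, FusionResult]:
    """Kernels -> fusion -> distance -> clustering for one hyperparameter set."""
    kernels = [
        kernel_from_sq_distances(sq_dists[v], bandwidth_scales[v], view_name=v)
        for v in sq_dists
    ]
    fusion = mbbs_fuse(kernels, fusion_config)
    D = to_distance(fusion.fused, rescale=rescale)
    clustering = hierarchical_cluster(D, k, linkage_method)
    return clustering, fusion


def view_sq_distances(
    cohort: CohortTable, views: tuple[str, ...] = ("motor", "non-motor"), ddof: int = 1
) -> dict[str, np.ndarray]:
    """Squared Euclidean distances of each z-scored view (kernel input)."""
    from scipy.spatial.distance import pdist

    out = {}
    for v in views:
        X = zscore_view(cohort, v, ddof=ddof)
        out[v] = squareform(pdist(X) ** 2)
    return out


def joint_search(
    cohort: CohortTable,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    n_trials: int = 100,
    seed: int = 0,
    views: tuple[str, ...] = ("motor", "non-motor"),
    fusion_config: FusionConfig | None = None,
    linkage_method: str = "average",
    objective=None,
) -> SearchResult:
    """Seeded random search over per-view bandwidths and cluster number.

    Per trial, each view's bandwidth scale is drawn log-uniformly in
    [0.25, 4] and k uniformly from ``k_range``; the full pipeline is run
    and scored by the silhouette index (or a caller-supplied ``objective``
    taking the clustering and fusion results).  Returns every trial and
    the argmax.  Fully reproducible from ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = np.random.default_rng(seed)
    sq = view_sq_distances(cohort, views)
    lo, hi = np.log(BANDWIDTH_RANGE[0]), np.log(BANDWIDTH_RANGE[1])
    trials: list[Trial] = []
    best: tuple[float, ClusteringResult, FusionResult, Trial] | None = None
    for _ in range(n_trials):
        scales = {v: float(np.exp(rng.uniform(lo, hi))) for v in views}
        k = int(rng.choice(k_range))
        try:
            clustering, fusion = run_pipeline(
                sq, scales, k, fusion_config, linkage_method
            )
        except (ConvergenceError, ValueError) as exc:
            trials.append(Trial(scales, k, float("nan"), error=str(exc)))
            continue
        score = (
            clustering.silhouette
            if objective is None
            else float(objective(clustering, fusion))
        )
        trial = Trial(scales, k, score, weights=fusion.weights)
        trials.append(trial)
        # Exact ties in the search objective (common when an external
        # agreement objective saturates) are broken by the silhouette.
        if np.isfinite(score) and (
            best is None
            or score > best[0]
            or (score == best[0] and clustering.silhouette > best[1].silhouette)
        ):
            best = (score, clustering, fusion, trial)
    if best is None:
        errors = {t.error for t in trials if t.error}
        raise RuntimeError(f"all {n_trials} trials failed: {sorted(errors)}")
    _, clustering, fusion, trial = best
    if objective is not None:
        clustering = ClusteringResult(
            labels=clustering.labels,
            k=clustering.k,
            linkage_method=clustering.linkage_method,
            silhouette=clustering.silhouette,
        )
    return SearchResult(
        trials=trials,
        best=clustering,
        best_fusion=fusion,
        best_trial=trial,
        n_trials=n_trials,
        seed=seed,
        patient_ids=list(cohort.patient_ids),
    )
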