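"""Clustering of featurized structures with per-algorithm model selection.

Four algorithms are offered, each paired with the model-selection rule that
picks its number of clusters:

* k-means — restarts initialized at random data points, the restart with
  the smallest within-cluster scatter loss kept; k chosen at the knee of
  the SSE-vs-k curve (chord-distance rule).
* Gaussian mixture — k chosen by minimizing BIC.
* single-linkage agglomerative — the dendrogram is built once and cut at
  each candidate k; the cut minimizing the Davies-Bouldin index wins.
* greedy cutoff clustering on a normalized USR score matrix (gmx-cluster
  style): the structure with the most neighbors within the cutoff becomes
  a cluster center, it and its neighbors are removed, repeat.

All tie-breaks resolve to the lowest index / smallest k so results are
deterministic given a seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .featurize import USRScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "KneeCurve",
    "scatter_loss",
    "sse",
    "find_knee",
    "kmeans_cluster",
    "gmm_cluster",
    "hierarchical_cluster",
    "davies_bouldin",
    "gmx_cluster_usr",
]


@dataclass
class KneeCurve:
    """A model-selection curve: criterion values over increasing k."""

    k_values: np.ndarray
    criterion: np.ndarray

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.criterion = np.asarray(self.criterion, dtype=float)
        if self.k_values.shape != self.criterion.shape:
            raise ValueError("k_values and criterion must have equal length")
        if len(self.k_values) and (np.diff(self.k_values) <= 0).any():
            raise ValueError("k_values must be strictly increasing")


@dataclass
class ClusterResult:
    """Labels plus the model-selection diagnostics that justified them.

    ``labels`` are 0-based and contiguous; ``k`` equals the number of
    distinct labels; ``diagnostics`` holds the (k, criterion) curve (SSE,
    BIC or DB) or, for the greedy cutoff method, per-round neighbor counts.
    """

    method: str
    labels: np.ndarray
    k: int
    diagnostics: KneeCurve | dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("labels must be 0-based and contiguous")
        if self.k != len(uniq):
            raise ValueError(f"k={self.k} does not match {len(uniq)} distinct labels")

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary labels to 0-based contiguous ones (order of first use)."""
    uniq, inv = np.unique(labels, return_inverse=True)
    return inv, len(uniq)


def scatter_loss(features: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster scatter L(C): half the sum, over clusters, of all
    ordered intra-cluster pairwise Euclidean distances — i.e. each unordered
    pair counted once."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        if len(members) > 1:
            total += pdist(members).sum()
    return float(total)


def sse(features: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Sum over structures of squared Euclidean distance to the centroid of
    their own cluster."""
    X = np.asarray(features, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    diffs = X - centroids[np.asarray(labels, dtype=int)]
    return float(np.einsum("ij,ij->", diffs, diffs))


def find_knee(curve: KneeCurve) -> int:
    """Locate the knee/elbow of a decreasing criterion curve.

    Returns the k maximizing the perpendicular distance to the chord
    joining the curve's endpoints, considering interior points only
    (endpoints are at distance zero by construction). Ties go to the
    smallest k. Warns if the criterion is not non-increasing overall or if
    the curve is effectively straight.
    """
    k = curve.k_values.astype(float)
    y = curve.criterion
    if len(k) < 3:
        raise ValueError("knee detection needs at least 3 points")
    if y[-1] > y[0]:
        logger.warning("criterion increases overall; knee may be meaningless")
    chord = np.array([k[-1] - k[0], y[-1] - y[0]])
    norm = np.linalg.norm(chord)
    if norm == 0:
        dist = np.zeros_like(y)
    else:
        # 2-D cross product gives signed area = distance * |chord|
        rel = np.stack([k - k[0], y - y[0]], axis=1)
        dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    interior = dist[1:-1]
    if interior.max() <= 1e-12:
        logger.warning("criterion curve is straight; returning smallest interior k")
        return int(curve.k_values[1])
    return int(curve.k_values[1 + int(np.argmax(interior))])


def _check_k_range(k_range: tuple[int, int], n: int) -> range:
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if k_min > k_max:
        raise ValueError(f"empty k range [{k_min}, {k_max}]")
    if k_min < 2 or k_max > n - 1:
        raise ValueError(f"k range [{k_min}, {k_max}] outside [2, {n - 1}]")
    return range(k_min, k_max + 1)


def kmeans_cluster(
    features: np.ndarray,
    k_range: tuple[int, int] | None = None,
    restarts: int = 10,
    seed: int | None = None,
) -> ClusterResult:
    """k-means over a range of k with scatter-loss restart selection.

    For each k, ``restarts`` runs are initialized at k distinct data points
    drawn uniformly at random; the run minimizing the within-cluster
    scatter loss is kept and its SSE recorded. The final k is chosen at the
    knee of the SSE curve (with the k=1 SSE about the global centroid
    prepended so a knee at k=2 is detectable).
    """
    X = np.asarray(features, dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError("k-means model selection needs at least 3 structures")
    if k_range is None:
        k_range = (2, min(50, n - 1))
    ks = _check_k_range(k_range, n)
    rng = np.random.default_rng(seed)

    sse_curve = [float(((X - X.mean(axis=0)) ** 2).sum())]  # k = 1
    winners: dict[int, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in ks:
            best_loss = np.inf
            best_labels = None
            for _ in range(restarts):
                init_idx = rng.choice(n, size=k, replace=False)
                km = KMeans(n_clusters=k, init=X[init_idx], n_init=1, max_iter=300)
                labels = km.fit_predict(X)
                loss = scatter_loss(X, labels)
                if loss < best_loss:
                    best_loss = loss
                    best_labels = labels
            labels, k_eff = _relabel(best_labels)
            centroids = np.array([X[labels == c].mean(axis=0) for c in range(k_eff)])
            sse_curve.append(sse(X, labels, centroids))
            winners[k] = labels

    curve = KneeCurve(np.array([1] + list(ks)), np.array(sse_curve))
    if len(ks) == 1:
        chosen = ks.start  # no selection needed for a single candidate
    else:
        chosen = max(find_knee(curve), ks.start)  # k=1 is diagnostic only
    labels, k_eff = _relabel(winners[chosen])
    return ClusterResult(
        method="kmeans", labels=labels, k=k_eff, diagnostics=curve, seed=seed
    )


def gmm_cluster(
    features: np.ndarray,
    k_range: tuple[int, int] | None = None,
    covariance: str = "full",
    seed: int | None = None,
    bic_mode: str = "standard",
) -> ClusterResult:
    """Gaussian-mixture clustering with the component count chosen by BIC.

    ``bic_mode='standard'`` penalizes the number of free mixture parameters
    (means, covariances, weights). ``bic_mode='literal'`` uses
    ln(n)*k - 2 ln(L-hat) with k the bare component count. Ties and the
    argmin both resolve to the smallest k. Labels are the most probable
    component per structure.
    """
    X = np.asarray(features, dtype=float)
    n = len(X)
    if k_range is None:
        k_range = (2, min(50, n - 1))
    ks = _check_k_range(k_range, n)
    if bic_mode not in ("standard", "literal"):
        raise ValueError(f"unknown bic_mode {bic_mode!r}")

    bics = []
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in ks:
            gm = GaussianMixture(
                n_components=k,
                covariance_type=covariance,
                reg_covar=1e-6,
                random_state=seed,
            )
            try:
                gm.fit(X)
            except Exception as exc:  # noqa: BLE001 - surface EM failures with k
                raise RuntimeError(f"GMM fit failed at k={k}: {exc}") from exc
            if bic_mode == "standard":
                bics.append(float(gm.bic(X)))
            else:
                bics.append(float(np.log(n) * k - 2.0 * gm.score(X) * n))
            fits[k] = gm

    curve = KneeCurve(np.array(list(ks)), np.array(bics))
    chosen = int(curve.k_values[int(np.argmin(curve.criterion))])
    labels, k_eff = _relabel(fits[chosen].predict(X))
    return ClusterResult(
        method="gmm", labels=labels, k=k_eff, diagnostics=curve, seed=seed
    )


def davies_bouldin(features: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case
    (sigma_i + sigma_j) / d(c_i, c_j) ratio, with c the cluster centroid
    and sigma the mean member-to-centroid distance. Lower is better;
    singletons contribute sigma = 0."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.array([X[labels == lab].mean(axis=0) for lab in uniq])
    sigmas = np.array(
        [
            np.linalg.norm(X[labels == lab] - c, axis=1).mean()
            for lab, c in zip(uniq, centroids)
        ]
    )
    sep = cdist(centroids, centroids)
    np.fill_diagonal(sep, np.inf)
    if (sep == 0).any():
        raise ValueError(
            "distinct clusters share identical centroids; Davies-Bouldin is "
            "undefined — merge the clusters or perturb the features"
        )
    ratios = (sigmas[:, None] + sigmas[None, :]) / sep
    return float(np.max(ratios, axis=1).mean())


def hierarchical_cluster(
    features: np.ndarray, candidate_ks: list[int] | None = None
) -> ClusterResult:
    """Single-linkage agglomerative clustering cut at the Davies-Bouldin
    optimum.

    The dendrogram is built once; each candidate k cuts it into k clusters
    and the cut with the smallest DB index wins (ties -> smallest k).
    Candidates whose cut degenerates (fewer than 2 distinct clusters, or an
    undefined DB) are skipped with a warning.
    """
    X = np.asarray(features, dtype=float)
    n = len(X)
    if candidate_ks is None:
        candidate_ks = list(range(2, min(100, n - 1) + 1))
    if not candidate_ks:
        raise ValueError("empty candidate k list")
    bad = [k for k in candidate_ks if not 2 <= k <= n - 1]
    if bad:
        raise ValueError(f"candidate ks outside [2, {n - 1}]: {bad}")

    Z = linkage(X, method="single")
    ks, dbs, cuts = [], [], {}
    for k in sorted(candidate_ks):
        labels, k_eff = _relabel(fcluster(Z, t=k, criterion="maxclust"))
        if k_eff < 2:
            logger.warning("cut at k=%d produced %d cluster(s); skipped", k, k_eff)
            continue
        try:
            db = davies_bouldin(X, labels)
        except ValueError:
            logger.warning("Davies-Bouldin undefined at k=%d; skipped", k)
            continue
        ks.append(k)
        dbs.append(db)
        cuts[k] = (labels, k_eff)
    if not ks:
        raise ValueError("no candidate cut produced a valid partition")

    curve = KneeCurve(np.array(ks), np.array(dbs))
    chosen = ks[int(np.argmin(dbs))]
    labels, k_eff = cuts[chosen]
    return ClusterResult(
        method="hierarchical", labels=labels, k=k_eff, diagnostics=curve, seed=None
    )


def gmx_cluster_usr(
    score_matrix: USRScoreMatrix, cutoff: float = 0.1
) -> ClusterResult:
    """Greedy cutoff clustering on a normalized USR score matrix.

    Repeatedly, among the remaining structures, the one with the largest
    number of neighbors (others within ``cutoff``, self excluded) becomes a
    cluster center; it and its neighbors form a cluster and are removed.
    Ties go to the lowest index. Deterministic and seed-free.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    S = score_matrix.scores
    n = len(score_matrix)
    labels = np.full(n, -1, dtype=int)
    remaining = np.ones(n, dtype=bool)
    adjacency = S <= cutoff
    np.fill_diagonal(adjacency, False)
    rounds = []
    cluster = 0
    while remaining.any():
        counts = (adjacency & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes lowest index on ties
        members = remaining & adjacency[center]
        members[center] = True
        labels[members] = cluster
        remaining &= ~members
        rounds.append(int(counts[center]))
        cluster += 1
    return ClusterResult(
        method="gmx_usr",
        labels=labels,
        k=cluster,
        diagnostics={"neighbor_counts": rounds, "cutoff": cutoff},
        seed=None,
    )
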