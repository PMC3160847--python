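"""Two-level hybrid clustering of TSSDs.

Level 1 is agglomerative (Ward linkage) clustering on the GM-distance
matrix, cut into ``k1`` fine clusters.  Level 2 aggregates those clusters
by their intra-cluster mean peakedness with an exact 1-D k-means into
``k2`` shape tiers; for ``k2 = 3`` the tiers are named, in descending mean
peakedness, ultra-dense, dense and scattered.

The Ward agglomeration is implemented directly via the Lance-Williams
update so that both dialects are available:

* ``classic``  — the update applied to the dissimilarities as given
  (the behaviour of R ``hclust(..., "ward.D")``);
* ``squared``  — the update applied to squared dissimilarities with
  square-root merge heights (R ``ward.D2`` / scipy ``linkage 'ward'``).

Merge ties are broken toward the smallest leaf index, making the tree
deterministic for any input.

The k-medoids (PAM-style) and 1-D k-means steps are exposed as
scikit-learn estimators (``KMedoids``, ``KMeans1D``) and the end-to-end
pipeline as ``TSSDShapeClassifier``; the module-level functions are thin
wrappers over these.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_random_state

from .core import TSSD
from .io import laplace_smooth, normalize
from .metric import DissimilarityMatrix, pairwise_matrix
from .shape import intra_cluster_peakedness

__all__ = [
    "Dendrogram",
    "Partition",
    "ShapeClasses",
    "hierarchical_ward",
    "cut_dendrogram",
    "KMedoids",
    "kmedoids_partition",
    "explained_variance",
    "KMeans1D",
    "kmeans_1d",
    "TSSDShapeClassifier",
    "two_level_classify",
]

logger = logging.getLogger(__name__)

#: class names for k2 = 3, ordered by descending mean peakedness
ShapeClasses = ("ultra-dense", "dense", "scattered")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over ``n_leaves`` items.

    ``merges`` has one row per internal node, in merge order:
    ``(child_a, child_b, height, size)`` with children indexed scipy-style
    (leaves ``0..n-1``, internal node of merge ``t`` is ``n + t``).
    """

    n_leaves: int
    merges: np.ndarray
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=np.float64)
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError(
                f"expected {self.n_leaves - 1} merges, got shape {self.merges.shape}"
            )

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix consumable by :mod:`scipy.cluster.hierarchy`."""
        return self.merges.copy()

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class Partition:
    """Cluster assignment: labels 1..k over an ordered id list."""

    ids: tuple[str, ...]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.ids),):
            raise ValueError("one label per id required")
        present = np.unique(self.labels)
        if present.size != self.k or present.min() < 1 or present.max() > self.k:
            raise ValueError(
                f"labels must cover 1..{self.k} with no empty cluster, got {present}"
            )

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def members(self, cluster: int) -> list[str]:
        return [self.ids[i] for i in np.flatnonzero(self.labels == cluster)]

    def as_dict(self) -> dict[str, int]:
        return {id_: int(lab) for id_, lab in zip(self.ids, self.labels)}


def _check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"need a square matrix, got shape {d.shape}")
    if (d < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    return d


def hierarchical_ward(
    d: DissimilarityMatrix | np.ndarray, dialect: str = "classic"
) -> Dendrogram:
    """Ward-linkage agglomeration of a precomputed dissimilarity matrix.

    ``classic`` applies the Lance-Williams Ward update to the
    dissimilarities as supplied; ``squared`` applies it to their squares
    and reports square-root heights.  Ties are broken toward the smallest
    leaf index, so the tree is deterministic.
    """
    if dialect not in ("classic", "squared"):
        raise ValueError(f"unknown Ward dialect {dialect!r}")
    ids = d.ids if isinstance(d, DissimilarityMatrix) else None
    mat = _check_square(d.d if isinstance(d, DissimilarityMatrix) else d)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")

    work = mat.copy() if dialect == "classic" else mat**2
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=np.int64)
    node_id = np.arange(n)
    merges = np.zeros((n - 1, 4), dtype=np.float64)

    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], work, np.inf)
        # row-major argmin: position index equals the cluster's smallest
        # original leaf, so ties resolve toward the smallest leaf index
        flat = int(np.argmin(masked))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        height = work[i, j]
        if dialect == "squared":
            height = float(np.sqrt(height))
        merges[step] = (node_id[i], node_id[j], height, sizes[i] + sizes[j])

        si, sj = sizes[i], sizes[j]
        sk = sizes
        new_row = ((si + sk) * work[i, :] + (sj + sk) * work[j, :] - sk * work[i, j]) / (
            si + sj + sk
        )
        work[i, :] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        active[j] = False
        sizes[i] = si + sj
        node_id[i] = n + step

    return Dendrogram(n_leaves=n, merges=merges, ids=ids)


def cut_dendrogram(t: Dendrogram, k: int) -> Partition:
    """Cut into ``k`` groups by discarding the ``k - 1`` last (highest) merges.

    Labels are assigned 1..k in order of each cluster's first-occurring leaf.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = t.merges[step]
        node = n + step
        parent[find(int(a))] = node
        parent[find(int(b))] = node

    roots = [find(i) for i in range(n)]
    label_of_root: dict[int, int] = {}
    labels = np.zeros(n, dtype=np.int64)
    for leaf, root in enumerate(roots):
        if root not in label_of_root:
            label_of_root[root] = len(label_of_root) + 1
        labels[leaf] = label_of_root[root]
    ids = t.ids if t.ids is not None else tuple(str(i) for i in range(n))
    return Partition(ids=ids, labels=labels, k=k)


class KMedoids(BaseEstimator, ClusterMixin):
    """PAM-style k-medoids on a precomputed dissimilarity matrix.

    Alternates assignment to the nearest medoid with medoid updates (each
    medoid becomes the member minimising the within-cluster distance sum)
    from seeded random initial medoids until assignments stop changing.
    The objective (sum of distances to own medoid) is non-increasing.

    Attributes
    ----------
    labels_ : ndarray
        Cluster index (0-based) per item.
    medoid_indices_ : ndarray
    inertia_ : float
    """

    def __init__(self, n_clusters: int = 3, max_iter: int = 300, random_state=None):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        d = _check_square(X.d if isinstance(X, DissimilarityMatrix) else X)
        n = d.shape[0]
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters must be in [1, {n}], got {k}")
        rng = check_random_state(self.random_state)
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        labels = np.argmin(d[:, medoids], axis=1)
        for _ in range(self.max_iter):
            # medoid update
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if members.size == 0:  # re-seed an emptied cluster
                    far = int(np.argmax(d[np.arange(n), medoids[labels]]))
                    new_medoids[c] = far
                    continue
                within = d[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[int(np.argmin(within))]
            new_labels = np.argmin(d[:, new_medoids], axis=1)
            if np.array_equal(new_labels, labels) and np.array_equal(
                new_medoids, medoids
            ):
                break
            medoids, labels = new_medoids, new_labels
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = float(d[np.arange(n), medoids[labels]].sum())
        return self


def kmedoids_partition(
    d: DissimilarityMatrix, k: int, seed: int | None = 0
) -> Partition:
    """k-medoids clustering of a GM-distance matrix (wraps :class:`KMedoids`)."""
    est = KMedoids(n_clusters=k, random_state=seed).fit(d)
    # relabel 1..k in order of first occurrence for a canonical Partition
    remap: dict[int, int] = {}
    labels = np.zeros(len(d), dtype=np.int64)
    for i, lab in enumerate(est.labels_):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    return Partition(ids=d.ids, labels=labels, k=k)


def explained_variance(d: DissimilarityMatrix | np.ndarray, p: Partition) -> float:
    """Fraction of squared-dissimilarity dispersion explained by a partition.

    EV = 1 - (sum_k W_k) / T, with W_k the within-cluster dispersion
    (1/n_k) * sum_{i<j in k} d_ij^2 and T the total (1/n) * sum_{i<j} d_ij^2.
    This is the standard decomposition for non-Euclidean dissimilarity data;
    EV is 0 for the one-cluster partition and 1 for all-singletons.
    """
    mat = _check_square(d.d if isinstance(d, DissimilarityMatrix) else d)
    n = mat.shape[0]
    if len(p.ids) != n:
        raise ValueError("partition and matrix sizes differ")
    sq = mat**2
    iu = np.triu_indices(n, k=1)
    total = sq[iu].sum() / n
    if total == 0:
        return 0.0
    within = 0.0
    for c in range(1, p.k + 1):
        idx = np.flatnonzero(p.labels == c)
        if idx.size < 2:
            continue
        sub = sq[np.ix_(idx, idx)]
        within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return float(1.0 - within / total)


class KMeans1D(BaseEstimator, ClusterMixin):
    """Globally optimal 1-D k-means by dynamic programming over sorted values.

    The 1-D optimum is attained on contiguous blocks of the sorted input,
    so an O(k n^2) DP finds it exactly — no seeding, no local minima.  If
    fewer distinct values than ``n_clusters`` exist, k is clamped with a
    warning.

    Attributes
    ----------
    labels_ : ndarray of cluster indices 0..k-1, ordered by cluster mean.
    cluster_centers_ : ndarray of the k cluster means, ascending.
    inertia_ : float, within-cluster sum of squares.
    n_clusters_ : effective k after clamping.
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=np.float64).ravel()
        if x.size == 0:
            raise ValueError("empty input")
        n = x.size
        k = self.n_clusters
        n_distinct = np.unique(x).size
        if k > n_distinct:
            warnings.warn(
                f"n_clusters={k} exceeds {n_distinct} distinct values; clamping",
                stacklevel=2,
            )
            k = n_distinct
        if k < 1:
            raise ValueError("n_clusters must be >= 1")

        order = np.argsort(x, kind="stable")
        xs = x[order]
        csum = np.concatenate([[0.0], np.cumsum(xs)])
        csq = np.concatenate([[0.0], np.cumsum(xs**2)])

        def block_cost(i: np.ndarray, j: int) -> np.ndarray:
            # SSE of xs[i:j] for a vector of starts i (inclusive, exclusive j)
            cnt = j - i
            s = csum[j] - csum[i]
            return (csq[j] - csq[i]) - s**2 / cnt

        # dp[m, j] = optimal SSE of splitting xs[:j] into m blocks
        dp = np.full((k + 1, n + 1), np.inf)
        dp[0, 0] = 0.0
        back = np.zeros((k + 1, n + 1), dtype=np.int64)
        for m in range(1, k + 1):
            for j in range(m, n + 1):
                starts = np.arange(m - 1, j)
                cand = dp[m - 1, starts] + block_cost(starts, j)
                best = int(np.argmin(cand))
                dp[m, j] = cand[best]
                back[m, j] = starts[best]

        # recover block boundaries
        bounds = [n]
        j = n
        for m in range(k, 0, -1):
            j = int(back[m, j])
            bounds.append(j)
        bounds.reverse()  # 0 = bounds[0] < ... < bounds[k] = n

        labels_sorted = np.zeros(n, dtype=np.int64)
        centers = np.zeros(k, dtype=np.float64)
        for c in range(k):
            lo, hi = bounds[c], bounds[c + 1]
            labels_sorted[lo:hi] = c
            centers[c] = xs[lo:hi].mean()
        labels = np.zeros(n, dtype=np.int64)
        labels[order] = labels_sorted

        self.labels_ = labels
        self.cluster_centers_ = centers
        self.inertia_ = float(dp[k, n])
        self.n_clusters_ = k
        return self


def kmeans_1d(scores: Sequence[float], k: int) -> tuple[Partition, np.ndarray]:
    """Exact 1-D k-means; returns a Partition (labels 1..k by ascending mean)
    and the cluster means."""
    est = KMeans1D(n_clusters=k).fit(np.asarray(scores, dtype=np.float64))
    ids = tuple(str(i) for i in range(len(est.labels_)))
    return (
        Partition(ids=ids, labels=est.labels_ + 1, k=est.n_clusters_),
        est.cluster_centers_,
    )


class TSSDShapeClassifier(BaseEstimator):
    """End-to-end two-level shape classification of TSSDs.

    Pipeline: Laplace-smooth -> normalise -> all-pairs GM-distance ->
    Ward dendrogram -> cut at ``k1`` -> intra-cluster mean peakedness ->
    exact 1-D k-means into ``k2`` tiers -> tiers named by descending mean
    peakedness (ultra-dense, dense, scattered for ``k2 = 3``; numeric
    ``tier1..tierK`` otherwise).  Every TSSD inherits its level-1
    cluster's tier.

    Parameters
    ----------
    k1 : int
        Number of fine (level-1) clusters; clamped to n with a warning.
    k2 : int
        Number of shape tiers.
    dialect : {"classic", "squared"}
        Ward dialect, see :func:`hierarchical_ward`.
    alpha, beta : float
        Peakedness exponents.
    smooth : bool
        Apply Laplace smoothing before normalisation (peakedness is always
        computed on the raw counts).
    report_ev : bool
        Also compute an explained-variance table over k2 candidates
        (1..max(10, k2)) for model selection.

    Attributes
    ----------
    labels_ : ndarray of class-name strings, one per input TSSD.
    level1_, level2_ : Partition
    distance_matrix_ : DissimilarityMatrix
    dendrogram_ : Dendrogram
    intra_peakedness_ : ndarray, mean peakedness per level-1 cluster.
    tier_names_ : tuple of class names indexed by level-2 label - 1.
    ev_table_ : list of (k2, EV) pairs (only when ``report_ev``).
    """

    def __init__(
        self,
        k1: int = 500,
        k2: int = 3,
        dialect: str = "classic",
        alpha: float = 1.0,
        beta: float = 1.0,
        smooth: bool = True,
        report_ev: bool = False,
    ):
        self.k1 = k1
        self.k2 = k2
        self.dialect = dialect
        self.alpha = alpha
        self.beta = beta
        self.smooth = smooth
        self.report_ev = report_ev

    def fit(self, X: Sequence[TSSD], y=None):
        tssds = list(X)
        n = len(tssds)
        if self.k2 < 1:
            raise ValueError(f"k2 must be >= 1, got {self.k2}")
        if n < self.k2:
            raise ValueError(f"need at least k2={self.k2} TSSDs, got {n}")
        k1 = self.k1
        if k1 > n:
            logger.warning("k1=%d exceeds n=%d; clamping to n", k1, n)
            k1 = n
        if k1 < 1:
            raise ValueError(f"k1 must be >= 1, got {self.k1}")

        prepared = [laplace_smooth(t) if self.smooth else t for t in tssds]
        normed = [normalize(t) for t in prepared]
        self.distance_matrix_ = pairwise_matrix(normed)

        if n == 1:
            level1 = Partition(ids=(tssds[0].id,), labels=np.array([1]), k=1)
            self.dendrogram_ = None
        else:
            self.dendrogram_ = hierarchical_ward(self.distance_matrix_, self.dialect)
            level1 = cut_dendrogram(self.dendrogram_, k1)
        self.level1_ = level1

        by_id = {t.id: t for t in tssds}
        scores = np.array(
            [
                intra_cluster_peakedness(
                    [by_id[i] for i in level1.members(c)], self.alpha, self.beta
                )
                for c in range(1, level1.k + 1)
            ]
        )
        self.intra_peakedness_ = scores

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate inputs clamp k2 silently here
            km = KMeans1D(n_clusters=min(self.k2, level1.k)).fit(scores)
        k2_eff = km.n_clusters_
        if k2_eff < min(self.k2, level1.k):
            logger.warning(
                "only %d distinct peakedness tiers; k2=%d clamped", k2_eff, self.k2
            )
        # tier index 0 = highest mean peakedness
        rank_desc = np.argsort(-km.cluster_centers_, kind="stable")
        tier_of_kmlabel = {int(lab): int(r) for r, lab in enumerate(rank_desc)}
        if self.k2 == 3:
            # named classes, assigned from the top: a degenerate single
            # group of deltas is ultra-dense, not an anonymous tier
            tier_names = ShapeClasses[:k2_eff]
        else:
            tier_names = tuple(f"tier{t + 1}" for t in range(k2_eff))
        self.tier_names_ = tier_names

        cluster_tier = np.array(
            [tier_of_kmlabel[int(lab)] for lab in km.labels_], dtype=np.int64
        )
        labels = np.array(
            [tier_names[cluster_tier[level1.labels[i] - 1]] for i in range(n)],
            dtype=object,
        )
        self.labels_ = labels
        self.level2_ = Partition(
            ids=tuple(t.id for t in tssds),
            labels=np.array(
                [cluster_tier[level1.labels[i] - 1] + 1 for i in range(n)]
            ),
            k=k2_eff,
        )
        if self.report_ev:
            self.ev_table_ = self._ev_table(scores)
        return self

    def _ev_table(self, scores: np.ndarray) -> list[tuple[int, float]]:
        """Explained variance of the 1-D level-2 model as a function of k2."""
        n_distinct = np.unique(scores).size
        total = float(((scores - scores.mean()) ** 2).sum())
        table: list[tuple[int, float]] = []
        for k in range(1, min(max(10, self.k2), n_distinct) + 1):
            km = KMeans1D(n_clusters=k).fit(scores)
            ev = 1.0 - km.inertia_ / total if total > 0 else 1.0
            table.append((k, float(ev)))
        return table

    def fit_predict(self, X: Sequence[TSSD], y=None) -> np.ndarray:
        return self.fit(X).labels_


def two_level_classify(
    tssds: Sequence[TSSD],
    k1: int = 500,
    k2: int = 3,
    dialect: str = "classic",
    alpha: float = 1.0,
    beta: float = 1.0,
    report_ev: bool = False,
) -> tuple[dict[str, str], TSSDShapeClassifier]:
    """Classify TSSDs into shape classes (wraps :class:`TSSDShapeClassifier`).

    Returns the id -> class-name mapping and the fitted classifier (which
    exposes both partitions, the distance matrix and the dendrogram).
    """
    est = TSSDShapeClassifier(
        k1=k1, k2=k2, dialect=dialect, alpha=alpha, beta=beta, report_ev=report_ev
    ).fit(tssds)
    return {t.id: lab for t, lab in zip(tssds, est.labels_)}, est
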