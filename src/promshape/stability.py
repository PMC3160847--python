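"""Bootstrap assessment of cluster stability via mean Jaccard coefficients.

The data are resampled with replacement B times; each pseudo data set is
clustered with the same procedure as the original, each original cluster
is matched to its most similar pseudo cluster by the Jaccard coefficient,
and the per-cluster stability is the mean best-match Jaccard over the B
replicates.  The overall stability S of a clustering is the cluster-size
weighted mean of the per-cluster values.

Jaccard coefficients are computed over sets of distinct original
identities (bootstrap multiplicity is ignored): an item absent from a
resample simply cannot contribute to the intersection.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Set
from dataclasses import dataclass

import numpy as np

from .cluster import Partition, cut_dendrogram, hierarchical_ward, kmedoids_partition
from .metric import DissimilarityMatrix

__all__ = ["StabilityReport", "jaccard", "bootstrap_stability"]

logger = logging.getLogger(__name__)


def jaccard(a: Set, b: Set) -> float:
    """|a ∩ b| / |a ∪ b|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class StabilityReport:
    """Per-cluster mean Jaccard stabilities and the overall weighted S."""

    cluster_jaccard: np.ndarray  # J̄_k, one entry per original cluster
    cluster_sizes: np.ndarray  # n_k
    B: int
    seed: int | None

    def __post_init__(self) -> None:
        self.cluster_jaccard = np.asarray(self.cluster_jaccard, dtype=np.float64)
        self.cluster_sizes = np.asarray(self.cluster_sizes, dtype=np.int64)
        if ((self.cluster_jaccard < 0) | (self.cluster_jaccard > 1)).any():
            raise ValueError("mean Jaccard values must lie in [0, 1]")

    @property
    def overall(self) -> float:
        """S: the size-weighted mean of the per-cluster mean Jaccards."""
        return float(
            (self.cluster_sizes * self.cluster_jaccard).sum() / self.cluster_sizes.sum()
        )

    def as_dict(self) -> dict:
        return {
            "overall_S": self.overall,
            "B": self.B,
            "seed": self.seed,
            "clusters": [
                {"cluster": i + 1, "size": int(s), "mean_jaccard": float(j)}
                for i, (s, j) in enumerate(
                    zip(self.cluster_sizes, self.cluster_jaccard)
                )
            ],
        }


def _cluster_matrix(
    d: DissimilarityMatrix, clusterer: str, k: int, dialect: str, seed
) -> Partition:
    if clusterer == "ward":
        if len(d) == 1:
            return Partition(ids=d.ids, labels=np.array([1]), k=1)
        return cut_dendrogram(hierarchical_ward(d, dialect), k)
    if clusterer == "kmedoids":
        return kmedoids_partition(d, k, seed=seed)
    raise ValueError(f"unknown clusterer {clusterer!r}")


def _best_match(original: set, pseudo_clusters: list[set]) -> float:
    """Jaccard of the most similar pseudo cluster.

    Ties go to the larger pseudo cluster, then the lowest index, so the
    result is deterministic; the tie-break does not change the value.
    """
    best = (-1.0, 0, 0)
    best_j = 0.0
    for idx, pc in enumerate(pseudo_clusters):
        j = jaccard(original, pc)
        key = (j, len(pc), -idx)
        if key > best:
            best = key
            best_j = j
    return best_j


def bootstrap_stability(
    d: DissimilarityMatrix,
    clusterer: str = "ward",
    k: int = 3,
    B: int = 100,
    seed: int | None = 0,
    dialect: str = "classic",
    reference: Partition | None = None,
    resample: Callable[[int, np.random.Generator], np.ndarray] | None = None,
) -> StabilityReport:
    """Bootstrap-Jaccard stability of clustering the items of ``d`` into ``k``.

    Parameters
    ----------
    d : DissimilarityMatrix
        Precomputed GM-distance matrix over the original items; pseudo data
        sets reuse its entries, so no distances are recomputed.
    clusterer : {"ward", "kmedoids"}
    reference : Partition, optional
        Original clustering to assess; computed from ``d`` when omitted.
    resample : callable, optional
        Test hook ``(b, rng) -> index array`` replacing the bootstrap draw
        (e.g. the identity for a self-check).
    seed : int
        Replicate ``b`` uses a generator seeded ``seed + b``, so any subset
        of replicates is independently reproducible.

    A replicate whose resample holds fewer than ``k`` distinct items is
    re-drawn (and logged).
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    n = len(d)
    if reference is None:
        reference = _cluster_matrix(d, clusterer, k, dialect, seed)
    if len(reference.ids) != n:
        raise ValueError("reference partition does not match the matrix")
    k = reference.k
    original_sets = [set(reference.members(c)) for c in range(1, k + 1)]

    sums = np.zeros(k, dtype=np.float64)
    for b in range(B):
        rng = np.random.default_rng(None if seed is None else seed + b)
        while True:
            idx = (
                resample(b, rng) if resample is not None else rng.integers(0, n, size=n)
            )
            distinct = np.unique(idx)
            if distinct.size >= k:
                break
            logger.info(
                "replicate %d drew %d < k=%d distinct items; re-drawing",
                b,
                distinct.size,
                k,
            )
        sub_ids = [d.ids[i] for i in distinct]
        sub = d.subset(sub_ids)
        pseudo = _cluster_matrix(
            sub, clusterer, k, dialect, None if seed is None else seed + b
        )
        pseudo_sets = [set(pseudo.members(c)) for c in range(1, pseudo.k + 1)]
        present = set(sub_ids)
        # compare within the resample universe: the original cluster is
        # restricted to the items the replicate actually drew, so a
        # perfectly reproduced cluster scores J = 1
        for ki, orig in enumerate(original_sets):
            sums[ki] += _best_match(orig & present, pseudo_sets)

    return StabilityReport(
        cluster_jaccard=sums / B,
        cluster_sizes=reference.sizes,
        B=B,
        seed=seed,
    )
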