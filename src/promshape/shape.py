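"""Shape statistics for TSSDs: peakedness, dominant peak, peak calling and
tissue specificity.

Peakedness summarises how concentrated a distribution is:

    P = (m / n)^alpha / w^beta

with m the tag count at the dominant peak (the mode), n the total tag
count and w the width in nucleotides.  With the default exponents
(alpha = beta = 1) P lies in (0, 1] and attains 1 exactly when every tag
maps to a single nucleotide.  The statistic captures similar features as
kurtosis but is cheaper and parameter-free.

Tissue specificity is the relative entropy (Kullback-Leibler divergence,
in bits) between a TSSD's tissue distribution and the tissue distribution
of all tags; 0 means the promoter's expression mirrors the background.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr

from .core import TSSD, NormalizedTSSD
from .metric import DissimilarityMatrix

__all__ = [
    "PeakCall",
    "TissueDistribution",
    "tssd_width",
    "dominant_peak",
    "peakedness",
    "intra_cluster_peakedness",
    "intra_cluster_dissimilarity",
    "call_peaks",
    "kl_tissue_specificity",
    "tissue_distribution",
]


def _counts(t) -> np.ndarray:
    if isinstance(t, TSSD):
        return t.counts
    if isinstance(t, NormalizedTSSD):
        return t.probs
    return np.asarray(t)


def tssd_width(t: TSSD) -> int:
    """Width in nt: the inclusive span between the outermost covered bases."""
    return int(_counts(t).size)


def dominant_peak(t) -> int:
    """Offset of the mode, ties broken toward the 5'-most position."""
    return int(np.argmax(_counts(t)))


def peakedness(t, alpha: float = 1.0, beta: float = 1.0) -> float:
    """Peakedness P = (m/n)^alpha / w^beta of a TSSD."""
    counts = _counts(t)
    n = float(counts.sum())
    if n <= 0:
        raise ValueError("peakedness requires at least one tag")
    m = float(counts.max())
    w = counts.size
    return (m / n) ** alpha / w**beta


def intra_cluster_peakedness(
    members: Sequence, alpha: float = 1.0, beta: float = 1.0
) -> float:
    """Mean peakedness across the TSSDs of one cluster."""
    if len(members) == 0:
        raise ValueError("cluster has no members")
    return float(np.mean([peakedness(t, alpha, beta) for t in members]))


def intra_cluster_dissimilarity(
    member_ids: Sequence[str], d: DissimilarityMatrix
) -> float:
    """Mean pairwise GM-distance within a cluster (0 for singletons)."""
    if len(member_ids) == 0:
        raise ValueError("cluster has no members")
    if len(member_ids) == 1:
        return 0.0
    sub = d.subset(member_ids).d
    iu = np.triu_indices(len(member_ids), k=1)
    return float(sub[iu].mean())


@dataclass
class PeakCall:
    """Result of peak identification within one TSSD.

    ``peaks`` holds 0-based offsets (5'->3') of accepted peaks, in
    ascending order; ``uniform`` is set when no position reaches the
    intensity threshold.
    """

    peaks: list[int]
    uniform: bool
    span: int
    intensity: float

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def call_peaks(t, span: int = 20, intensity: float = 0.05) -> PeakCall:
    """Identify peaks in a TSSD histogram.

    A candidate is any position carrying at least ``intensity`` of the
    total tag mass.  Candidates are visited in order of decreasing mass
    (ties 5'-first) and accepted unless an already-accepted peak lies
    within ``span/2`` nt — i.e. two candidates closer than half a peak
    width count as one peak.  A TSSD with no candidate is "uniform".
    """
    if span <= 0:
        raise ValueError(f"span must be positive, got {span}")
    if not 0 < intensity < 1:
        raise ValueError(f"intensity must be in (0, 1), got {intensity}")
    counts = _counts(t).astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot call peaks on an empty histogram")
    probs = counts / total
    # ">= intensity" with a guard against float round-off at the threshold
    candidates = np.flatnonzero(probs >= intensity - 1e-12)
    if candidates.size == 0:
        return PeakCall(peaks=[], uniform=True, span=span, intensity=intensity)
    order = sorted(candidates, key=lambda i: (-probs[i], i))
    half = span / 2.0
    accepted: list[int] = []
    for cand in order:
        if all(abs(cand - p) > half for p in accepted):
            accepted.append(int(cand))
    accepted.sort()
    return PeakCall(peaks=accepted, uniform=False, span=span, intensity=intensity)


@dataclass
class TissueDistribution:
    """Tissue fractions of one TSSD (p) against the all-tag background (q)."""

    p: dict[str, float]
    q: dict[str, float]

    def __post_init__(self) -> None:
        for name, dist in (("p", self.p), ("q", self.q)):
            if not dist:
                raise ValueError(f"{name} is empty")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total!r}")
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"{name} has negative entries")
        missing = [t for t, v in self.p.items() if v > 0 and self.q.get(t, 0.0) <= 0]
        if missing:
            raise ValueError(
                f"tissues {missing} carry mass in p but none in the background q"
            )


def kl_tissue_specificity(td: TissueDistribution) -> float:
    """Relative entropy D(p || q) in bits; 0 iff p equals q.

    High values flag tissue-restricted promoters whose tag tissue profile
    departs from the aggregate profile of the whole library.
    """
    tissues = sorted(td.q)
    p = np.array([td.p.get(t, 0.0) for t in tissues])
    q = np.array([td.q[t] for t in tissues])
    return float(rel_entr(p, q).sum() / math.log(2))


def tissue_distribution(
    t: TSSD, background: Mapping[str, float] | Sequence[TSSD]
) -> TissueDistribution:
    """Build the (p, q) pair for one TSSD.

    ``background`` is either a ready tissue-fraction mapping or a
    collection of TSSDs whose pooled tissue counts define q.
    """
    if not t.tissue_counts:
        raise ValueError(f"TSSD {t.id} carries no tissue labels")
    n = sum(t.tissue_counts.values())
    p = {k: v / n for k, v in t.tissue_counts.items()}
    if isinstance(background, Mapping):
        q = dict(background)
    else:
        pooled: dict[str, int] = {}
        for other in background:
            for k, v in other.tissue_counts.items():
                pooled[k] = pooled.get(k, 0) + v
        total = sum(pooled.values())
        if total == 0:
            raise ValueError("background TSSDs carry no tissue labels")
        q = {k: v / total for k, v in pooled.items()}
    return TissueDistribution(p=p, q=q)
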