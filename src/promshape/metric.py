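"""GM-distance: a translation-minimised 1-D transport metric between TSSDs.

The base distance is MDPA (minimum difference of pair assignments), the
minimum number of one-bin element moves converting one ordinal histogram
into another — for histograms of equal mass it equals the L1 distance
between their cumulative sums (1-D optimal transport with unit ground
distance).  Because two TSSDs generally differ in width and have no shared
coordinate frame, the GM-distance slides one normalised histogram over the
other, zero-padding both to a common frame at each integer offset, and
takes the minimum MDPA over all offsets with at least one overlapping
position.  The result compares distributions in shape, independent of
genomic location and of tag magnitude.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NormalizedTSSD

__all__ = ["DissimilarityMatrix", "mdpa_distance", "gm_distance", "pairwise_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    """Symmetric all-pairs GM-distance matrix with TSSD identifiers."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.d = np.asarray(self.d, dtype=np.float64)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} ids")
        if (self.d < 0).any():
            raise ValueError("dissimilarities must be non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        self._index = {id_: i for i, id_ in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def between(self, id_a: str, id_b: str) -> float:
        try:
            return float(self.d[self._index[id_a], self._index[id_b]])
        except KeyError as exc:
            raise KeyError(f"unknown TSSD id {exc.args[0]!r}") from None

    def subset(self, ids: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self._index[i] for i in ids]
        return DissimilarityMatrix(tuple(ids), self.d[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, sep="\t", float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=np.float64))

    def write_condensed_tsv(self, path: str | Path) -> None:
        """Upper-triangle (id_a, id_b, distance) rows — compact for large n."""
        with open(path, "w") as handle:
            for i in range(len(self.ids)):
                for j in range(i + 1, len(self.ids)):
                    handle.write(f"{self.ids[i]}\t{self.ids[j]}\t{self.d[i, j]:.17g}\n")


def _as_hist(x) -> np.ndarray:
    if isinstance(x, NormalizedTSSD):
        return x.probs
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("histogram must be a non-empty 1-D vector")
    return arr


def mdpa_distance(a, b) -> float:
    """MDPA between two equal-length, equal-mass histograms.

    Equals the sum of absolute cumulative differences — the minimum total
    number of one-bin moves transforming ``a`` into ``b``.
    """
    ha, hb = _as_hist(a), _as_hist(b)
    if ha.size != hb.size:
        raise ValueError(f"histogram lengths differ: {ha.size} vs {hb.size}")
    if abs(float(ha.sum()) - float(hb.sum())) > 1e-9:
        raise ValueError(
            f"histogram masses differ: {ha.sum()!r} vs {hb.sum()!r}"
        )
    return float(np.abs(np.cumsum(ha - hb)).sum())


def _gm_min(pa: np.ndarray, pb: np.ndarray) -> float:
    """Minimum MDPA over all integer offsets with >= 1 overlapping position.

    Works on cumulative distributions extended over a common integer frame:
    at offset ``s`` the MDPA equals sum_i |cdfA(i - s) - cdfB(i)|, and both
    CDFs are 0 before their support and 1 after it (mass 1), so a finite
    frame covering every alignment suffices.  All offsets are evaluated at
    once via a sliding-window view.
    """
    wa, wb = pa.size, pb.size
    ca, cb = np.cumsum(pa), np.cumsum(pb)
    frame = 2 * wa + wb - 2  # i in [-(wa-1), wa+wb-2]
    if frame <= 0:  # wa == wb == 1: single offset, identical deltas
        return float(abs(ca[0] - cb[0]))
    cb_frame = np.concatenate([np.zeros(wa - 1), cb, np.ones(wa - 1)])
    ca_line = np.concatenate([np.zeros(wa + wb - 2), ca, np.ones(wa + wb - 2)])
    windows = np.lib.stride_tricks.sliding_window_view(ca_line, frame)
    # row r corresponds to offset s = wb - 1 - r, r = 0 .. wa+wb-2
    dists = np.abs(windows - cb_frame).sum(axis=1)
    return float(dists.min())


def gm_distance(a, b) -> float:
    """GM-distance between two normalised TSSDs (or probability vectors).

    Minimum MDPA over every translational alignment of the two zero-padded
    histograms; symmetric, non-negative, zero for identical shapes, and
    invariant to genomic location and total tag count.
    """
    ha, hb = _as_hist(a), _as_hist(b)
    for h in (ha, hb):
        if abs(float(h.sum()) - 1.0) > 1e-9:
            raise ValueError("gm_distance requires histograms normalised to sum 1")
    return _gm_min(ha, hb)


def pairwise_matrix(
    tssds: Sequence[NormalizedTSSD], progress_every: int = 500_000
) -> DissimilarityMatrix:
    """All-pairs GM-distance matrix.

    Results are identical regardless of evaluation order.  Cost is
    O(n^2 * mean_width^2); for n in the thousands expect a long run and use
    ``write_condensed_tsv`` for storage.
    """
    n = len(tssds)
    if n < 1:
        raise ValueError("need at least one TSSD")
    ids = tuple(t.id for t in tssds)
    probs = [t.probs for t in tssds]
    total_pairs = n * (n - 1) // 2
    if total_pairs:
        logger.info(
            "computing %d pairwise GM-distances (O(n^2 w^2) — may be slow for n >~ 5000)",
            total_pairs,
        )
    d = np.zeros((n, n), dtype=np.float64)
    done = 0
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _gm_min(probs[i], probs[j])
            done += 1
            if progress_every and done % progress_every == 0:
                logger.info("pairwise GM-distance: %d / %d pairs", done, total_pairs)
    return DissimilarityMatrix(ids, d)
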