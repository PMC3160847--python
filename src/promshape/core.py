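"""Core domain types for TSS-distribution (TSSD) analysis.

A TSSD is the per-nucleotide histogram of CAGE tag 5' ends inside one
promoter's tag cluster.  Histograms are always stored in the sense
direction (index 0 = 5'-most covered base), so minus-strand distributions
are reversed relative to genomic coordinates at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Tag", "TSSD", "NormalizedTSSD"]

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class Tag:
    """One mapped 5' tag: a genomic interval with a count and optional tissue label.

    Coordinates are 0-based half-open.  CTSS-derived tags are 1 nt wide;
    full-length CAGE tags are ~20 nt.
    """

    chrom: str
    start: int
    end: int
    strand: str
    count: int = 1
    tissue: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} (expected + or -)")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (end-1 on the minus strand)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class TSSD:
    """A TSS distribution: per-nucleotide tag 5'-end counts, oriented 5'->3'.

    Attributes
    ----------
    anchor : int
        Genomic coordinate of the 5'-most covered position.  Index ``i`` of
        ``counts`` maps to ``anchor + i`` on the plus strand and
        ``anchor - i`` on the minus strand.
    counts : ndarray of int
        Trimmed support: ``counts[0] > 0`` and ``counts[-1] > 0``.
    tissue_counts : dict
        Total tag count per tissue; sums to ``n`` when labels are present.
    """

    id: str
    chrom: str
    strand: str
    anchor: int
    counts: np.ndarray
    tissue_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts[0] == 0 or self.counts[-1] == 0:
            raise ValueError("counts must be trimmed to the covered support")
        if self.counts.sum() < 1:
            raise ValueError("TSSD must contain at least one tag")
        if self.tissue_counts:
            total = sum(self.tissue_counts.values())
            if total != int(self.counts.sum()):
                raise ValueError(
                    f"tissue counts sum to {total}, histogram to {self.counts.sum()}"
                )

    @property
    def n(self) -> int:
        """Total tag count."""
        return int(self.counts.sum())

    @property
    def w(self) -> int:
        """Width in nucleotides (number of positions between the outermost
        covered bases, inclusive)."""
        return int(self.counts.size)

    def genomic_span(self) -> tuple[int, int]:
        """Half-open genomic interval covered by the support."""
        if self.strand == "+":
            return self.anchor, self.anchor + self.w
        return self.anchor - self.w + 1, self.anchor + 1

    def genomic_position(self, offset: int) -> int:
        """Genomic coordinate of histogram offset ``offset``."""
        return self.anchor + offset if self.strand == "+" else self.anchor - offset

    def with_counts(self, counts: np.ndarray) -> "TSSD":
        return replace(self, counts=np.asarray(counts, dtype=np.int64))


@dataclass
class NormalizedTSSD:
    """A TSSD whose histogram is normalised to sum to one (shape only).

    Normalisation makes distributions comparable in shape rather than in
    magnitude, which is what the GM-distance operates on.
    """

    id: str
    chrom: str
    strand: str
    anchor: int
    probs: np.ndarray
    tissue_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 1 or self.probs.size == 0:
            raise ValueError("probs must be a non-empty 1-D vector")
        if (self.probs < 0).any():
            raise ValueError("probs must be non-negative")
        if abs(float(self.probs.sum()) - 1.0) > 1e-9:
            raise ValueError(f"probs must sum to 1, got {self.probs.sum()!r}")

    @property
    def w(self) -> int:
        return int(self.probs.size)
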