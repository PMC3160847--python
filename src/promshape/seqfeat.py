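"""Sequence-level promoter diagnostics on windows aligned at dominant peaks.

Two diagnostics are provided, both operating on user-supplied, equal-width
sequence windows whose dominant TSS sits at a fixed offset:

* a position-weight-matrix scan (e.g. a TATA-box PWM) reporting the
  density of hits per relative position, with a hit defined by the
  relative log-odds score (s - s_min) / (s_max - s_min) reaching a
  threshold (default 70%);
* the positional density of pyrimidine-purine (PyPu) dinucleotides, the
  canonical metazoan initiator signal straddling the TSS at -1/+1.

Sequences are assumed sense-oriented (TSSDs are stored 5'->3'), so only
the given strand is scanned.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "PositionWeightMatrix",
    "PositionalDensity",
    "read_pwm",
    "read_fasta_windows",
    "pwm_scan",
    "pypu_density",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_PYRIMIDINES = frozenset("CT")
_PURINES = frozenset("AG")


@dataclass
class PositionWeightMatrix:
    """Log-odds PWM built from a 4 x L count or frequency table.

    Columns are positions, rows A, C, G, T.  Counts are converted to
    per-position frequencies with a pseudocount (default 0.01) and scored
    as log-odds against a uniform background.
    """

    counts: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"PWM must be 4 x L, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("PWM entries must be non-negative")
        freqs = self.counts + self.pseudocount
        freqs = freqs / freqs.sum(axis=0, keepdims=True)
        self.log_odds = np.log2(freqs / 0.25)
        self.score_min = float(self.log_odds.min(axis=0).sum())
        self.score_max = float(self.log_odds.max(axis=0).sum())

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def score(self, word: str) -> float:
        """Log-odds score of an L-mer; raises on non-ACGT letters."""
        if len(word) != self.length:
            raise ValueError(f"word length {len(word)} != PWM length {self.length}")
        idx = [_BASE_INDEX[b] for b in word.upper()]
        return float(self.log_odds[idx, np.arange(self.length)].sum())

    def relative_score(self, word: str) -> float:
        """Score rescaled to [0, 1] between the worst and best possible words."""
        span = self.score_max - self.score_min
        if span == 0:
            return 1.0
        return (self.score(word) - self.score_min) / span


@dataclass
class PositionalDensity:
    """Per-offset site density relative to the dominant peak (sites per TSSD)."""

    offsets: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.offsets.shape != self.density.shape:
            raise ValueError("offsets and density must align")
        if (self.density < 0).any():
            raise ValueError("density must be non-negative")

    def at(self, offset: int) -> float:
        hits = np.flatnonzero(self.offsets == offset)
        if hits.size == 0:
            raise KeyError(f"offset {offset} outside the scanned window")
        return float(self.density[hits[0]])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("offset\tdensity\n")
            for o, v in zip(self.offsets, self.density):
                handle.write(f"{o}\t{v:.6g}\n")


def read_pwm(path: str | Path) -> PositionWeightMatrix:
    """Read a tab-separated 4 x L count/frequency table.

    Rows may carry an A/C/G/T label in the first column (any order);
    unlabelled rows are taken as A, C, G, T from top to bottom.  Lines
    starting with ``>`` or ``#`` are ignored, so JASPAR-style ``.pfm``
    files with a header line parse directly.
    """
    rows: dict[str, list[float]] = {}
    unlabelled: list[list[float]] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip().replace("[", " ").replace("]", " ")
            if not line or line.startswith((">", "#")):
                continue
            fields = line.split()
            if fields[0].upper() in _BASE_INDEX:
                rows[fields[0].upper()] = [float(x) for x in fields[1:]]
            else:
                unlabelled.append([float(x) for x in fields])
    if rows:
        if set(rows) != set(_BASES):
            raise ValueError(f"PWM rows must cover A,C,G,T; got {sorted(rows)}")
        matrix = np.array([rows[b] for b in _BASES])
    elif len(unlabelled) == 4:
        matrix = np.array(unlabelled)
    else:
        raise ValueError(f"expected 4 PWM rows, got {len(unlabelled)}")
    return PositionWeightMatrix(matrix)


def read_fasta_windows(path: str | Path) -> list[str]:
    """Read aligned sequence windows from FASTA (all must share one length)."""
    seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if seqs and len({len(s) for s in seqs}) != 1:
        raise ValueError("FASTA windows must all have the same length")
    return seqs


def pwm_scan(
    seqs: Sequence[str],
    pwm: PositionWeightMatrix,
    rel_threshold: float = 0.70,
    peak_index: int | None = None,
) -> PositionalDensity:
    """Scan aligned windows with a PWM and report per-offset hit density.

    A hit at an offset means the L-mer starting there reaches
    ``rel_threshold`` of the relative log-odds score; densities are hits
    per offset divided by the number of sequences, and each hit is
    anchored at the first position of the match (for a TATA PWM, the
    first T of the box).  Offsets are reported relative to ``peak_index``
    (default: the window centre).  L-mers containing non-ACGT letters are
    skipped.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError(f"rel_threshold must be in (0, 1], got {rel_threshold}")
    if not seqs:
        raise ValueError("no sequences supplied")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("sequences must be aligned to a common width")
    if peak_index is None:
        peak_index = width // 2
    L = pwm.length
    n_starts = width - L + 1
    if n_starts < 1:
        raise ValueError(f"windows of width {width} are shorter than the PWM ({L})")
    hits = np.zeros(n_starts, dtype=np.float64)
    for seq in seqs:
        seq = seq.upper()
        for start in range(n_starts):
            word = seq[start : start + L]
            if any(b not in _BASE_INDEX for b in word):
                continue
            if pwm.relative_score(word) >= rel_threshold:
                hits[start] += 1
    offsets = np.arange(n_starts) - peak_index
    return PositionalDensity(offsets=offsets, density=hits / len(seqs))


def pypu_density(
    seqs: Sequence[str], peak_offsets: Sequence[Sequence[int]] | Sequence[int]
) -> PositionalDensity:
    """Positional density of PyPu dinucleotides around annotated peaks.

    For every (sequence, peak) pair and every relative offset delta, the
    dinucleotide straddling position ``peak + delta`` (the bases at -1 and
    +1, i.e. string indices ``pos - 1`` and ``pos``) is tested for
    pyrimidine-then-purine ({C,T} followed by {A,G}).  The density at
    delta is the PyPu fraction over the pairs whose bases there are
    unambiguous; pairs with an N (or falling off the window) are excluded
    from that offset's denominator.
    """
    if not seqs:
        raise ValueError("no sequences supplied")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("sequences must be aligned to a common width")
    norm_offsets: list[list[int]] = []
    for po in peak_offsets:
        norm_offsets.append([int(po)] if isinstance(po, (int, np.integer)) else [int(x) for x in po])
    if len(norm_offsets) != len(seqs):
        raise ValueError("need one peak-offset entry per sequence")
    if any(len(p) == 0 for p in norm_offsets):
        raise ValueError("every sequence needs at least one annotated peak")

    min_peak = min(min(p) for p in norm_offsets)
    max_peak = max(max(p) for p in norm_offsets)
    deltas = np.arange(1 - max_peak, width - min_peak)
    pypu = np.zeros(deltas.size, dtype=np.float64)
    valid = np.zeros(deltas.size, dtype=np.float64)
    for seq, peaks in zip(seqs, norm_offsets):
        seq = seq.upper()
        for peak in peaks:
            for di, delta in enumerate(deltas):
                pos = peak + delta
                if pos - 1 < 0 or pos >= width:
                    continue
                minus, plus = seq[pos - 1], seq[pos]
                if minus not in "ACGT" or plus not in "ACGT":
                    continue
                valid[di] += 1
                if minus in _PYRIMIDINES and plus in _PURINES:
                    pypu[di] += 1
    keep = valid > 0
    with np.errstate(invalid="ignore"):
        density = np.where(keep, pypu / np.maximum(valid, 1), 0.0)
    return PositionalDensity(offsets=deltas[keep], density=density[keep])
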