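"""Reading tag inputs, assembling TSSDs, and serialising results.

Input dialects
--------------
CTSS TSV   : ``chrom TAB pos TAB strand TAB count [TAB tissue]`` — one row per
             tag 5'-end position (per tissue when the fifth column is present).
Tag BED6   : full-length tag intervals; the name column carries the tissue
             label (``.`` = unlabelled), the score column the tag count.
TSSD BED6+ : one row per TSSD with extra columns for the histogram, the
             per-tissue totals and optional annotations; round-trips.

TSSD assembly follows the tag-cluster rule: same-strand tags chained by
single linkage whenever two intervals overlap by at least ``min_overlap``
(default 2 bp, which suppresses the 1-bp tiling artefacts of earlier
cluster builds), then chains with fewer than ``min_tags`` tags (default
100) are discarded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import replace
from pathlib import Path

import numpy as np

from .core import TSSD, NormalizedTSSD, Tag

__all__ = [
    "read_ctss",
    "read_tag_bed",
    "build_tssds",
    "laplace_smooth",
    "normalize",
    "write_tssd_bed",
    "read_tssd_bed",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input line; message carries the 1-based line number."""


def _parse_count(text: str, path: str, lineno: int) -> int:
    try:
        count = int(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer count {text!r}") from None
    if count < 1:
        raise ParseError(f"{path}:{lineno}: count must be >= 1, got {count}")
    return count


def read_ctss(path: str | Path, coordinate_base: int = 0) -> list[Tag]:
    """Read a CTSS table into 1-nt tags, summing duplicate rows.

    Parameters
    ----------
    coordinate_base : {0, 1}
        Base of the position column.  1-based input is shifted down by one
        so that all internal coordinates are 0-based half-open.

    Duplicate ``(chrom, pos, strand, tissue)`` keys are summed rather than
    rejected, so per-library files can be concatenated.
    """
    if coordinate_base not in (0, 1):
        raise ValueError(f"coordinate_base must be 0 or 1, got {coordinate_base}")
    path = Path(path)
    acc: dict[tuple[str, int, str, str | None], int] = defaultdict(int)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected >=4 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, strand, count_s = fields[:4]
            tissue = fields[4] if len(fields) > 4 and fields[4] not in ("", ".") else None
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                pos = int(pos_s) - coordinate_base
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer position {pos_s!r}") from None
            count = _parse_count(count_s, str(path), lineno)
            acc[(chrom, pos, strand, tissue)] += count
    return [
        Tag(chrom=c, start=p, end=p + 1, strand=s, count=n, tissue=t)
        for (c, p, s, t), n in sorted(acc.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3] or ""))
    ]


def read_tag_bed(path: str | Path) -> list[Tag]:
    """Read full-length tag intervals from BED6 (name = tissue, score = count)."""
    path = Path(path)
    tags: list[Tag] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: need 6 columns, got {len(fields)}")
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start ({start}, {end})")
            count = _parse_count(score_s, str(path), lineno)
            tissue = name if name not in ("", ".") else None
            tags.append(Tag(chrom, start, end, strand, count, tissue))
    return tags


def _extend_tag(tag: Tag, length: int) -> Tag:
    """Extend a tag 3'-wards to ``length`` nt, preserving its 5' end."""
    if tag.end - tag.start >= length:
        return tag
    if tag.strand == "+":
        return replace(tag, end=tag.start + length)
    return replace(tag, start=tag.end - length)


def build_tssds(
    tags: Iterable[Tag],
    min_overlap: int = 2,
    min_tags: int = 100,
    extend_to: int | None = None,
    id_prefix: str = "TSSD",
) -> list[TSSD]:
    """Chain overlapping same-strand tags into TSSDs.

    Single-linkage chains of tags whose intervals pairwise overlap by at
    least ``min_overlap`` nt form one cluster; the cluster histogram records
    the 5'-end position of every tag (strand-aware), reversed for minus-strand
    clusters so index 0 is always the 5'-most covered base.  Chains totalling
    fewer than ``min_tags`` tags are dropped.  The default threshold of 100
    suits deep libraries; a lower threshold is acceptable for small sets as
    long as it is held fixed across a study.

    ``extend_to`` extends short tags (e.g. 1-nt CTSS records) 3'-wards to a
    nominal CAGE tag length before chaining, preserving 5' ends.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    if min_tags < 1:
        raise ValueError(f"min_tags must be >= 1, got {min_tags}")
    tag_list = list(tags)
    if extend_to is not None:
        tag_list = [_extend_tag(t, extend_to) for t in tag_list]

    by_group: dict[tuple[str, str], list[Tag]] = defaultdict(list)
    for tag in tag_list:
        by_group[(tag.chrom, tag.strand)].append(tag)

    tssds: list[TSSD] = []
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda t: (t.start, t.end))
        # sweep: a tag joins the open chain iff it overlaps the chain's
        # rightmost extent by >= min_overlap
        chains: list[list[Tag]] = []
        current: list[Tag] = []
        max_end = -1
        for tag in group:
            if current and tag.start <= max_end - min_overlap:
                current.append(tag)
                max_end = max(max_end, tag.end)
            else:
                if current:
                    chains.append(current)
                current = [tag]
                max_end = tag.end
        if current:
            chains.append(current)

        for chain in chains:
            total = sum(t.count for t in chain)
            if total < min_tags:
                continue
            fives = np.array([t.five_prime for t in chain])
            counts_per_pos: dict[int, int] = defaultdict(int)
            tissue_counts: dict[str, int] = defaultdict(int)
            any_tissue = False
            for tag in chain:
                counts_per_pos[tag.five_prime] += tag.count
                if tag.tissue is not None:
                    any_tissue = True
                    tissue_counts[tag.tissue] += tag.count
            lo, hi = int(fives.min()), int(fives.max())
            hist = np.zeros(hi - lo + 1, dtype=np.int64)
            for pos, cnt in counts_per_pos.items():
                hist[pos - lo] = cnt
            if strand == "-":
                hist = hist[::-1]
                anchor = hi
            else:
                anchor = lo
            if any_tissue and sum(tissue_counts.values()) != total:
                raise ValueError(
                    f"chain at {chrom}:{lo} mixes labelled and unlabelled tags"
                )
            tssds.append(
                TSSD(
                    id="",  # assigned below in deterministic order
                    chrom=chrom,
                    strand=strand,
                    anchor=anchor,
                    counts=hist,
                    tissue_counts=dict(tissue_counts) if any_tissue else {},
                )
            )

    tssds.sort(key=lambda t: (t.chrom, t.genomic_span()[0], t.strand))
    width = max(4, len(str(len(tssds))))
    for i, t in enumerate(tssds, start=1):
        t.id = f"{id_prefix}_{i:0{width}d}"
    logger.info("built %d TSSDs from %d tags", len(tssds), len(tag_list))
    return tssds


def laplace_smooth(t: TSSD) -> TSSD:
    """Apply Laplace's rule of succession: add one tag to every position of
    the trimmed support.  Dampens background noise without widening the TSSD.

    The added pseudo-tags belong to no tissue, so the result carries no
    tissue breakdown; tissue specificity is always computed on raw counts.
    """
    return replace(t, counts=t.counts + 1, tissue_counts={})


def normalize(t: TSSD) -> NormalizedTSSD:
    """Normalise the histogram to sum to one (shape-only representation)."""
    n = t.n
    if n <= 0:
        raise ValueError("cannot normalize an empty TSSD")
    return NormalizedTSSD(
        id=t.id,
        chrom=t.chrom,
        strand=t.strand,
        anchor=t.anchor,
        probs=t.counts / n,
        tissue_counts=dict(t.tissue_counts),
    )


def _format_tissue_counts(tc: dict[str, int]) -> str:
    if not tc:
        return "."
    return ",".join(f"{k}:{v}" for k, v in sorted(tc.items()))


def _parse_tissue_counts(text: str) -> dict[str, int]:
    if text in (".", ""):
        return {}
    out: dict[str, int] = {}
    for item in text.split(","):
        key, _, val = item.rpartition(":")
        out[key] = int(val)
    return out


def write_tssd_bed(
    tssds: Sequence[TSSD],
    path: str | Path,
    annotations: dict[str, dict[str, object]] | None = None,
    annotation_columns: Sequence[str] = (),
) -> None:
    """Write TSSDs as BED6+ rows.

    Columns: chrom, start, end (half-open genomic span of the support),
    id, score (= total tags, capped at 1000 for browser compatibility),
    strand, n, w, counts (comma-separated 5'->3'), tissue_counts, then any
    requested annotation columns (e.g. class, peakedness, n_peaks).
    """
    annotations = annotations or {}
    path = Path(path)
    with open(path, "w") as handle:
        for t in tssds:
            start, end = t.genomic_span()
            extra = annotations.get(t.id, {})
            row = [
                t.chrom,
                str(start),
                str(end),
                t.id,
                str(min(t.n, 1000)),
                t.strand,
                str(t.n),
                str(t.w),
                ",".join(str(c) for c in t.counts),
                _format_tissue_counts(t.tissue_counts),
            ]
            for col in annotation_columns:
                row.append(str(extra.get(col, ".")))
            handle.write("\t".join(row) + "\n")


def read_tssd_bed(path: str | Path) -> list[TSSD]:
    """Read TSSDs written by :func:`write_tssd_bed` (histograms included)."""
    path = Path(path)
    out: list[TSSD] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(f"{path}:{lineno}: need >=10 columns, got {len(fields)}")
            chrom, start_s, _end_s, name, _score, strand = fields[:6]
            counts = np.array([int(x) for x in fields[8].split(",")], dtype=np.int64)
            tissue_counts = _parse_tissue_counts(fields[9])
            start = int(start_s)
            anchor = start if strand == "+" else start + counts.size - 1
            out.append(
                TSSD(
                    id=name,
                    chrom=chrom,
                    strand=strand,
                    anchor=anchor,
                    counts=counts,
                    tissue_counts=tissue_counts,
                )
            )
    return out
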