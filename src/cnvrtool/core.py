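"""Genomic-interval data model and interval algebra.

Coordinates are 1-based and inclusive at both ends throughout the package,
matching the convention of SNP-array CNV callers and the printed coordinates
in the CNV literature (e.g. ``chr3:113598223-113659549``).  The length of an
interval is therefore ``end - start + 1``.  BED input/output converts to and
from the 0-based half-open convention at the boundary (see
:mod:`cnvrtool.io_formats`).

Chromosome labels are plain strings without a ``"chr"`` prefix ("1".."22",
"X"); :func:`normalize_chrom` strips the prefix on input.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))
CHROM_X = "X"


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix and surrounding whitespace."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome label without ``chr`` prefix.
    start, end : int
        1-based inclusive base positions, ``1 <= start <= end``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return f"{self.chrom}:{self.start}-{self.end}"


class CnvType(enum.Enum):
    """Direction of a copy-number change relative to the diploid state."""

    DEL = "DEL"
    DUP = "DUP"


def cnv_type_from_copy_number(copy_number: int) -> CnvType:
    """Classify a copy number as deletion (<2) or duplication (>2).

    Copy-number-neutral calls (CN = 2, e.g. LOH segments) have no CNV type
    and must be rejected upstream; passing one raises ``ValueError``.
    """
    if copy_number < 2:
        return CnvType.DEL
    if copy_number > 2:
        return CnvType.DUP
    raise ValueError("copy number 2 is copy-neutral and has no CNV type")


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base positions shared by two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[float, float]:
    """Overlap as a fraction of each interval's own length.

    Returns ``(ov / len(a), ov / len(b))``; both are in [0, 1].  The
    reciprocal-overlap rule used for consensus calling requires *both*
    fractions to reach the threshold.
    """
    ov = overlap_length(a, b)
    return ov / a.length_bp, ov / b.length_bp


def intersect(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval | None:
    """The shared span of two intervals, or None when they are disjoint."""
    if overlap_length(a, b) == 0:
        return None
    return GenomicInterval(a.chrom, max(a.start, b.start), min(a.end, b.end))


def span(intervals: Iterable[GenomicInterval]) -> GenomicInterval:
    """Minimal single interval covering all inputs (one chromosome only)."""
    intervals = list(intervals)
    if not intervals:
        raise ValueError("span() of an empty collection")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError(f"span() across chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge transitively overlapping intervals into maximal regions.

    Two intervals belong to the same output region when they share at least
    one base position, directly or through a chain of overlaps.  Abutting
    intervals (``a.end + 1 == b.start``) do NOT merge: region construction
    requires an overlap of at least one base.  Output is sorted by
    ``(chrom, start)`` and pairwise disjoint within each chromosome.
    """
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in items:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start <= merged[-1].end
        ):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end
                )
        else:
            merged.append(iv)
    return merged


def merge_groups(
    intervals: Iterable[GenomicInterval],
) -> list[list[int]]:
    """Indices of the inputs grouped by transitive overlap.

    Same clustering semantics as :func:`merge_intervals` but reporting which
    input intervals fell into each merged region; used to attach member CNVs
    to their CNVR.  Groups are ordered by (chrom, start) of their region.
    """
    items = list(intervals)
    order = sorted(
        range(len(items)), key=lambda i: (items[i].chrom, items[i].start, items[i].end)
    )
    groups: list[list[int]] = []
    cur_chrom: str | None = None
    cur_end = -1
    for i in order:
        iv = items[i]
        if groups and iv.chrom == cur_chrom and iv.start <= cur_end:
            groups[-1].append(i)
            cur_end = max(cur_end, iv.end)
        else:
            groups.append([i])
            cur_chrom = iv.chrom
            cur_end = iv.end
    return groups
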