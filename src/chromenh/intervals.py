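"""Genomic interval primitives and interval algebra.

All coordinates are 0-based, half-open (BED convention). Chromosome names
are matched by exact string equality; no "chr" normalization is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint base, floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is at most ``max_gap`` bases.

    Mirrors ``bedtools merge -d max_gap``: two intervals on the same
    chromosome merge iff ``start_next - end_prev <= max_gap`` (overlapping
    or book-ended intervals always merge). Output is sorted and pairwise
    separated by more than ``max_gap`` on each chromosome.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and iv.chrom == merged[-1].chrom
            and iv.start - merged[-1].end <= max_gap
        ):
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(iv)
    return merged


def bidirectional_overlap(
    a: GenomicInterval, b: GenomicInterval, min_fraction: float
) -> bool:
    """True iff the overlap covers >= ``min_fraction`` of BOTH intervals.

    Symmetric in (a, b). Intervals on different chromosomes never overlap
    bidirectionally (returns False, not an error).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    ov = a.overlap_length(b)
    return ov >= min_fraction * len(a) and ov >= min_fraction * len(b)


def min_distance(interval: GenomicInterval, position: int, chrom: str) -> float:
    """Distance in bp from a point to an interval.

    Zero when the position lies inside [start, end); otherwise the distance
    to the nearest covered base (the last covered base is ``end - 1``).
    Returns +inf for a different chromosome.
    """
    if position < 0:
        raise ValueError(f"position must be >= 0, got {position}")
    if chrom != interval.chrom:
        return math.inf
    if interval.start <= position < interval.end:
        return 0
    if position < interval.start:
        return interval.start - position
    return position - (interval.end - 1)


def sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def total_bases(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases covered by a set of pairwise-disjoint intervals."""
    return sum(len(iv) for iv in intervals)
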