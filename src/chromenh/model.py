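"""Domain containers: segmentations, peak sets, genes, expression, signal tracks.

A Segmentation is the post-processed output of a hidden-Markov chromatin-state
model (ChromHMM-style): per chromosome, an ordered list of non-overlapping
labeled state intervals at a fixed bin resolution. Gaps are permitted and are
treated as "unmarked" chromatin downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

UNMARKED = "unmarked"


@dataclass(frozen=True)
class StateSegment:
    interval: GenomicInterval
    state: int

    def __post_init__(self) -> None:
        if self.state < 1:
            raise ValueError(f"state labels start at 1, got {self.state}")


class Segmentation:
    """Ordered, non-overlapping chromatin-state segments per chromosome."""

    def __init__(
        self,
        segments: Iterable[StateSegment],
        state_count: int = 11,
        resolution: int = 200,
    ):
        self.state_count = state_count
        self.resolution = resolution
        by_chrom: dict[str, list[StateSegment]] = {}
        for seg in segments:
            if not 1 <= seg.state <= state_count:
                raise ValueError(
                    f"state {seg.state} outside 1..{state_count} "
                    f"at {seg.interval.chrom}:{seg.interval.start}"
                )
            by_chrom.setdefault(seg.interval.chrom, []).append(seg)
        self._by_chrom: dict[str, list[StateSegment]] = {}
        for chrom, segs in sorted(by_chrom.items()):
            segs.sort(key=lambda s: s.interval.start)
            for prev, cur in zip(segs, segs[1:]):
                if cur.interval.start < prev.interval.end:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"{prev.interval.start}-{prev.interval.end} and "
                        f"{cur.interval.start}-{cur.interval.end}"
                    )
            self._by_chrom[chrom] = segs
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def segments(self, chrom: Optional[str] = None) -> list[StateSegment]:
        if chrom is not None:
            return list(self._by_chrom.get(chrom, []))
        return [s for segs in self._by_chrom.values() for s in segs]

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, states) arrays for one chromosome, cached."""
        if chrom not in self._arrays:
            segs = self._by_chrom.get(chrom, [])
            self._arrays[chrom] = (
                np.array([s.interval.start for s in segs], dtype=np.int64),
                np.array([s.interval.end for s in segs], dtype=np.int64),
                np.array([s.state for s in segs], dtype=np.int64),
            )
        return self._arrays[chrom]

    def state_at(self, chrom: str, position: int) -> int | str:
        """State covering a base, or "unmarked" when no segment covers it."""
        starts, ends, states = self.arrays(chrom)
        if len(starts) == 0:
            return UNMARKED
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i >= 0 and position < ends[i]:
            return int(states[i])
        return UNMARKED

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Segmentation):
            return NotImplemented
        return (
            self.state_count == other.state_count
            and self.segments() == other.segments()
        )


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.score is not None and not np.isfinite(self.score):
            raise ValueError(f"peak score must be finite, got {self.score}")


class PeakSet:
    """Named collection of peaks, kept sorted by (chrom, start)."""

    def __init__(self, label: str, peaks: Iterable[Peak]):
        self.label = label
        self.peaks = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.label == other.label and self.peaks == other.peaks

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def midpoints(self) -> list[tuple[str, int]]:
        return [(p.interval.chrom, p.interval.midpoint) for p in self.peaks]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


class ExpressionMatrix:
    """FPKM per gene per condition, with derived log2 fold-changes.

    Thin wrapper around a DataFrame indexed by gene_id, one column per
    condition. FPKM must be non-negative; log2fc uses a pseudocount of 1 so
    it is finite for zero-FPKM genes.
    """

    def __init__(self, fpkm: pd.DataFrame):
        if fpkm.index.has_duplicates:
            dups = fpkm.index[fpkm.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if (fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be >= 0")
        self.fpkm = fpkm.astype(float)

    @property
    def conditions(self) -> list[str]:
        return list(self.fpkm.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    def values(self, condition: str, gene_ids: Optional[Sequence[str]] = None) -> np.ndarray:
        col = self.fpkm[condition]
        if gene_ids is not None:
            col = col.loc[list(gene_ids)]
        return col.to_numpy()

    def log2fc(
        self, cond_numerator: str, cond_denominator: str, pseudocount: float = 1.0
    ) -> pd.Series:
        """log2((FPKM_num + pc) / (FPKM_den + pc)) per gene."""
        num = self.fpkm[cond_numerator] + pseudocount
        den = self.fpkm[cond_denominator] + pseudocount
        return np.log2(num / den)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.fpkm.equals(other.fpkm)


class SignalTrack:
    """Stepwise-constant signal with bedGraph semantics.

    Steps are sorted, non-overlapping (start, end, value) records per
    chromosome; uncovered bases have value 0. ``chrom_lengths`` (optional)
    enables right-clipping of windows in aggregate profiles.
    """

    def __init__(
        self,
        steps: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        chrom_lengths: Optional[Mapping[str, int]] = None,
    ):
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in sorted(steps.items()):
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError("starts/ends/values length mismatch")
            if len(starts) and (
                (np.diff(starts) < 0).any() or (starts[1:] < ends[:-1]).any()
            ):
                raise ValueError(f"steps on {chrom} must be sorted, non-overlapping")
            if len(starts) and (starts >= ends).any():
                raise ValueError(f"empty steps on {chrom}")
            self._steps[chrom] = (starts, ends, values)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None

    @property
    def chromosomes(self) -> list[str]:
        return list(self._steps)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._steps.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, float)),
        )

    def values_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are 0."""
        if start >= end:
            return np.empty(0, float)
        out = np.zeros(end - start, dtype=float)
        starts, ends, values = self.steps(chrom)
        if len(starts) == 0:
            return out
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start)
            b = min(int(ends[i]), end)
            if a < b:
                out[a - start : b - start] = values[i]
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if set(self._steps) != set(other._steps):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self._steps[c], other._steps[c]))
            for c in self._steps
        )


def validate_chromosome_vocabulary(*named_objects: tuple[str, Iterable[str]]) -> list[str]:
    """Warn-style check that inputs share chromosome names.

    Returns a list of human-readable warnings; empty when every pair of
    inputs shares at least one chromosome name. Exact string matching.
    """
    warnings = []
    items = [(name, set(chroms)) for name, chroms in named_objects]
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (na, ca), (nb, cb) = items[i], items[j]
            if ca and cb and not (ca & cb):
                warnings.append(
                    f"{na} and {nb} have disjoint chromosome vocabularies "
                    f"({sorted(ca)[:3]}... vs {sorted(cb)[:3]}...)"
                )
    return warnings
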