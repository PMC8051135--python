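"""TF binding-site analysis between two conditions.

Classifies peak sharing, TSS proximity, chromatin-state transitions at site
midpoints, aggregate signal profiles around site midpoints, and the FRiP
(fraction of reads in peaks) QC metric.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, merge_intervals, min_distance
from .model import UNMARKED, GeneRecord, PeakSet, Segmentation, SignalTrack

DEFAULT_ACTIVE_STATES = frozenset(range(1, 7))  # states 1-6 are "active"


class SiteClass(enum.Enum):
    """Chromatin-state transition class of a binding site (A -> B)."""

    REPRESSED_TO_ACTIVE = "repressed_to_active"
    ACTIVE_TO_ACTIVE = "active_to_active"
    ACTIVE_TO_REPRESSED = "active_to_repressed"
    OTHER = "other"


@dataclass
class PeakSharing:
    labels_a: list[str]  # "shared" / "a_only" per peak of A
    labels_b: list[str]  # "shared" / "b_only" per peak of B
    n_a: int
    n_b: int
    shared_a: int
    shared_b: int


def _overlaps_any(
    peak: GenomicInterval,
    starts: np.ndarray,
    ends: np.ndarray,
    min_overlap_bp: int,
) -> bool:
    """Any overlap >= min_overlap_bp with a sorted, merged interval list."""
    if len(starts) == 0:
        return False
    lo = int(np.searchsorted(ends, peak.start + min_overlap_bp, side="left"))
    hi = int(np.searchsorted(starts, peak.end - min_overlap_bp, side="right"))
    for i in range(lo, hi):
        ov = min(int(ends[i]), peak.end) - max(int(starts[i]), peak.start)
        if ov >= min_overlap_bp:
            return True
    return False


def _merged_arrays(intervals: Sequence[GenomicInterval]):
    merged = merge_intervals(intervals, max_gap=0)
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for iv in merged:
        s, e = by_chrom.setdefault(iv.chrom, ([], []))
        s.append(iv.start)
        e.append(iv.end)
    return {
        c: (np.array(s, dtype=np.int64), np.array(e, dtype=np.int64))
        for c, (s, e) in by_chrom.items()
    }


def classify_peak_sharing(
    peaks_a: PeakSet, peaks_b: PeakSet, min_overlap_bp: int = 1
) -> PeakSharing:
    """Label each peak shared iff it overlaps the other set by >= min_overlap_bp.

    Coordinates are half-open, so book-ended peaks share no base and stay
    unique at the default 1-bp criterion.
    """
    if min_overlap_bp < 1:
        raise ValueError(f"min_overlap_bp must be >= 1, got {min_overlap_bp}")

    def label(peaks: PeakSet, other: PeakSet, unique_tag: str) -> list[str]:
        merged = _merged_arrays(other.intervals())
        out = []
        for p in peaks:
            arrs = merged.get(p.interval.chrom)
            hit = arrs is not None and _overlaps_any(
                p.interval, arrs[0], arrs[1], min_overlap_bp
            )
            out.append("shared" if hit else unique_tag)
        return out

    labels_a = label(peaks_a, peaks_b, "a_only")
    labels_b = label(peaks_b, peaks_a, "b_only")
    return PeakSharing(
        labels_a=labels_a,
        labels_b=labels_b,
        n_a=len(peaks_a),
        n_b=len(peaks_b),
        shared_a=labels_a.count("shared"),
        shared_b=labels_b.count("shared"),
    )


def tss_proximal_fraction(
    peaks: PeakSet, genes: Sequence[GeneRecord], max_dist: int = 1000
) -> tuple[list[bool], float]:
    """Flag peaks within ``max_dist`` bp of any TSS (boundary inclusive).

    Distance is from the peak interval to the TSS point; a TSS inside the
    peak has distance 0. Returns the per-peak flags and the proximal
    fraction of all peaks.
    """
    if max_dist < 0:
        raise ValueError(f"max_dist must be >= 0, got {max_dist}")
    if not genes:
        raise ValueError("empty gene list")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in tss_by_chrom.items()}
    flags = []
    for p in peaks:
        iv = p.interval
        tss = tss_by_chrom.get(iv.chrom)
        if tss is None or len(tss) == 0:
            flags.append(False)
            continue
        # nearest TSS to the interval: any in [start - max_dist, end - 1 + max_dist]
        lo = int(np.searchsorted(tss, iv.start - max_dist, side="left"))
        flags.append(lo < len(tss) and int(tss[lo]) <= iv.end - 1 + max_dist)
    n = len(flags)
    return flags, (sum(flags) / n if n else float("nan"))


def site_state(peak, seg: Segmentation) -> int | str:
    """Chromatin state at the peak midpoint, or "unmarked" in a gap."""
    iv = peak.interval if hasattr(peak, "interval") else peak
    return seg.state_at(iv.chrom, iv.midpoint)


def transition_class(
    sharing_label: str,
    state_a: int | str,
    state_b: int | str,
    active_states: frozenset[int] = DEFAULT_ACTIVE_STATES,
) -> SiteClass:
    """Assign the A->B chromatin transition class of one binding site.

    "unmarked" counts as not-active (repressed and unmarked chromatin are
    grouped). Every site receives exactly one class.
    """
    a_active = isinstance(state_a, int) and state_a in active_states
    b_active = isinstance(state_b, int) and state_b in active_states
    if sharing_label == "b_only" and not a_active and b_active:
        return SiteClass.REPRESSED_TO_ACTIVE
    if sharing_label == "shared" and a_active and b_active:
        return SiteClass.ACTIVE_TO_ACTIVE
    if sharing_label == "a_only" and a_active and not b_active:
        return SiteClass.ACTIVE_TO_REPRESSED
    return SiteClass.OTHER


@dataclass
class ProfileMatrix:
    """Mean signal (or density) in bins of offsets around site midpoints."""

    bin_offsets: np.ndarray  # left edge of each bin, relative to midpoint
    values: np.ndarray
    half_window: int
    bin_width: int
    n_anchors: int

    @property
    def center_bin_index(self) -> int:
        """Index of the bin containing offset 0."""
        return int(np.searchsorted(self.bin_offsets, 0, side="right")) - 1

    def bin_centers(self) -> np.ndarray:
        return self.bin_offsets + self.bin_width / 2


def single_anchor_profile(
    chrom: str,
    midpoint: int,
    track: SignalTrack,
    half_window: int,
    bin_width: int,
) -> np.ndarray:
    """Per-bin mean signal for one anchor; NaN for fully clipped bins."""
    n_bins = 2 * half_window // bin_width
    lo, hi = midpoint - half_window, midpoint + half_window
    clip_lo = max(lo, 0)
    clip_hi = hi
    if track.chrom_lengths and chrom in track.chrom_lengths:
        clip_hi = min(hi, track.chrom_lengths[chrom])
    out = np.full(n_bins, np.nan)
    if clip_lo >= clip_hi:
        return out
    vals = track.values_array(chrom, clip_lo, clip_hi)
    for b in range(n_bins):
        a = max(lo + b * bin_width, clip_lo)
        e = min(lo + (b + 1) * bin_width, clip_hi)
        if a < e:
            out[b] = vals[a - clip_lo : e - clip_lo].mean()
    return out


def aggregate_profile(
    anchors: PeakSet,
    track: SignalTrack,
    half_window: int = 1000,
    bin_width: int = 10,
) -> ProfileMatrix:
    """Mean signal per offset bin around anchor midpoints.

    The profile is the unweighted mean over anchors of per-anchor bin means;
    anchors whose window runs past the chromosome bounds contribute only to
    the bins they cover (per-bin denominators adjusted).
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    if half_window % bin_width != 0:
        raise ValueError("half_window must be a multiple of bin_width")
    profiles = np.stack(
        [
            single_anchor_profile(
                p.interval.chrom, p.interval.midpoint, track, half_window, bin_width
            )
            for p in anchors
        ]
    )
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(profiles, axis=0)
    offsets = np.arange(-half_window, half_window, bin_width)
    return ProfileMatrix(offsets, mean, half_window, bin_width, len(anchors))


def frip(read_intervals: Sequence[GenomicInterval], peaks: PeakSet) -> float:
    """Fraction of reads overlapping any peak by >= 1 bp.

    Reads are interval spans (BED records), not alignment-file records.
    """
    if not read_intervals:
        raise ValueError("FRiP requires at least one read")
    if len(peaks) == 0:
        return 0.0
    merged = _merged_arrays(peaks.intervals())
    n_in = 0
    for r in read_intervals:
        arrs = merged.get(r.chrom)
        if arrs is not None and _overlaps_any(r, arrs[0], arrs[1], 1):
            n_in += 1
    return n_in / len(read_intervals)
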