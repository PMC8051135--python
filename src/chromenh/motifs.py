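"""PWM scanning at a relative-score threshold and motif-density profiles.

Relative score follows the JASPAR convention: rel = (score - min) / (max -
min) over the per-position log-odds extrema, and the paper-style "80%
threshold" keeps windows with rel >= 0.8. Density profiles count motif-hit
centers in offset bins around classified binding sites; overlapping hits
all count (density, not annotation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .model import PeakSet
from .peaks import ProfileMatrix
from .pwm import PWM

_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float  # log-odds, bits
    rel_score: float


def _window_scores(codes: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand scores for every window; (scores, valid) arrays."""
    L = len(pwm)
    if len(codes) < L:
        return np.empty(0), np.empty(0, bool)
    lo = pwm.log_odds()
    lo_pad = np.vstack([lo.T, np.zeros(len(pwm))])  # row 4: N placeholder
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~(win == 4).any(axis=1)
    scores = lo_pad[win, np.arange(L)].sum(axis=1)
    return scores, valid


def scan_encoded(
    codes: np.ndarray,
    pwm: PWM,
    rel_threshold: float = 0.8,
    both_strands: bool = True,
) -> list[tuple[int, str, float, float]]:
    """Scan encoded sequence; returns (window_start, strand, score, rel)."""
    if not 0 < rel_threshold <= 1:
        raise ValueError(f"rel_threshold must be in (0, 1], got {rel_threshold}")
    smin, smax = pwm.score_bounds()
    span = smax - smin
    hits: list[tuple[int, str, float, float]] = []
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    for strand, mat in strands:
        scores, valid = _window_scores(codes, mat)
        if len(scores) == 0:
            continue
        if span <= 0:
            # degenerate PWM: every score equals the maximum
            rel = np.ones_like(scores)
        else:
            rel = (scores - smin) / span
        keep = valid & (rel >= rel_threshold)
        for i in np.flatnonzero(keep):
            hits.append((int(i), strand, float(scores[i]), float(rel[i])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def scan_sequence(
    seq: str,
    pwm: PWM,
    rel_threshold: float = 0.8,
    both_strands: bool = True,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """All windows of ``seq`` scoring >= ``rel_threshold`` relative score.

    Reverse-strand hits are reported on forward-strand coordinates. Windows
    containing N are skipped. A sequence shorter than the motif yields an
    empty list.
    """
    codes = encode_sequence(seq)
    L = len(pwm)
    return [
        MotifHit(pwm.motif_id, chrom, offset + i, offset + i + L, strand, score, rel)
        for i, strand, score, rel in scan_encoded(codes, pwm, rel_threshold, both_strands)
    ]


GenomeLike = Mapping[str, Union[str, np.ndarray]]


def _genome_codes(genome: GenomeLike) -> dict[str, np.ndarray]:
    return {
        c: (s if isinstance(s, np.ndarray) else encode_sequence(s))
        for c, s in genome.items()
    }


def motif_density_profile(
    sites: PeakSet,
    genome: GenomeLike,
    pwm: PWM,
    labels: Optional[Sequence[str]] = None,
    half_window: int = 500,
    bin_width: int = 10,
    rel_threshold: float = 0.8,
    both_strands: bool = True,
) -> dict[str, ProfileMatrix]:
    """Motif-hit density (hits per bp per site) around site midpoints.

    One profile per site-class label (a single "all" profile when labels are
    omitted). Hit positions are motif-window centers; windows that run past
    chromosome bounds are clipped with per-bin denominators adjusted.
    """
    if half_window % bin_width != 0:
        raise ValueError("half_window must be a multiple of bin_width")
    if labels is not None and len(labels) != len(sites):
        raise ValueError("labels must align with sites")
    codes = _genome_codes(genome)
    n_bins = 2 * half_window // bin_width
    offsets = np.arange(-half_window, half_window, bin_width)
    counts: dict[str, np.ndarray] = {}
    covered: dict[str, np.ndarray] = {}
    n_anchors: dict[str, int] = {}
    L = len(pwm)
    for k, peak in enumerate(sites):
        label = "all" if labels is None else labels[k]
        if label not in counts:
            counts[label] = np.zeros(n_bins)
            covered[label] = np.zeros(n_bins)
            n_anchors[label] = 0
        n_anchors[label] += 1
        iv = peak.interval
        chrom_codes = codes.get(iv.chrom)
        if chrom_codes is None:
            raise KeyError(f"site chromosome {iv.chrom!r} absent from genome")
        mid = iv.midpoint
        lo = max(mid - half_window, 0)
        hi = min(mid + half_window, len(chrom_codes))
        # per-bin covered bases for this (possibly clipped) window
        bin_lo = np.maximum(offsets + mid, lo)
        bin_hi = np.minimum(offsets + bin_width + mid, hi)
        covered[label] += np.maximum(bin_hi - bin_lo, 0)
        if hi - lo < L:
            continue
        for i, strand, score, rel in scan_encoded(
            chrom_codes[lo:hi], pwm, rel_threshold, both_strands
        ):
            center = lo + i + L // 2
            b = (center - mid + half_window) // bin_width
            if 0 <= b < n_bins:
                counts[label][b] += 1
    out = {}
    for label in counts:
        with np.errstate(divide="ignore", invalid="ignore"):
            density = np.where(covered[label] > 0, counts[label] / covered[label], 0.0)
        out[label] = ProfileMatrix(
            offsets.copy(), density, half_window, bin_width, n_anchors[label]
        )
    return out


def hits_to_bed_rows(hits: Sequence[MotifHit]) -> list[str]:
    """BED6 rows for motif hits (score = 1000 * rel_score, integer)."""
    return [
        f"{h.chrom}\t{h.start}\t{h.end}\t{h.motif_id}\t{int(round(1000 * h.rel_score))}\t{h.strand}"
        for h in sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))
    ]
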