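"""Position weight matrices and log-odds scoring bounds.

A PWM holds per-position probabilities over {A, C, G, T} plus a background
distribution. PWMs built from count matrices (JASPAR PFMs) receive a
pseudocount of 0.25 per cell before normalization so every probability is
strictly positive and log-odds scores stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

ALPHABET = "ACGT"
DEFAULT_BACKGROUND = np.full(4, 0.25)
DEFAULT_PSEUDOCOUNT = 0.25


@dataclass
class PWM:
    motif_id: str
    matrix: np.ndarray  # (length, 4) probabilities, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())
    counts: Optional[np.ndarray] = None  # original PFM counts, if any

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise ValueError("PWM matrix must have shape (length >= 1, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: Optional[np.ndarray] = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (length, 4)")
        if (counts < 0).any():
            raise ValueError("counts must be >= 0")
        padded = counts + pseudocount
        matrix = padded / padded.sum(axis=1, keepdims=True)
        bg = DEFAULT_BACKGROUND.copy() if background is None else background
        return cls(motif_id, matrix, bg, counts=counts)

    @classmethod
    def from_consensus(
        cls, motif_id: str, consensus: str, consensus_weight: float = 0.97
    ) -> "PWM":
        """Sharp synthetic PWM concentrated on one consensus sequence."""
        off = (1.0 - consensus_weight) / 3.0
        matrix = np.full((len(consensus), 4), off)
        for i, base in enumerate(consensus.upper()):
            matrix[i, ALPHABET.index(base)] = consensus_weight
        return cls(motif_id, matrix)

    def log_odds(self) -> np.ndarray:
        """(length, 4) matrix of log2(p / background), in bits."""
        if (self.matrix <= 0).any():
            raise ValueError(
                f"PWM {self.motif_id} has zero-probability cells; "
                "apply a pseudocount when building from counts"
            )
        return np.log2(self.matrix / self.background)

    def score_bounds(self) -> tuple[float, float]:
        """(min_score, max_score) of the log-odds score over all sequences.

        Positions are independent, so the extrema are the sums of the
        per-position column minima and maxima.
        """
        lo = self.log_odds()
        return float(lo.min(axis=1).sum()), float(lo.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
        )


def pwm_score_bounds(pwm: PWM) -> tuple[float, float]:
    """Module-level alias for :meth:`PWM.score_bounds`."""
    return pwm.score_bounds()
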