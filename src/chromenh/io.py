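"""Readers and writers for every file dialect the pipeline touches.

Dialects: BED3/BED6, ChromHMM-style segmentation BED (4th column "E<k>"),
gene table TSV, expression TSV, JASPAR PFM, FASTA, bedGraph. All writers
emit tab separators, LF line endings, sorted records and no trailing
whitespace, so equal objects produce byte-identical files. Malformed input
lines are reported with their line numbers.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .intervals import GenomicInterval
from .model import (
    ExpressionMatrix,
    GeneRecord,
    Peak,
    PeakSet,
    Segmentation,
    SignalTrack,
    StateSegment,
)
from .pwm import DEFAULT_PSEUDOCOUNT, PWM

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file; message carries offending line numbers."""


def _lines(path: PathLike):
    with open(path, "rt", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.strip():
                yield lineno, line


def _parse_coords(path, lineno, fields):
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0 or start >= end:
        raise FormatError(
            f"{path}:{lineno}: invalid interval {chrom}:{start}-{end} "
            "(require 0 <= start < end)"
        )
    return GenomicInterval(chrom, start, end)


# ---------------------------------------------------------------- BED3/BED6


def read_bed(path: PathLike, label: str | None = None) -> PeakSet:
    """Read BED3 or BED6 into a PeakSet (label defaults to the file stem)."""
    peaks = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        iv = _parse_coords(path, lineno, fields)
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
        peaks.append(Peak(iv, name=name, score=score))
    return PeakSet(label or Path(path).stem, peaks)


def write_bed(path: PathLike, peaks: PeakSet, bed6: bool = True) -> None:
    rows = []
    for p in sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)):
        iv = p.interval
        if bed6:
            score = "." if p.score is None else format(p.score, "g")
            rows.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name or '.'}\t{score}\t.")
        else:
            rows.append(f"{iv.chrom}\t{iv.start}\t{iv.end}")
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ------------------------------------------------------- segmentation BED

_STATE_RE = re.compile(r"^E(\d+)$")


def read_segmentation(
    path: PathLike, state_count: int = 11, resolution: int = 200
) -> Segmentation:
    """Read a ChromHMM segments BED (chrom, start, end, "E<k>").

    Requires per-chromosome sorted, non-overlapping records; violations are
    reported with their line numbers.
    """
    segments = []
    last_seen: dict[str, tuple[int, int]] = {}  # chrom -> (end, lineno)
    bad_order: list[str] = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        iv = _parse_coords(path, lineno, fields)
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: missing state label column")
        m = _STATE_RE.match(fields[3])
        if not m:
            raise FormatError(f"{path}:{lineno}: unknown state label {fields[3]!r}")
        state = int(m.group(1))
        if not 1 <= state <= state_count:
            raise FormatError(
                f"{path}:{lineno}: state {state} outside 1..{state_count}"
            )
        if iv.chrom in last_seen and iv.start < last_seen[iv.chrom][0]:
            bad_order.append(
                f"line {lineno} (overlaps or precedes line {last_seen[iv.chrom][1]})"
            )
        last_seen[iv.chrom] = (iv.end, lineno)
        segments.append(StateSegment(iv, state))
    if bad_order:
        raise FormatError(f"{path}: unsorted segmentation: " + "; ".join(bad_order))
    return Segmentation(segments, state_count=state_count, resolution=resolution)


def write_segmentation(path: PathLike, seg: Segmentation) -> None:
    rows = [
        f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\tE{s.state}"
        for s in seg.segments()
    ]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ------------------------------------------------------------- gene table


def read_genes(path: PathLike) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: gene table must have columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene ids: {dups[:5]}")
    return [
        GeneRecord(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss))
        for r in df.itertuples()
    ]


def write_genes(path: PathLike, genes: Iterable[GeneRecord]) -> None:
    rows = ["gene_id\tchrom\tstrand\ttss"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
        rows.append(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}")
    Path(path).write_text("\n".join(rows) + "\n")


# ------------------------------------------------------------- expression


def read_expression(path: PathLike) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be gene_id")
    df = df.set_index("gene_id")
    arr = df.to_numpy()
    if (arr < 0).any():
        bad = df.index[(arr < 0).any(axis=1)].tolist()
        raise FormatError(f"{path}: negative FPKM for genes {bad[:5]}")
    return ExpressionMatrix(df)


def write_expression(path: PathLike, expr: ExpressionMatrix) -> None:
    df = expr.fpkm.sort_index()
    with open(path, "wt", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")


# ------------------------------------------------------------- JASPAR PFM


def read_jaspar(
    path: PathLike, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> list[PWM]:
    """Read JASPAR PFM count matrices into PWMs.

    Counts are normalized per position after adding ``pseudocount`` to
    every cell, so all probabilities are strictly positive.
    """
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
        motif_id = m.matrix_id or m.name
        if m.matrix_id and m.name and m.name != m.matrix_id:
            motif_id = f"{m.matrix_id} {m.name}"
        pwms.append(PWM.from_counts(motif_id, counts, pseudocount=pseudocount))
    return pwms


def _format_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_jaspar(path: PathLike, pwms: Iterable[PWM]) -> None:
    chunks = []
    for pwm in pwms:
        counts = pwm.counts
        if counts is None:
            raise ValueError(f"PWM {pwm.motif_id} has no count matrix to write")
        chunks.append(f">{pwm.motif_id}")
        for j, base in enumerate("ACGT"):
            vals = " ".join(_format_count(c) for c in counts[:, j])
            chunks.append(f"{base} [ {vals} ]")
    Path(path).write_text("\n".join(chunks) + "\n")


# ------------------------------------------------------------------ FASTA


def read_fasta(path: PathLike) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    for _, line in _lines(path):
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(parts)
            name = line[1:].split()[0]
            parts = []
        else:
            if name is None:
                raise FormatError(f"{path}: sequence data before first header")
            parts.append(line.strip().upper())
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def write_fasta(path: PathLike, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "wt", newline="\n") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------- bedGraph


def read_bedgraph(path: PathLike) -> SignalTrack:
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        iv = _parse_coords(path, lineno, fields)
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: missing value column")
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
    steps = {}
    for chrom, recs in by_chrom.items():
        recs.sort()
        steps[chrom] = (
            np.array([r[0] for r in recs], dtype=np.int64),
            np.array([r[1] for r in recs], dtype=np.int64),
            np.array([r[2] for r in recs], dtype=float),
        )
    return SignalTrack(steps)


def write_bedgraph(path: PathLike, track: SignalTrack) -> None:
    with open(path, "wt", newline="\n") as fh:
        for chrom in sorted(track.chromosomes):
            starts, ends, values = track.steps(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")
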