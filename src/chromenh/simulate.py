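"""Synthetic paired-condition datasets with planted, ground-truth structure.

The generator emulates the study design the pipeline targets: two cell
states (a progenitor and a differentiated thyrotrope-like condition), each
with an 11-state chromatin segmentation at 200-bp resolution, TF peak sets
with shared/unique structure placed with respect to chromatin state,
log-normal FPKM with a planted promoter-binding expression boost, a
signature gene set relocated near differentiated-condition stretch
enhancers, a random genome with motif consensi planted at binding-site
centers, and triangular-bump signal tracks.

Every component draws from its own seeded stream, so the full dataset is a
pure function of the configuration and changing one component's parameters
does not perturb the others.

Default dwell probabilities of the enhancer states (0.818 / 0.838 per
200-bp bin) make merged enhancer runs exceed 3 kb with probability ~4.9%
and ~7.1% in the two conditions — the stretch-enhancer fractions the
pipeline is expected to report.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as chio
from .enhancers import EnhancerSet, call_enhancers
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
from .peaks import SiteClass, transition_class
from .pwm import PWM

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_MOTIF_CONSENSUS = {
    "pou_like": "TATGCAAAT",  # POU/homeodomain octamer-like
    "bzip_like": "TTGACTCAATC",  # AP-1-like TGACTCA core with flanks
    "hth_like": "GTTGCCATGGCAAC",  # RFX-like palindromic X-box
    "bhlh_like": "AACAGCTGTT",  # E-box CAGCTG core with flanks
}

# which site population each family is planted in
PLANT_RULES = [
    ("pou_like", "all"),
    ("bzip_like", "a_only"),
    ("hth_like", "repressed_to_active"),
    ("bhlh_like", "repressed_to_active"),
]


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    bin_size: int = 200
    state_count: int = 11
    enhancer_states: tuple = (2, 3)
    active_states: tuple = (1, 2, 3, 4, 5, 6)
    conditions: tuple = ("progenitor", "thyrotrope")
    # Markov-chain parameters (per 200-bp bin)
    enhancer_stay_prob: tuple = (0.818, 0.838)  # per condition
    enhancer_entry_prob: float = 0.028
    state_stay_prob: float = 0.55
    # enhancer calling
    max_gap: int = 1
    stretch_min_bp: int = 3000
    # genes and expression
    n_genes: int = 1500
    fpkm_log_mean: float = 1.0  # natural-log scale
    fpkm_log_sd: float = 1.5
    fpkm_condition_sd: float = 0.4
    promoter_bound_boost: float = 4.0
    bound_fraction: float = 0.1
    signature_set_size: int = 25
    signature_window: int = 50_000
    # peaks
    n_sites: int = 4000
    peak_class_probs: tuple = (0.4, 0.3, 0.3)  # shared, a_only, b_only
    state_preference_prob: float = 0.9
    peak_width_mean: float = 400.0
    peak_width_sd: float = 100.0
    peak_width_min: int = 150
    peak_width_max: int = 750
    min_site_separation: int = 800
    # sequence and motifs
    motif_plant_prob: float = 0.5
    motif_consensus: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_CONSENSUS))
    motif_consensus_weight: float = 0.97
    # signal tracks
    track_height: float = 4.0
    track_half_width: int = 250
    track_baseline: float = 0.1
    track_step: int = 5

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are supported")
        if any(v < 0 for v in (self.n_genes, self.n_sites, self.signature_set_size)):
            raise ValueError("counts must be >= 0")
        if not math.isclose(sum(self.peak_class_probs), 1.0, abs_tol=1e-9):
            raise ValueError("peak_class_probs must sum to 1")

    def motif_families(self) -> dict[str, PWM]:
        return {
            name: PWM.from_consensus(name, consensus, self.motif_consensus_weight)
            for name, consensus in self.motif_consensus.items()
        }

    def transition_matrix(self, condition: str) -> np.ndarray:
        """Row-stochastic state-transition matrix for one condition."""
        ci = self._condition_index(condition)
        S = self.state_count
        enh = [s - 1 for s in self.enhancer_states]
        other = [s for s in range(S) if s not in enh]
        p = self.enhancer_stay_prob[ci]
        q = self.enhancer_entry_prob
        stay = self.state_stay_prob
        m = np.zeros((S, S))
        for s in enh:
            m[s, enh] = p / len(enh)
            m[s, other] = (1 - p) / len(other)
        for s in other:
            m[s, enh] = q / len(enh)
            m[s, s] = stay
            rest = [t for t in other if t != s]
            m[s, rest] = (1 - stay - q) / len(rest)
        return m

    def _condition_index(self, condition: str) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError as exc:
            raise ValueError(
                f"unknown condition {condition!r}; expected one of {self.conditions}"
            ) from exc

    def to_yaml(self) -> str:
        d = asdict(self)
        for key in ("enhancer_states", "active_states", "conditions",
                    "enhancer_stay_prob", "peak_class_probs"):
            d[key] = list(d[key])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        for key in ("enhancer_states", "active_states", "conditions",
                    "enhancer_stay_prob", "peak_class_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


_STREAMS = {
    "segmentation:0": 0,
    "segmentation:1": 1,
    "genes": 2,
    "peaks": 3,
    "sequence": 4,
    "tracks": 5,
}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    )


# ------------------------------------------------------------ segmentation


def simulate_segmentation(
    config: SimulationConfig,
    condition: str,
    initial_state: Optional[int] = None,
) -> Segmentation:
    """First-order Markov chain over chromatin states at bin resolution.

    Runs of equal state are collapsed into segments. A trailing partial bin
    of each chromosome is dropped. Deterministic for a fixed seed and
    condition.
    """
    matrix = np.asarray(config.transition_matrix(condition), dtype=float)
    _check_stochastic(matrix, config.state_count)
    rng = _rng(config, f"segmentation:{config._condition_index(condition)}")
    cum = np.cumsum(matrix, axis=1)
    segments = []
    for chrom in sorted(config.chrom_lengths):
        n_bins = config.chrom_lengths[chrom] // config.bin_size
        if n_bins == 0:
            continue
        states = np.empty(n_bins, dtype=np.int64)
        if initial_state is None:
            states[0] = rng.integers(1, config.state_count + 1)
        else:
            states[0] = initial_state
        u = rng.random(n_bins - 1)
        cur = states[0] - 1
        for i in range(1, n_bins):
            cur = int(np.searchsorted(cum[cur], u[i - 1], side="right"))
            cur = min(cur, config.state_count - 1)  # guard float edge
            states[i] = cur + 1
        # collapse runs
        change = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [n_bins]])
        for s, e in zip(starts, ends):
            segments.append(
                StateSegment(
                    GenomicInterval(
                        chrom, int(s) * config.bin_size, int(e) * config.bin_size
                    ),
                    int(states[s]),
                )
            )
    return Segmentation(
        segments, state_count=config.state_count, resolution=config.bin_size
    )


def _check_stochastic(matrix: np.ndarray, state_count: int) -> None:
    if matrix.shape != (state_count, state_count):
        raise ValueError(f"transition matrix must be {state_count}x{state_count}")
    if (matrix < 0).any() or not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must be >= 0 and sum to 1 (±1e-9)")


# ------------------------------------------------------------------- peaks


def _bin_states(seg: Segmentation, config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-bin state array per chromosome (0 where unmarked)."""
    out = {}
    for chrom in sorted(config.chrom_lengths):
        n_bins = config.chrom_lengths[chrom] // config.bin_size
        arr = np.zeros(n_bins, dtype=np.int64)
        starts, ends, states = seg.arrays(chrom)
        for s, e, st in zip(starts, ends, states):
            arr[s // config.bin_size : e // config.bin_size] = st
        out[chrom] = arr
    return out


def simulate_peaks(
    config: SimulationConfig, seg_a: Segmentation, seg_b: Segmentation
) -> tuple[PeakSet, PeakSet, pd.DataFrame]:
    """Peak sets for both conditions with ground-truth class labels.

    Sites come in three classes — shared (same interval in both
    conditions), A-only and B-only. Unique-site midpoints fall, with
    probability ``state_preference_prob``, in bins active in their own
    condition and inactive in the other; shared sites prefer bins active in
    both. Site midpoints are kept ``min_site_separation`` apart so the
    planted classes stay recoverable.
    """
    rng = _rng(config, "peaks")
    active = set(config.active_states)
    chroms = sorted(config.chrom_lengths)
    states_a = _bin_states(seg_a, config)
    states_b = _bin_states(seg_b, config)
    margin = 4  # bins held back at chromosome ends so peaks fit
    all_bins, pref = [], {"shared": [], "a_only": [], "b_only": []}
    for chrom in chroms:
        sa, sb = states_a[chrom], states_b[chrom]
        a_act = np.isin(sa, list(active))
        b_act = np.isin(sb, list(active))
        n = len(sa)
        ok = np.zeros(n, dtype=bool)
        ok[margin : n - margin] = True
        for b in np.flatnonzero(ok):
            all_bins.append((chrom, int(b)))
        for b in np.flatnonzero(ok & a_act & b_act):
            pref["shared"].append((chrom, int(b)))
        for b in np.flatnonzero(ok & a_act & ~b_act):
            pref["a_only"].append((chrom, int(b)))
        for b in np.flatnonzero(ok & b_act & ~a_act):
            pref["b_only"].append((chrom, int(b)))

    classes = ["shared", "a_only", "b_only"]
    drawn = [classes[i] for i in rng.choice(3, size=config.n_sites, p=config.peak_class_probs)]

    chosen_mids: dict[str, list[int]] = {c: [] for c in chroms}

    def place(klass: str) -> tuple[str, int]:
        for _ in range(2000):
            pool = pref[klass] if (pref[klass] and rng.random() < config.state_preference_prob) else all_bins
            if not pool:
                break
            chrom, b = pool[int(rng.integers(len(pool)))]
            mid = b * config.bin_size + config.bin_size // 2
            mids = chosen_mids[chrom]
            i = bisect.bisect_left(mids, mid)
            if i > 0 and mid - mids[i - 1] < config.min_site_separation:
                continue
            if i < len(mids) and mids[i] - mid < config.min_site_separation:
                continue
            mids.insert(i, mid)
            return chrom, mid
        raise ValueError(
            f"could not place a {klass} site: requested peak count exceeds "
            "available eligible bins"
        )

    rows = []
    for k, klass in enumerate(drawn):
        chrom, mid = place(klass)
        w = int(np.clip(round(rng.normal(config.peak_width_mean, config.peak_width_sd)),
                        config.peak_width_min, config.peak_width_max))
        start = mid - w // 2
        end = start + w
        sa = int(states_a[chrom][mid // config.bin_size])
        sb = int(states_b[chrom][mid // config.bin_size])
        trans = transition_class(
            klass if klass != "shared" else "shared",
            sa if sa else "unmarked",
            sb if sb else "unmarked",
            frozenset(active),
        )
        rows.append(
            {
                "site_id": f"S{k:05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "midpoint": mid,
                "width": w,
                "klass": klass,
                "state_a": sa,
                "state_b": sb,
                "transition": trans.value,
            }
        )
    truth = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    def peakset(label: str, keep: Sequence[str]) -> PeakSet:
        sub = truth[truth["klass"].isin(keep)]
        return PeakSet(
            label,
            [
                Peak(GenomicInterval(r.chrom, int(r.start), int(r.end)), name=r.site_id)
                for r in sub.itertuples()
            ],
        )

    peaks_a = peakset(config.conditions[0], ["shared", "a_only"])
    peaks_b = peakset(config.conditions[1], ["shared", "b_only"])
    return peaks_a, peaks_b, truth


# ------------------------------------------------------ genes + expression


def simulate_genes_expression(
    config: SimulationConfig,
    enhancer_sets: Mapping[str, EnhancerSet],
) -> tuple[list[GeneRecord], ExpressionMatrix, dict]:
    """Genes with uniform TSSs, log-normal FPKM and planted effects.

    A random ``bound_fraction`` of genes has its differentiated-condition
    FPKM multiplied by ``promoter_bound_boost``; ``signature_set_size``
    genes are relocated so each TSS lies within ``signature_window`` of a
    distinct differentiated-condition stretch enhancer. The truth dict
    records every planted membership.
    """
    rng = _rng(config, "genes")
    cond_a, cond_b = config.conditions
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    n = config.n_genes
    chrom_idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    tss = np.array(
        [rng.integers(0, config.chrom_lengths[chroms[i]]) for i in chrom_idx]
    )
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    base = rng.normal(config.fpkm_log_mean, config.fpkm_log_sd, size=n)
    eps_a = rng.normal(0.0, config.fpkm_condition_sd, size=n)
    eps_b = rng.normal(0.0, config.fpkm_condition_sd, size=n)
    fpkm_a = np.exp(base + eps_a)
    fpkm_b = np.exp(base + eps_b)

    n_bound = int(round(config.bound_fraction * n))
    bound_idx = rng.choice(n, size=n_bound, replace=False)
    fpkm_b[bound_idx] *= config.promoter_bound_boost

    signature_idx = np.empty(0, dtype=np.int64)
    assignment: dict[str, str] = {}
    if config.signature_set_size > 0:
        stretch = enhancer_sets[cond_b].stretch()
        if len(stretch) < config.signature_set_size:
            raise ValueError(
                f"{len(stretch)} stretch enhancers available but "
                f"{config.signature_set_size} needed for the signature set"
            )
        signature_idx = rng.choice(n, size=config.signature_set_size, replace=False)
        enh_pick = rng.choice(
            len(stretch), size=config.signature_set_size, replace=False
        )
        for gi, ei in zip(signature_idx, enh_pick):
            iv = stretch[ei].interval
            lo = max(0, iv.start - config.signature_window)
            hi = min(config.chrom_lengths[iv.chrom] - 1, iv.end - 1 + config.signature_window)
            chrom_idx[gi] = chroms.index(iv.chrom)
            tss[gi] = rng.integers(lo, hi + 1)
            assignment[f"G{gi:05d}"] = f"{iv.chrom}:{iv.start}-{iv.end}"

    genes = [
        GeneRecord(f"G{i:05d}", chroms[chrom_idx[i]], strands[i], int(tss[i]))
        for i in range(n)
    ]
    expr = ExpressionMatrix(
        pd.DataFrame(
            {cond_a: fpkm_a, cond_b: fpkm_b},
            index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        )
    )
    truth = {
        "bound_ids": sorted(f"G{i:05d}" for i in bound_idx),
        "signature_ids": sorted(f"G{i:05d}" for i in signature_idx),
        "signature_enhancers": assignment,
    }
    return genes, expr, truth


# --------------------------------------------------------- genome + motifs


def simulate_sequences_motifs(
    config: SimulationConfig, sites: pd.DataFrame
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with motif consensi planted at site midpoints.

    Families are planted in the order POU-like (all sites), bZIP-like
    (A-only sites), HTH-like then bHLH-like (repressed-to-active sites),
    each independently with probability ``motif_plant_prob``; a later plant
    overwrites overlapping earlier plants and only survivors are recorded
    in the truth table (offset 0 from the site midpoint).
    """
    rng = _rng(config, "sequence")
    arrays: dict[str, np.ndarray] = {}
    for chrom in sorted(config.chrom_lengths):
        codes = rng.integers(0, 4, size=config.chrom_lengths[chrom], dtype=np.uint8)
        arrays[chrom] = _BASES[codes].copy()

    families = config.motif_families()
    n_skipped = 0
    plants_by_site: dict[str, list[dict]] = {}
    for family, rule in PLANT_RULES:
        if family not in families:
            continue
        consensus = families[family].consensus()
        L = len(consensus)
        planted_bytes = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)
        if rule == "all":
            sel = sites
        elif rule in ("shared", "a_only", "b_only"):
            sel = sites[sites["klass"] == rule]
        else:
            sel = sites[sites["transition"] == rule]
        for r in sel.itertuples():
            if rng.random() >= config.motif_plant_prob:
                continue
            if L > r.width:
                n_skipped += 1
                continue
            start = r.midpoint - L // 2
            arrays[r.chrom][start : start + L] = planted_bytes
            plants_by_site.setdefault(r.site_id, []).append(
                {
                    "site_id": r.site_id,
                    "family": family,
                    "chrom": r.chrom,
                    "start": start,
                    "end": start + L,
                    "offset": 0,
                }
            )
    if n_skipped:
        warnings.warn(f"{n_skipped} motif plants skipped (motif longer than peak)")

    survivors = []
    for site_id, plants in plants_by_site.items():
        # all plants at a site share the midpoint, so any later plant
        # overwrites every earlier one; only the last survives intact
        survivors.append(plants[-1])
    truth = (
        pd.DataFrame(survivors, columns=["site_id", "family", "chrom", "start", "end", "offset"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    genome = {c: a.tobytes().decode("ascii") for c, a in arrays.items()}
    return genome, truth


# ------------------------------------------------------------ signal tracks


def simulate_tracks(
    config: SimulationConfig, peaks: Mapping[str, PeakSet]
) -> dict[str, SignalTrack]:
    """Triangular signal bumps centered on each condition's peak midpoints.

    The triangle (height ``track_height``, half-base ``track_half_width``)
    sits on a flat baseline and is sampled at ``track_step``-bp steps at
    their midpoints, so aggregate-profile bin means have a closed form.
    """
    h, w, step = config.track_height, config.track_half_width, config.track_step
    tracks = {}
    for cond, pset in peaks.items():
        steps: dict[str, tuple[list, list, list]] = {}
        mids: dict[str, list[int]] = {}
        for chrom in sorted(config.chrom_lengths):
            mids[chrom] = []
        for p in pset:
            mids[p.interval.chrom].append(p.interval.midpoint)
        for chrom in sorted(config.chrom_lengths):
            length = config.chrom_lengths[chrom]
            starts: list[int] = []
            ends: list[int] = []
            values: list[float] = []
            cursor = 0
            for mid in sorted(mids[chrom]):
                lo, hi = max(mid - w, 0), min(mid + w, length)
                if lo > cursor:
                    starts.append(cursor)
                    ends.append(lo)
                    values.append(config.track_baseline)
                for s in range(lo, hi, step):
                    e = min(s + step, hi)
                    x = abs((s + e) / 2.0 - mid)
                    starts.append(s)
                    ends.append(e)
                    values.append(config.track_baseline + h * max(0.0, 1.0 - x / w))
                cursor = hi
            if cursor < length:
                starts.append(cursor)
                ends.append(length)
                values.append(config.track_baseline)
            steps[chrom] = (
                np.array(starts, dtype=np.int64),
                np.array(ends, dtype=np.int64),
                np.array(values, dtype=float),
            )
        tracks[cond] = SignalTrack(steps, chrom_lengths=config.chrom_lengths)
    return tracks


# ----------------------------------------------------------- full dataset


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    segmentations: dict[str, Segmentation]
    enhancers: dict[str, EnhancerSet]
    peaks: dict[str, PeakSet]
    sites: pd.DataFrame
    genes: list[GeneRecord]
    expression: ExpressionMatrix
    gene_truth: dict
    genome: Optional[dict[str, str]] = None
    motif_truth: Optional[pd.DataFrame] = None
    tracks: Optional[dict[str, SignalTrack]] = None


def simulate_dataset(
    config: SimulationConfig,
    with_sequence: bool = True,
    with_tracks: bool = True,
) -> SimulatedDataset:
    """Generate the complete paired-condition dataset.

    ``with_sequence`` / ``with_tracks`` skip the genome+motif and
    signal-track components when a caller only needs the interval-level
    parts; the remaining components are unaffected because every component
    owns its own random stream.
    """
    cond_a, cond_b = config.conditions
    seg_a = simulate_segmentation(config, cond_a)
    seg_b = simulate_segmentation(config, cond_b)
    enh = {
        c: call_enhancers(
            s,
            enhancer_states=config.enhancer_states,
            max_gap=config.max_gap,
            stretch_min_bp=config.stretch_min_bp,
            label=c,
        )
        for c, s in ((cond_a, seg_a), (cond_b, seg_b))
    }
    peaks_a, peaks_b, sites = simulate_peaks(config, seg_a, seg_b)
    genes, expr, gene_truth = simulate_genes_expression(config, enh)
    genome = motif_truth = tracks = None
    if with_sequence:
        genome, motif_truth = simulate_sequences_motifs(config, sites)
    if with_tracks:
        tracks = simulate_tracks(config, {cond_a: peaks_a, cond_b: peaks_b})
    return SimulatedDataset(
        config=config,
        segmentations={cond_a: seg_a, cond_b: seg_b},
        enhancers=enh,
        peaks={cond_a: peaks_a, cond_b: peaks_b},
        sites=sites,
        genes=genes,
        expression=expr,
        gene_truth=gene_truth,
        genome=genome,
        motif_truth=motif_truth,
        tracks=tracks,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the dataset to standard text formats (plus truth tables)."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    for cond, seg in ds.segmentations.items():
        chio.write_segmentation(out / f"segmentation_{cond}.bed", seg)
    for cond, eset in ds.enhancers.items():
        pset = PeakSet(
            cond,
            [
                Peak(e.interval, name="stretch" if e.is_stretch else "typical")
                for e in eset
            ],
        )
        chio.write_bed(out / f"enhancers_{cond}.bed", pset)
    for cond, pset in ds.peaks.items():
        chio.write_bed(out / f"peaks_{cond}.bed", pset)
    chio.write_genes(out / "genes.tsv", ds.genes)
    chio.write_expression(out / "expression.tsv", ds.expression)
    if ds.genome is not None:
        chio.write_fasta(out / "genome.fa", ds.genome)
    if ds.tracks is not None:
        for cond, track in ds.tracks.items():
            chio.write_bedgraph(out / f"signal_{cond}.bedgraph", track)
    ds.sites.to_csv(out / "truth" / "sites.tsv", sep="\t", index=False, lineterminator="\n")
    if ds.motif_truth is not None:
        ds.motif_truth.to_csv(
            out / "truth" / "motifs.tsv", sep="\t", index=False, lineterminator="\n"
        )
    gene_rows = []
    for g in ds.genes:
        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "bound": g.gene_id in set(ds.gene_truth["bound_ids"]),
                "signature": g.gene_id in set(ds.gene_truth["signature_ids"]),
                "signature_enhancer": ds.gene_truth["signature_enhancers"].get(
                    g.gene_id, ""
                ),
            }
        )
    pd.DataFrame(gene_rows).to_csv(
        out / "truth" / "genes.tsv", sep="\t", index=False, lineterminator="\n"
    )
    (out / "config.yaml").write_text(ds.config.to_yaml())
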