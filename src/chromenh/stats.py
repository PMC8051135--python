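"""Enrichment and expression statistics.

Centerpiece: an expression-matched permutation test for enrichment of
stretch enhancers near a signature gene set. The observed statistic is the
number of DISTINCT stretch enhancers with at least one signature-gene TSS
within a half-window (default 50 kb each side); the null redraws the gene
set 10,000 times from expression-matched quantile bins and the empirical p
is the plain fraction of null counts >= observed (2/10,000 -> 0.0002), with
the add-one estimate (k+1)/(N+1) reported alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enhancers import Enhancer
from .intervals import GenomicInterval
from .model import ExpressionMatrix, GeneRecord

DEFAULT_HALF_WINDOW = 50_000
DEFAULT_N_BINS = 10
DEFAULT_N_PERMUTATIONS = 10_000


# ------------------------------------------------- proximal enhancer count


class _StretchIndex:
    """Sorted per-chromosome arrays for distinct-enhancer window queries.

    A TSS t lies within ``half_window`` of enhancer [s, e) iff
    s - hw <= t <= e - 1 + hw. Enhancers are disjoint and sorted, so both
    bounds are monotone and the qualifying enhancers for t form a
    contiguous index range found by two searchsorted calls.
    """

    def __init__(self, stretch: Sequence[Enhancer], half_window: int):
        for enh in stretch:
            if not enh.is_stretch:
                raise ValueError(
                    f"non-stretch enhancer in stretch list: {enh.interval}"
                )
        self.half_window = half_window
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for gid, enh in enumerate(stretch):
            iv = enh.interval
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gid))
        for chrom, recs in by_chrom.items():
            recs.sort()
            self._chrom[chrom] = (
                np.array([r[0] - half_window for r in recs], dtype=np.int64),
                np.array([r[1] - 1 + half_window for r in recs], dtype=np.int64),
                np.array([r[2] for r in recs], dtype=np.int64),
            )

    def ids_near(self, chrom: str, tss: int) -> np.ndarray:
        arrs = self._chrom.get(chrom)
        if arrs is None:
            return np.empty(0, dtype=np.int64)
        lo_bounds, hi_bounds, ids = arrs
        lo = int(np.searchsorted(hi_bounds, tss, side="left"))
        hi = int(np.searchsorted(lo_bounds, tss, side="right"))
        return ids[lo:hi]


def count_proximal_stretch_enhancers(
    gene_set: Sequence[GeneRecord],
    stretch: Sequence[Enhancer],
    half_window: int = DEFAULT_HALF_WINDOW,
) -> int:
    """Distinct stretch enhancers with >= 1 gene-set TSS within the window.

    An enhancer near several genes of the set counts once.
    """
    if not gene_set:
        warnings.warn("empty gene set: proximal stretch-enhancer count is 0")
        return 0
    index = _StretchIndex(stretch, half_window)
    seen: set[int] = set()
    for g in gene_set:
        seen.update(index.ids_near(g.chrom, g.tss).tolist())
    return len(seen)


# ------------------------------------------------ expression-matched draws


def quantile_bins(values: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Quantile-bin ids (0..n_bins-1) for a vector of values."""
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def _match_expression(
    expr: ExpressionMatrix, condition: str, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """(gene_ids array, bin id per gene) on log10(FPKM + 1)."""
    ids = np.array(expr.gene_ids)
    vals = np.log10(expr.values(condition) + 1.0)
    return ids, quantile_bins(vals, n_bins)


def expression_matched_sample(
    expr: ExpressionMatrix,
    target_ids: Sequence[str],
    condition: str,
    n_bins: int = DEFAULT_N_BINS,
    rng: Optional[np.random.Generator] = None,
) -> list[str]:
    """Draw a non-target gene set with the target's exact bin occupancy.

    Universe genes are binned into ``n_bins`` quantile bins of
    log10(FPKM + 1) in ``condition``; for each target gene one non-target
    gene is drawn uniformly without replacement from the same bin.
    """
    rng = rng or np.random.default_rng()
    target = set(target_ids)
    if len(expr.gene_ids) < 2 * len(target):
        raise ValueError("universe must hold at least twice the target set")
    missing = target - set(expr.gene_ids)
    if missing:
        raise ValueError(f"target genes absent from universe: {sorted(missing)[:5]}")
    ids, bins = _match_expression(expr, condition, n_bins)
    is_target = np.isin(ids, list(target))
    target_bins = bins[is_target]
    sampled: list[str] = []
    for b in np.unique(target_bins):
        need = int((target_bins == b).sum())
        pool = ids[(bins == b) & ~is_target]
        if len(pool) < need:
            raise ValueError(
                f"expression bin {int(b)} has {len(pool)} non-target genes "
                f"but {need} are needed"
            )
        sampled.extend(rng.choice(pool, size=need, replace=False).tolist())
    return sampled


# --------------------------------------------------------- permutation test


def empirical_pvalue(observed: int, null_counts: Sequence[int]) -> float:
    """Plain empirical p: fraction of null counts >= observed."""
    null = np.asarray(null_counts)
    if len(null) == 0:
        raise ValueError("empty null distribution")
    return float((null >= observed).sum() / len(null))


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    n_permutations: int
    empirical_p: float
    add_one_p: float  # (k + 1) / (N + 1), the statistically safer estimate
    seed: int
    parameters: dict = field(default_factory=dict)

    def null_histogram(self) -> pd.DataFrame:
        vals, cnts = np.unique(self.null_counts, return_counts=True)
        return pd.DataFrame({"count": vals, "n_permutations": cnts})


def permutation_enrichment_test(
    target_ids: Sequence[str],
    genes: Sequence[GeneRecord],
    expr: ExpressionMatrix,
    stretch: Sequence[Enhancer],
    condition: str,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    half_window: int = DEFAULT_HALF_WINDOW,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
) -> PermutationResult:
    """Expression-matched permutation test for stretch-enhancer proximity.

    Observed: distinct stretch enhancers within ``half_window`` of any
    target-gene TSS. Null: ``n_permutations`` expression-matched gene sets
    of the same size, each counted the same way. Reproducible under a fixed
    seed, including the null counts.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in genes}
    target_genes = [gene_by_id[t] for t in target_ids]
    index = _StretchIndex(stretch, half_window)

    def count(gene_records: Iterable[GeneRecord]) -> int:
        seen: set[int] = set()
        for g in gene_records:
            seen.update(index.ids_near(g.chrom, g.tss).tolist())
        return len(seen)

    observed = count(target_genes)

    # precompute matching structures once; per-permutation work is cheap
    ids, bins = _match_expression(expr, condition, n_bins)
    if len(ids) < 2 * len(target_ids):
        raise ValueError("universe must hold at least twice the target set")
    is_target = np.isin(ids, list(target_ids))
    if is_target.sum() != len(set(target_ids)):
        missing = set(target_ids) - set(ids)
        raise ValueError(f"target genes absent from universe: {sorted(missing)[:5]}")
    target_bins = bins[is_target]
    pools = []
    for b in np.unique(target_bins):
        need = int((target_bins == b).sum())
        pool_ids = ids[(bins == b) & ~is_target]
        if len(pool_ids) < need:
            raise ValueError(
                f"expression bin {int(b)} has {len(pool_ids)} non-target genes "
                f"but {need} are needed"
            )
        # cache per-gene enhancer-id hit lists for the pool
        pool_hits = [
            index.ids_near(gene_by_id[g].chrom, gene_by_id[g].tss) for g in pool_ids
        ]
        pools.append((need, pool_hits))

    null_counts = np.empty(n_permutations, dtype=np.int64)
    for it in range(n_permutations):
        seen: set[int] = set()
        for need, pool_hits in pools:
            for j in rng.choice(len(pool_hits), size=need, replace=False):
                hits = pool_hits[j]
                if len(hits):
                    seen.update(hits.tolist())
        null_counts[it] = len(seen)

    k = int((null_counts >= observed).sum())
    p = k / n_permutations
    if k == 0:
        warnings.warn(
            "no null count reached the observed statistic; the plain empirical "
            "p is 0.0 — prefer the add-one estimate"
        )
    return PermutationResult(
        observed=observed,
        null_counts=null_counts,
        n_permutations=n_permutations,
        empirical_p=p,
        add_one_p=(k + 1) / (n_permutations + 1),
        seed=seed,
        parameters={
            "half_window": half_window,
            "n_bins": n_bins,
            "set_size": len(target_ids),
            "condition": condition,
        },
    )


# --------------------------------------------------- expression comparisons


def bound_vs_unbound_expression_test(
    expr: ExpressionMatrix, bound_ids: Sequence[str], condition: str
) -> tuple[float, float]:
    """Mann-Whitney U (two-sided) on FPKM of bound vs unbound genes.

    Exact distribution when both groups have <= 20 observations and no ties
    span the groups; otherwise the normal approximation with tie correction
    (no continuity correction).
    """
    bound = set(bound_ids)
    x = expr.values(condition, [g for g in expr.gene_ids if g in bound])
    y = expr.values(condition, [g for g in expr.gene_ids if g not in bound])
    return mannwhitney_u(x, y)


def mannwhitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        # every observation identical: U at its mean, no evidence either way
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if max(len(x), len(y)) <= 20 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def group_expression_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA: (F, p) from F(k-1, n-k).

    Degenerate all-equal input (zero variance everywhere, equal means)
    returns F = 0, p = 1 with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        warnings.warn("all observations identical: F undefined, reporting p = 1")
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def nearest_gene_log2fc(
    enhancers: Sequence[Enhancer],
    labels: Sequence[str],
    genes: Sequence[GeneRecord],
    expr: ExpressionMatrix,
    cond_numerator: str,
    cond_denominator: str,
) -> dict[str, list[float]]:
    """log2 fold-change of the gene nearest each enhancer, grouped by label.

    Nearest = minimal TSS-to-interval distance; ties break to the
    lexicographically smaller gene_id. log2fc uses a pseudocount of 1.
    """
    if not genes:
        raise ValueError("empty gene list")
    if len(labels) != len(enhancers):
        raise ValueError("labels must align with enhancers")
    lfc = expr.log2fc(cond_numerator, cond_denominator)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (g.tss, g.gene_id))
    out: dict[str, list[float]] = {}
    for enh, label in zip(enhancers, labels):
        iv = enh.interval
        cands = by_chrom.get(iv.chrom)
        if cands is None:
            continue
        tss_arr = np.array([g.tss for g in cands], dtype=np.int64)
        # nearest TSS: inside the interval -> distance 0; otherwise flanks
        lo = int(np.searchsorted(tss_arr, iv.start, side="left"))
        hi = int(np.searchsorted(tss_arr, iv.end - 1, side="right"))
        candidates = []
        if lo < hi:  # at least one TSS inside the interval
            candidates.extend(cands[lo:hi])
        if lo > 0:
            candidates.append(cands[lo - 1])
        if hi < len(cands):
            candidates.append(cands[hi])
        best = min(
            candidates,
            key=lambda g: (_point_distance(iv, g.tss), g.gene_id),
        )
        out.setdefault(label, []).append(float(lfc[best.gene_id]))
    return out


def _point_distance(iv: GenomicInterval, tss: int) -> int:
    if iv.start <= tss < iv.end:
        return 0
    return iv.start - tss if tss < iv.start else tss - (iv.end - 1)


def select_top_percent_de(
    expr: ExpressionMatrix,
    cond_numerator: str,
    cond_denominator: str,
    percent: float = 5.0,
    direction: str = "up",
) -> list[str]:
    """Top-percent genes by log2 fold-change among expressed genes.

    Expressed = FPKM > 0 in either condition; returns the
    ceil(percent/100 * n_expressed) genes with the most extreme log2fc in
    the requested direction ("up": numerator-elevated; "down": the reverse).
    """
    if not 0 < percent < 100:
        raise ValueError(f"percent must be in (0, 100), got {percent}")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    fpkm = expr.fpkm
    expressed = fpkm[(fpkm[cond_numerator] > 0) | (fpkm[cond_denominator] > 0)]
    lfc = np.log2((expressed[cond_numerator] + 1) / (expressed[cond_denominator] + 1))
    n = math.ceil(percent / 100.0 * len(expressed))
    ordered = lfc.sort_values(ascending=(direction == "down"), kind="stable")
    return ordered.index[:n].tolist()


# ------------------------------------------------------------- proportions


@dataclass(frozen=True)
class ProportionReport:
    numerator: int
    denominator: int
    percent: int  # round-half-up integer percent


def costain_proportions(n_double: int, n_marker: int) -> ProportionReport:
    """Integer percent of double-positive cells, round-half-up (8/26 -> 31)."""
    if n_marker < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= n_double <= n_marker:
        raise ValueError("numerator must satisfy 0 <= numerator <= denominator")
    percent = int(math.floor(100.0 * n_double / n_marker + 0.5))
    return ProportionReport(n_double, n_marker, percent)
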