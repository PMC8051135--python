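"""Enrichment statistics: counting, matching, permutation, rank tests."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chromenh.enhancers import Enhancer
from chromenh.intervals import GenomicInterval, min_distance
from chromenh.model import ExpressionMatrix, GeneRecord
from chromenh.stats import (
    bound_vs_unbound_expression_test,
    costain_proportions,
    count_proximal_stretch_enhancers,
    empirical_pvalue,
    expression_matched_sample,
    group_expression_anova,
    mannwhitney_u,
    nearest_gene_log2fc,
    permutation_enrichment_test,
    select_top_percent_de,
)
from chromenh.simulate import SimulationConfig, simulate_genes_expression


def stretch(triples):
    return [Enhancer(GenomicInterval(c, s, e), is_stretch=True) for c, s, e in triples]


def gene(gid, chrom, tss):
    return GeneRecord(gid, chrom, "+", tss)


class TestProximalCount:
    def test_window_boundary(self):
        enh = stretch([("c1", 0, 1000)])
        # distance to the last covered base 999: 51000 -> 50001, 50999 -> 50000
        assert count_proximal_stretch_enhancers([gene("G1", "c1", 51_000)], enh) == 0
        assert count_proximal_stretch_enhancers([gene("G1", "c1", 50_999)], enh) == 1

    def test_enhancer_near_two_genes_counts_once(self):
        enh = stretch([("c1", 100_000, 104_000)])
        genes = [gene("G1", "c1", 90_000), gene("G2", "c1", 110_000)]
        assert count_proximal_stretch_enhancers(genes, enh) == 1

    def test_empty_gene_set_warns_zero(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            assert count_proximal_stretch_enhancers([], stretch([("c1", 0, 4000)])) == 0
        assert any("empty gene set" in str(x.message) for x in w)

    def test_non_stretch_input_rejected(self):
        enh = [Enhancer(GenomicInterval("c1", 0, 100), is_stretch=False)]
        with pytest.raises(ValueError, match="non-stretch"):
            count_proximal_stretch_enhancers([gene("G1", "c1", 0)], enh)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(10):
            triples, pos = [], 0
            for _ in range(200):
                pos += int(rng.integers(1000, 40_000))
                w = int(rng.integers(3001, 8000))
                triples.append((f"c{rng.integers(1, 4)}", pos, pos + w))
                pos += w
            enh = stretch(triples)
            genes = [
                gene(f"G{i}", f"c{rng.integers(1, 4)}", int(rng.integers(0, pos)))
                for i in range(50)
            ]
            brute = sum(
                1
                for e in enh
                if any(
                    min_distance(e.interval, g.tss, g.chrom) <= 50_000 for g in genes
                )
            )
            assert count_proximal_stretch_enhancers(genes, enh) == brute


def make_expr(fpkm_b, fpkm_a=None, prefix="G"):
    ids = [f"{prefix}{i:04d}" for i in range(len(fpkm_b))]
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "progenitor": fpkm_a if fpkm_a is not None else fpkm_b,
                "thyrotrope": fpkm_b,
            },
            index=pd.Index(ids, name="gene_id"),
        )
    )


class TestExpressionMatchedSample:
    def test_bin_histogram_matches_exactly(self, rng):
        expr = make_expr(rng.lognormal(1, 1.5, size=400))
        from chromenh.stats import _match_expression

        ids, bins = _match_expression(expr, "thyrotrope", 10)
        target = rng.choice(ids, size=30, replace=False).tolist()
        bin_of = dict(zip(ids, bins))
        want = np.bincount([bin_of[t] for t in target], minlength=10)
        for _ in range(20):
            sample = expression_matched_sample(expr, target, "thyrotrope", rng=rng)
            got = np.bincount([bin_of[s] for s in sample], minlength=10)
            assert (got == want).all()
            assert not set(sample) & set(target)
            assert len(set(sample)) == len(target)

    def test_single_bin_uniformity(self, rng):
        expr = make_expr(np.full(10, 5.0))  # all genes in one bin
        target = [expr.gene_ids[0]]
        counts = {g: 0 for g in expr.gene_ids[1:]}
        for _ in range(9000):
            (s,) = expression_matched_sample(expr, target, "thyrotrope", n_bins=1, rng=rng)
            counts[s] += 1
        p = 1 / 9
        se = np.sqrt(p * (1 - p) / 9000)
        for c in counts.values():
            assert abs(c / 9000 - p) < 3.5 * se

    def test_insufficient_bin_raises_naming_bin(self, rng):
        # two well-separated expression groups -> deterministic quantile bins
        expr = make_expr(np.r_[np.full(5, 0.01), np.full(5, 1000.0)])
        target = expr.gene_ids[5:9]  # 4 of the 5 high-expression genes
        with pytest.raises(ValueError, match="expression bin"):
            expression_matched_sample(expr, target, "thyrotrope", n_bins=2, rng=rng)

    def test_matched_mean_close_to_target(self, rng):
        expr = make_expr(rng.lognormal(1, 1.5, size=1000))
        vals = np.log10(expr.values("thyrotrope") + 1)
        bin_width = (np.quantile(vals, 0.9) - np.quantile(vals, 0.1)) / 8
        target = rng.choice(expr.gene_ids, size=25, replace=False).tolist()
        t_mean = np.log10(expr.values("thyrotrope", target) + 1).mean()
        diffs = []
        for _ in range(200):
            sample = expression_matched_sample(expr, target, "thyrotrope", rng=rng)
            diffs.append(np.log10(expr.values("thyrotrope", sample) + 1).mean() - t_mean)
        assert abs(np.mean(diffs)) < 0.5 * bin_width


class TestEmpiricalP:
    def test_plain_fraction_convention(self):
        null = np.r_[np.full(9998, 3), [28, 30]]
        assert empirical_pvalue(28, null) == pytest.approx(0.0002)

    def test_observed_zero_gives_one(self):
        assert empirical_pvalue(0, np.zeros(100, dtype=int)) == 1.0

    def test_monotone_in_observed(self, rng):
        null = rng.integers(0, 30, size=500)
        ps = [empirical_pvalue(k, null) for k in range(35)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(seed=2)
    from chromenh.simulate import simulate_dataset

    return simulate_dataset(cfg, with_sequence=False, with_tracks=False)


class TestPermutationTest:
    def test_reproducible_under_seed(self, planted):
        ds = planted
        kwargs = dict(
            target_ids=ds.gene_truth["signature_ids"],
            genes=ds.genes,
            expr=ds.expression,
            stretch=ds.enhancers["thyrotrope"].stretch(),
            condition="thyrotrope",
            n_permutations=200,
            seed=11,
        )
        r1 = permutation_enrichment_test(**kwargs)
        r2 = permutation_enrichment_test(**kwargs)
        assert r1.observed == r2.observed
        assert np.array_equal(r1.null_counts, r2.null_counts)
        assert r1.empirical_p == r2.empirical_p

    def test_zero_exceedances_warns_and_reports_add_one(self, planted):
        ds = planted
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            res = permutation_enrichment_test(
                ds.gene_truth["signature_ids"],
                ds.genes,
                ds.expression,
                ds.enhancers["thyrotrope"].stretch(),
                "thyrotrope",
                n_permutations=300,
                seed=3,
            )
        if res.empirical_p == 0.0:
            assert res.add_one_p == pytest.approx(1 / 301)
            assert any("add-one" in str(x.message) for x in w)
        assert res.observed >= ds.config.signature_set_size

    def test_invalid_n_permutations(self, planted):
        ds = planted
        with pytest.raises(ValueError):
            permutation_enrichment_test(
                ds.gene_truth["signature_ids"],
                ds.genes,
                ds.expression,
                ds.enhancers["thyrotrope"].stretch(),
                "thyrotrope",
                n_permutations=0,
            )


def exhaustive_mw_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all labelings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    mu = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_disjoint_small_groups_exact(self):
        u, p = mannwhitney_u(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 labelings as extreme

    def test_identical_groups_p_one(self):
        u, p = mannwhitney_u(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert p == 1.0

    def test_exact_mode_matches_enumeration(self, rng):
        for _ in range(8):
            n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            vals = rng.choice(np.arange(100), size=n1 + n2, replace=False).astype(float)
            x, y = vals[:n1], vals[n1:]
            _, p = mannwhitney_u(x, y)
            assert p == pytest.approx(exhaustive_mw_p(x, y), abs=1e-9)

    def test_planted_boost_detected(self):
        detected = 0
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed,
                chrom_lengths={"c1": 400_000},
                n_genes=2000,
                signature_set_size=0,
                promoter_bound_boost=4.0,
            )
            genes, expr, truth = simulate_genes_expression(cfg, {})
            _, p = bound_vs_unbound_expression_test(
                expr, truth["bound_ids"], "thyrotrope"
            )
            detected += p < 1e-6
        assert detected >= 19


class TestAnova:
    def test_identical_groups(self):
        f, p = group_expression_anova([[1, 2, 3], [1, 2, 3]])
        assert f == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        f, p = group_expression_anova([[1, 2], [5, 6]])
        assert f == pytest.approx(32.0)
        assert p == pytest.approx(0.0299, abs=5e-4)

    def test_degenerate_constant_input(self):
        with warnings.catch_warnings(record=True):
            warnings.simplefilter("always")
            f, p = group_expression_anova([[2.0, 2.0], [2.0, 2.0]])
        assert (f, p) == (0.0, 1.0)

    def test_null_p_uniform(self, rng):
        ps = [
            group_expression_anova([rng.normal(size=6), rng.normal(size=6), rng.normal(size=6)])[1]
            for _ in range(2000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_bad_groups_rejected(self):
        with pytest.raises(ValueError):
            group_expression_anova([[1, 2]])
        with pytest.raises(ValueError):
            group_expression_anova([[1, 2], [3]])


class TestNearestGene:
    def test_nearest_and_tie_break(self):
        expr = make_expr(np.array([8.0, 2.0, 4.0]), np.array([1.0, 1.0, 1.0]))
        genes = [
            gene("G0000", "c1", 500),
            gene("G0001", "c1", 10_000),
            gene("G0002", "c1", 500),  # tie with G0000
        ]
        enh = [Enhancer(GenomicInterval("c1", 0, 100), is_stretch=True)]
        out = nearest_gene_log2fc(enh, ["x"], genes, expr, "thyrotrope", "progenitor")
        # tie at distance 401 -> lexicographically smaller G0000 wins
        assert out["x"] == [pytest.approx(np.log2(9 / 2))]

    def test_planted_direction_recovered(self, rng):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 300
            fpkm_a = r.lognormal(1, 1, size=n)
            fpkm_b = fpkm_a * r.lognormal(0, 0.3, size=n)
            boosted = r.choice(n, size=60, replace=False)
            suppressed = np.array([i for i in range(n) if i not in set(boosted)])[:60]
            fpkm_b[boosted] *= 4
            fpkm_a[suppressed] *= 4
            tss = np.sort(r.choice(3_000_000, size=n, replace=False))
            genes = [gene(f"G{i:04d}", "c1", int(tss[i])) for i in range(n)]
            expr = make_expr(fpkm_b, fpkm_a)
            enh, labels = [], []
            for i in boosted:  # B-specific enhancers next to boosted genes
                enh.append(Enhancer(GenomicInterval("c1", int(tss[i]) + 200, int(tss[i]) + 3601), True))
                labels.append("b_specific")
            for i in suppressed:
                enh.append(Enhancer(GenomicInterval("c1", int(tss[i]) + 200, int(tss[i]) + 3601), True))
                labels.append("a_specific")
            out = nearest_gene_log2fc(enh, labels, genes, expr, "thyrotrope", "progenitor")
            wins += np.median(out["b_specific"]) > np.median(out["a_specific"])
        assert wins == 20


class TestTopPercent:
    def test_counts_and_extremes(self, rng):
        fpkm_b = rng.lognormal(1, 2, size=100)
        expr = make_expr(fpkm_b, rng.lognormal(1, 2, size=100))
        top = select_top_percent_de(expr, "thyrotrope", "progenitor", percent=5)
        assert len(top) == 5
        lfc = expr.log2fc("thyrotrope", "progenitor")
        assert set(top) == set(lfc.sort_values(ascending=False).index[:5])

    def test_only_expressed_genes_count(self):
        fpkm_a = np.array([0.0, 0.0, 1.0, 2.0])
        fpkm_b = np.array([0.0, 5.0, 3.0, 0.0])
        expr = make_expr(fpkm_b, fpkm_a)
        # gene 0 is unexpressed in both -> n_expressed = 3, ceil(0.5*3) = 2
        top = select_top_percent_de(expr, "thyrotrope", "progenitor", percent=50)
        assert len(top) == 2
        assert "G0000" not in top

    def test_matches_sort_oracle(self, rng):
        fpkm_b = rng.lognormal(0, 2, size=1000)
        fpkm_a = rng.lognormal(0, 2, size=1000)
        expr = make_expr(fpkm_b, fpkm_a)
        for direction in ("up", "down"):
            got = select_top_percent_de(expr, "thyrotrope", "progenitor", 7, direction)
            lfc = np.log2((fpkm_b + 1) / (fpkm_a + 1))
            order = np.argsort(-lfc if direction == "up" else lfc, kind="stable")
            want = [f"G{i:04d}" for i in order[: len(got)]]
            assert got == want


class TestProportions:
    @pytest.mark.parametrize(
        "num,den,percent", [(5, 11, 45), (8, 26, 31), (8, 270, 3), (1, 8, 13), (63, 76, 83)]
    )
    def test_round_half_up(self, num, den, percent):
        assert costain_proportions(num, den).percent == percent

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            costain_proportions(1, 0)
        with pytest.raises(ValueError):
            costain_proportions(5, 4)
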