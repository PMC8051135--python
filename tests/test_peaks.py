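"""Peak sharing, TSS proximity, transition classes, profiles, FRiP."""

import numpy as np
import pytest

from chromenh.intervals import GenomicInterval, min_distance
from chromenh.model import GeneRecord, Peak, PeakSet, Segmentation, SignalTrack, StateSegment
from chromenh.peaks import (
    SiteClass,
    aggregate_profile,
    classify_peak_sharing,
    frip,
    single_anchor_profile,
    site_state,
    transition_class,
    tss_proximal_fraction,
)
from chromenh.simulate import SimulationConfig, simulate_peaks, simulate_segmentation, simulate_tracks


def pset(label, triples, names=None):
    return PeakSet(
        label,
        [
            Peak(GenomicInterval(c, s, e), name=None if names is None else names[i])
            for i, (c, s, e) in enumerate(triples)
        ],
    )


class TestPeakSharing:
    def test_single_bp_overlap_is_shared(self):
        rep = classify_peak_sharing(pset("A", [("c1", 0, 100)]), pset("B", [("c1", 99, 150)]))
        assert rep.labels_a == ["shared"] and rep.labels_b == ["shared"]

    def test_book_ended_peaks_stay_unique(self):
        rep = classify_peak_sharing(pset("A", [("c1", 0, 100)]), pset("B", [("c1", 100, 150)]))
        assert rep.labels_a == ["a_only"] and rep.labels_b == ["b_only"]

    def test_role_swap_symmetry(self, rng):
        def random_pset(label):
            return pset(
                label,
                [
                    (f"c{rng.integers(1, 3)}", int(s), int(s) + int(w))
                    for s, w in zip(rng.integers(0, 50_000, 150), rng.integers(50, 600, 150))
                ],
            )

        a, b = random_pset("A"), random_pset("B")
        fwd = classify_peak_sharing(a, b)
        rev = classify_peak_sharing(b, a)
        assert fwd.shared_a == rev.shared_b and fwd.shared_b == rev.shared_a
        assert fwd.labels_a == ["shared" if l == "shared" else "a_only" for l in rev.labels_b]

    def test_recovers_planted_truth(self, default_dataset):
        ds = default_dataset
        pa = ds.peaks[ds.config.conditions[0]]
        pb = ds.peaks[ds.config.conditions[1]]
        rep = classify_peak_sharing(pa, pb)
        truth = ds.sites.set_index("site_id")["klass"]
        correct = total = 0
        for p, lab in zip(pa, rep.labels_a):
            want = "shared" if truth[p.name] == "shared" else "a_only"
            correct += lab == want
            total += 1
        for p, lab in zip(pb, rep.labels_b):
            want = "shared" if truth[p.name] == "shared" else "b_only"
            correct += lab == want
            total += 1
        assert correct / total >= 0.99


class TestTssProximity:
    def test_boundary_inclusive(self):
        peaks = pset("A", [("c1", 100, 200)])
        near = [GeneRecord("G1", "c1", "+", 1199)]
        far = [GeneRecord("G1", "c1", "+", 1200)]
        assert tss_proximal_fraction(peaks, near)[0] == [True]  # distance 1000
        assert tss_proximal_fraction(peaks, far)[0] == [False]  # distance 1001

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            tss_proximal_fraction(pset("A", [("c1", 0, 10)]), [])

    def test_matches_all_pairs_oracle(self, rng):
        peaks = pset(
            "A",
            [
                (f"c{rng.integers(1, 4)}", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 100_000, 300), rng.integers(50, 800, 300))
            ],
        )
        genes = [
            GeneRecord(f"G{i}", f"c{rng.integers(1, 4)}", "+", int(rng.integers(0, 100_000)))
            for i in range(300)
        ]
        flags, frac = tss_proximal_fraction(peaks, genes, max_dist=1000)
        for p, flag in zip(peaks, flags):
            brute = min(
                min_distance(p.interval, g.tss, g.chrom) for g in genes
            ) <= 1000
            assert flag == brute
        assert frac == pytest.approx(sum(flags) / len(flags))


class TestSiteState:
    seg = Segmentation(
        [
            StateSegment(GenomicInterval("c1", 0, 400), 3),
            StateSegment(GenomicInterval("c1", 600, 800), 8),
        ]
    )

    def test_midpoint_inside_segment(self):
        assert site_state(Peak(GenomicInterval("c1", 100, 300)), self.seg) == 3

    def test_midpoint_in_gap_is_unmarked(self):
        assert site_state(Peak(GenomicInterval("c1", 450, 550)), self.seg) == "unmarked"

    def test_straddling_peak_uses_midpoint_base(self):
        # peak [300, 900): midpoint 600 -> state 8, not the longer state-3 side
        assert site_state(Peak(GenomicInterval("c1", 300, 900)), self.seg) == 8


class TestTransitionClass:
    @pytest.mark.parametrize(
        "label,sa,sb,expected",
        [
            ("b_only", 8, 2, SiteClass.REPRESSED_TO_ACTIVE),
            ("b_only", "unmarked", 2, SiteClass.REPRESSED_TO_ACTIVE),
            ("shared", 1, 6, SiteClass.ACTIVE_TO_ACTIVE),
            ("a_only", 4, "unmarked", SiteClass.ACTIVE_TO_REPRESSED),
            ("shared", 8, 2, SiteClass.OTHER),
            ("b_only", 2, 2, SiteClass.OTHER),
            ("a_only", 7, 2, SiteClass.OTHER),
        ],
    )
    def test_definitions(self, label, sa, sb, expected):
        assert transition_class(label, sa, sb) == expected

    def test_partitions_all_sites(self, default_dataset):
        ds = default_dataset
        counts = {c: 0 for c in SiteClass}
        for r in ds.sites.itertuples():
            sa = r.state_a if r.state_a else "unmarked"
            sb = r.state_b if r.state_b else "unmarked"
            counts[transition_class(r.klass, sa, sb)] += 1
        assert sum(counts.values()) == len(ds.sites)

    def test_null_frequencies_match_combinatorial_expectation(self):
        # uniform classes, no state preference: class freq = p_label * p(state combo)
        cfg = SimulationConfig(
            seed=23,
            peak_class_probs=(1 / 3, 1 / 3, 1 / 3),
            state_preference_prob=0.0,
            n_sites=3000,
        )
        seg_a = simulate_segmentation(cfg, "progenitor")
        seg_b = simulate_segmentation(cfg, "thyrotrope")
        _, _, truth = simulate_peaks(cfg, seg_a, seg_b)
        # joint (active_a, active_b) probability measured over genome bins
        from chromenh.simulate import _bin_states

        active = set(cfg.active_states)
        sa = np.concatenate([v for _, v in sorted(_bin_states(seg_a, cfg).items())])
        sb = np.concatenate([v for _, v in sorted(_bin_states(seg_b, cfg).items())])
        a_act, b_act = np.isin(sa, list(active)), np.isin(sb, list(active))
        p_expect = {
            SiteClass.REPRESSED_TO_ACTIVE: (1 / 3) * (~a_act & b_act).mean(),
            SiteClass.ACTIVE_TO_ACTIVE: (1 / 3) * (a_act & b_act).mean(),
            SiteClass.ACTIVE_TO_REPRESSED: (1 / 3) * (a_act & ~b_act).mean(),
        }
        n = len(truth)
        obs = truth["transition"].value_counts()
        for klass, p in p_expect.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(obs.get(klass.value, 0) / n - p) < 3 * se + 0.01


class TestAggregateProfile:
    def test_constant_track(self):
        track = SignalTrack({"c1": (np.array([0]), np.array([10_000]), np.array([2.5]))})
        anchors = pset("A", [("c1", 4000, 4200), ("c1", 6000, 6400)])
        prof = aggregate_profile(anchors, track, half_window=500, bin_width=10)
        assert np.allclose(prof.values, 2.5)

    def test_symmetric_triangle_gives_symmetric_profile(self):
        cfg = SimulationConfig(chrom_lengths={"c1": 40_000})
        anchors = pset("A", [("c1", 19_900, 20_100)])
        tracks = simulate_tracks(cfg, {"x": anchors})
        prof = aggregate_profile(anchors, tracks["x"], half_window=500, bin_width=10)
        assert np.allclose(prof.values, prof.values[::-1], atol=1e-9)

    def test_center_bin_matches_closed_form(self):
        # triangle height h, half-base w, baseline b, sampled at 5-bp step
        # midpoints: center bin mean = b + h * (1 - 2.5 / w)
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed, chrom_lengths={"c1": 300_000}, n_sites=40,
                signature_set_size=0,
            )
            seg = simulate_segmentation(cfg, "progenitor")
            segb = simulate_segmentation(cfg, "thyrotrope")
            pa, _, _ = simulate_peaks(cfg, seg, segb)
            tracks = simulate_tracks(cfg, {"x": pa})
            prof = aggregate_profile(pa, tracks["x"], half_window=500, bin_width=10)
            expected = cfg.track_baseline + cfg.track_height * (
                1 - 2.5 / cfg.track_half_width
            )
            center = prof.values[prof.center_bin_index]
            assert abs(center - expected) / expected < 0.05

    def test_profile_is_mean_of_single_anchor_profiles(self):
        track = SignalTrack(
            {
                "c1": (
                    np.array([0, 5000, 9000]),
                    np.array([3000, 7000, 12_000]),
                    np.array([1.0, 3.0, 0.5]),
                )
            },
            chrom_lengths={"c1": 12_000},
        )
        anchors = pset("A", [("c1", 2000, 2400), ("c1", 6000, 6200), ("c1", 11_500, 11_900)])
        prof = aggregate_profile(anchors, track, half_window=1000, bin_width=20)
        singles = np.stack(
            [
                single_anchor_profile(p.interval.chrom, p.interval.midpoint, track, 1000, 20)
                for p in anchors
            ]
        )
        assert np.allclose(prof.values, np.nanmean(singles, axis=0), equal_nan=True)

    def test_empty_anchor_set_rejected(self):
        track = SignalTrack({"c1": (np.array([0]), np.array([100]), np.array([1.0]))})
        with pytest.raises(ValueError):
            aggregate_profile(pset("A", []), track)


class TestFrip:
    def test_fraction(self):
        reads = [GenomicInterval("c1", i * 100, i * 100 + 50) for i in range(10)]
        peaks = pset("P", [("c1", 0, 120), ("c1", 210, 260)])  # hits reads 0,1,2
        assert frip(reads, peaks) == pytest.approx(0.30)

    def test_no_peaks_is_zero(self):
        assert frip([GenomicInterval("c1", 0, 50)], pset("P", [])) == 0.0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            frip([], pset("P", [("c1", 0, 10)]))

    def test_matches_brute_force(self, rng):
        reads = [
            GenomicInterval(f"c{rng.integers(1, 3)}", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 50_000, 2000), rng.integers(20, 100, 2000))
        ]
        peaks = pset(
            "P",
            [
                (f"c{rng.integers(1, 3)}", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 50_000, 200), rng.integers(100, 500, 200))
            ],
        )
        brute = sum(
            any(r.overlap_length(p.interval) >= 1 for p in peaks) for r in reads
        ) / len(reads)
        assert frip(reads, peaks) == pytest.approx(brute)
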