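import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopbench.core import GenomicInterval, Loop, LoopSet, PeakSet, PETRecord, PETTrack
from loopbench.metrics import (
    ConfusionCounts,
    accuracy,
    activation_rate,
    enrichment_score,
    filter_significant,
    global_es,
    peak_co_occupancy,
    resolution_levels,
    scale_scores,
    uv_rate,
)
from conftest import iv, loop, random_intervals, random_loops
from oracles import (
    oracle_accuracy,
    oracle_ar,
    oracle_es,
    oracle_filter_significant,
    oracle_pc,
    oracle_uv_rate,
)


def make_pet(rng, sizes, mapq=(40, 40), dup=False, lig="inter_ligation"):
    chrom = sizes.chroms[int(rng.integers(2))]
    s1 = int(rng.integers(0, sizes[chrom] - 100_000))
    s2 = s1 + int(rng.integers(20_000, 90_000))
    return PETRecord(
        iv(chrom, s1, s1 + 50), iv(chrom, s2, s2 + 50), mapq[0], mapq[1], dup, lig
    )


class TestUVRate:
    def test_direct_ratio(self, rng, sizes):
        passing = [make_pet(rng, sizes) for _ in range(4)]
        failing = (
            [make_pet(rng, sizes, mapq=(10, 40)) for _ in range(2)]
            + [make_pet(rng, sizes, dup=True) for _ in range(2)]
            + [make_pet(rng, sizes, lig="self_ligation") for _ in range(2)]
        )
        assert uv_rate(passing + failing) == pytest.approx(0.4)

    def test_all_duplicates_give_zero(self, rng, sizes):
        assert uv_rate([make_pet(rng, sizes, dup=True) for _ in range(5)]) == 0.0

    def test_empty_collection_is_an_error(self):
        with pytest.raises(ValueError):
            uv_rate([])

    def test_mapq_threshold_is_inclusive(self, rng, sizes):
        assert uv_rate([make_pet(rng, sizes, mapq=(30, 30))]) == 1.0
        assert uv_rate([make_pet(rng, sizes, mapq=(29, 30))]) == 0.0

    def test_matches_counting_oracle_on_random_flags(self, rng, sizes):
        pets = []
        for _ in range(1000):
            mapq = (int(rng.integers(0, 60)), int(rng.integers(0, 60)))
            dup = bool(rng.random() < 0.3)
            lig = ["inter_ligation", "self_ligation", "invalid"][int(rng.integers(3))]
            pets.append(make_pet(rng, sizes, mapq=mapq, dup=dup, lig=lig))
        assert uv_rate(pets) == pytest.approx(oracle_uv_rate(pets))


class TestPeakCoOccupancy:
    def test_identical_anchor_and_peak(self):
        anchors = [iv("c", 100, 600)]
        peaks = PeakSet([iv("c", 100, 600)])
        assert peak_co_occupancy(anchors, peaks, "literal").value == pytest.approx(1.0)
        assert peak_co_occupancy(anchors, peaks, "normalized").value == pytest.approx(1.0)

    def test_no_overlap_gives_zero(self):
        anchors = [iv("c", 0, 100), iv("c", 200, 300)]
        peaks = PeakSet([iv("c", 10_000, 10_500)])
        assert peak_co_occupancy(anchors, peaks).value == 0.0

    def test_empty_peaks_give_zero(self):
        assert peak_co_occupancy([iv("c", 0, 100)], PeakSet([])).value == 0.0

    def test_empty_anchors_are_an_error(self):
        with pytest.raises(ValueError):
            peak_co_occupancy([], PeakSet([iv("c", 0, 100)]))

    def test_longest_overlap_wins(self):
        anchors = [iv("c", 100, 400)]
        peaks = PeakSet([iv("c", 90, 200), iv("c", 150, 400)])  # overlaps 100 vs 250
        table = peak_co_occupancy(anchors, peaks).table
        assert table.loc[0, "peak_start"] == 150

    def test_literal_mode_can_exceed_one(self):
        anchors = [iv("c", 0, 100), iv("c", 500, 600)]
        peaks = PeakSet([iv("c", 0, 100), iv("c", 500, 600)])
        assert peak_co_occupancy(anchors, peaks, "literal").value == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("mode", ["literal", "normalized"])
    def test_matches_all_pairs_oracle(self, seed, mode, sizes):
        rng = np.random.default_rng(seed)
        anchors = random_intervals(rng, 20, sizes, min_len=100, max_len=1500)
        peaks = PeakSet(random_intervals(rng, 10, sizes, min_len=100, max_len=1500))
        got = peak_co_occupancy(anchors, peaks, mode).value
        assert got == pytest.approx(oracle_pc(anchors, peaks.intervals, mode), rel=1e-12)


class TestEnrichmentScore:
    def test_direct_formula(self):
        # anchors of length 100 -> l_m = 100; flank counts 2+3 and 4+4
        lp = loop("c", 1000, 1100, 5000, 5100, pet_count=10)
        positions = (
            [950, 960]  # [900, 1000)
            + [1150, 1160, 1170]  # [1100, 1200)
            + [4950, 4960, 4970, 4980]  # [4900, 5000)
            + [5150, 5160, 5170, 5180]  # [5100, 5200)
        )
        track = PETTrack({"c": positions})
        assert enrichment_score(lp, track) == pytest.approx(10 / 5)

    def test_zero_count_gives_zero(self):
        lp = loop("c", 1000, 1100, 5000, 5100, pet_count=0)
        assert enrichment_score(lp, PETTrack({"c": [950.0]})) == 0.0

    def test_zero_neighbours_guarded_by_pseudocount(self):
        lp = loop("c", 1000, 1100, 5000, 5100, pet_count=4)
        assert enrichment_score(lp, PETTrack({"c": []})) == 4.0

    def test_missing_pet_count_is_an_error(self):
        lp = loop("c", 1000, 1100, 5000, 5100)
        with pytest.raises(ValueError):
            enrichment_score(lp, PETTrack({"c": []}))

    def test_scale_invariance_under_doubling(self, rng, sizes):
        lp = loop("chrA", 10_000, 10_200, 50_000, 50_200, pet_count=6)
        positions = list(rng.integers(9_000, 52_000, size=400).astype(float))
        es1 = enrichment_score(lp, PETTrack({"chrA": positions}))
        doubled = loop("chrA", 10_000, 10_200, 50_000, 50_200, pet_count=12)
        es2 = enrichment_score(doubled, PETTrack({"chrA": positions + positions}))
        assert es2 == pytest.approx(es1)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_window_recount_oracle(self, seed, sizes):
        rng = np.random.default_rng(seed)
        loops = random_loops(rng, 25, sizes, pets=(0, 15))
        positions = {
            c: list(rng.integers(0, sizes[c], size=600).astype(float))
            for c in sizes.chroms
        }
        track = PETTrack(positions, sizes=sizes)
        for lp in loops:
            expected, _ = oracle_es(lp, positions, sizes)
            assert enrichment_score(lp, track) == pytest.approx(expected)


class TestGlobalES:
    def test_two_chromosome_coverage_correction_by_hand(self, ):
        from loopbench.core import ChromSizes

        sizes = ChromSizes({"chrA": 1000, "chrB": 1000})
        # chrA: 4 positions, chrB: 2 -> alpha_A = 0.75, alpha_B = 1.5
        positions = {"chrA": [10.0, 20.0, 250.0, 350.0], "chrB": [10.0, 250.0]}
        track = PETTrack(positions, sizes=sizes)
        loop_a = loop("chrA", 100, 200, 400, 500, pet_count=6)
        loop_b = loop("chrB", 100, 200, 400, 500, pet_count=2)
        # chrA windows [0,100),[200,300),[300,400),[500,600): left 2+1, right 1+0 -> P_n 1
        # chrB windows likewise: left 1+1, right 0+0 -> P_n 0 -> pseudocount 1
        report = global_es(LoopSet([loop_a, loop_b]), track, sizes, pet_length=1.0)
        per = report.per_chrom.set_index("chrom")
        assert per.loc["chrA", "alpha"] == pytest.approx(0.75)
        assert per.loc["chrB", "alpha"] == pytest.approx(1.5)
        assert per.loc["chrA", "es"] == pytest.approx(6 / 1 * 0.75)
        assert per.loc["chrB", "es"] == pytest.approx(2 / 1 * 1.5)
        assert report.es_global == pytest.approx(6 / 8 * 4.5 + 2 / 8 * 3.0)

    def test_uniform_coverage_alpha_collapses_to_one(self, rng):
        from loopbench.core import ChromSizes

        sizes = ChromSizes({"chrA": 100_000})
        positions = {"chrA": list(rng.integers(0, 100_000, size=500).astype(float))}
        track = PETTrack(positions, sizes=sizes)
        loops = LoopSet(random_loops(rng, 10, sizes, span=(5_000, 50_000), pets=(1, 9)))
        report = global_es(loops, track, sizes, pet_length=100.0)
        assert report.per_chrom["alpha"].iloc[0] == pytest.approx(1.0)
        expected = report.per_loop["pet_count"].sum() / np.maximum(
            report.per_loop["p_n"], 1
        ).sum()
        assert report.es_global == pytest.approx(expected)

    def test_loops_on_uncovered_chromosome_error(self, sizes):
        track = PETTrack({"chrA": [1.0, 2.0]}, sizes=sizes)
        loops = LoopSet([loop("chrB", 100, 200, 400, 500, pet_count=2)])
        with pytest.raises(ValueError, match="zero PET coverage"):
            global_es(loops, track, sizes, pet_length=100.0)


class TestAccuracy:
    def test_perfect_caller(self, rng, sizes):
        truth = LoopSet(random_loops(rng, 10, sizes))
        false_sets = [LoopSet(random_loops(rng, 10, sizes, span=(500_000, 560_000)))]
        counts = accuracy(truth, truth, false_sets)
        if counts.fp == 0:  # false sets drawn far from the truth span
            assert counts.acc == pytest.approx(1.0)
        assert counts.tp == 10 and counts.fn == 0

    def test_printed_formula_arithmetic(self):
        assert ConfusionCounts(8, 2, 8, 2).acc == pytest.approx(0.8)

    def test_empty_truth_is_an_error(self, rng, sizes):
        detected = LoopSet(random_loops(rng, 3, sizes))
        with pytest.raises(ValueError):
            accuracy(detected, LoopSet([]), [detected])

    def test_missing_false_sets_are_an_error(self, rng, sizes):
        detected = LoopSet(random_loops(rng, 3, sizes))
        with pytest.raises(ValueError):
            accuracy(detected, detected, [])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed, sizes):
        rng = np.random.default_rng(seed)
        detected = LoopSet(random_loops(rng, 30, sizes, span=(1_000, 80_000)))
        truth = LoopSet(random_loops(rng, 20, sizes, span=(1_000, 80_000)))
        false_sets = [
            LoopSet(random_loops(rng, 20, sizes, span=(1_000, 80_000)))
            for _ in range(3)
        ]
        counts = accuracy(detected, truth, false_sets)
        tp, fp, tn, fn, acc = oracle_accuracy(detected, truth, false_sets)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)
        assert counts.acc == pytest.approx(acc)

    def test_monotone_in_true_detections(self, rng, sizes):
        truth = LoopSet(random_loops(rng, 15, sizes))
        detected = LoopSet(random_loops(rng, 15, sizes))
        false_sets = [LoopSet(random_loops(rng, 15, sizes)) for _ in range(2)]
        base = accuracy(detected, truth, false_sets).acc
        # add a detected loop that hits the truth and no false set
        extra = truth[0]
        if not any(
            oracle_accuracy(LoopSet([extra]), LoopSet([extra]), [fs])[1] > 0
            for fs in false_sets
        ):
            grown = accuracy(LoopSet(list(detected) + [extra]), truth, false_sets).acc
            assert grown >= base


class TestScaleScores:
    def test_min_max_definition(self):
        assert list(scale_scores([0.2, 0.5, 0.8])) == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_input_maps_to_ones(self):
        assert list(scale_scores([0.7, 0.7])) == [1.0, 1.0]

    def test_single_value_is_an_error(self):
        with pytest.raises(ValueError):
            scale_scores([0.5])

    def test_mapping_round_trip(self):
        scaled = scale_scores({"a": 0.6, "b": 0.9})
        assert scaled == {"a": 0.0, "b": 1.0}

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=10, unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_preserves_order_and_bounds(self, values):
        scaled = scale_scores(values)
        assert np.all((scaled >= 0) & (scaled <= 1))
        # monotone: sorting by raw value sorts the scaled values too
        assert np.all(np.diff(scaled[np.argsort(values)]) >= 0)


class TestFilterSignificant:
    def test_hichip_below_eight_pets_removed(self):
        loops = LoopSet([loop("c", 0, 100, 5000, 5100, pet_count=7)])
        assert len(filter_significant(loops, "hichip")) == 0

    def test_chiapet_boundary_pass(self):
        loops = LoopSet([loop("c", 0, 100, 5000, 5100, pet_count=3, p_value=0.04)])
        assert len(filter_significant(loops, "chiapet")) == 1

    def test_p_value_boundary_inclusive(self):
        loops = LoopSet([loop("c", 0, 100, 5000, 5100, pet_count=5, p_value=0.05)])
        assert len(filter_significant(loops, "chiapet")) == 1

    def test_missing_p_and_fdr_pass(self):
        loops = LoopSet([loop("c", 0, 100, 5000, 5100, pet_count=9)])
        assert len(filter_significant(loops, "hichip")) == 1

    def test_unknown_protocol_is_an_error(self):
        with pytest.raises(ValueError, match="protocol"):
            filter_significant(LoopSet([]), "hic")

    def test_matches_filter_oracle_on_mixed_set(self, rng, sizes):
        loops = []
        for lp in random_loops(rng, 100, sizes, pets=(0, 15)):
            p = float(rng.random()) if rng.random() < 0.5 else None
            f = float(rng.random()) if rng.random() < 0.5 else None
            loops.append(
                loop(
                    lp.anchor1.chrom,
                    lp.anchor1.start,
                    lp.anchor1.end,
                    lp.anchor2.start,
                    lp.anchor2.end,
                    pet_count=lp.pet_count,
                    p_value=p,
                    fdr=f,
                )
            )
        got = filter_significant(LoopSet(loops), "chiapet")
        expected = oracle_filter_significant(loops, 3, 0.05, 0.05)
        assert [g.key() for g in got] == [e.key() for e in expected]


class TestActivationRate:
    def _annotation(self):
        enhancers = PeakSet([iv("c", 0, 20_000)])
        promoters = PeakSet([iv("c", 50_000, 70_000)])
        return enhancers, promoters

    def test_active_only_marks_give_active(self):
        enh, prom = self._annotation()
        loops = LoopSet([loop("c", 100, 600, 51_000, 51_500, pet_count=5)])
        report = activation_rate(
            loops, enh, prom, [PeakSet([iv("c", 0, 100_000)])], [PeakSet([])]
        )
        assert report.loop_states == ["active"]
        assert report.activation_rate == 1.0
        assert report.n_ep == 1

    def test_equal_overlap_is_other(self):
        enh, prom = self._annotation()
        loops = LoopSet([loop("c", 100, 600, 51_000, 51_500, pet_count=5)])
        marks = [PeakSet([iv("c", 100, 350)])]  # 250 bp on anchor1 only
        report = activation_rate(loops, enh, prom, marks, marks)
        assert report.loop_states == ["other"]

    def test_no_marks_at_all_is_other(self):
        enh, prom = self._annotation()
        loops = LoopSet([loop("c", 100, 600, 51_000, 51_500, pet_count=5)])
        report = activation_rate(loops, enh, prom, [PeakSet([])], [PeakSet([])])
        assert report.loop_states == ["other"]

    def test_unannotated_loops_are_an_error(self):
        enh, prom = self._annotation()
        loops = LoopSet([loop("c", 200_000, 200_500, 400_000, 400_500, pet_count=5)])
        with pytest.raises(ValueError, match="annotated"):
            activation_rate(loops, enh, prom, [PeakSet([])], [PeakSet([])])

    def test_promoter_label_wins_for_dual_annotated_anchor(self):
        enhancers = PeakSet([iv("c", 0, 100_000)])  # covers everything
        promoters = PeakSet([iv("c", 50_000, 70_000)])
        loops = LoopSet([loop("c", 100, 600, 51_000, 51_500, pet_count=5)])
        report = activation_rate(
            loops, enhancers, promoters, [PeakSet([iv("c", 0, 1_000)])], [PeakSet([])]
        )
        assert report.n_ep == 1  # anchor2 is both E and P -> P

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_basepair_oracle(self, seed, sizes):
        rng = np.random.default_rng(seed)
        loops = LoopSet(
            random_loops(rng, 50, sizes, anchor_len=(60, 120), span=(1_000, 50_000), pets=(3, 9))
        )
        enh = PeakSet(random_intervals(rng, 80, sizes, min_len=500, max_len=5000))
        prom = PeakSet(random_intervals(rng, 80, sizes, min_len=500, max_len=5000))
        active = [
            PeakSet(random_intervals(rng, 40, sizes, min_len=200, max_len=2000))
            for _ in range(2)
        ]
        repressive = [PeakSet(random_intervals(rng, 40, sizes, min_len=200, max_len=2000))]
        report = activation_rate(loops, enh, prom, active, repressive)
        ar, states = oracle_ar(
            loops, enh.intervals, prom.intervals,
            [a.intervals for a in active], [r.intervals for r in repressive],
        )
        assert report.activation_rate == pytest.approx(ar)
        assert report.loop_states == [s for s in states if s != "unannotated"]


class TestResolutionLevels:
    def test_one_loop_per_bin(self):
        loops = LoopSet(
            [
                loop("c", 0, 100, 5_000, 5_100),  # 5 kb
                loop("c", 0, 100, 50_000, 50_100),  # 50 kb
                loop("c", 0, 100, 500_000, 500_100),  # 500 kb
            ]
        )
        assert resolution_levels(loops) == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_boundary_ten_kb_in_first_bin(self):
        loops = LoopSet([loop("c", 0, 100, 10_000, 10_100)])
        assert resolution_levels(loops).le_10kb == 1.0

    def test_all_loops_beyond_one_mb_error(self):
        loops = LoopSet([loop("c", 0, 100, 2_000_000, 2_000_100)])
        with pytest.raises(ValueError):
            resolution_levels(loops)

    def test_interchromosomal_loops_excluded(self):
        loops = LoopSet(
            [
                Loop(iv("c1", 0, 100), iv("c2", 0, 100)),
                loop("c1", 0, 100, 5_000, 5_100),
            ]
        )
        assert resolution_levels(loops).le_10kb == 1.0
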