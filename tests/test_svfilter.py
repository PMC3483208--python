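import itertools

import numpy as np
import pytest

from svref.fixtures import match_calls_to_truth
from svref.io_formats import GenomicInterval, ReadPairAlignment, SvRecord
from svref.pairscreen import FilterConfig, screen
from svref.readsim import LibraryModel
from svref.svfilter import (
    compare_to_control,
    filter_by_size,
    filter_by_tracks,
    overlap_fraction,
    run_cascade,
)
from svref.tracks import IntervalTrack

LIB = LibraryModel(50, 315.0, 44.0)
CFG = FilterConfig()


def call(sv_type="deletion", c1="chr1", a=(1000, 1100), c2=None, b=(3000, 3100), size=None, support=4):
    return SvRecord(
        sv_type,
        GenomicInterval(c1, *a),
        GenomicInterval(c2 or c1, *b),
        size=size,
        support=support,
    )


def track(*ivs):
    return IntervalTrack.from_intervals("t", [GenomicInterval(*iv) for iv in ivs])


def del_pair(name, a, b, chrom="chr1"):
    return ReadPairAlignment.from_mates(
        name, (chrom, a, a + 50, "+", 60), (chrom, b, b + 50, "-", 60)
    )


class TestOverlapFraction:
    def test_no_intersection(self):
        assert overlap_fraction(call(), track(("chr2", 0, 10_000))) == 0.0

    def test_full_coverage(self):
        assert overlap_fraction(call(), track(("chr1", 0, 10_000))) == 1.0

    def test_mixed_70_30(self):
        c = call(a=(1000, 1100), b=(3000, 3100))
        t = track(("chr1", 1000, 1070), ("chr1", 3000, 3030))
        assert overlap_fraction(c, t) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_bitmap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ivs = [
            ("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 5_000, 20), rng.integers(1, 400, 20))
        ]
        t = track(*ivs)
        c = call(a=(100, 900), b=(2000, 3500))
        bitmap = np.zeros(10_000, dtype=bool)
        for _, s, e in ivs:
            bitmap[s:e] = True
        expected = (bitmap[100:900].sum() + bitmap[2000:3500].sum()) / (800 + 1500)
        assert overlap_fraction(c, t) == pytest.approx(expected)


class TestTrackFilters:
    def test_lowmap_boundary_intra(self):
        # 85% overlap removes, 84.9% keeps (inclusive cutoff)
        c = call(a=(0, 1000), b=(10_000, 11_000))
        exactly = track(("chr1", 0, 1000), ("chr1", 10_000, 10_700))
        kept, removed = filter_by_tracks([c], exactly, None, None, CFG)
        assert removed["low_mappability"] == [c]
        just_under = track(("chr1", 0, 1000), ("chr1", 10_000, 10_698))
        kept, removed = filter_by_tracks([c], just_under, None, None, CFG)
        assert kept == [c]

    def test_lowmap_inter_cutoff_50(self):
        c = call(sv_type="translocation", c2="chr2")
        half = track(("chr1", 1000, 1100), ("chr2", 3050, 3100))
        # anchors 100+100 bp, covered 100+50 = 75% >= 50% -> removed
        _, removed = filter_by_tracks([c], half, None, None, CFG)
        assert removed["low_mappability"] == [c]

    def test_repeatmasker_only_weak_interchromosomal(self):
        rm = track(("chr1", 0, 10_000), ("chr2", 0, 10_000))
        strong = call(sv_type="translocation", c2="chr2", support=4)
        weak = call(sv_type="translocation", c2="chr2", support=3)
        intra = call(support=2)
        kept, removed = filter_by_tracks([strong, weak, intra], None, None, rm, CFG)
        assert strong in kept and intra in kept
        assert removed["repeat_masker"] == [weak]

    def test_simple_repeat_cutoff(self):
        sr = track(("chr1", 1000, 1100))  # covers 50% of summed anchors
        c = call()
        _, removed = filter_by_tracks([c], None, sr, None, CFG)
        assert removed["simple_repeats"] == [c]

    def test_all_tracks_empty_identity(self):
        calls = [call(), call(sv_type="translocation", c2="chr2")]
        empty = IntervalTrack("e", [])
        kept, removed = filter_by_tracks(calls, empty, empty, empty, CFG)
        assert kept == calls and not any(removed.values())


class TestSizeFilter:
    @pytest.mark.parametrize(
        "sv_type,size,kept_expected",
        [
            ("deletion", 600, True),
            ("deletion", 599, False),
            ("duplication", 300, True),
            ("duplication", 299, False),
            ("inversion", 5, True),
        ],
    )
    def test_boundaries(self, sv_type, size, kept_expected):
        c = call(sv_type=sv_type, size=size)
        kept, removed = filter_by_size([c], CFG)
        assert (c in kept) is kept_expected

    def test_translocation_passes(self):
        c = call(sv_type="translocation", c2="chr2", size=None)
        kept, _ = filter_by_size([c], CFG)
        assert kept == [c]


class TestControlComparison:
    def test_single_control_pair_removes_at_support_1(self):
        tumor_call = call(a=(1000, 1400), b=(3000, 3400), size=1600)
        control = [del_pair("c0", 1100, 3100)]
        kept, removed = compare_to_control([tumor_call], control, LIB, CFG)
        assert removed == [tumor_call]
        cfg2 = FilterConfig(control_min_support=2)
        kept, removed = compare_to_control([tumor_call], control, LIB, cfg2)
        assert kept == [tumor_call]

    def test_tumor_only_call_kept(self):
        tumor_call = call(a=(1000, 1400), b=(3000, 3400))
        control = [del_pair("c0", 50_000, 52_000)]
        kept, _ = compare_to_control([tumor_call], control, LIB, CFG)
        assert kept == [tumor_call]

    def test_type_ignored(self):
        # control evidence is an inversion-signature cluster at the same spot
        inv_pair = ReadPairAlignment.from_mates(
            "c0", ("chr1", 1100, 1150, "+", 60), ("chr1", 3100, 3150, "+", 60)
        )
        tumor_call = call(a=(1000, 1400), b=(3000, 3400))
        kept, removed = compare_to_control([tumor_call], [inv_pair], LIB, CFG)
        assert removed == [tumor_call]

    def test_both_anchors_required(self):
        tumor_call = call(a=(1000, 1400), b=(30_000, 30_400))
        control = [del_pair("c0", 1100, 3100)]  # only anchor A overlaps
        kept, _ = compare_to_control([tumor_call], control, LIB, CFG)
        assert kept == [tumor_call]
        kept, _ = compare_to_control(
            [tumor_call], control, LIB, CFG, single_anchor=True
        )
        assert kept == []


class TestCascade:
    def _pairs(self):
        pairs = []
        for i in range(4):
            pairs.append(del_pair(f"d{i}", 1000 + 30 * i, 3000 + 30 * i))
        for i in range(3):
            pairs.append(
                ReadPairAlignment.from_mates(
                    f"t{i}", ("chr1", 8000 + 40 * i, 8050 + 40 * i, "+", 60),
                    ("chr2", 2000 + 40 * i, 2050 + 40 * i, "-", 60),
                )
            )
        return pairs

    def test_no_filters_counts_constant(self):
        report = run_cascade(self._pairs(), LIB, CFG)
        counts = report.counts
        assert counts[0] == counts[1] == counts[2]
        assert report.skipped == ["control", "low_map", "simp_rep"]

    def test_counts_monotone_non_increasing(self, germline_exp):
        tumor = germline_exp.simulate("tumor", coverage=15.0, seed=3)
        control = germline_exp.simulate("control", coverage=15.0, seed=4)
        report = run_cascade(
            tumor, germline_exp.lib, germline_exp.filter_cfg,
            control_pairs=control,
            lowmap=germline_exp.low_mappability_track(),
            simple_repeats=IntervalTrack("sr", []),
        )
        counts = report.counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_stage_order_does_not_change_final_set(self):
        # post-detection stages are pure predicates: any order, same survivors
        calls = [
            call(a=(0, 1000), b=(10_000, 11_000), size=900),
            call(sv_type="translocation", c2="chr2", support=2),
            call(sv_type="duplication", size=250),
            call(size=5_000),
        ]
        lowmap = track(("chr1", 0, 1000), ("chr1", 10_000, 10_800))
        rm = track(("chr1", 900, 1200), ("chr2", 2900, 3200))
        from svref.svfilter import _fails_lowmap, _fails_repeatmasker, _fails_size

        predicates = [
            lambda c: _fails_lowmap(c, lowmap, CFG),
            lambda c: _fails_repeatmasker(c, rm, CFG),
            lambda c: _fails_size(c, CFG),
        ]
        results = set()
        for order in itertools.permutations(range(3)):
            kept = list(calls)
            for idx in order:
                kept = [c for c in kept if not predicates[idx](c)]
            results.add(frozenset(id(c) for c in kept))
        assert len(results) == 1


class TestGermlineEndToEnd:
    def test_germline_artifact_patterns_and_zero_survivors(self, germline_exp):
        exp = germline_exp
        tumor = exp.simulate("tumor", coverage=20.0, seed=1)
        control = exp.simulate("control", coverage=20.0, seed=2)
        calls = exp.screen_and_call(tumor)
        matched = match_calls_to_truth(calls, exp.germline_truth, exp.lib)
        # interchromosomal retroelement -> translocation pattern,
        # intrachromosomal -> deletion pattern,
        # retrogene -> translocation plus one deletion per intron
        assert matched["germ_re_inter"]
        assert all(c.sv_type == "translocation" for c in matched["germ_re_inter"])
        assert matched["germ_re_intra"]
        for i in (1, 2, 3):
            hits = matched[f"germ_retrogene_intron{i}"]
            assert hits and all(c.sv_type == "deletion" for c in hits)
        assert matched["germ_retrogene"]

        ctrl_screened, _ = screen(control, exp.lib, exp.filter_cfg)
        kept, removed = compare_to_control(calls, ctrl_screened, exp.lib, exp.filter_cfg)
        # zero germline calls survive; precision 1.0 against somatic truth
        for c in kept:
            assert match_calls_to_truth([c], exp.truth, exp.lib)["DEL_SOM"]
        som = match_calls_to_truth(kept, exp.truth, exp.lib)
        assert som["DEL_SOM"]
        germ_after = match_calls_to_truth(kept, exp.germline_truth, exp.lib)
        assert not any(germ_after.values())
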