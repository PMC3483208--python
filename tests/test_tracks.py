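from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svref.io_formats import FormatError, GenomicInterval, revcomp
from svref.tracks import (
    IntervalTrack,
    KmerIndex,
    TrackConfig,
    breakpoint_mappability,
    kmer_occurrence_counts,
    low_mappability_track,
    merge_intervals,
    read_track,
    uniqueness_scores,
    write_track,
)

from conftest import random_genome


def brute_force_counts(genome, k):
    """Independent canonical k-mer counting oracle."""
    counter = Counter()
    for seq in genome.values():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            counter[min(km, revcomp(km))] += 1
    return {
        name: np.array(
            [counter[min(seq[i : i + k], revcomp(seq[i : i + k]))] for i in range(len(seq) - k + 1)]
        )
        for name, seq in genome.items()
    }


class TestKmerCounting:
    def test_random_genome_all_unique(self, rng):
        genome = random_genome(rng, {"c": 10_000})
        scores = uniqueness_scores(genome, 50)["c"]
        assert (scores == 1.0).all()
        assert scores.size == 10_000 - 49

    def test_matches_brute_force_oracle(self, rng):
        base = random_genome(rng, {"a": 3_000, "b": 2_000})
        seg = base["a"][500:700]
        genome = {"a": base["a"] + seg, "b": base["b"] + seg}  # 3 copies total
        k = 30
        expected = brute_force_counts(genome, k)
        got = kmer_occurrence_counts(genome, k)
        for name in genome:
            assert (got[name] == expected[name]).all()

    def test_three_copies_score_below_threshold(self, rng):
        base = random_genome(rng, {"c": 5_000})
        seg = base["c"][1_000:1_200]
        genome = {"c": base["c"] + seg + base["c"][:100] + seg}
        scores = uniqueness_scores(genome, 50)["c"]
        inside = scores[1_050 : 1_150]  # fully inside the first copy
        np.testing.assert_allclose(inside, 1 / 3)

    def test_two_copies_score_half_not_flagged(self, rng):
        base = random_genome(rng, {"c": 5_000})
        seg = base["c"][1_000:1_200]
        genome = {"c": base["c"] + base["c"][:77] + seg}
        scores = uniqueness_scores(genome, 50)["c"]
        assert (scores[1_050:1_150] == 0.5).all()
        cfg = TrackConfig(window=50, uniqueness_threshold=0.5, flank=265)
        track = low_mappability_track(genome, cfg)
        assert track.intervals == []  # "more than 2 times" means >= 3 copies

    def test_reverse_complement_counted(self, rng):
        genome = random_genome(rng, {"c": 2_000})
        seg = genome["c"][100:200]
        genome = {"c": genome["c"] + revcomp(seg) + genome["c"][:60] + seg}
        got = kmer_occurrence_counts(genome, 40)["c"]
        expected = brute_force_counts(genome, 40)["c"]
        assert (got == expected).all()
        assert got[120] >= 3

    def test_k_validation(self, rng):
        genome = random_genome(rng, {"c": 100})
        with pytest.raises(ValueError):
            kmer_occurrence_counts(genome, 0)
        with pytest.raises(ValueError):
            kmer_occurrence_counts(genome, 101)

    @given(st.integers(0, 2**32 - 1), st.integers(2, 6))
    def test_counts_oracle_property(self, seed, k):
        rng = np.random.default_rng(seed)
        genome = random_genome(rng, {"c": int(rng.integers(k, 120))})
        got = kmer_occurrence_counts(genome, k)
        expected = brute_force_counts(genome, k)
        assert (got["c"] == expected["c"]).all()

    def test_kmer_index_query(self, rng):
        genome = random_genome(rng, {"c": 1_000})
        idx = KmerIndex(genome, 25)
        assert idx.count(genome["c"][100:125]) == 1
        assert idx.count(revcomp(genome["c"][100:125])) == 1
        assert idx.count("A" * 25) in (0, idx.count("T" * 25))


class TestLowMappabilityTrack:
    def test_all_unique_empty(self, rng):
        genome = random_genome(rng, {"c": 5_000})
        assert low_mappability_track(genome).intervals == []

    def test_repeat_region_flagged_and_merged(self, rng):
        base = random_genome(rng, {"c": 5_000})
        seg = base["c"][1_000:1_500]  # 500 bp, spans multiple windows
        genome = {"c": base["c"] + seg + base["c"][:90] + seg}
        track = low_mappability_track(genome)
        covering = [iv for iv in track.intervals if iv.start <= 1_200 < iv.end]
        assert len(covering) == 1
        assert covering[0].length >= 300

    def test_non_adjacent_windows_not_merged(self):
        # synthetic scores: windows 0 and 2 low, window 1 unique
        scores = {"c": np.ones(151, dtype=np.float64)}
        scores["c"][:50] = 0.2
        scores["c"][100:150] = 0.2
        track = low_mappability_track({"c": "A" * 200}, TrackConfig(), scores=scores)
        assert len(track.intervals) == 2

    def test_monotone_in_repeat_copies(self, rng):
        base = random_genome(rng, {"c": 6_000})
        seg = base["c"][2_000:2_300]
        g3 = {"c": base["c"] + seg + base["c"][:70] + seg}
        g4 = {"c": g3["c"] + base["c"][70:140] + seg}
        t3 = low_mappability_track(g3)
        t4 = low_mappability_track(g4)
        # every flagged region of the 3-copy genome stays flagged with 4 copies
        shared_end = 6_000 + 300  # both genomes agree up to here
        for iv in t3.intervals:
            if iv.start >= shared_end:
                continue
            trimmed = GenomicInterval(iv.chrom, iv.start, min(iv.end, shared_end))
            assert t4.covered_bases(trimmed) == trimmed.length


class TestBreakpointMappability:
    def test_fully_unique_is_100(self, rng):
        genome = random_genome(rng, {"c": 5_000})
        scores = uniqueness_scores(genome, 50)
        assert breakpoint_mappability(scores, "c", 2_500) == 100.0

    def test_values_multiples_of_ten(self, rng):
        genome = random_genome(rng, {"c": 5_000})
        scores = uniqueness_scores(genome, 50)
        scores["c"][2_500:2_700] = 1 / 3
        value = breakpoint_mappability(scores, "c", 2_500)
        assert value in {0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0}

    def test_one_flank_repeat_is_50(self, rng):
        genome = random_genome(rng, {"c": 5_000})
        scores = uniqueness_scores(genome, 50)
        scores["c"][2_500 - 265 : 2_500] = 1 / 3  # left flank inside a repeat
        assert breakpoint_mappability(scores, "c", 2_500) == 50.0

    def test_all_repeat_is_0(self, rng):
        genome = random_genome(rng, {"c": 5_000})
        scores = uniqueness_scores(genome, 50)
        scores["c"][2_000:3_000] = 0.25
        assert breakpoint_mappability(scores, "c", 2_500) == 0.0

    def test_near_chromosome_end_uses_available_windows(self, rng):
        genome = random_genome(rng, {"c": 1_000})
        scores = uniqueness_scores(genome, 50)
        value = breakpoint_mappability(scores, "c", 100)  # only 2 left windows fit
        assert value == 100.0


class TestTrackIO:
    def test_overlapping_merged(self, tmp_path):
        (tmp_path / "t.bed").write_text("chr1\t100\t200\nchr1\t150\t300\n")
        track = read_track(tmp_path / "t.bed")
        assert track.intervals == [GenomicInterval("chr1", 100, 300)]

    def test_empty_file(self, tmp_path):
        (tmp_path / "e.bed").write_text("")
        assert read_track(tmp_path / "e.bed").intervals == []

    def test_round_trip(self, tmp_path, rng):
        intervals = [
            GenomicInterval("chr1", int(a), int(a) + int(b))
            for a, b in zip(rng.integers(0, 10_000, 30), rng.integers(1, 500, 30))
        ]
        track = IntervalTrack.from_intervals("t", intervals)
        write_track(track, tmp_path / "rt.bed")
        assert read_track(tmp_path / "rt.bed").intervals == track.intervals

    def test_malformed_line_number(self, tmp_path):
        (tmp_path / "bad.bed").write_text("chr1\t100\t200\nchr1\tbogus\n")
        with pytest.raises(FormatError, match=":2"):
            read_track(tmp_path / "bad.bed")


class TestCoveredBases:
    @given(st.integers(0, 2**32 - 1))
    def test_bitmap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        intervals = [
            GenomicInterval("c", int(a), int(a) + int(b))
            for a, b in zip(rng.integers(0, n, 15), rng.integers(1, 60, 15))
        ]
        track = IntervalTrack.from_intervals("t", intervals)
        bitmap = np.zeros(n + 100, dtype=bool)
        for iv in intervals:
            bitmap[iv.start : iv.end] = True
        q = GenomicInterval("c", int(rng.integers(0, n)), int(rng.integers(n, n + 100)))
        assert track.covered_bases(q) == int(bitmap[q.start : q.end].sum())

    def test_merge_intervals_sorted_disjoint(self, rng):
        intervals = [
            GenomicInterval("c", int(a), int(a) + int(b))
            for a, b in zip(rng.integers(0, 1000, 50), rng.integers(1, 100, 50))
        ]
        merged = merge_intervals(intervals)
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start  # disjoint and non-touching after merge
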