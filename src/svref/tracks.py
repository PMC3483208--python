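"""Mappability and repeat tracks.

Mappability is defined from k-mer uniqueness: the score of a position is
``1 / occurrences`` of the k-mer starting there, counting a k-mer and its
reverse complement as the same key (aligners map both strands).  Low
mappability regions are assembled as adjacent fixed-width windows whose
mean score falls below a threshold, and the breakpoint-mappability metric
reports the percentage of fully-unique windows in a fixed flank on each
side of a breakpoint.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .io_formats import Genome, GenomicInterval, read_bed, write_bed

__all__ = [
    "IntervalTrack",
    "TrackConfig",
    "KmerIndex",
    "kmer_occurrence_counts",
    "uniqueness_scores",
    "low_mappability_track",
    "breakpoint_mappability",
    "read_track",
    "write_track",
    "merge_intervals",
]


@dataclass(frozen=True)
class TrackConfig:
    """Windowing parameters for mappability tracks.

    ``flank`` is the region examined on each side of a breakpoint for the
    breakpoint-mappability metric; the default 265 equals insert mean minus
    read length for the reference library (315 - 50).
    """

    window: int = 50
    uniqueness_threshold: float = 0.5
    flank: int = 265
    kmer: int | None = None  # defaults to `window`

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if not (0 < self.uniqueness_threshold <= 1):
            raise ValueError("uniqueness_threshold must be in (0, 1]")
        if self.flank < self.window:
            raise ValueError("flank must be >= window")

    @property
    def k(self) -> int:
        return self.kmer if self.kmer is not None else self.window


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort by (chrom, start) and merge overlapping or touching intervals."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class IntervalTrack:
    """A named, sorted, merged set of genomic intervals (BED semantics)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Iterable[GenomicInterval]
    ) -> "IntervalTrack":
        return cls(name, merge_intervals(intervals))

    def __post_init__(self) -> None:
        self._index: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            starts, ends = self._index.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def __len__(self) -> int:
        return len(self.intervals)

    def __bool__(self) -> bool:  # an empty track is still a valid track
        return True

    def covered_bases(self, interval: GenomicInterval) -> int:
        """Number of bases of ``interval`` covered by the track."""
        entry = self._index.get(interval.chrom)
        if entry is None:
            return 0
        starts, ends = entry
        i = bisect.bisect_right(ends, interval.start)
        covered = 0
        while i < len(starts) and starts[i] < interval.end:
            covered += min(ends[i], interval.end) - max(starts[i], interval.start)
            i += 1
        return covered

    def total_bases(self) -> int:
        return sum(iv.length for iv in self.intervals)


# ---------------------------------------------------------------------------
# Canonical k-mer counting (vectorised rolling hash)
# ---------------------------------------------------------------------------

_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
    _CODES[ord(chr(_b).lower())] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_HASH_BASE = np.uint64(0x9E3779B97F4A7C15 | 1)
_HASH_BASE_INV = np.uint64(pow(int(_HASH_BASE), -1, 1 << 64))


def _encode(seq: str) -> np.ndarray:
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _rolling_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """64-bit polynomial rolling hash of every k-mer (forward strand)."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    with np.errstate(over="ignore"):
        powers = np.empty(n, dtype=np.uint64)
        powers[0] = 1
        if n > 1:
            powers[1:] = np.multiply.accumulate(
                np.full(n - 1, _HASH_BASE, dtype=np.uint64)
            )
        inv_powers = np.empty(n, dtype=np.uint64)
        inv_powers[0] = 1
        if n > 1:
            inv_powers[1:] = np.multiply.accumulate(
                np.full(n - 1, _HASH_BASE_INV, dtype=np.uint64)
            )
        terms = (codes.astype(np.uint64) + np.uint64(1)) * powers
        prefix = np.zeros(n + 1, dtype=np.uint64)
        np.cumsum(terms, out=prefix[1:])
        window = prefix[k:] - prefix[:-k]
        return window * inv_powers[: n - k + 1]


def _canonical_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Strand-symmetric k-mer hashes: min(hash(kmer), hash(revcomp))."""
    fwd = _rolling_hashes(codes, k)
    rc_codes = _COMP[codes][::-1]
    rev_all = _rolling_hashes(rc_codes, k)
    # revcomp of codes[i:i+k] starts at position n-k-i of rc_codes
    rev = rev_all[::-1]
    return np.minimum(fwd, rev)


def kmer_occurrence_counts(genome: Genome, k: int) -> dict[str, np.ndarray]:
    """Per-position occurrence count of each k-mer across the whole genome.

    A k-mer and its reverse complement share one count.  Position ``i`` of
    the returned array for a chromosome holds the genome-wide occurrence
    count of the k-mer starting at ``i``; arrays have length ``L - k + 1``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    shortest = min(len(s) for s in genome.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest chromosome length {shortest}")
    hashed = {name: _canonical_hashes(_encode(seq), k) for name, seq in genome.items()}
    allh = np.concatenate(list(hashed.values()))
    _, inverse, counts = np.unique(allh, return_inverse=True, return_counts=True)
    per_pos = counts[inverse].astype(np.uint32)
    out: dict[str, np.ndarray] = {}
    offset = 0
    for name, h in hashed.items():
        out[name] = per_pos[offset : offset + h.size]
        offset += h.size
    return out


def uniqueness_scores(genome: Genome, k: int) -> dict[str, np.ndarray]:
    """Per-position uniqueness score 1/occurrences (no score in last k-1 bp)."""
    counts = kmer_occurrence_counts(genome, k)
    return {name: (1.0 / c).astype(np.float64) for name, c in counts.items()}


class KmerIndex:
    """Dictionary-backed canonical k-mer counter for sequence queries.

    Used as the independent oracle for positional counts and as the
    sequence-level mapping-quality model on small genomes.
    """

    def __init__(self, genome: Genome, k: int):
        self.k = k
        self._counts: dict[int, int] = {}
        for seq in genome.values():
            h = _canonical_hashes(_encode(seq), k)
            for value in h.tolist():
                self._counts[value] = self._counts.get(value, 0) + 1

    def count(self, seq: str) -> int:
        if len(seq) != self.k:
            raise ValueError(f"query length {len(seq)} != k={self.k}")
        h = _canonical_hashes(_encode(seq), self.k)
        return self._counts.get(int(h[0]), 0)


# ---------------------------------------------------------------------------
# Track construction
# ---------------------------------------------------------------------------


def low_mappability_track(
    genome: Genome,
    cfg: TrackConfig = TrackConfig(),
    scores: Mapping[str, np.ndarray] | None = None,
) -> IntervalTrack:
    """Assemble low-mappability regions as merged adjacent windows.

    The genome is tiled into ``cfg.window``-sized intervals; a window is
    flagged when the mean per-position uniqueness score inside it is below
    ``cfg.uniqueness_threshold``; adjacent flagged windows merge.
    """
    if scores is None:
        scores = uniqueness_scores(genome, cfg.k)
    intervals: list[GenomicInterval] = []
    w = cfg.window
    for chrom, arr in scores.items():
        chrom_len = len(genome[chrom])
        for start in range(0, chrom_len, w):
            segment = arr[start : start + w]
            if segment.size == 0:
                continue
            if float(segment.mean()) < cfg.uniqueness_threshold:
                intervals.append(
                    GenomicInterval(chrom, start, min(start + w, chrom_len))
                )
    return IntervalTrack.from_intervals("low_mappability", intervals)


def breakpoint_mappability(
    scores: Mapping[str, np.ndarray],
    chrom: str,
    breakpoint: int,
    cfg: TrackConfig = TrackConfig(),
) -> float:
    """Percentage of fully-unique windows in the flanks of a breakpoint.

    Each flank of ``cfg.flank`` bp is tiled into ``cfg.window``-bp windows
    anchored at the breakpoint (the trailing remainder is dropped); a
    window qualifies when every per-position score inside it equals 1.
    Returns ``100 * qualifying / available`` where ``available`` is
    normally ``2 * (flank // window)`` but shrinks near chromosome ends.
    """
    arr = scores[chrom]
    w = cfg.window
    n_side = cfg.flank // w
    windows: list[tuple[int, int]] = []
    for i in range(n_side):
        windows.append((breakpoint - (i + 1) * w, breakpoint - i * w))
        windows.append((breakpoint + i * w, breakpoint + (i + 1) * w))
    available = qualifying = 0
    for start, end in windows:
        if start < 0 or end > arr.size:
            continue  # window extends past scored positions; flagged by caller
        available += 1
        if bool((arr[start:end] == 1.0).all()):
            qualifying += 1
    if available == 0:
        raise ValueError(
            f"breakpoint {chrom}:{breakpoint} has no full flank window in range"
        )
    return 100.0 * qualifying / available


# ---------------------------------------------------------------------------
# BED track I/O
# ---------------------------------------------------------------------------


def read_track(path: str | Path, name: str | None = None) -> IntervalTrack:
    """Read a BED file as a merged, sorted track."""
    intervals = read_bed(path)
    return IntervalTrack.from_intervals(name or Path(path).stem, intervals)


def write_track(track: IntervalTrack, path: str | Path) -> None:
    write_bed(track.intervals, path)
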