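"""Library/dataset statistics and a closed-form detection-probability model.

The detection model treats the number of breakpoint-spanning, fully
anchored, mappability-surviving read pairs as Poisson with rate
``lambda = m * N * w / G`` and reports ``P(X >= s)``.  The capture window
``w`` depends on how junction-spanning mates are handled; with the
simulator's majority-side placement a pair stays discordant whenever both
mate midpoints fall on opposite sides of the breakpoint, giving
``w = insert_mean - read_length`` (the default "anchor" mode).  The
stricter ``"inner"`` mode (``insert_mean - 2 * read_length``: both mates
fully anchored) and the optimistic ``"outer"`` mode (``insert_mean``) are
available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .io_formats import ReadPairAlignment
from .readsim import LibraryModel

__all__ = [
    "DetectionModel",
    "physical_coverage",
    "detection_probability",
    "LibraryStats",
    "library_stats",
    "relative_coverage",
]


@dataclass(frozen=True)
class DetectionModel:
    """Inputs of the closed-form SV detection-probability model."""

    n_pairs: int
    genome_size: int
    lib: LibraryModel
    mappable_fraction: float = 1.0
    min_support: int = 2

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be > 0")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if not (0.0 <= self.mappable_fraction <= 1.0):
            raise ValueError("mappable_fraction must be in [0, 1]")


def physical_coverage(n_pairs: int, lib: LibraryModel, genome_size: int) -> float:
    """Fold physical coverage: effective pairs x insert mean / genome size.

    ``n_pairs`` should count mapped, non-duplicate pairs.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    return n_pairs * lib.insert_mean / genome_size


_WINDOW_MODES = ("anchor", "inner", "outer")


def breakpoint_capture_window(lib: LibraryModel, mode: str = "anchor") -> float:
    if mode == "anchor":
        return lib.insert_mean - lib.read_length
    if mode == "inner":
        return lib.insert_mean - 2 * lib.read_length
    if mode == "outer":
        return lib.insert_mean
    raise ValueError(f"unknown window mode {mode!r}; choose from {_WINDOW_MODES}")


def detection_probability(model: DetectionModel, window_mode: str = "anchor") -> float:
    """P(detecting one breakpoint) = P(Poisson(lambda) >= min_support)."""
    window = breakpoint_capture_window(model.lib, window_mode)
    if window <= 0:
        warnings.warn("non-positive capture window; detection probability is 0")
        return 0.0
    lam = model.mappable_fraction * model.n_pairs * window / model.genome_size
    return float(sps.poisson.sf(model.min_support - 1, lam))


@dataclass
class LibraryStats:
    insert_mean: float
    insert_sd: float
    n_concordant: int
    mapq_hist: dict[int, int]
    counts: dict[str, int]


def library_stats(
    pairs: Sequence[ReadPairAlignment],
    max_concordant_span: float | None = None,
) -> LibraryStats:
    """Estimate insert statistics and tally mapping qualities and categories.

    Insert mean/SD come from same-chromosome FR pairs; spans above
    ``max_concordant_span`` (default 10x the median) are treated as
    discordant and excluded from the estimate.  The MAPQ histogram covers
    every mapped mate, so its total is twice the mapped pair count.
    """
    spans = []
    hist: dict[int, int] = {}
    counts = {
        "total": len(pairs),
        "unmapped": 0,
        "same_chrom": 0,
        "diff_chrom": 0,
    }
    for p in pairs:
        if not p.both_mapped:
            counts["unmapped"] += 1
            continue
        hist[p.mapq_a] = hist.get(p.mapq_a, 0) + 1
        hist[p.mapq_b] = hist.get(p.mapq_b, 0) + 1
        if p.same_chrom:
            counts["same_chrom"] += 1
            if p.orientation == "FR":
                spans.append(p.span)
        else:
            counts["diff_chrom"] += 1
    if not spans:
        raise ValueError("no concordant FR pairs available for insert estimation")
    arr = np.asarray(spans, dtype=np.float64)
    cutoff = max_concordant_span if max_concordant_span is not None else 10 * np.median(arr)
    arr = arr[arr <= cutoff]
    return LibraryStats(
        insert_mean=float(arr.mean()),
        insert_sd=float(arr.std(ddof=0)),
        n_concordant=int(arr.size),
        mapq_hist=hist,
        counts=counts,
    )


def relative_coverage(
    pairs: Sequence[ReadPairAlignment],
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
) -> dict[str, dict]:
    """Binned fragment counts normalised to genome-wide mean 1.0.

    Uses fragment midpoints of mapped same-chromosome pairs; reports the
    per-chromosome bin vector and median relative depth (copy-number
    changes shift a chromosome's median away from 1).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    bins = {
        chrom: np.zeros(max(1, -(-length // bin_size)), dtype=np.float64)
        for chrom, length in chrom_lengths.items()
    }
    for p in pairs:
        if not (p.both_mapped and p.same_chrom) or p.chrom_a not in bins:
            continue
        mid = (min(p.pos_a, p.pos_b) + max(p.end_a, p.end_b)) // 2
        arr = bins[p.chrom_a]
        arr[min(mid // bin_size, arr.size - 1)] += 1
    all_bins = np.concatenate(list(bins.values()))
    mean = all_bins.mean() if all_bins.size else 0.0
    out: dict[str, dict] = {}
    for chrom, arr in bins.items():
        rel = arr / mean if mean > 0 else arr
        out[chrom] = {"bins": rel, "median": float(np.median(rel))}
    return out
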