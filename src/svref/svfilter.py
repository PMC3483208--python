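"""Post-detection filter cascade.

Stage order: no-filter baseline (perfect
duplicates and zero-MAPQ reads already removed), mapping-quality filter,
imperfect-duplicate removal, tumor/control comparison, low-mappability
overlap, simple-repeat overlap, and the custom stage (RepeatMasker overlap
for weakly supported interchromosomal calls plus deletion/duplication size
cutoffs).  Call counts after every stage are recorded separately for
intra- and interchromosomal calls.

All overlap and size cutoffs are inclusive: an overlap fraction >= cutoff
removes the call, a size >= cutoff retains it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .io_formats import GenomicInterval, ReadPairAlignment, SvRecord
from .pairscreen import (
    FilterConfig,
    filter_mapq,
    remove_imperfect_duplicates,
    remove_perfect_duplicates,
)
from .readsim import LibraryModel
from .svcall import call_svs, cluster_pairs
from .tracks import IntervalTrack

__all__ = [
    "compare_to_control",
    "overlap_fraction",
    "filter_by_tracks",
    "filter_by_size",
    "run_cascade",
    "CascadeReport",
]


def compare_to_control(
    tumor_calls: Sequence[SvRecord],
    control_pairs: Sequence[ReadPairAlignment],
    lib: LibraryModel,
    cfg: FilterConfig,
    cluster_dist: float | None = None,
    single_anchor: bool = False,
) -> tuple[list[SvRecord], list[SvRecord]]:
    """Remove tumor calls whose anchors are also supported in the control.

    Control clusters are built from screened control pairs and retained at
    ``cfg.control_min_support`` (default 1: a single control read pair is
    evidence of a germline event).  A tumor call is removed when BOTH of
    its anchors intersect the corresponding anchors of any control
    cluster, ignoring SV type; ``single_anchor=True`` relaxes this to
    one-anchor intersection.
    """
    control_clusters = [
        c
        for c in cluster_pairs(control_pairs, lib, cfg, cluster_dist)
        if c.support >= cfg.control_min_support
    ]
    by_chrom: dict[str, list[tuple[GenomicInterval, GenomicInterval]]] = {}
    for c in control_clusters:
        by_chrom.setdefault(c.anchor_a.chrom, []).append((c.anchor_a, c.anchor_b))
        if c.anchor_b.chrom != c.anchor_a.chrom:
            by_chrom.setdefault(c.anchor_b.chrom, []).append((c.anchor_a, c.anchor_b))

    def germline(call: SvRecord) -> bool:
        candidates = by_chrom.get(call.anchor_a.chrom, [])
        for ca, cb in candidates:
            for first, second in ((ca, cb), (cb, ca)):
                hit_a = call.anchor_a.overlaps(first)
                hit_b = call.anchor_b.overlaps(second)
                if single_anchor:
                    if hit_a or hit_b:
                        return True
                elif hit_a and hit_b:
                    return True
        return False

    kept, removed = [], []
    for call in tumor_calls:
        (removed if germline(call) else kept).append(call)
    return kept, removed


def overlap_fraction(call: SvRecord, track: IntervalTrack) -> float:
    """Fraction of the call's summed anchor bases covered by a track."""
    len_a, len_b = call.anchor_a.length, call.anchor_b.length
    if len_a == 0 or len_b == 0:
        raise ValueError(f"zero-length anchor in call {call.name!r}")
    covered = track.covered_bases(call.anchor_a) + track.covered_bases(call.anchor_b)
    return covered / (len_a + len_b)


def _fails_lowmap(call: SvRecord, track: IntervalTrack | None, cfg: FilterConfig) -> bool:
    if track is None:
        return False
    cutoff = cfg.lowmap_cutoff_inter if call.interchromosomal else cfg.lowmap_cutoff_intra
    return overlap_fraction(call, track) >= cutoff


def _fails_simple_repeat(
    call: SvRecord, track: IntervalTrack | None, cfg: FilterConfig
) -> bool:
    if track is None:
        return False
    return overlap_fraction(call, track) >= cfg.simple_repeat_cutoff


def _fails_repeatmasker(
    call: SvRecord, track: IntervalTrack | None, cfg: FilterConfig
) -> bool:
    if track is None or not call.interchromosomal:
        return False
    if not (cfg.min_support <= call.support <= cfg.repeatmasker_max_support):
        return False
    return overlap_fraction(call, track) >= cfg.repeatmasker_cutoff


def _fails_size(call: SvRecord, cfg: FilterConfig) -> bool:
    if call.size is None:
        return False
    if call.sv_type == "deletion":
        return call.size < cfg.del_min_size
    if call.sv_type == "duplication":
        return call.size < cfg.dup_min_size
    return False


def filter_by_tracks(
    calls: Sequence[SvRecord],
    lowmap: IntervalTrack | None,
    simple_repeats: IntervalTrack | None,
    repeat_masker: IntervalTrack | None,
    cfg: FilterConfig,
) -> tuple[list[SvRecord], dict[str, list[SvRecord]]]:
    """Apply the three repeat/mappability overlap filters.

    Removal reasons are attributed in order low-mappability, simple
    repeats, RepeatMasker; a call is removed once.
    """
    kept: list[SvRecord] = []
    removed: dict[str, list[SvRecord]] = {
        "low_mappability": [],
        "simple_repeats": [],
        "repeat_masker": [],
    }
    for call in calls:
        if _fails_lowmap(call, lowmap, cfg):
            removed["low_mappability"].append(call)
        elif _fails_simple_repeat(call, simple_repeats, cfg):
            removed["simple_repeats"].append(call)
        elif _fails_repeatmasker(call, repeat_masker, cfg):
            removed["repeat_masker"].append(call)
        else:
            kept.append(call)
    return kept, removed


def filter_by_size(
    calls: Sequence[SvRecord], cfg: FilterConfig
) -> tuple[list[SvRecord], list[SvRecord]]:
    """Remove undersized deletions (< 600 bp) and duplications (< 300 bp).

    Inversions and translocations pass through unaffected.
    """
    kept, removed = [], []
    for call in calls:
        (removed if _fails_size(call, cfg) else kept).append(call)
    return kept, removed


@dataclass
class CascadeReport:
    """Per-stage call accounting for the filter cascade."""

    stages: list[dict] = field(default_factory=list)
    kept: list[SvRecord] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def record(self, label: str, calls: Sequence[SvRecord]) -> None:
        intra = sum(1 for c in calls if not c.interchromosomal)
        inter = len(calls) - intra
        self.stages.append({"stage": label, "intra": intra, "inter": inter, "total": len(calls)})

    @property
    def counts(self) -> list[int]:
        return [s["total"] for s in self.stages]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as out:
            json.dump({"stages": self.stages, "skipped": self.skipped}, out, indent=2)


def run_cascade(
    tumor_pairs: Sequence[ReadPairAlignment],
    lib: LibraryModel,
    cfg: FilterConfig,
    control_pairs: Sequence[ReadPairAlignment] | None = None,
    lowmap: IntervalTrack | None = None,
    simple_repeats: IntervalTrack | None = None,
    repeat_masker: IntervalTrack | None = None,
    cluster_dist: float | None = None,
) -> CascadeReport:
    """Run the full pre- and post-detection cascade with per-stage counts.

    The three pre-detection stages re-run detection on progressively
    cleaner pair sets (per-stage call counts measure each filter's effect);
    the post-detection stages whittle down the final call set.  Stages
    without inputs (no control, no track) are skipped with a note.  The
    surviving calls are tagged high-confidence via ``CascadeReport.kept``.
    """
    report = CascadeReport()
    zero_mq = replace(cfg, mq_min=1)

    def detect(pairs):
        return call_svs(cluster_pairs(pairs, lib, cfg, cluster_dist), cfg)

    mapped = [p for p in tumor_pairs if p.both_mapped]
    base = filter_mapq(remove_perfect_duplicates(list(mapped)), zero_mq)
    report.record("no_filt", detect(base))

    mq_pairs = filter_mapq(base, cfg)
    report.record("m_qual", detect(mq_pairs))

    dedup_pairs = remove_imperfect_duplicates(mq_pairs, cfg)
    calls = detect(dedup_pairs)
    report.record("i_dupl", calls)

    if control_pairs is not None:
        control_mapped = [p for p in control_pairs if p.both_mapped]
        control_screened = remove_imperfect_duplicates(
            filter_mapq(remove_perfect_duplicates(list(control_mapped)), cfg), cfg
        )
        calls, _ = compare_to_control(calls, control_screened, lib, cfg, cluster_dist)
        report.record("control", calls)
    else:
        report.skipped.append("control")

    if lowmap is not None:
        calls = [c for c in calls if not _fails_lowmap(c, lowmap, cfg)]
        report.record("low_map", calls)
    else:
        report.skipped.append("low_map")

    if simple_repeats is not None:
        calls = [c for c in calls if not _fails_simple_repeat(c, simple_repeats, cfg)]
        report.record("simp_rep", calls)
    else:
        report.skipped.append("simp_rep")

    calls = [c for c in calls if not _fails_repeatmasker(c, repeat_masker, cfg)]
    calls, _ = filter_by_size(calls, cfg)
    report.record("custom", calls)

    report.kept = calls
    return report
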