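"""One-command synthetic experiment builder.

Builds toy genomes with engineered breakpoint mappability, a 20-SV
benchmark truth set (10 large deletions with a fixed size catalog plus 10
interchromosomal translocations as 5 reciprocal pairs), germline
retroelement/retrogene fixtures present in both tumor and control, and
duplicate-injection demos -- everything the tests and the acceptance run
need, generated from a seed with no external data.

Mappability engineering: a breakpoint flank is tiled into 50-bp windows;
to hit a target fraction f, ``ceil((100 - f) / 10)`` windows across the
junction's two flanks (10% granularity, so the measured metric is f
rounded down to a multiple of 10) are overwritten with repeat runs
planted once per flank-period in three periods, making every position
inside a covered window carry a >= 3-copy k-mer while every position
outside stays unique.  See :func:`_apply_spikes` for the construction
details that keep the metric exact.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    Genome,
    GenomicInterval,
    ReadPairAlignment,
    SvRecord,
    write_bedpe,
    write_fasta,
)
from .pairscreen import FilterConfig, screen
from .readsim import (
    LibraryModel,
    SimConfig,
    UniqueKmerMapq,
    fragments_to_alignments,
    inject_duplicates,
    simulate_fragments,
)
from .rearrange import (
    CoordinateMap,
    GermlineSpec,
    RetroelementInsertion,
    RetrogeneInsertion,
    SvPlanEntry,
    apply_plan,
    inject_germline_artifacts,
    plan_to_table,
)
from .svcall import call_svs, cluster_pairs
from .tracks import IntervalTrack, TrackConfig, kmer_occurrence_counts, write_track

log = logging.getLogger(__name__)

__all__ = [
    "TABLE1_TRANSLOCATIONS",
    "TABLE1_DELETIONS",
    "PRESETS",
    "Experiment",
    "build_experiment",
    "dup_demo_pairs",
    "match_call",
    "match_calls_to_truth",
]

# (name, reciprocal name, chrom A, chrom B, mappability A_B, mappability B_A)
TABLE1_TRANSLOCATIONS = [
    ("TR_15_12", "TR_12_15", "chr15", "chr12", 100.0, 100.0),
    ("TR_10_X", "TR_X_10", "chr10", "chrX", 50.0, 50.0),
    ("TR_16_6", "TR_6_16", "chr16", "chr6", 70.2, 52.8),
    ("TR_7_11", "TR_11_7", "chr7", "chr11", 66.0, 73.8),
    ("TR_14_13", "TR_13_14", "chr14", "chr13", 18.5, 36.4),
]

# (name, chrom, size bp, mappability %)
TABLE1_DELETIONS = [
    ("DEL_1", "chr1", 576_373, 100.0),
    ("DEL_2", "chr2", 46_610, 95.1),
    ("DEL_3", "chr3", 600_033, 85.3),
    ("DEL_4", "chr4", 5_963, 100.0),
    ("DEL_5", "chr5", 64_735, 100.0),
    ("DEL_8", "chr8", 1_433, 77.4),
    ("DEL_9", "chr9", 10_789, 100.0),
    ("DEL_17", "chr17", 3_066, 100.0),
    ("DEL_18", "chr18", 1_000_440, 100.0),
    ("DEL_19", "chr19", 21_449, 100.0),
]

PRESETS = ("table1", "germline-demo", "minimal", "dup-demo")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n, dtype=np.uint8)]).decode()


def windows_for_target(value: float) -> int:
    """Number of 50-bp repeat windows for a mappability target: one per
    started 10% of non-mappability, ceil((100 - f) / 10)."""
    if not (0 <= value <= 100):
        raise ValueError("mappability target must be a percentage")
    return min(10, int(math.ceil((100.0 - value) / 10.0 - 1e-9)))


def engineered_mappability(value: float) -> int:
    """The breakpoint-mappability value the fixture can realise for a target
    (multiple-of-10 granularity; logged when it differs from the request)."""
    realised = 100 - 10 * windows_for_target(value)
    if abs(realised - value) > 1e-9:
        log.warning("mappability target %.1f engineered as %d", value, realised)
    return realised


@dataclass
class Experiment:
    """An in-memory synthetic experiment plus lazy derived artifacts."""

    preset: str
    seed: int
    ref: Genome
    tumor: Genome
    control: Genome
    tumor_map: CoordinateMap
    control_map: CoordinateMap
    truth: list[SvRecord]
    germline_truth: list[SvRecord]
    plan: list[SvPlanEntry]
    lib: LibraryModel
    filter_cfg: FilterConfig
    track_cfg: TrackConfig
    mappability_targets: dict[str, int] = field(default_factory=dict)
    record_flanks: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    repeat_intervals: list[GenomicInterval] = field(default_factory=list)
    _ref_counts: dict | None = field(default=None, repr=False)

    # -- derived artifacts ---------------------------------------------------

    @property
    def ref_kmer_counts(self) -> dict:
        if self._ref_counts is None:
            self._ref_counts = kmer_occurrence_counts(self.ref, self.lib.read_length)
        return self._ref_counts

    @property
    def mapq_model(self) -> UniqueKmerMapq:
        return UniqueKmerMapq(self.ref_kmer_counts)

    def repeat_masker_track(self) -> IntervalTrack:
        return IntervalTrack.from_intervals("repeat_masker", self.repeat_intervals)

    def measured_mappability(self, record_name: str) -> float:
        """Junction mappability of a truth record: percentage of fully-unique
        windows across its two breakpoint flanks."""
        flanks = self.record_flanks[record_name]
        w = self.track_cfg.window
        n_side = self.track_cfg.flank // w
        qualifying = available = 0
        for chrom, bp, side in flanks:
            counts = self.ref_kmer_counts[chrom]
            for i in range(n_side):
                if side == "left":
                    a, b = bp - (i + 1) * w, bp - i * w
                else:
                    a, b = bp + i * w, bp + (i + 1) * w
                if a < 0 or b > counts.size:
                    continue
                available += 1
                if bool((counts[a:b] == 1).all()):
                    qualifying += 1
        return 100.0 * qualifying / available

    def low_mappability_track(self) -> IntervalTrack:
        from .tracks import low_mappability_track

        scores = {
            name: (1.0 / arr).astype(np.float64)
            for name, arr in self.ref_kmer_counts.items()
        }
        return low_mappability_track(self.ref, self.track_cfg, scores=scores)

    # -- pipeline shortcuts --------------------------------------------------

    def n_pairs_for_coverage(self, coverage: float, which: str = "tumor") -> int:
        genome = self.tumor if which == "tumor" else self.control
        size = sum(len(s) for s in genome.values())
        return int(round(coverage * size / self.lib.insert_mean))

    def simulate(
        self,
        which: str = "tumor",
        coverage: float = 19.0,
        seed: int = 0,
        perfect_dup_rate: float = 0.0,
        imperfect_dup_rate: float = 0.0,
    ) -> list[ReadPairAlignment]:
        """Simulate a library from tumor or control and emit truth alignments."""
        genome = self.tumor if which == "tumor" else self.control
        cmap = self.tumor_map if which == "tumor" else self.control_map
        cfg = SimConfig(
            n_pairs=self.n_pairs_for_coverage(coverage, which),
            seed=seed,
            perfect_dup_rate=perfect_dup_rate,
            imperfect_dup_rate=imperfect_dup_rate,
        )
        fragments, _ = simulate_fragments(genome, self.lib, cfg)
        fragments = inject_duplicates(fragments, cfg, seed=cfg.seed + 1)
        return fragments_to_alignments(
            fragments, self.lib, cmap, self.mapq_model, self.filter_cfg.min_anchor
        )

    def screen_and_call(
        self, pairs: list[ReadPairAlignment], cluster_dist: float | None = None
    ) -> list[SvRecord]:
        screened, _ = screen(pairs, self.lib, self.filter_cfg)
        clusters = cluster_pairs(screened, self.lib, self.filter_cfg, cluster_dist)
        return call_svs(clusters, self.filter_cfg)

    def detection_rate(
        self, coverage: float, seed: int, which: str = "tumor"
    ) -> tuple[int, int]:
        """(detected, total) somatic truth records at a coverage and seed."""
        pairs = self.simulate(which=which, coverage=coverage, seed=seed)
        calls = self.screen_and_call(pairs)
        matched = match_calls_to_truth(calls, self.truth, self.lib)
        return sum(1 for hits in matched.values() if hits), len(self.truth)

    # -- persistence ---------------------------------------------------------

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "tracks").mkdir(parents=True, exist_ok=True)
        write_fasta(self.ref, out / "ref.fa")
        write_fasta(self.tumor, out / "tumor.fa")
        write_fasta(self.control, out / "control.fa")
        plan_to_table(self.plan, out / "plan.tsv")
        write_bedpe(self.truth + self.germline_truth, out / "truth.bedpe")
        self.tumor_map.write_tsv(out / "tumor.liftover.tsv")
        self.control_map.write_tsv(out / "control.liftover.tsv")
        write_track(self.low_mappability_track(), out / "tracks" / "low_mappability.bed")
        write_track(self.repeat_masker_track(), out / "tracks" / "repeat_masker.bed")
        write_track(
            IntervalTrack("simple_repeats", []), out / "tracks" / "simple_repeats.bed"
        )
        manifest = {
            "preset": self.preset,
            "seed": self.seed,
            "library": {
                "read_length": self.lib.read_length,
                "insert_mean": self.lib.insert_mean,
                "insert_sd": self.lib.insert_sd,
            },
            "mappability_targets": self.mappability_targets,
            "truth": [r.name for r in self.truth],
            "germline_truth": [r.name for r in self.germline_truth],
            "chromosome_lengths": {c: len(s) for c, s in self.ref.items()},
        }
        with open(out / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Mappability spike-ins
# ---------------------------------------------------------------------------


@dataclass
class _FlankSpike:
    chrom: str
    breakpoint: int
    side: str  # 'left' or 'right'
    n_windows: int


def _spike_plan(
    record_flanks: dict[str, list[tuple[str, int, str]]],
    targets: dict[str, int],
    window: int,
    flank: int,
) -> list[_FlankSpike]:
    """Distribute repeat windows over each record's two flanks (first flank
    gets the larger half)."""
    spikes: list[_FlankSpike] = []
    n_side = flank // window
    for name, flanks in record_flanks.items():
        w_total = (100 - targets[name]) // 10
        w_first = w_total - w_total // 2
        for (chrom, bp, side), w in zip(flanks, (w_first, w_total // 2)):
            if w == 0:
                continue
            if w > n_side:
                raise ValueError(f"{name}: cannot place {w} repeat windows per flank")
            spikes.append(_FlankSpike(chrom, bp, side, w))
    return spikes


def _apply_spikes(
    genome: Genome,
    spikes: list[_FlankSpike],
    rng: np.random.Generator,
    window: int,
    flank: int,
    periods: int = 3,
) -> tuple[Genome, list[GenomicInterval]]:
    """Overwrite flank windows with multi-copy repeat runs.

    A spike's repeat unit is planted once per 265-bp-period for ``periods``
    periods away from the breakpoint, always occupying the outermost
    ``n_windows`` windows of each period, so (a) the breakpoint-mappability
    metric -- which only sees the innermost period -- measures exactly the
    rounded target, and (b) the whole read-accessible neighbourhood is
    suppressed at the same rate, including positions that large-insert
    fragments reach beyond the metric flank.  Each run extends
    ``window - 1`` bp past its windows toward the breakpoint so that every
    position inside a covered window carries a fully-repeat k-mer while
    every position outside stays unique.  The single bases flanking each
    run are set to letters that differ between the copies, which keeps
    run-boundary junction k-mers collision-free (a 1-bp overhang would
    otherwise collide between copies with probability 1/4 and corrupt the
    metric).
    """
    n_side = flank // window
    period = n_side * window
    letters = b"ACGT"
    arrays: dict[str, bytearray] = {}
    repeat_intervals: list[GenomicInterval] = []

    def _bounds_check(arr: bytearray, spike: _FlankSpike, start: int, end: int) -> None:
        if start - 1 < 0 or end >= len(arr):
            raise ValueError(
                f"repeat spike at {spike.chrom}:{spike.breakpoint} out of bounds"
            )

    for spike in spikes:
        arr = arrays.setdefault(
            spike.chrom, bytearray(genome[spike.chrom], "ascii")
        )
        if spike.n_windows == n_side:
            # fully suppressed flank: a tandem repeat tiled with one period
            base_unit = _random_seq(rng, period).encode("ascii")
            total = period * periods + window - 1
            tiled = (base_unit * (periods + 1))[:total]
            if spike.side == "left":
                start = spike.breakpoint - period * periods
            else:
                start = spike.breakpoint
            end = start + total
            _bounds_check(arr, spike, start, end)
            arr[start:end] = tiled
            # boundary bases must break the tandem periodicity, or junction
            # k-mers collide with interior copies and corrupt the metric
            arr[start - 1] = next(b for b in letters if b != base_unit[period - 1])
            arr[end] = next(b for b in letters if b != base_unit[total % period])
            repeat_intervals.append(GenomicInterval(spike.chrom, start, end))
            continue
        length = window * spike.n_windows + window - 1
        unit = _random_seq(rng, length).encode("ascii")
        for k in range(periods):
            if spike.side == "left":
                start = spike.breakpoint - period * (k + 1)
                pre, post = letters[(k + 1) % 4], letters[k % 4]
            else:
                start = spike.breakpoint + period * (k + 1) - window * spike.n_windows
                pre, post = letters[(k - 1) % 4], letters[k % 4]
            end = start + length
            _bounds_check(arr, spike, start, end)
            arr[start:end] = unit
            arr[start - 1] = pre
            arr[end] = post
            repeat_intervals.append(GenomicInterval(spike.chrom, start, end))
    out: Genome = {}
    for name, seq in genome.items():
        out[name] = arrays[name].decode() if name in arrays else seq
    return out, repeat_intervals


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def build_experiment(
    preset: str = "table1",
    seed: int = 0,
    out_dir: str | Path | None = None,
    lib: LibraryModel | None = None,
    filter_cfg: FilterConfig | None = None,
    chrom_margin: int = 30_000,
    tr_chrom_length: int = 60_000,
) -> Experiment:
    """Build a synthetic experiment for a named preset.

    Presets: ``table1`` (the 20-SV benchmark: 10 large deletions and 5
    reciprocal translocations across mappability classes),
    ``germline-demo`` (retroelement/retrogene artifacts shared by tumor
    and control plus one somatic deletion), ``minimal`` (one clean
    deletion).  The ``dup-demo`` pair fixture is available via
    :func:`dup_demo_pairs`.  Same seed, same output -- byte for byte.
    """
    lib = lib or LibraryModel()
    filter_cfg = filter_cfg or FilterConfig()
    track_cfg = TrackConfig(
        window=lib.read_length,
        flank=int(lib.insert_mean - lib.read_length),
        kmer=lib.read_length,
    )
    rng = np.random.default_rng(seed)
    if preset == "table1":
        exp = _build_table1(
            seed, rng, lib, filter_cfg, track_cfg, chrom_margin, tr_chrom_length
        )
    elif preset == "germline-demo":
        exp = _build_germline_demo(seed, rng, lib, filter_cfg, track_cfg)
    elif preset == "minimal":
        exp = _build_minimal(seed, rng, lib, filter_cfg, track_cfg)
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS[:3]}")
    if out_dir is not None:
        exp.write(out_dir)
    return exp


def _build_table1(
    seed, rng, lib, filter_cfg, track_cfg, margin, tr_len
) -> Experiment:
    window, flank = track_cfg.window, track_cfg.flank
    chrom_lengths: dict[str, int] = {}
    for _, chrom, size, _m in TABLE1_DELETIONS:
        chrom_lengths[chrom] = size + 2 * margin
    for _, _, chrom_a, chrom_b, _, _ in TABLE1_TRANSLOCATIONS:
        chrom_lengths[chrom_a] = tr_len
        chrom_lengths[chrom_b] = tr_len

    def _order(name: str) -> tuple:
        tail = name[3:]
        return (0, int(tail)) if tail.isdigit() else (1, tail)

    genome: Genome = {
        name: _random_seq(rng, chrom_lengths[name])
        for name in sorted(chrom_lengths, key=_order)
    }

    plan: list[SvPlanEntry] = []
    record_flanks: dict[str, list[tuple[str, int, str]]] = {}
    targets: dict[str, int] = {}
    for name, chrom, size, mapp in TABLE1_DELETIONS:
        s, e = margin, margin + size
        plan.append(SvPlanEntry(name, "deletion", chrom, s, size=size))
        record_flanks[name] = [(chrom, s, "left"), (chrom, e, "right")]
        targets[name] = engineered_mappability(mapp)
    for name, recip, chrom_a, chrom_b, mapp_ab, mapp_ba in TABLE1_TRANSLOCATIONS:
        pa = chrom_lengths[chrom_a] // 2
        pb = chrom_lengths[chrom_b] // 2
        plan.append(
            SvPlanEntry(name, "translocation", chrom_a, pa, chrom_b=chrom_b, pos_b=pb)
        )
        record_flanks[name] = [(chrom_a, pa, "left"), (chrom_b, pb, "right")]
        record_flanks[recip] = [(chrom_b, pb, "left"), (chrom_a, pa, "right")]
        targets[name] = engineered_mappability(mapp_ab)
        targets[recip] = engineered_mappability(mapp_ba)

    spikes = _spike_plan(record_flanks, targets, window, flank)
    ref, repeat_intervals = _apply_spikes(genome, spikes, rng, window, flank)

    tumor, truth, tumor_map = apply_plan(ref, plan)
    _rename_reciprocals(truth)
    return Experiment(
        preset="table1",
        seed=seed,
        ref=ref,
        tumor=tumor,
        control=ref,
        tumor_map=tumor_map,
        control_map=CoordinateMap.identity(ref),
        truth=truth,
        germline_truth=[],
        plan=plan,
        lib=lib,
        filter_cfg=filter_cfg,
        track_cfg=track_cfg,
        mappability_targets=targets,
        record_flanks=record_flanks,
        repeat_intervals=repeat_intervals,
    )


def _rename_reciprocals(records: list[SvRecord]) -> None:
    """TR_A_B_recip -> TR_B_A: label each junction by its own chromosome order."""
    for rec in records:
        if rec.name.endswith("_recip"):
            stem = rec.name[: -len("_recip")]
            parts = stem.split("_")
            if len(parts) == 3 and parts[0] == "TR":
                rec.name = f"TR_{parts[2]}_{parts[1]}"


def _build_germline_demo(seed, rng, lib, filter_cfg, track_cfg) -> Experiment:
    genome: Genome = {
        "chrA": _random_seq(rng, 120_000),
        "chrB": _random_seq(rng, 120_000),
        "chrC": _random_seq(rng, 80_000),
    }
    exon_len, intron_len, gene_start = 600, 2_000, 60_000
    exons = []
    pos = gene_start
    for _ in range(4):
        exons.append(GenomicInterval("chrA", pos, pos + exon_len))
        pos += exon_len + intron_len
    spec = GermlineSpec(
        retroelements=(
            RetroelementInsertion(
                "germ_re_inter", GenomicInterval("chrA", 20_000, 21_500), "chrB", 40_000
            ),
            RetroelementInsertion(
                "germ_re_intra", GenomicInterval("chrA", 100_000, 101_500), "chrA", 110_000
            ),
        ),
        retrogenes=(
            RetrogeneInsertion("germ_retrogene", tuple(exons), "chrB", 80_000),
        ),
    )
    germ_genome, germline_truth, germ_map = inject_germline_artifacts(genome, spec)
    plan = [SvPlanEntry("DEL_SOM", "deletion", "chrC", 30_000, size=6_000)]
    tumor, truth, som_map = apply_plan(germ_genome, plan)
    return Experiment(
        preset="germline-demo",
        seed=seed,
        ref=genome,
        tumor=tumor,
        control=germ_genome,
        tumor_map=som_map.compose(germ_map),
        control_map=germ_map,
        truth=truth,
        germline_truth=germline_truth,
        plan=plan,
        lib=lib,
        filter_cfg=filter_cfg,
        track_cfg=track_cfg,
    )


def _build_minimal(seed, rng, lib, filter_cfg, track_cfg) -> Experiment:
    genome: Genome = {
        "chr1": _random_seq(rng, 50_000),
        "chr2": _random_seq(rng, 50_000),
    }
    plan = [SvPlanEntry("DEL_MIN", "deletion", "chr1", 20_000, size=5_000)]
    tumor, truth, tumor_map = apply_plan(genome, plan)
    return Experiment(
        preset="minimal",
        seed=seed,
        ref=genome,
        tumor=tumor,
        control=genome,
        tumor_map=tumor_map,
        control_map=CoordinateMap.identity(genome),
        truth=truth,
        germline_truth=[],
        plan=plan,
        lib=lib,
        filter_cfg=filter_cfg,
        track_cfg=track_cfg,
    )


def build_breakpoint_fixture(
    w_left: int = 0,
    w_right: int = 0,
    seed: int = 0,
    chrom_length: int = 60_000,
    del_size: int = 5_000,
    lib: LibraryModel | None = None,
    filter_cfg: FilterConfig | None = None,
) -> Experiment:
    """A one-deletion experiment with engineered flank mappability.

    ``w_left``/``w_right`` repeat windows are planted on the outer flanks
    of the deletion's two breakpoints; the resulting mappable fraction of
    each breakpoint neighbourhood is ``1 - w * window / flank`` per side,
    which is the ``mappable_fraction`` input of the detection model.
    """
    lib = lib or LibraryModel()
    filter_cfg = filter_cfg or FilterConfig()
    track_cfg = TrackConfig(
        window=lib.read_length,
        flank=int(lib.insert_mean - lib.read_length),
        kmer=lib.read_length,
    )
    rng = np.random.default_rng(seed)
    genome: Genome = {"chr1": _random_seq(rng, chrom_length)}
    s = (chrom_length - del_size) // 2
    e = s + del_size
    plan = [SvPlanEntry("DEL_POWER", "deletion", "chr1", s, size=del_size)]
    flanks = {"DEL_POWER": [("chr1", s, "left"), ("chr1", e, "right")]}
    spikes = [
        _FlankSpike("chr1", bp, side, w)
        for (_, bp, side), w in zip(flanks["DEL_POWER"], (w_left, w_right))
        if w > 0
    ]
    ref, repeat_intervals = _apply_spikes(
        genome, spikes, rng, track_cfg.window, track_cfg.flank
    )
    tumor, truth, tumor_map = apply_plan(ref, plan)
    targets = {"DEL_POWER": 100 - 10 * (w_left + w_right)}
    return Experiment(
        preset="breakpoint-power",
        seed=seed,
        ref=ref,
        tumor=tumor,
        control=ref,
        tumor_map=tumor_map,
        control_map=CoordinateMap.identity(ref),
        truth=truth,
        germline_truth=[],
        plan=plan,
        lib=lib,
        filter_cfg=filter_cfg,
        track_cfg=track_cfg,
        mappability_targets=targets,
        record_flanks=flanks,
        repeat_intervals=repeat_intervals,
    )


def mappable_fraction(w_left: int, w_right: int, track_cfg: TrackConfig) -> float:
    """Mappable fraction of a breakpoint neighbourhood engineered by
    :func:`build_breakpoint_fixture` -- the product of per-side unique
    fractions over the capture flank."""
    per_side = lambda w: 1.0 - w * track_cfg.window / track_cfg.flank
    return per_side(w_left) * per_side(w_right)


def dup_demo_pairs(
    lib: LibraryModel | None = None, offsets: tuple[tuple[int, int], ...] = ((0, 0), (2, 2), (4, 4))
) -> list[ReadPairAlignment]:
    """The imperfect-duplicate demo: one discordant fragment amplified into a
    chain of near-duplicates with 2-bp offsets between neighbours.

    Without imperfect-duplicate removal the stack clusters into one
    spurious deletion call; with it, a single representative survives and
    the minimum-support cutoff silences the locus.
    """
    lib = lib or LibraryModel()
    r = lib.read_length
    base_a, base_b = 10_000, 10_000 + 1_550
    pairs = []
    for i, (da, db) in enumerate(offsets):
        pairs.append(
            ReadPairAlignment.from_mates(
                f"dup{i}",
                ("chr1", base_a + da, base_a + da + r, "+", 60),
                ("chr1", base_b + db, base_b + db + r, "-", 60),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Truth matching
# ---------------------------------------------------------------------------


def match_call(
    call: SvRecord, rec: SvRecord, lib: LibraryModel, slack: float | None = None
) -> bool:
    """Does a call support a truth record?

    Requires matching SV type, chromosome-wise anchor correspondence (in
    either order), anchors within ``slack`` (default: insert mean) of the
    truth breakpoints, and -- when the truth record declares junction
    sides -- the call anchor centred on the declared side of the
    breakpoint, which separates the two calls of a reciprocal
    translocation.
    """
    if call.sv_type != rec.sv_type:
        return False
    slack = lib.insert_mean if slack is None else slack
    side_slack = lib.read_length // 2
    sides = rec.sides or (None, None)
    for ca, cb in ((call.anchor_a, call.anchor_b), (call.anchor_b, call.anchor_a)):
        ok = True
        for c_iv, t_iv, side in ((ca, rec.anchor_a, sides[0]), (cb, rec.anchor_b, sides[1])):
            if c_iv.chrom != t_iv.chrom:
                ok = False
                break
            bp = t_iv.start
            if c_iv.distance_to(bp) > slack and not c_iv.overlaps(t_iv):
                ok = False
                break
            mid = (c_iv.start + c_iv.end) / 2
            if side == "left" and mid >= bp + side_slack:
                ok = False
                break
            if side == "right" and mid <= bp - side_slack:
                ok = False
                break
        if ok:
            return True
    return False


def match_calls_to_truth(
    calls: list[SvRecord],
    truth: list[SvRecord],
    lib: LibraryModel,
    slack: float | None = None,
) -> dict[str, list[SvRecord]]:
    """Map every truth record name to the calls supporting it."""
    return {
        rec.name: [c for c in calls if match_call(c, rec, lib, slack)] for rec in truth
    }
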