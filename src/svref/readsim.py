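"""Paired-end sequencing simulator and truth-alignment emitter.

Fragments are drawn from a genome with chromosome choice proportional to
length, start uniform over valid positions and fragment (outer insert)
length Normal(mean, sd) rounded to the nearest integer and truncated at
one read length.  R1 is the first ``read_length`` bases of the fragment,
R2 the reverse complement of the last ``read_length`` bases (FR library).

Because the pipeline must be testable without an external aligner, the
simulator can also emit truth alignments: each mate is lifted from the
derived genome to the reference through a :class:`~svref.rearrange.CoordinateMap`;
mates spanning a junction are placed at the true donor-side position of
their larger anchor, mimicking a correct split-free alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io_formats import (
    Genome,
    ReadPairAlignment,
    revcomp,
    write_pairs_sam,
)
from .rearrange import CoordinateMap

log = logging.getLogger(__name__)

__all__ = [
    "LibraryModel",
    "SimConfig",
    "Fragment",
    "simulate_fragments",
    "simulate_pairs",
    "inject_duplicates",
    "fragment_reads",
    "write_fastq",
    "UniqueKmerMapq",
    "fragments_to_alignments",
    "emit_truth_sam",
]


@dataclass(frozen=True)
class LibraryModel:
    """Sequencing library parameters: read length, insert mean and SD.

    Insert size is the outer fragment length (leftmost read start to
    rightmost read end).
    """

    read_length: int = 50
    insert_mean: float = 315.0
    insert_sd: float = 44.0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")
        if self.insert_mean < 2 * self.read_length:
            warnings.warn(
                "insert mean below twice the read length: mates will overlap",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs (pair count, seed, duplicate injection)."""

    n_pairs: int = 0
    seed: int = 0
    perfect_dup_rate: float = 0.0
    imperfect_dup_rate: float = 0.0
    imperfect_offset_max: int = 2
    base_quality: int = 30

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        for rate in (self.perfect_dup_rate, self.imperfect_dup_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("duplicate rates must be in [0, 1]")
        if self.imperfect_offset_max < 0:
            raise ValueError("imperfect_offset_max must be >= 0")


@dataclass(slots=True)
class Fragment:
    """A simulated DNA fragment on the (possibly derived) genome."""

    name: str
    chrom: str
    start: int
    end: int
    dup: str = ""  # "", "perfect" or "imperfect"
    source: str = ""  # name of the original fragment for duplicates

    @property
    def length(self) -> int:
        return self.end - self.start


def simulate_fragments(
    genome: Genome, lib: LibraryModel, cfg: SimConfig
) -> tuple[list[Fragment], dict]:
    """Draw random fragments; returns fragments plus resampling statistics.

    Fragments running off a chromosome end or containing N are resampled
    (their counts are reported in the stats dict).
    """
    names = list(genome)
    lengths = np.array([len(genome[c]) for c in names], dtype=np.int64)
    max_len = int(lengths.max()) if names else 0
    if max_len < lib.read_length:
        raise ValueError("genome shorter than one read length")
    rng = np.random.default_rng(cfg.seed)
    probs = lengths / lengths.sum()
    fragments: list[Fragment] = []
    stats = {"resampled_short_chrom": 0, "resampled_n_run": 0}
    has_n = {c: "N" in genome[c] for c in names}
    n_needed = cfg.n_pairs
    serial = 0
    while len(fragments) < n_needed:
        batch = max(1024, n_needed - len(fragments))
        chrom_idx = rng.choice(len(names), size=batch, p=probs)
        flen = np.rint(rng.normal(lib.insert_mean, lib.insert_sd, size=batch)).astype(
            np.int64
        )
        np.maximum(flen, lib.read_length, out=flen)
        u = rng.random(batch)
        for ci, fl, ui in zip(chrom_idx, flen, u):
            if len(fragments) >= n_needed:
                break
            chrom = names[ci]
            valid = lengths[ci] - fl + 1
            if valid <= 0:
                stats["resampled_short_chrom"] += 1
                continue
            start = int(ui * valid)
            end = start + int(fl)
            if has_n[chrom] and "N" in genome[chrom][start:end]:
                stats["resampled_n_run"] += 1
                continue
            fragments.append(Fragment(f"frag{serial}", chrom, start, end))
            serial += 1
    if stats["resampled_short_chrom"] or stats["resampled_n_run"]:
        log.info("fragment resampling: %s", stats)
    return fragments, stats


def inject_duplicates(
    fragments: Sequence[Fragment], cfg: SimConfig, seed: int | None = None
) -> list[Fragment]:
    """Append PCR duplicates to a fragment stream.

    Each original fragment independently spawns a perfect duplicate with
    probability ``perfect_dup_rate`` or an imperfect one with probability
    ``imperfect_dup_rate``.  Imperfect duplicates shift each mate
    independently by up to ``imperfect_offset_max`` bp (at least one mate
    shifted), in the same orientation.  To target an output duplicate
    *fraction* f, set the rate to ``f / (1 - f)``.
    """
    if cfg.perfect_dup_rate == 0 and cfg.imperfect_dup_rate == 0:
        return list(fragments)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out: list[Fragment] = []
    m = cfg.imperfect_offset_max
    for frag in fragments:
        out.append(frag)
        if frag.dup:
            continue
        u = rng.random()
        if u < cfg.perfect_dup_rate:
            out.append(
                Fragment(
                    f"{frag.name}.dP",
                    frag.chrom,
                    frag.start,
                    frag.end,
                    dup="perfect",
                    source=frag.name,
                )
            )
        elif u < cfg.perfect_dup_rate + cfg.imperfect_dup_rate:
            while True:
                da = int(rng.integers(-m, m + 1))
                db = int(rng.integers(-m, m + 1))
                if max(abs(da), abs(db)) >= 1:
                    break
            out.append(
                Fragment(
                    f"{frag.name}.dI",
                    frag.chrom,
                    max(0, frag.start + da),
                    frag.end + db,
                    dup="imperfect",
                    source=frag.name,
                )
            )
    return out


def fragment_reads(frag: Fragment, genome: Genome, lib: LibraryModel) -> tuple[str, str]:
    """(R1, R2) sequences of a fragment: FR orientation, fixed read length."""
    seq = genome[frag.chrom][frag.start : frag.end]
    r = lib.read_length
    return seq[:r], revcomp(seq[-r:])


def write_fastq(
    fragments: Sequence[Fragment],
    genome: Genome,
    lib: LibraryModel,
    cfg: SimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    qual = chr(cfg.base_quality + 33) * lib.read_length
    with open(r1_path, "w") as out1, open(r2_path, "w") as out2:
        for frag in fragments:
            r1, r2 = fragment_reads(frag, genome, lib)
            out1.write(f"@{frag.name}/1\n{r1}\n+\n{qual}\n")
            out2.write(f"@{frag.name}/2\n{r2}\n+\n{qual}\n")


def simulate_pairs(
    genome: Genome,
    lib: LibraryModel,
    cfg: SimConfig,
    out_prefix: str | Path | None = None,
) -> tuple[list[Fragment], dict]:
    """Simulate a paired-end library; optionally write FASTQ files.

    Returns the truth fragment stream (duplicates injected per ``cfg``)
    and the resampling statistics.
    """
    fragments, stats = simulate_fragments(genome, lib, cfg)
    fragments = inject_duplicates(fragments, cfg, seed=cfg.seed + 1)
    if out_prefix is not None:
        prefix = str(out_prefix)
        write_fastq(fragments, genome, lib, cfg, prefix + "_R1.fastq", prefix + "_R2.fastq")
    return fragments, stats


# ---------------------------------------------------------------------------
# Truth alignments
# ---------------------------------------------------------------------------


class UniqueKmerMapq:
    """Positional mapping-quality model from reference k-mer occurrence counts.

    A mate placed at a reference position whose read-length k-mer occurs
    once gets MAPQ ``unique`` (default 60), twice ``two`` (default 3) and
    more often ``multi`` (default 0) -- so the standard "< 23" filter
    removes every read with more than one equally valid mapping position.
    Junction reads whose k-mer does not exist in the reference count as
    unique.  Pluggable: any ``(chrom, pos) -> int`` callable works.
    """

    def __init__(
        self,
        counts: dict[str, np.ndarray],
        unique: int = 60,
        two: int = 3,
        multi: int = 0,
    ):
        self.counts = counts
        self.unique = unique
        self.two = two
        self.multi = multi

    def __call__(self, chrom: str, pos: int) -> int:
        arr = self.counts[chrom]
        idx = min(max(pos, 0), arr.size - 1)
        c = int(arr[idx])
        if c <= 1:
            return self.unique
        if c == 2:
            return self.two
        return self.multi


def _lift_mate(
    cmap: CoordinateMap,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    min_anchor: int,
) -> tuple[str, int, int, str] | None:
    """Place one mate on the reference; None if no adequate anchor exists."""
    pieces = cmap.lift_interval(chrom, start, end)
    if len(pieces) == 1:
        ref_chrom, ref_start, ref_end, pstrand, _, _ = pieces[0]
        out_strand = strand if pstrand == "+" else ("-" if strand == "+" else "+")
        return ref_chrom, ref_start, ref_end, out_strand
    best = max(pieces, key=lambda p: p[2] - p[1])
    anchor = best[2] - best[1]
    if anchor < min_anchor:
        return None
    ref_chrom, ra, rb, pstrand, da, db = best
    length = end - start
    if pstrand == "+":
        ref_start = ra - (da - start)
        ref_end = ref_start + length
        out_strand = strand
    else:
        ref_end = rb + (da - start)
        ref_start = ref_end - length
        out_strand = "-" if strand == "+" else "+"
    if ref_start < 0:
        ref_start, ref_end = 0, length
    return ref_chrom, ref_start, ref_end, out_strand


def fragments_to_alignments(
    fragments: Sequence[Fragment],
    lib: LibraryModel,
    cmap: CoordinateMap,
    mapq_model: Callable[[str, int], int],
    min_anchor: int = 3,
) -> list[ReadPairAlignment]:
    """Turn truth fragments into reference-space read-pair alignments."""
    r = lib.read_length
    pairs: list[ReadPairAlignment] = []
    for frag in fragments:
        m1 = _lift_mate(cmap, frag.chrom, frag.start, frag.start + r, "+", min_anchor)
        m2 = _lift_mate(cmap, frag.chrom, frag.end - r, frag.end, "-", min_anchor)
        if m1 is None or m2 is None:
            continue
        mate1 = (m1[0], m1[1], m1[2], m1[3], mapq_model(m1[0], m1[1]))
        mate2 = (m2[0], m2[1], m2[2], m2[3], mapq_model(m2[0], m2[1]))
        pairs.append(
            ReadPairAlignment.from_mates(frag.name, mate1, mate2, source=frag.dup)
        )
    return pairs


def emit_truth_sam(
    fragments: Sequence[Fragment],
    lib: LibraryModel,
    cmap: CoordinateMap,
    mapq_model: Callable[[str, int], int],
    ref_lengths: dict[str, int],
    path: str | Path,
    min_anchor: int = 3,
) -> list[ReadPairAlignment]:
    """Write the truth alignments of a fragment stream as SAM."""
    pairs = fragments_to_alignments(fragments, lib, cmap, mapq_model, min_anchor)
    write_pairs_sam(pairs, ref_lengths, path)
    return pairs
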