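"""Shared genomic domain types and flat-file I/O.

This module is the single source of coordinate-convention truth for the
package: **all internal coordinates are 0-based, half-open**.  The only
place where a shift happens is the SAM boundary (1-based in the file,
handled by pysam), BED and BEDPE are already 0-based half-open and are
read/written without any shift.

It also hosts the core record types (:class:`GenomicInterval`,
:class:`ReadPairAlignment`, :class:`SvRecord`) so that every other module
can import them without circular dependencies; domain modules re-export
them where the API reads more naturally.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

#: Ordered chromosome name -> uppercase sequence.
Genome = dict

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, pos: int) -> int:
        """Distance from a point to this interval (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


# ---------------------------------------------------------------------------
# Read pair alignments
# ---------------------------------------------------------------------------

_ORIENT = {"+": "F", "-": "R"}


@dataclass(slots=True)
class ReadPairAlignment:
    """One aligned read pair, mates normalised so A <= B by (chrom, pos).

    Coordinates are 0-based half-open footprints (``pos`` inclusive start,
    ``end`` exclusive).  ``span`` is the *outer* fragment span (leftmost
    start to rightmost end), defined only when both mates map to the same
    chromosome.
    """

    name: str
    chrom_a: str
    pos_a: int
    end_a: int
    strand_a: str
    mapq_a: int
    chrom_b: str
    pos_b: int
    end_b: int
    strand_b: str
    mapq_b: int
    mapped_a: bool = True
    mapped_b: bool = True
    perfect_dup: bool = False
    imperfect_dup: bool = False
    source: str = ""

    @classmethod
    def from_mates(
        cls,
        name: str,
        mate1: tuple[str, int, int, str, int],
        mate2: tuple[str, int, int, str, int],
        **kwargs,
    ) -> "ReadPairAlignment":
        """Build a pair from two ``(chrom, pos, end, strand, mapq)`` mates,
        normalising mate order by (chrom, pos)."""
        if (mate2[0], mate2[1]) < (mate1[0], mate1[1]):
            mate1, mate2 = mate2, mate1
        return cls(name, *mate1, *mate2, **kwargs)

    @property
    def both_mapped(self) -> bool:
        return self.mapped_a and self.mapped_b

    @property
    def same_chrom(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def span(self) -> int | None:
        if not (self.both_mapped and self.same_chrom):
            return None
        return max(self.end_a, self.end_b) - min(self.pos_a, self.pos_b)

    @property
    def orientation(self) -> str | None:
        """FR/RF/FF/RR strand pattern of the leftmost/rightmost mate.

        Defined only for mapped same-chromosome pairs; derived, never stored.
        """
        if not (self.both_mapped and self.same_chrom):
            return None
        if self.pos_a <= self.pos_b:
            left, right = self.strand_a, self.strand_b
        else:  # pragma: no cover - normalised constructor prevents this
            left, right = self.strand_b, self.strand_a
        return _ORIENT[left] + _ORIENT[right]

    @property
    def coord_key(self) -> tuple:
        """Identity key used for perfect-duplicate detection."""
        return (
            self.chrom_a,
            self.pos_a,
            self.strand_a,
            self.chrom_b,
            self.pos_b,
            self.strand_b,
        )

    @property
    def sum_mapq(self) -> int:
        return self.mapq_a + self.mapq_b

    def normalised(self) -> "ReadPairAlignment":
        if (self.chrom_b, self.pos_b) < (self.chrom_a, self.pos_a):
            return replace(
                self,
                chrom_a=self.chrom_b,
                pos_a=self.pos_b,
                end_a=self.end_b,
                strand_a=self.strand_b,
                mapq_a=self.mapq_b,
                mapped_a=self.mapped_b,
                chrom_b=self.chrom_a,
                pos_b=self.pos_a,
                end_b=self.end_a,
                strand_b=self.strand_a,
                mapq_b=self.mapq_a,
                mapped_b=self.mapped_a,
            )
        return self


# ---------------------------------------------------------------------------
# SV records (truth entries and calls share one schema)
# ---------------------------------------------------------------------------

SV_TYPES = ("deletion", "inversion", "duplication", "translocation")


@dataclass(slots=True)
class SvRecord:
    """A structural variant: either a truth record or a pipeline call.

    ``anchor_a``/``anchor_b`` are ordered by (chrom, start).  For truth
    records the anchors are 1-bp breakpoint markers and ``sides`` records
    which flank of each breakpoint participates in the junction ("left"
    means the sequence left of the breakpoint is retained/joined).
    """

    sv_type: str
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    size: int | None = None
    support: int = 0
    origin: str = "call"
    germline: bool = False
    name: str = ""
    sides: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.size is not None and self.size <= 0:
            raise ValueError(f"SV size must be positive, got {self.size}")
        if self.support < 0:
            raise ValueError("support must be >= 0")
        if (self.anchor_b.chrom, self.anchor_b.start) < (
            self.anchor_a.chrom,
            self.anchor_a.start,
        ):
            self.anchor_a, self.anchor_b = self.anchor_b, self.anchor_a
            if self.sides is not None:
                self.sides = (self.sides[1], self.sides[0])

    @property
    def interchromosomal(self) -> bool:
        return self.anchor_a.chrom != self.anchor_b.chrom


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into an ordered ``{name: SEQUENCE}`` map.

    Sequences are uppercased; record order is preserved.  Raises
    :class:`FormatError` naming the offending record for empty sequences
    or duplicated names, and for files that do not start with a header.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.read(1)
        if first != ">":
            raise FormatError(f"{path}: not a FASTA file (missing '>' header)")
    genome: Genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty name")
        if rec.id in genome:
            raise FormatError(f"{path}: duplicated record name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        genome[rec.id] = seq
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    """Write a genome as FASTA with fixed line wrapping."""
    with open(path, "w") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM read-pair I/O (via pysam; positions converted by pysam to 0-based)
# ---------------------------------------------------------------------------


def read_pairs_sam(path: str | Path) -> list[ReadPairAlignment]:
    """Read primary mate-paired records from a SAM/BAM file.

    Returns one :class:`ReadPairAlignment` per primary pair; pairs with an
    unmapped mate are returned with the corresponding ``mapped_*`` flag
    cleared so downstream screening can count them.  Orphan mates trigger
    a warning and are skipped.  Input need not be sorted.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[ReadPairAlignment] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            pairs.append(_pair_from_segments(mate, rec))
    for name in pending:
        log.warning("orphan mate skipped: %s", name)
    return pairs


def _segment_mate(rec: pysam.AlignedSegment) -> tuple[tuple, bool]:
    if rec.is_unmapped:
        return ("*", 0, 1, "+", 0), False
    end = rec.reference_end
    if end is None:  # no CIGAR; fall back to a 1-bp footprint
        end = rec.reference_start + 1
    return (
        rec.reference_name,
        rec.reference_start,
        end,
        "-" if rec.is_reverse else "+",
        rec.mapping_quality,
    ), True


def _pair_from_segments(
    r1: pysam.AlignedSegment, r2: pysam.AlignedSegment
) -> ReadPairAlignment:
    m1, ok1 = _segment_mate(r1)
    m2, ok2 = _segment_mate(r2)
    flags = dict(duplicate=r1.is_duplicate or r2.is_duplicate)
    if ok1 and ok2:
        pair = ReadPairAlignment.from_mates(r1.query_name, m1, m2)
    else:
        # keep deterministic order for partially mapped pairs
        pair = ReadPairAlignment(r1.query_name, *m1, *m2, mapped_a=ok1, mapped_b=ok2)
    pair.perfect_dup = flags["duplicate"]
    return pair


def write_pairs_sam(
    pairs: Iterable[ReadPairAlignment],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write read pairs as unsorted SAM (sequence-less, CIGAR from footprint)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pair in pairs:
            a, b = _segments_from_pair(pair, out.header)
            out.write(a)
            out.write(b)


def _segments_from_pair(pair: ReadPairAlignment, header) -> tuple:
    def seg(first: bool) -> pysam.AlignedSegment:
        rec = pysam.AlignedSegment(header=header)
        rec.query_name = pair.name
        if first:
            chrom, pos, end, strand, mapq, mapped = (
                pair.chrom_a,
                pair.pos_a,
                pair.end_a,
                pair.strand_a,
                pair.mapq_a,
                pair.mapped_a,
            )
            mchrom, mpos, mstrand, mmapped = (
                pair.chrom_b,
                pair.pos_b,
                pair.strand_b,
                pair.mapped_b,
            )
        else:
            chrom, pos, end, strand, mapq, mapped = (
                pair.chrom_b,
                pair.pos_b,
                pair.end_b,
                pair.strand_b,
                pair.mapq_b,
                pair.mapped_b,
            )
            mchrom, mpos, mstrand, mmapped = (
                pair.chrom_a,
                pair.pos_a,
                pair.strand_a,
                pair.mapped_a,
            )
        flag = 0x1 | (0x40 if first else 0x80)
        if mapped:
            if strand == "-":
                flag |= 0x10
        else:
            flag |= 0x4
        if mmapped:
            if mstrand == "-":
                flag |= 0x20
        else:
            flag |= 0x8
        if pair.perfect_dup or pair.imperfect_dup:
            flag |= 0x400
        rec.flag = flag
        if mapped:
            rec.reference_name = chrom
            rec.reference_start = pos
            rec.mapping_quality = mapq
            rec.cigarstring = f"{end - pos}M"
        if mmapped:
            rec.next_reference_name = mchrom
            rec.next_reference_start = mpos
        rec.query_sequence = None
        return rec

    return seg(True), seg(False)


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into a list of intervals (no merging)."""
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as out:
        for iv in intervals:
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


_BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
    "strand1\tstrand2\tsize\torigin\tgermline\tid\tsides\n"
)


def write_bedpe(records: Sequence[SvRecord], path: str | Path) -> None:
    """Write SV records as 10-column BEDPE plus bookkeeping columns.

    Column 7 (name) carries the SV type, column 8 (score) the supporting
    pair count, per the interchange contract.  Anchors must already be
    ordered; a violation raises :class:`FormatError`.
    """
    with open(path, "w") as out:
        out.write(_BEDPE_HEADER)
        for rec in records:
            a, b = rec.anchor_a, rec.anchor_b
            if (b.chrom, b.start) < (a.chrom, a.start):
                raise FormatError(f"anchor order violation in record {rec.name!r}")
            sides = ",".join(rec.sides) if rec.sides else "."
            out.write(
                "\t".join(
                    [
                        a.chrom,
                        str(a.start),
                        str(a.end),
                        b.chrom,
                        str(b.start),
                        str(b.end),
                        rec.sv_type,
                        str(rec.support),
                        ".",
                        ".",
                        "." if rec.size is None else str(rec.size),
                        rec.origin,
                        "1" if rec.germline else "0",
                        rec.name or ".",
                        sides,
                    ]
                )
                + "\n"
            )


def read_bedpe(path: str | Path) -> list[SvRecord]:
    """Read SV records written by :func:`write_bedpe` (round-trip exact)."""
    records: list[SvRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"{path}:{lineno}: BEDPE line has <10 columns")
            size = None
            origin, germline, name, sides = "call", False, "", None
            if len(f) >= 11 and f[10] != ".":
                size = int(f[10])
            if len(f) >= 12:
                origin = f[11]
            if len(f) >= 13:
                germline = f[12] == "1"
            if len(f) >= 14 and f[13] != ".":
                name = f[13]
            if len(f) >= 15 and f[14] != ".":
                parts = f[14].split(",")
                sides = (parts[0], parts[1])
            records.append(
                SvRecord(
                    sv_type=f[6],
                    anchor_a=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    anchor_b=GenomicInterval(f[3], int(f[4]), int(f[5])),
                    size=size,
                    support=int(f[7]),
                    origin=origin,
                    germline=germline,
                    name=name,
                    sides=sides,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Screened-pair TSV (CLI interchange between `screen` and `call`)
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = [
    "name",
    "chrom_a",
    "pos_a",
    "end_a",
    "strand_a",
    "mapq_a",
    "chrom_b",
    "pos_b",
    "end_b",
    "strand_b",
    "mapq_b",
    "mapped_a",
    "mapped_b",
]


def write_pairs_tsv(pairs: Iterable[ReadPairAlignment], path: str | Path) -> None:
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t")
        writer.writerow(_PAIR_COLUMNS)
        for p in pairs:
            writer.writerow(
                [
                    p.name,
                    p.chrom_a,
                    p.pos_a,
                    p.end_a,
                    p.strand_a,
                    p.mapq_a,
                    p.chrom_b,
                    p.pos_b,
                    p.end_b,
                    p.strand_b,
                    p.mapq_b,
                    int(p.mapped_a),
                    int(p.mapped_b),
                ]
            )


def read_pairs_tsv(path: str | Path) -> list[ReadPairAlignment]:
    pairs = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            pairs.append(
                ReadPairAlignment(
                    name=row["name"],
                    chrom_a=row["chrom_a"],
                    pos_a=int(row["pos_a"]),
                    end_a=int(row["end_a"]),
                    strand_a=row["strand_a"],
                    mapq_a=int(row["mapq_a"]),
                    chrom_b=row["chrom_b"],
                    pos_b=int(row["pos_b"]),
                    end_b=int(row["end_b"]),
                    strand_b=row["strand_b"],
                    mapq_b=int(row["mapq_b"]),
                    mapped_a=row["mapped_a"] == "1",
                    mapped_b=row["mapped_b"] == "1",
                )
            )
    return pairs
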