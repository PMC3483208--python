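"""Derive rearranged genomes from a reference and an SV plan.

A derived ("tumor" or sample-strain) chromosome is represented as an
ordered list of reference blocks, which makes three things exact and
testable: sequence construction, length conservation, and the
derived-to-reference coordinate map needed to emit truth alignments
without running an aligner.

Deletions, inversions and tandem duplications are confined to one
chromosome; translocations are modelled as reciprocal joins between two
chromosomes at stated breakpoints (a reciprocal pair yields two truth
records, one per derived junction).
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io_formats import (
    Genome,
    GenomicInterval,
    SvRecord,
    revcomp,
)

__all__ = [
    "SvPlanEntry",
    "SvRecord",
    "PlanError",
    "Block",
    "CoordinateMap",
    "apply_plan",
    "plan_from_table",
    "plan_to_table",
    "GermlineSpec",
    "RetroelementInsertion",
    "RetrogeneInsertion",
    "inject_germline_artifacts",
]

INTRA_TYPES = ("deletion", "inversion", "tandem_duplication")


class PlanError(ValueError):
    """Raised for invalid rearrangement plans (bounds, overlap, typing)."""


@dataclass(frozen=True, slots=True)
class SvPlanEntry:
    """One planned edit, in reference coordinates.

    Intra-chromosomal types use ``chrom_a``/``pos_a``/``size`` (the edited
    interval is ``[pos_a, pos_a + size)``); translocations join
    ``chrom_a:pos_a`` to ``chrom_b:pos_b``.
    """

    name: str
    sv_type: str
    chrom_a: str
    pos_a: int
    chrom_b: str | None = None
    pos_b: int | None = None
    size: int | None = None
    reciprocal: bool = True

    def __post_init__(self) -> None:
        if self.sv_type in INTRA_TYPES:
            if self.size is None or self.size <= 0:
                raise PlanError(
                    f"{self.name}: {self.sv_type} requires a positive size"
                )
            if self.chrom_b not in (None, self.chrom_a):
                raise PlanError(f"{self.name}: {self.sv_type} must stay on one chromosome")
        elif self.sv_type == "translocation":
            if self.chrom_b is None or self.pos_b is None:
                raise PlanError(f"{self.name}: translocation requires two breakpoints")
            if self.chrom_b == self.chrom_a:
                raise PlanError(f"{self.name}: translocation must join two chromosomes")
            if self.size is not None:
                raise PlanError(f"{self.name}: translocation size must be absent")
        else:
            raise PlanError(f"{self.name}: unknown SV type {self.sv_type!r}")

    @property
    def interval(self) -> GenomicInterval:
        if self.sv_type not in INTRA_TYPES:
            raise PlanError(f"{self.name}: translocations have no single interval")
        return GenomicInterval(self.chrom_a, self.pos_a, self.pos_a + self.size)


# ---------------------------------------------------------------------------
# Blocks and coordinate maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Block:
    """A reference slice ``[ref_start, ref_end)`` placed on a derived chromosome.

    ``strand == '-'`` means the slice appears reverse-complemented.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


class CoordinateMap:
    """Derived-genome layout: ordered reference blocks per derived chromosome."""

    def __init__(self, blocks: dict[str, list[Block]]):
        self.blocks = {name: list(bl) for name, bl in blocks.items()}
        self._starts: dict[str, list[int]] = {}
        for name, bl in self.blocks.items():
            starts, total = [], 0
            for b in bl:
                starts.append(total)
                total += b.length
            self._starts[name] = starts

    @classmethod
    def identity(cls, genome: Genome) -> "CoordinateMap":
        return cls({name: [Block(name, 0, len(seq))] for name, seq in genome.items()})

    def derived_length(self, chrom: str) -> int:
        bl = self.blocks[chrom]
        if not bl:
            return 0
        return self._starts[chrom][-1] + bl[-1].length

    def derived_lengths(self) -> dict[str, int]:
        return {name: self.derived_length(name) for name in self.blocks}

    def build_genome(self, ref: Genome) -> Genome:
        derived: Genome = {}
        for name, bl in self.blocks.items():
            parts = []
            for b in bl:
                piece = ref[b.ref_chrom][b.ref_start : b.ref_end]
                parts.append(piece if b.strand == "+" else revcomp(piece))
            derived[name] = "".join(parts)
        return derived

    def to_ref(self, chrom: str, pos: int) -> tuple[str, int, str]:
        """Map a derived position to (ref_chrom, ref_pos, strand)."""
        starts = self._starts[chrom]
        i = bisect_right(starts, pos) - 1
        if i < 0 or pos >= self.derived_length(chrom):
            raise IndexError(f"position {chrom}:{pos} outside derived genome")
        b = self.blocks[chrom][i]
        offset = pos - starts[i]
        if b.strand == "+":
            return b.ref_chrom, b.ref_start + offset, "+"
        return b.ref_chrom, b.ref_end - 1 - offset, "-"

    def lift_interval(
        self, chrom: str, start: int, end: int
    ) -> list[tuple[str, int, int, str, int, int]]:
        """Project a derived interval onto the reference.

        Returns pieces ``(ref_chrom, ref_start, ref_end, strand,
        derived_start, derived_end)`` in derived order.
        """
        if not (0 <= start < end <= self.derived_length(chrom)):
            raise IndexError(f"interval {chrom}:{start}-{end} outside derived genome")
        starts = self._starts[chrom]
        pieces = []
        i = bisect_right(starts, start) - 1
        pos = start
        while pos < end:
            b = self.blocks[chrom][i]
            b_start = starts[i]
            take = min(end, b_start + b.length) - pos
            off = pos - b_start
            if b.strand == "+":
                pieces.append(
                    (b.ref_chrom, b.ref_start + off, b.ref_start + off + take, "+", pos, pos + take)
                )
            else:
                pieces.append(
                    (b.ref_chrom, b.ref_end - off - take, b.ref_end - off, "-", pos, pos + take)
                )
            pos += take
            i += 1
        return pieces

    def ref_to_derived(self, ref_chrom: str, ref_pos: int) -> tuple[str, int] | None:
        """Inverse lookup (first matching block); None if position was deleted."""
        for name, bl in self.blocks.items():
            starts = self._starts[name]
            for b, d0 in zip(bl, starts):
                if b.ref_chrom == ref_chrom and b.ref_start <= ref_pos < b.ref_end:
                    if b.strand == "+":
                        return name, d0 + (ref_pos - b.ref_start)
                    return name, d0 + (b.ref_end - 1 - ref_pos)
        return None

    def compose(self, inner: "CoordinateMap") -> "CoordinateMap":
        """Compose with a map whose reference is this map's derived genome.

        ``outer.compose(inner)`` maps outer-derived coordinates through
        ``outer`` (whose blocks reference inner's derived genome) down to
        ``inner``'s reference.
        """
        out: dict[str, list[Block]] = {}
        for name, bl in self.blocks.items():
            pieces: list[Block] = []
            for b in bl:
                sub = inner.lift_interval(b.ref_chrom, b.ref_start, b.ref_end)
                subblocks = [Block(c, s, e, st) for c, s, e, st, _, _ in sub]
                if b.strand == "-":
                    subblocks = [
                        Block(s.ref_chrom, s.ref_start, s.ref_end, "-" if s.strand == "+" else "+")
                        for s in reversed(subblocks)
                    ]
                pieces.extend(subblocks)
            out[name] = pieces
        return CoordinateMap(out)

    # -- TSV serialisation --------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as out:
            writer = csv.writer(out, delimiter="\t")
            writer.writerow(
                ["derived_chrom", "derived_start", "derived_end", "ref_chrom", "ref_start", "ref_end", "strand"]
            )
            for name, bl in self.blocks.items():
                for b, d0 in zip(bl, self._starts[name]):
                    writer.writerow(
                        [name, d0, d0 + b.length, b.ref_chrom, b.ref_start, b.ref_end, b.strand]
                    )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CoordinateMap":
        blocks: dict[str, list[Block]] = {}
        with open(path, newline="") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            for row in reader:
                blocks.setdefault(row["derived_chrom"], []).append(
                    Block(
                        row["ref_chrom"],
                        int(row["ref_start"]),
                        int(row["ref_end"]),
                        row["strand"],
                    )
                )
        return cls(blocks)


# ---------------------------------------------------------------------------
# Plan application
# ---------------------------------------------------------------------------


def _validate_plan(genome: Genome, plan: Sequence[SvPlanEntry]) -> None:
    offenders = []
    occupied: dict[str, list[tuple[int, int, str]]] = {}

    def claim(chrom, start, end, name):
        occupied.setdefault(chrom, []).append((start, end, name))

    for entry in plan:
        if entry.chrom_a not in genome:
            offenders.append(f"{entry.name}: unknown chromosome {entry.chrom_a}")
            continue
        if entry.sv_type in INTRA_TYPES:
            length = len(genome[entry.chrom_a])
            if entry.pos_a < 0 or entry.pos_a + entry.size > length:
                offenders.append(f"{entry.name}: interval out of bounds")
                continue
            claim(entry.chrom_a, entry.pos_a, entry.pos_a + entry.size, entry.name)
        else:
            if entry.chrom_b not in genome:
                offenders.append(f"{entry.name}: unknown chromosome {entry.chrom_b}")
                continue
            ok = True
            for chrom, pos in ((entry.chrom_a, entry.pos_a), (entry.chrom_b, entry.pos_b)):
                if not (0 < pos < len(genome[chrom])):
                    offenders.append(f"{entry.name}: breakpoint {chrom}:{pos} out of bounds")
                    ok = False
            if ok:
                claim(entry.chrom_a, entry.pos_a, entry.pos_a + 1, entry.name)
                claim(entry.chrom_b, entry.pos_b, entry.pos_b + 1, entry.name)
    for chrom, spans in occupied.items():
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 < e1:
                offenders.append(f"overlapping edits on {chrom}: {n1} and {n2}")
    if offenders:
        raise PlanError("invalid plan: " + "; ".join(offenders))


def apply_plan(
    genome: Genome, plan: Sequence[SvPlanEntry], seed: int | None = None
) -> tuple[Genome, list[SvRecord], CoordinateMap]:
    """Apply an SV plan to a genome.

    Returns the derived genome, truth records carrying reference-coordinate
    breakpoints, and the derived-to-reference :class:`CoordinateMap`.
    ``seed`` is accepted for interface symmetry; plan application is
    deterministic.
    """
    _validate_plan(genome, plan)
    records: list[SvRecord] = []

    # stage 1: intra-chromosomal edits, walked left to right per chromosome
    per_chrom: dict[str, list[SvPlanEntry]] = {}
    for entry in plan:
        if entry.sv_type in INTRA_TYPES:
            per_chrom.setdefault(entry.chrom_a, []).append(entry)
    blocks: dict[str, list[Block]] = {}
    for name, seq in genome.items():
        edits = sorted(per_chrom.get(name, []), key=lambda e: e.pos_a)
        bl: list[Block] = []
        cursor = 0
        for e in edits:
            s, t = e.pos_a, e.pos_a + e.size
            if s > cursor:
                bl.append(Block(name, cursor, s))
            if e.sv_type == "deletion":
                records.append(
                    SvRecord(
                        "deletion",
                        GenomicInterval(name, s, s + 1),
                        GenomicInterval(name, t, t + 1),
                        size=e.size,
                        origin="truth",
                        name=e.name,
                        sides=("left", "right"),
                    )
                )
            elif e.sv_type == "inversion":
                bl.append(Block(name, s, t, "-"))
                records.append(
                    SvRecord(
                        "inversion",
                        GenomicInterval(name, s, s + 1),
                        GenomicInterval(name, t, t + 1),
                        size=e.size,
                        origin="truth",
                        name=e.name,
                        sides=("left", "right"),
                    )
                )
            else:  # tandem duplication
                bl.append(Block(name, s, t))
                bl.append(Block(name, s, t))
                records.append(
                    SvRecord(
                        "duplication",
                        GenomicInterval(name, s, s + 1),
                        GenomicInterval(name, t, t + 1),
                        size=e.size,
                        origin="truth",
                        name=e.name,
                        sides=("left", "right"),
                    )
                )
            cursor = t
        if cursor < len(seq):
            bl.append(Block(name, cursor, len(seq)))
        blocks[name] = bl

    # stage 2: translocations, applied sequentially on the working layout
    def locate(chrom: str, pos: int) -> tuple[str, int, int]:
        """Find (derived_chrom, block_index, offset) of a ref position."""
        for dname, bl in blocks.items():
            for i, b in enumerate(bl):
                if b.strand == "+" and b.ref_chrom == chrom and b.ref_start <= pos < b.ref_end:
                    return dname, i, pos - b.ref_start
        raise PlanError(f"breakpoint {chrom}:{pos} not found (deleted or inverted?)")

    def split(dname: str, i: int, offset: int) -> tuple[list[Block], list[Block]]:
        bl = blocks[dname]
        b = bl[i]
        head = bl[:i]
        tail = bl[i + 1 :]
        if offset > 0:
            head = head + [Block(b.ref_chrom, b.ref_start, b.ref_start + offset, b.strand)]
        mid = [Block(b.ref_chrom, b.ref_start + offset, b.ref_end, b.strand)]
        return head, mid + tail

    for entry in plan:
        if entry.sv_type != "translocation":
            continue
        da, ia, offa = locate(entry.chrom_a, entry.pos_a)
        db, ib, offb = locate(entry.chrom_b, entry.pos_b)
        if da == db:
            raise PlanError(
                f"{entry.name}: breakpoints resolve to the same derived chromosome"
            )
        head_a, tail_a = split(da, ia, offa)
        head_b, tail_b = split(db, ib, offb)
        blocks[da] = head_a + tail_b
        if entry.reciprocal:
            blocks[db] = head_b + tail_a
        a_iv = GenomicInterval(entry.chrom_a, entry.pos_a, entry.pos_a + 1)
        b_iv = GenomicInterval(entry.chrom_b, entry.pos_b, entry.pos_b + 1)
        records.append(
            SvRecord(
                "translocation",
                a_iv,
                b_iv,
                origin="truth",
                name=entry.name,
                sides=("left", "right"),
            )
        )
        if entry.reciprocal:
            records.append(
                SvRecord(
                    "translocation",
                    GenomicInterval(entry.chrom_b, entry.pos_b, entry.pos_b + 1),
                    GenomicInterval(entry.chrom_a, entry.pos_a, entry.pos_a + 1),
                    origin="truth",
                    name=f"{entry.name}_recip",
                    sides=("left", "right"),
                )
            )

    cmap = CoordinateMap(blocks)
    derived = cmap.build_genome(genome)
    return derived, records, cmap


# ---------------------------------------------------------------------------
# Plan tables
# ---------------------------------------------------------------------------

_PLAN_COLUMNS = ["name", "sv_type", "chrom_a", "pos_a", "chrom_b", "pos_b", "size"]


def plan_to_table(plan: Sequence[SvPlanEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t")
        writer.writerow(_PLAN_COLUMNS)
        for e in plan:
            writer.writerow(
                [
                    e.name,
                    e.sv_type,
                    e.chrom_a,
                    e.pos_a,
                    e.chrom_b or "-",
                    "-" if e.pos_b is None else e.pos_b,
                    "-" if e.size is None else e.size,
                ]
            )


def plan_from_table(path: str | Path) -> list[SvPlanEntry]:
    """Parse a tab-delimited plan; '-' size is allowed only for translocations."""
    plan: list[SvPlanEntry] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            try:
                size = None if row["size"] in ("-", "", None) else int(row["size"])
                chrom_b = None if row["chrom_b"] in ("-", "", None) else row["chrom_b"]
                pos_b = None if row["pos_b"] in ("-", "", None) else int(row["pos_b"])
                plan.append(
                    SvPlanEntry(
                        name=row["name"],
                        sv_type=row["sv_type"],
                        chrom_a=row["chrom_a"],
                        pos_a=int(row["pos_a"]),
                        chrom_b=chrom_b,
                        pos_b=pos_b,
                        size=size,
                    )
                )
            except (KeyError, ValueError, PlanError) as exc:
                raise PlanError(f"{path}: row {lineno}: {exc}") from exc
    return plan


# ---------------------------------------------------------------------------
# Germline artifacts (strain-background retroelement / retrogene insertions)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class RetroelementInsertion:
    """A copy of ``donor`` inserted at ``target_chrom:target_pos``."""

    name: str
    donor: GenomicInterval
    target_chrom: str
    target_pos: int
    inverted: bool = False


@dataclass(frozen=True, slots=True)
class RetrogeneInsertion:
    """Exons of a gene concatenated and inserted at ``target_chrom:target_pos``."""

    name: str
    exons: tuple[GenomicInterval, ...]
    target_chrom: str
    target_pos: int

    def __post_init__(self) -> None:
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise PlanError(f"{self.name}: exons must share one chromosome")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise PlanError(f"{self.name}: exons must be sorted and separated")

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(a.chrom, a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass(frozen=True)
class GermlineSpec:
    retroelements: tuple[RetroelementInsertion, ...] = ()
    retrogenes: tuple[RetrogeneInsertion, ...] = ()

    def __bool__(self) -> bool:
        return bool(self.retroelements or self.retrogenes)


def inject_germline_artifacts(
    genome: Genome, spec: GermlineSpec, seed: int | None = None
) -> tuple[Genome, list[SvRecord], CoordinateMap]:
    """Insert retroelement/retrogene copies and record expected call patterns.

    Against the unmodified reference, an interchromosomal retroelement copy
    produces a balanced-translocation pattern, an intrachromosomal copy a
    deletion pattern, and a retrogene one translocation plus one deletion
    pattern per intron.  All emitted records are flagged ``germline``.
    """
    records: list[SvRecord] = []
    insertions: dict[str, list[tuple[int, list[Block], str]]] = {}

    for re_ins in spec.retroelements:
        donor = re_ins.donor
        if donor.chrom not in genome or re_ins.target_chrom not in genome:
            raise PlanError(f"{re_ins.name}: unknown chromosome")
        if donor.end > len(genome[donor.chrom]):
            raise PlanError(f"{re_ins.name}: donor outside chromosome bounds")
        if donor.length > len(genome[re_ins.target_chrom]):
            raise PlanError(f"{re_ins.name}: donor longer than target chromosome")
        strand = "-" if re_ins.inverted else "+"
        insertions.setdefault(re_ins.target_chrom, []).append(
            (re_ins.target_pos, [Block(donor.chrom, donor.start, donor.end, strand)], re_ins.name)
        )
        site = GenomicInterval(re_ins.target_chrom, re_ins.target_pos, re_ins.target_pos + 1)
        if re_ins.target_chrom != donor.chrom:
            records.append(
                SvRecord(
                    "translocation",
                    site,
                    donor,
                    origin="truth",
                    germline=True,
                    name=re_ins.name,
                )
            )
        else:
            lo = min(re_ins.target_pos, donor.start)
            hi = max(re_ins.target_pos, donor.end)
            records.append(
                SvRecord(
                    "deletion",
                    site,
                    donor,
                    size=hi - lo,
                    origin="truth",
                    germline=True,
                    name=re_ins.name,
                )
            )

    for rg in spec.retrogenes:
        gene_chrom = rg.exons[0].chrom
        if gene_chrom not in genome or rg.target_chrom not in genome:
            raise PlanError(f"{rg.name}: unknown chromosome")
        total = sum(e.length for e in rg.exons)
        if total > len(genome[rg.target_chrom]):
            raise PlanError(f"{rg.name}: retrogene longer than target chromosome")
        insertions.setdefault(rg.target_chrom, []).append(
            (
                rg.target_pos,
                [Block(e.chrom, e.start, e.end) for e in rg.exons],
                rg.name,
            )
        )
        gene_span = GenomicInterval(gene_chrom, rg.exons[0].start, rg.exons[-1].end)
        records.append(
            SvRecord(
                "translocation",
                GenomicInterval(rg.target_chrom, rg.target_pos, rg.target_pos + 1),
                gene_span,
                origin="truth",
                germline=True,
                name=rg.name,
            )
        )
        for i, intron in enumerate(rg.introns, 1):
            records.append(
                SvRecord(
                    "deletion",
                    GenomicInterval(intron.chrom, intron.start, intron.start + 1),
                    GenomicInterval(intron.chrom, intron.end, intron.end + 1),
                    size=intron.length,
                    origin="truth",
                    germline=True,
                    name=f"{rg.name}_intron{i}",
                    sides=("left", "right"),
                )
            )

    blocks: dict[str, list[Block]] = {}
    for name, seq in genome.items():
        todo = sorted(insertions.get(name, []), key=lambda x: x[0])
        bl: list[Block] = []
        cursor = 0
        for pos, ins_blocks, ins_name in todo:
            if not (0 <= pos <= len(seq)):
                raise PlanError(f"{ins_name}: insertion point out of bounds")
            if pos > cursor:
                bl.append(Block(name, cursor, pos))
            bl.extend(ins_blocks)
            cursor = pos
        if cursor < len(seq) or not bl:
            bl.append(Block(name, cursor, len(seq)))
        blocks[name] = bl

    cmap = CoordinateMap(blocks)
    return cmap.build_genome(genome), records, cmap
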