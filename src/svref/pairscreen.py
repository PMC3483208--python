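"""Pre-detection read-pair screening.

Classifies mapped pairs into concordant/discordant signatures against the
library model, removes pairs with a low-mapping-quality mate, removes
perfect PCR duplicates (coordinate-identical pairs) and imperfect
duplicates (pairs whose mates sit within a small offset of each other in
the same orientation -- amplification plus slippage/sequencing error that
escapes coordinate-identity de-duplication).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import ReadPairAlignment
from .readsim import LibraryModel

__all__ = [
    "FilterConfig",
    "ReadPairAlignment",
    "PAIR_CLASSES",
    "classify_pair",
    "filter_mapq",
    "remove_perfect_duplicates",
    "remove_imperfect_duplicates",
    "screen",
    "ScreenStats",
]

PAIR_CLASSES = (
    "concordant",
    "del_signature",
    "short_insert_signature",
    "inversion_signature",
    "translocation_signature",
    "unusable",
)


@dataclass
class FilterConfig:
    """Every pipeline threshold in one place.

    Defaults: mapping-quality cutoff 23
    (reads scoring 0-22 are removed), insert-size deviation threshold of 8
    standard deviations, minimum 2 supporting read pairs, minimum anchoring
    region 3 bp, imperfect-duplicate offset 2 bp, low-mappability overlap
    cutoffs 85% (intrachromosomal) / 50% (interchromosomal), simple-repeat
    cutoff 50%, RepeatMasker cutoff 80% applied only to interchromosomal
    calls with 2-3 supporting pairs, and size cutoffs of 600 bp for
    deletions / 300 bp for duplications.  Overlap and size cutoffs are
    inclusive thresholds exactly as worded ("50% or greater" removes;
    size >= cutoff is retained).
    """

    mq_min: int = 23
    sd_multiplier: float = 8.0
    min_support: int = 2
    min_anchor: int = 3
    dup_offset_max: int = 2
    lowmap_cutoff_intra: float = 0.85
    lowmap_cutoff_inter: float = 0.50
    simple_repeat_cutoff: float = 0.50
    repeatmasker_cutoff: float = 0.80
    repeatmasker_max_support: int = 3
    del_min_size: int = 600
    dup_min_size: int = 300
    control_min_support: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.mq_min <= 60):
            raise ValueError("mq_min must be in [0, 60]")
        if self.sd_multiplier < 0 or self.min_support < 1 or self.min_anchor < 0:
            raise ValueError("invalid threshold configuration")
        for frac in (
            self.lowmap_cutoff_intra,
            self.lowmap_cutoff_inter,
            self.simple_repeat_cutoff,
            self.repeatmasker_cutoff,
        ):
            if not (0 <= frac <= 1):
                raise ValueError("overlap cutoffs must be fractions in [0, 1]")


def classify_pair(
    pair: ReadPairAlignment, lib: LibraryModel, cfg: FilterConfig
) -> str:
    """Assign a pair to exactly one signature class.

    Different chromosomes -> translocation; same-chromosome FF/RR ->
    inversion; RF -> short-insert (duplication-type); FR with outer span
    strictly above mean + k*SD -> deletion, strictly below mean - k*SD ->
    short-insert; otherwise concordant.  Pairs with an unmapped mate are
    unusable.
    """
    if not pair.both_mapped:
        return "unusable"
    if not pair.same_chrom:
        return "translocation_signature"
    orient = pair.orientation
    if orient in ("FF", "RR"):
        return "inversion_signature"
    if orient == "RF":
        return "short_insert_signature"
    span = pair.span
    hi = lib.insert_mean + cfg.sd_multiplier * lib.insert_sd
    lo = lib.insert_mean - cfg.sd_multiplier * lib.insert_sd
    if span > hi:
        return "del_signature"
    if span < lo:
        return "short_insert_signature"
    return "concordant"


def filter_mapq(
    pairs: Iterable[ReadPairAlignment], cfg: FilterConfig
) -> list[ReadPairAlignment]:
    """Keep a pair iff BOTH mates have mapping quality >= ``cfg.mq_min``."""
    return [p for p in pairs if p.mapq_a >= cfg.mq_min and p.mapq_b >= cfg.mq_min]


def remove_perfect_duplicates(
    pairs: Sequence[ReadPairAlignment],
) -> list[ReadPairAlignment]:
    """Keep one pair per identical coordinate/strand signature.

    The representative is the pair with the highest summed mapping quality
    (ties broken by input order); dropped pairs are flagged ``perfect_dup``.
    Pairs with an unmapped mate pass through untouched.
    """
    best: dict[tuple, ReadPairAlignment] = {}
    passthrough: list[ReadPairAlignment] = []
    order: list[tuple] = []
    for p in pairs:
        if not p.both_mapped:
            passthrough.append(p)
            continue
        key = p.coord_key
        cur = best.get(key)
        if cur is None:
            best[key] = p
            order.append(key)
        elif p.sum_mapq > cur.sum_mapq:
            cur.perfect_dup = True
            best[key] = p
        else:
            p.perfect_dup = True
    kept = [best[k] for k in order]
    kept.extend(passthrough)
    return kept


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        parent = self.parent
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def remove_imperfect_duplicates(
    pairs: Sequence[ReadPairAlignment], cfg: FilterConfig
) -> list[ReadPairAlignment]:
    """Collapse imperfect-duplicate groups to one representative each.

    Two pairs join a group iff they share chromosomes and per-mate strands
    and both mates lie within ``cfg.dup_offset_max`` bp of each other;
    grouping is transitive (union-find), so chains of small offsets
    collapse together.  The representative has the highest summed mapping
    quality (ties: leftmost A mate, then input order).
    """
    m = cfg.dup_offset_max
    indexed = list(enumerate(pairs))
    groups: dict[tuple, list[tuple[int, ReadPairAlignment]]] = {}
    passthrough: list[tuple[int, ReadPairAlignment]] = []
    for i, p in indexed:
        if not p.both_mapped:
            passthrough.append((i, p))
            continue
        key = (p.chrom_a, p.strand_a, p.chrom_b, p.strand_b)
        groups.setdefault(key, []).append((i, p))

    kept: list[tuple[int, ReadPairAlignment]] = list(passthrough)
    for members in groups.values():
        members.sort(key=lambda ip: (ip[1].pos_a, ip[0]))
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            pi = members[i][1]
            for j in range(i + 1, len(members)):
                pj = members[j][1]
                if pj.pos_a - pi.pos_a > m:
                    break
                if abs(pj.pos_b - pi.pos_b) <= m:
                    uf.union(i, j)
        clusters: dict[int, list[tuple[int, ReadPairAlignment]]] = {}
        for i, member in enumerate(members):
            clusters.setdefault(uf.find(i), []).append(member)
        for cluster in clusters.values():
            rep = min(
                cluster, key=lambda ip: (-ip[1].sum_mapq, ip[1].pos_a, ip[0])
            )
            for idx, p in cluster:
                if p is not rep[1]:
                    p.imperfect_dup = True
            kept.append(rep)
    kept.sort(key=lambda ip: ip[0])
    return [p for _, p in kept]


@dataclass
class ScreenStats:
    """Per-library accounting: unmapped, duplicates, anomalous categories."""

    total_pairs: int = 0
    unmapped: int = 0
    perfect_dups_removed: int = 0
    mapq_removed: int = 0
    imperfect_dups_removed: int = 0
    concordant: int = 0
    anomalous_same_chrom: int = 0
    anomalous_diff_chrom: int = 0
    class_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "unmapped": self.unmapped,
            "perfect_dups_removed": self.perfect_dups_removed,
            "mapq_removed": self.mapq_removed,
            "imperfect_dups_removed": self.imperfect_dups_removed,
            "concordant": self.concordant,
            "anomalous_same_chrom": self.anomalous_same_chrom,
            "anomalous_diff_chrom": self.anomalous_diff_chrom,
            "class_counts": dict(self.class_counts),
        }


def screen(
    pairs: Sequence[ReadPairAlignment],
    lib: LibraryModel,
    cfg: FilterConfig,
    dedup: tuple[str, ...] = ("perfect", "imperfect"),
) -> tuple[list[ReadPairAlignment], ScreenStats]:
    """Full pre-detection screen: unmapped, duplicates, mapping quality.

    Order: drop unmapped pairs, remove
    perfect duplicates, apply the mapping-quality filter, remove imperfect
    duplicates, then count signature classes among survivors.
    """
    stats = ScreenStats(total_pairs=len(pairs))
    mapped = []
    for p in pairs:
        if p.both_mapped:
            mapped.append(p)
        else:
            stats.unmapped += 1
    current = mapped
    if "perfect" in dedup:
        before = len(current)
        current = remove_perfect_duplicates(current)
        stats.perfect_dups_removed = before - len(current)
    before = len(current)
    current = filter_mapq(current, cfg)
    stats.mapq_removed = before - len(current)
    if "imperfect" in dedup:
        before = len(current)
        current = remove_imperfect_duplicates(current, cfg)
        stats.imperfect_dups_removed = before - len(current)
    for p in current:
        cls = classify_pair(p, lib, cfg)
        stats.class_counts[cls] = stats.class_counts.get(cls, 0) + 1
        if cls == "concordant":
            stats.concordant += 1
        elif cls == "translocation_signature":
            stats.anomalous_diff_chrom += 1
        elif cls != "unusable":
            stats.anomalous_same_chrom += 1
    return current, stats
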