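"""Cluster screened discordant read pairs into SV candidates.

Two pairs of the same signature class, chromosome pair and per-mate
orientation join a cluster when both their A mates and their B mates lie
within a window of each other (transitive closure by union-find).  The
default window reuses the classification deviation threshold,
``insert_mean + k * insert_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import GenomicInterval, ReadPairAlignment, SvRecord
from .pairscreen import FilterConfig, classify_pair, _UnionFind
from .readsim import LibraryModel

__all__ = ["SvCluster", "cluster_pairs", "call_svs", "CLASS_TO_SV_TYPE"]

CLASS_TO_SV_TYPE = {
    "del_signature": "deletion",
    "short_insert_signature": "duplication",
    "inversion_signature": "inversion",
    "translocation_signature": "translocation",
}


@dataclass
class SvCluster:
    """A group of read pairs supporting the same rearrangement.

    ``anchor_a``/``anchor_b`` are the footprint envelopes of the mate
    alignments on each side; ``width_a``/``width_b`` are the spreads of
    the mate *start* positions (the anchoring-region widths, which stay
    near zero for imperfect-duplicate clusters).
    """

    cls: str
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    width_a: int
    width_b: int
    support: int
    strand_a: str
    strand_b: str
    members: list[ReadPairAlignment] = field(default_factory=list)


def cluster_pairs(
    pairs: Sequence[ReadPairAlignment],
    lib: LibraryModel,
    cfg: FilterConfig,
    cluster_dist: float | None = None,
) -> list[SvCluster]:
    """Cluster discordant pairs (concordant/unusable pairs are ignored)."""
    d = (
        cluster_dist
        if cluster_dist is not None
        else lib.insert_mean + cfg.sd_multiplier * lib.insert_sd
    )
    groups: dict[tuple, list[ReadPairAlignment]] = {}
    for p in pairs:
        cls = classify_pair(p, lib, cfg)
        if cls in ("concordant", "unusable"):
            continue
        key = (cls, p.chrom_a, p.chrom_b, p.strand_a, p.strand_b)
        groups.setdefault(key, []).append(p)

    clusters: list[SvCluster] = []
    for (cls, *_key), members in groups.items():
        members.sort(key=lambda p: p.pos_a)
        uf = _UnionFind(len(members))
        for i, pi in enumerate(members):
            for j in range(i + 1, len(members)):
                pj = members[j]
                if pj.pos_a - pi.pos_a > d:
                    break
                if abs(pj.pos_b - pi.pos_b) <= d:
                    uf.union(i, j)
        by_root: dict[int, list[ReadPairAlignment]] = {}
        for i, p in enumerate(members):
            by_root.setdefault(uf.find(i), []).append(p)
        for group in by_root.values():
            clusters.append(_make_cluster(cls, group))
    clusters.sort(
        key=lambda c: (c.anchor_a.chrom, c.anchor_a.start, c.anchor_b.chrom, c.anchor_b.start)
    )
    return clusters


def _make_cluster(cls: str, group: list[ReadPairAlignment]) -> SvCluster:
    p0 = group[0]
    pos_a = [p.pos_a for p in group]
    end_a = [p.end_a for p in group]
    pos_b = [p.pos_b for p in group]
    end_b = [p.end_b for p in group]
    return SvCluster(
        cls=cls,
        anchor_a=GenomicInterval(p0.chrom_a, min(pos_a), max(end_a)),
        anchor_b=GenomicInterval(p0.chrom_b, min(pos_b), max(end_b)),
        width_a=max(pos_a) - min(pos_a),
        width_b=max(pos_b) - min(pos_b),
        support=len(group),
        strand_a=p0.strand_a,
        strand_b=p0.strand_b,
        members=group,
    )


def call_svs(clusters: Sequence[SvCluster], cfg: FilterConfig) -> list[SvRecord]:
    """Turn clusters into SV calls.

    A cluster is called when its support reaches ``cfg.min_support`` and
    both anchoring-region widths reach ``cfg.min_anchor`` (the latter
    suppresses calls from residual imperfect-duplicate stacks).  Sizes:
    deletions report the inner distance between anchors, duplications and
    inversions the outer envelope span; translocations carry no size.
    """
    calls: list[SvRecord] = []
    for idx, cluster in enumerate(clusters):
        if cluster.support < cfg.min_support:
            continue
        if cluster.width_a < cfg.min_anchor or cluster.width_b < cfg.min_anchor:
            continue
        sv_type = CLASS_TO_SV_TYPE[cluster.cls]
        size: int | None = None
        if sv_type == "deletion":
            size = max(1, cluster.anchor_b.start - cluster.anchor_a.end)
        elif sv_type in ("duplication", "inversion"):
            size = max(1, cluster.anchor_b.end - cluster.anchor_a.start)
        calls.append(
            SvRecord(
                sv_type=sv_type,
                anchor_a=cluster.anchor_a,
                anchor_b=cluster.anchor_b,
                size=size,
                support=cluster.support,
                origin="call",
                name=f"call{idx}",
            )
        )
    return calls
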