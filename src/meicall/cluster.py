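"""Clustering of tagged anchors into candidate insertion events.

Forward-strand discordant anchors form 5' clusters, reverse-strand anchors
3' clusters; right-clipped anchors form 5' clipped clusters, left-clipped
anchors 3' clipped clusters. Compatible 5'/3' clusters are joined into
events, clipped evidence is merged into discordant evidence, and breakpoints
and prediction windows are estimated.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .config import CallerConfig
from .extract import InsertSizeStats
from .mobilome import FAMILIES, TAG_POLYA, TAG_POLYT, TAG_UNMAPPED, Anchor

KIND_DISC5 = "disc5"
KIND_DISC3 = "disc3"
KIND_CLIP5 = "clip5"
KIND_CLIP3 = "clip3"

_HOMOPOLYMER_TAGS = (TAG_POLYA, TAG_POLYT)


@dataclass
class Cluster:
    kind: str  # disc5 | disc3 | clip5 | clip3
    chrom: str
    start: int  # span start (min anchor start)
    end: int  # span end (max anchor end, exclusive)
    tag: str  # family or polyA/polyT
    anchors: list = field(default_factory=list)
    clip_mode_pos: Optional[int] = None  # clipped clusters: modal clip position

    @property
    def support(self) -> int:
        return len(self.anchors)

    @property
    def inner_border(self) -> int:
        """Border closest to the insertion: disc5 -> max end, disc3 -> min start."""
        if self.kind == KIND_DISC5:
            return self.end
        if self.kind == KIND_DISC3:
            return self.start
        return self.clip_mode_pos


@dataclass
class MEIEvent:
    """A candidate insertion assembled from up to four clusters."""

    chrom: str
    disc5: Optional[Cluster] = None
    disc3: Optional[Cluster] = None
    clip5: Optional[Cluster] = None
    clip3: Optional[Cluster] = None
    tsd_bp: Optional[int] = None
    breakpoint: Optional[tuple] = None  # (lo, hi) half-open; point when hi==lo+1
    window: Optional[tuple] = None  # (start, end) half-open

    @property
    def clusters(self) -> list:
        return [c for c in (self.disc5, self.disc3, self.clip5, self.clip3) if c]

    @property
    def anchors(self) -> list:
        return [a for c in self.clusters for a in c.anchors]

    @property
    def support(self) -> int:
        return sum(c.support for c in self.clusters)

    @property
    def family(self) -> Optional[str]:
        for cluster in (self.clip5, self.clip3, self.disc5, self.disc3):
            if cluster is not None and cluster.tag in FAMILIES:
                return cluster.tag
        return None

    @property
    def polyA_side(self) -> str:
        # for a '+' insertion the trailing polyA shows up in the 3' clipped
        # cluster; for a '-' insertion the reference-strand reads show a
        # leading polyT in the 5' clipped cluster
        if self.clip3 is not None and self.clip3.tag == TAG_POLYA:
            return "3prime"
        if self.clip5 is not None and self.clip5.tag == TAG_POLYT:
            return "5prime"
        return "none"

    @property
    def has_5p_evidence(self) -> bool:
        return self.disc5 is not None or self.clip5 is not None

    @property
    def has_3p_evidence(self) -> bool:
        return self.disc3 is not None or self.clip3 is not None


def _clusterable(anchor: Anchor) -> bool:
    return anchor.tag != TAG_UNMAPPED


def cluster_discordant(anchors: Iterable[Anchor], cfg: CallerConfig) -> list[Cluster]:
    """Single-linkage chaining of same-strand, same-tag discordant anchors.

    Anchors sorted by start are chained while the start-to-start gap is at
    most ``neighborhood_distance``. Forward strand -> 5' cluster, reverse ->
    3' cluster.
    """
    groups: dict = defaultdict(list)
    for anchor in anchors:
        if anchor.evidence != "discordant" or not _clusterable(anchor):
            continue
        groups[(anchor.chrom, anchor.strand, anchor.tag)].append(anchor)
    clusters = []
    for (chrom, strand, tag), members in sorted(groups.items()):
        members.sort(key=lambda a: (a.start, a.end, a.name))
        chain = [members[0]]
        for anchor in members[1:]:
            if anchor.start - chain[-1].start <= cfg.neighborhood_distance:
                chain.append(anchor)
            else:
                clusters.append(_make_disc_cluster(chrom, strand, tag, chain))
                chain = [anchor]
        clusters.append(_make_disc_cluster(chrom, strand, tag, chain))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end, c.kind, c.tag))
    return clusters


def _make_disc_cluster(chrom, strand, tag, members) -> Cluster:
    return Cluster(
        kind=KIND_DISC5 if strand == "+" else KIND_DISC3,
        chrom=chrom,
        start=min(a.start for a in members),
        end=max(a.end for a in members),
        tag=tag,
        anchors=list(members),
    )


def cluster_clipped(anchors: Iterable[Anchor], cfg: CallerConfig) -> list[Cluster]:
    """Group same-side, same-tag clipped anchors around modal clip positions.

    Repeatedly take the most frequent remaining clip position (ties to the
    smallest) and absorb every anchor within ``clip_position_tolerance`` of
    it.
    """
    groups: dict = defaultdict(list)
    for anchor in anchors:
        if anchor.evidence != "clipped" or not _clusterable(anchor):
            continue
        groups[(anchor.chrom, anchor.side, anchor.tag)].append(anchor)
    clusters = []
    for (chrom, side, tag), members in sorted(groups.items()):
        members.sort(key=lambda a: (a.clip_pos, a.start, a.name))
        remaining = list(members)
        while remaining:
            mode_pos, _ = max(
                Counter(a.clip_pos for a in remaining).items(),
                key=lambda kv: (kv[1], -kv[0]),
            )
            taken = [
                a for a in remaining if abs(a.clip_pos - mode_pos) <= cfg.clip_position_tolerance
            ]
            taken_ids = {id(a) for a in taken}
            remaining = [a for a in remaining if id(a) not in taken_ids]
            clusters.append(
                Cluster(
                    kind=KIND_CLIP5 if side == "5prime" else KIND_CLIP3,
                    chrom=chrom,
                    start=min(a.start for a in taken),
                    end=max(a.end for a in taken),
                    tag=tag,
                    anchors=taken,
                    clip_mode_pos=mode_pos,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.clip_mode_pos, c.kind, c.tag))
    return clusters


def join_discordant(c5: Cluster, c3: Cluster, cfg: CallerConfig) -> bool:
    """True when a 5' and a 3' discordant cluster describe the same event.

    The 5' cluster must lie upstream of (or overlap) the 3' cluster, an
    overlap may not exceed ``max_cluster_overlap``, and a gap may not exceed
    ``max_cluster_join_distance``.
    """
    if c5.kind != KIND_DISC5 or c3.kind != KIND_DISC3:
        raise ValueError("join_discordant expects (disc5, disc3)")
    if c5.chrom != c3.chrom or c5.tag != c3.tag:
        return False
    if c3.start < c5.start or c3.end < c5.end:
        return False  # 3' cluster must extend downstream of the 5' cluster
    overlap = min(c5.end, c3.end) - max(c5.start, c3.start)
    if overlap > 0:
        return overlap <= cfg.max_cluster_overlap
    gap = c3.start - c5.end
    return gap <= cfg.max_cluster_join_distance


def _clip_tags_compatible(tag5: str, tag3: str) -> bool:
    if tag5 in FAMILIES and tag3 in FAMILIES:
        return tag5 == tag3
    if tag5 in _HOMOPOLYMER_TAGS and tag3 in FAMILIES:
        return True
    if tag3 in _HOMOPOLYMER_TAGS and tag5 in FAMILIES:
        return True
    return False


def join_clipped(c5: Cluster, c3: Cluster, cfg: CallerConfig) -> Optional[int]:
    """TSD/deletion size when two clipped clusters join, else None.

    With R the 5' (right-clip) modal position and L the 3' (left-clip) modal
    position, the clusters join when ``R - L`` lies in
    ``[-max_target_deletion_gap, +max_cluster_overlap]``; the value is the
    signed target-site duplication (+) / deletion (-) size.
    """
    if c5.kind != KIND_CLIP5 or c3.kind != KIND_CLIP3:
        raise ValueError("join_clipped expects (clip5, clip3)")
    if c5.chrom != c3.chrom or not _clip_tags_compatible(c5.tag, c3.tag):
        return None
    delta = c5.clip_mode_pos - c3.clip_mode_pos
    if -cfg.max_target_deletion_gap <= delta <= cfg.max_cluster_overlap:
        return delta
    return None


def _greedy_pairs(fives, threes, key):
    """Greedy nearest-first matching; key(c5, c3) -> sort key or None."""
    scored = []
    for i, c5 in enumerate(fives):
        for j, c3 in enumerate(threes):
            score = key(c5, c3)
            if score is not None:
                scored.append((score, i, j))
    scored.sort()
    used5: set = set()
    used3: set = set()
    pairs = []
    for _score, i, j in scored:
        if i in used5 or j in used3:
            continue
        used5.add(i)
        used3.add(j)
        pairs.append((i, j))
    return pairs, used5, used3


def pair_clipped_clusters(clusters: list, cfg: CallerConfig) -> list[MEIEvent]:
    """Join clipped clusters into events; leftovers become lone-cluster events."""
    fives = [c for c in clusters if c.kind == KIND_CLIP5]
    threes = [c for c in clusters if c.kind == KIND_CLIP3]

    def key(c5, c3):
        delta = join_clipped(c5, c3, cfg)
        if delta is None:
            return None
        return (abs(delta), c5.clip_mode_pos, c3.clip_mode_pos)

    pairs, used5, used3 = _greedy_pairs(fives, threes, key)
    events = [
        MEIEvent(
            chrom=fives[i].chrom,
            clip5=fives[i],
            clip3=threes[j],
            tsd_bp=join_clipped(fives[i], threes[j], cfg),
        )
        for i, j in pairs
    ]
    events += [
        MEIEvent(chrom=c.chrom, clip5=c) for i, c in enumerate(fives) if i not in used5
    ]
    events += [
        MEIEvent(chrom=c.chrom, clip3=c) for j, c in enumerate(threes) if j not in used3
    ]
    return events


def pair_discordant_clusters(clusters: list, cfg: CallerConfig) -> list[MEIEvent]:
    fives = [c for c in clusters if c.kind == KIND_DISC5]
    threes = [c for c in clusters if c.kind == KIND_DISC3]

    def key(c5, c3):
        if not join_discordant(c5, c3, cfg):
            return None
        gap = max(0, c3.start - c5.end)
        return (gap, c5.start, c3.start)

    pairs, used5, used3 = _greedy_pairs(fives, threes, key)
    events = [
        MEIEvent(chrom=fives[i].chrom, disc5=fives[i], disc3=threes[j])
        for i, j in pairs
    ]
    events += [
        MEIEvent(chrom=c.chrom, disc5=c) for i, c in enumerate(fives) if i not in used5
    ]
    events += [
        MEIEvent(chrom=c.chrom, disc3=c) for j, c in enumerate(threes) if j not in used3
    ]
    return events


def _disc_inner_interval(event: MEIEvent) -> tuple:
    borders = [c.inner_border for c in (event.disc5, event.disc3) if c is not None]
    return (min(borders), max(borders))


def _clip_positions(event: MEIEvent) -> list:
    return [c.clip_mode_pos for c in (event.clip5, event.clip3) if c is not None]


def _families_compatible(disc_event: MEIEvent, clip_event: MEIEvent) -> bool:
    df, cf = disc_event.family, clip_event.family
    if df is None:
        return False
    return cf is None or cf == df


def merge_clip_into_disc(
    disc_events: list, clip_events: list, cfg: CallerConfig
) -> list[MEIEvent]:
    """Attach clipped events to compatible discordant events, nearest first.

    A clipped event attaches when its clip positions fall inside, or within
    ``neighborhood_distance`` of, the discordant event's inner interval.
    Each event participates at most once; exact distance ties go to the
    leftmost discordant event.
    """
    scored = []
    for ci, clip_event in enumerate(clip_events):
        positions = _clip_positions(clip_event)
        for di, disc_event in enumerate(disc_events):
            if disc_event.chrom != clip_event.chrom:
                continue
            if not _families_compatible(disc_event, clip_event):
                continue
            lo, hi = _disc_inner_interval(disc_event)
            dist = max(
                (lo - p) if p < lo else (p - hi) if p > hi else 0 for p in positions
            )
            if dist <= cfg.neighborhood_distance:
                scored.append((dist, lo, di, ci))
    scored.sort()
    used_clip: set = set()
    used_disc: set = set()
    merged = [
        MEIEvent(chrom=e.chrom, disc5=e.disc5, disc3=e.disc3) for e in disc_events
    ]
    for _dist, _lo, di, ci in scored:
        if ci in used_clip or di in used_disc:
            continue
        used_clip.add(ci)
        used_disc.add(di)
        clip_event = clip_events[ci]
        merged[di].clip5 = clip_event.clip5
        merged[di].clip3 = clip_event.clip3
        merged[di].tsd_bp = clip_event.tsd_bp
    for ci, clip_event in enumerate(clip_events):
        if ci not in used_clip:
            merged.append(clip_event)
    return merged


def estimate_breakpoint(
    event: MEIEvent,
    stats: Optional[InsertSizeStats],
    read_len: int,
    cfg: CallerConfig,
) -> MEIEvent:
    """Fill in ``event.breakpoint`` and ``event.window`` in place.

    Preference order: both clipped borders; one clipped border; both
    discordant inner borders; a single cluster extrapolated through the
    insert-size distribution.
    """
    if not event.clusters:
        raise ValueError("event without clusters")
    tol = cfg.clip_position_tolerance
    if event.clip5 is not None and event.clip3 is not None:
        r, l = event.clip5.clip_mode_pos, event.clip3.clip_mode_pos
        lo, hi = min(r, l), max(r, l)
        event.breakpoint = (lo, max(hi, lo + 1))
        event.window = event.breakpoint
    elif event.clip5 is not None or event.clip3 is not None:
        pos = (event.clip5 or event.clip3).clip_mode_pos
        event.breakpoint = (pos, pos + 1)
        event.window = (max(0, pos - tol), pos + tol + 1)
    elif event.disc5 is not None and event.disc3 is not None:
        inner5 = event.disc5.inner_border
        inner3 = event.disc3.inner_border
        lo, hi = min(inner5, inner3), max(inner5, inner3)
        hi = max(hi, lo + 1)
        mid = (lo + hi) // 2
        event.window = (lo, hi)
        event.breakpoint = (mid, mid + 1)
    else:
        if stats is None:
            raise ValueError("single discordant cluster requires insert-size stats")
        span = int(round(stats.median + cfg.insert_size_sd_multiplier * stats.sd))
        if event.disc5 is not None:
            c = event.disc5
            lo = c.end
            hi = max(c.start + span - read_len, lo + 1)
        else:
            c = event.disc3
            hi = c.start
            lo = min(c.end - span + read_len, hi - 1)
            lo = max(0, lo)
        event.window = (lo, hi)
        mid = (lo + hi) // 2
        event.breakpoint = (mid, mid + 1)
    return event


def build_events(
    anchors: Iterable[Anchor],
    cfg: CallerConfig,
    stats: Optional[InsertSizeStats] = None,
    read_len: int = 100,
) -> list[MEIEvent]:
    """Full clustering pipeline: anchors -> events with breakpoints."""
    anchors = list(anchors)
    by_chrom: dict = defaultdict(list)
    for anchor in anchors:
        by_chrom[anchor.chrom].append(anchor)
    events: list[MEIEvent] = []
    for chrom in sorted(by_chrom):
        chrom_anchors = by_chrom[chrom]
        disc_clusters = cluster_discordant(chrom_anchors, cfg)
        clip_clusters = cluster_clipped(chrom_anchors, cfg)
        disc_events = pair_discordant_clusters(disc_clusters, cfg)
        clip_events = pair_clipped_clusters(clip_clusters, cfg)
        merged = merge_clip_into_disc(disc_events, clip_events, cfg)
        for event in merged:
            estimate_breakpoint(event, stats, read_len, cfg)
        events.extend(merged)
    events.sort(key=lambda e: (e.chrom, e.window))
    return events
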