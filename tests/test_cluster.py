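import numpy as np
import pytest

from meicall.cluster import (
    Cluster,
    MEIEvent,
    build_events,
    cluster_clipped,
    cluster_discordant,
    estimate_breakpoint,
    join_clipped,
    join_discordant,
    merge_clip_into_disc,
    pair_clipped_clusters,
)
from meicall.extract import InsertSizeStats
from meicall.mobilome import Anchor


def disc_anchor(start, strand="+", tag="Alu", chrom="chr1", name=None, length=100):
    return Anchor(
        name=name or f"d{start}{strand}",
        chrom=chrom,
        start=start,
        end=start + length,
        strand=strand,
        evidence="discordant",
        tag=tag,
        origin="multimapped_mate",
    )


def clip_anchor(clip_pos, side="5prime", tag="Alu", chrom="chr1", name=None):
    start = clip_pos - 80 if side == "5prime" else clip_pos
    return Anchor(
        name=name or f"c{clip_pos}{side}",
        chrom=chrom,
        start=start,
        end=start + 80,
        strand="+",
        evidence="clipped",
        tag=tag,
        origin="clipped_tail",
        side=side,
        clip_pos=clip_pos,
    )


def make_cluster(kind, start, end, tag="Alu", chrom="chr1", n=5, clip_mode_pos=None):
    anchors = [disc_anchor(start + i, name=f"{kind}{start}_{i}") for i in range(n)]
    return Cluster(
        kind=kind, chrom=chrom, start=start, end=end, tag=tag,
        anchors=anchors, clip_mode_pos=clip_mode_pos,
    )


class TestClusterDiscordant:
    def test_chain_within_neighborhood(self, cfg):
        anchors = [disc_anchor(100), disc_anchor(250), disc_anchor(420)]
        clusters = cluster_discordant(anchors, cfg)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.kind == "disc5" and c.support == 3
        assert (c.start, c.end) == (100, 520)

    def test_gap_splits_clusters(self, cfg):
        clusters = cluster_discordant([disc_anchor(100), disc_anchor(350)], cfg)
        assert len(clusters) == 2

    def test_boundary_gap_exactly_200(self, cfg):
        clusters = cluster_discordant([disc_anchor(100), disc_anchor(300)], cfg)
        assert len(clusters) == 1
        clusters = cluster_discordant([disc_anchor(100), disc_anchor(301)], cfg)
        assert len(clusters) == 2

    def test_singleton(self, cfg):
        clusters = cluster_discordant([disc_anchor(100)], cfg)
        assert len(clusters) == 1 and clusters[0].support == 1

    def test_strand_separation(self, cfg):
        anchors = [disc_anchor(100, "+"), disc_anchor(150, "-")]
        kinds = {c.kind for c in cluster_discordant(anchors, cfg)}
        assert kinds == {"disc5", "disc3"}

    def test_family_separation(self, cfg):
        anchors = [disc_anchor(100, tag="Alu"), disc_anchor(150, tag="L1")]
        assert len(cluster_discordant(anchors, cfg)) == 2

    def test_order_independence(self, cfg):
        rng = np.random.default_rng(17)
        anchors = [
            disc_anchor(int(rng.integers(0, 3000)), rng.choice(["+", "-"]),
                        rng.choice(["Alu", "L1"]), name=f"a{i}")
            for i in range(40)
        ]
        ref = cluster_discordant(anchors, cfg)
        for _ in range(5):
            shuffled = list(anchors)
            rng.shuffle(shuffled)
            out = cluster_discordant(shuffled, cfg)
            assert [sorted(a.name for a in c.anchors) for c in out] == [
                sorted(a.name for a in c.anchors) for c in ref
            ]

    def test_matches_brute_force_single_linkage(self, cfg):
        # oracle: connected components under |start_i - start_j| <= d
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(1, 31))
            anchors = [
                disc_anchor(int(rng.integers(0, 2000)), name=f"a{i}") for i in range(n)
            ]
            clusters = cluster_discordant(anchors, cfg)
            components = brute_force_single_linkage(
                anchors, cfg.neighborhood_distance
            )
            got = sorted(sorted(a.name for a in c.anchors) for c in clusters)
            assert got == components


def brute_force_single_linkage(anchors, d):
    """Exhaustive union-find over the pairwise linkage predicate."""
    parent = list(range(len(anchors)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            if abs(anchors[i].start - anchors[j].start) <= d:
                parent[find(i)] = find(j)
    groups = {}
    for i, a in enumerate(anchors):
        groups.setdefault(find(i), []).append(a.name)
    return sorted(sorted(g) for g in groups.values())


class TestJoinDiscordant:
    def test_small_overlap_joinable(self, cfg):
        c5 = make_cluster("disc5", 1000, 1400)
        c3 = make_cluster("disc3", 1390, 1800)
        assert join_discordant(c5, c3, cfg)

    def test_gap_700_not_joinable(self, cfg):
        c5 = make_cluster("disc5", 1000, 1400)
        c3 = make_cluster("disc3", 2100, 2500)
        assert not join_discordant(c5, c3, cfg)

    def test_gap_600_joinable(self, cfg):
        c5 = make_cluster("disc5", 1000, 1400)
        c3 = make_cluster("disc3", 2000, 2500)
        assert join_discordant(c5, c3, cfg)

    def test_overlap_70_not_joinable(self, cfg):
        c5 = make_cluster("disc5", 1000, 1500)
        c3 = make_cluster("disc3", 1430, 1800)
        assert not join_discordant(c5, c3, cfg)

    def test_family_mismatch(self, cfg):
        c5 = make_cluster("disc5", 1000, 1400, tag="Alu")
        c3 = make_cluster("disc3", 1390, 1800, tag="L1")
        assert not join_discordant(c5, c3, cfg)

    def test_three_prime_upstream_rejected(self, cfg):
        c5 = make_cluster("disc5", 1400, 1800)
        c3 = make_cluster("disc3", 1000, 1390)
        assert not join_discordant(c5, c3, cfg)


class TestClusterClipped:
    def test_modal_position(self, cfg):
        anchors = [clip_anchor(5000), clip_anchor(5001, name="b"), clip_anchor(5000, name="c")]
        clusters = cluster_clipped(anchors, cfg)
        assert len(clusters) == 1
        assert clusters[0].kind == "clip5"
        assert clusters[0].clip_mode_pos == 5000
        assert clusters[0].support == 3

    def test_scatter_beyond_tolerance_splits(self, cfg):
        anchors = [clip_anchor(5000), clip_anchor(5010)]
        assert len(cluster_clipped(anchors, cfg)) == 2

    def test_singleton_polyt_left_clip(self, cfg):
        clusters = cluster_clipped([clip_anchor(5000, side="3prime", tag="polyT")], cfg)
        assert len(clusters) == 1
        assert clusters[0].kind == "clip3"
        assert clusters[0].tag == "polyT"

    def test_mode_tie_smallest(self, cfg):
        anchors = [clip_anchor(5002), clip_anchor(5001, name="b")]
        clusters = cluster_clipped(anchors, cfg)
        assert len(clusters) == 1 and clusters[0].clip_mode_pos == 5001


class TestJoinClipped:
    def c5(self, pos, tag="Alu"):
        return make_cluster("clip5", pos - 80, pos, tag=tag, clip_mode_pos=pos)

    def c3(self, pos, tag="polyA"):
        return make_cluster("clip3", pos, pos + 80, tag=tag, clip_mode_pos=pos)

    def test_tsd_13(self, cfg):
        assert join_clipped(self.c5(5013), self.c3(5000), cfg) == 13

    def test_deletion_7(self, cfg):
        assert join_clipped(self.c5(5000), self.c3(5007, tag="Alu"), cfg) == -7

    def test_overlap_60_rejected(self, cfg):
        assert join_clipped(self.c5(5060), self.c3(5000), cfg) is None

    def test_boundaries(self, cfg):
        assert join_clipped(self.c5(5050), self.c3(5000), cfg) == 50
        assert join_clipped(self.c5(5051), self.c3(5000), cfg) is None
        assert join_clipped(self.c5(5000), self.c3(5020, tag="Alu"), cfg) == -20
        assert join_clipped(self.c5(5000), self.c3(5021, tag="Alu"), cfg) is None

    def test_family_polytail_compatibility(self, cfg):
        assert join_clipped(self.c5(5013, tag="polyT"), self.c3(5000, tag="L1"), cfg) == 13
        assert join_clipped(self.c5(5013, tag="Alu"), self.c3(5000, tag="L1"), cfg) is None
        # two homopolymer clusters cannot name a family
        assert join_clipped(self.c5(5013, tag="polyT"), self.c3(5000, tag="polyA"), cfg) is None


class TestMergeClipIntoDisc:
    def disc_event(self, inner5, inner3, tag="Alu"):
        return MEIEvent(
            chrom="chr1",
            disc5=make_cluster("disc5", inner5 - 300, inner5, tag=tag),
            disc3=make_cluster("disc3", inner3, inner3 + 300, tag=tag),
        )

    def clip_event(self, r, l, tag5="Alu", tag3="polyA"):
        return MEIEvent(
            chrom="chr1",
            clip5=make_cluster("clip5", r - 80, r, tag=tag5, clip_mode_pos=r),
            clip3=make_cluster("clip3", l, l + 80, tag=tag3, clip_mode_pos=l),
            tsd_bp=r - l,
        )

    def test_attach_inside_inner_interval(self, cfg):
        merged = merge_clip_into_disc(
            [self.disc_event(4900, 5100)], [self.clip_event(5013, 5000)], cfg
        )
        assert len(merged) == 1
        assert merged[0].clip5 is not None and merged[0].tsd_bp == 13

    def test_distant_clip_event_stays_separate(self, cfg):
        merged = merge_clip_into_disc(
            [self.disc_event(4900, 5100)], [self.clip_event(15013, 15000)], cfg
        )
        assert len(merged) == 2
        assert merged[0].clip5 is None

    def test_tie_goes_to_leftmost(self, cfg):
        left = self.disc_event(4000, 4400)
        right = self.disc_event(5600, 6000)
        clip = self.clip_event(5000, 5000)  # 600 from both inner intervals
        cfg_wide = cfg.replace(neighborhood_distance=700)
        merged = merge_clip_into_disc([left, right], [clip], cfg_wide)
        attached = [e for e in merged if e.clip5 is not None]
        assert len(attached) == 1
        assert attached[0].disc5.start == left.disc5.start

    def test_family_incompatible_not_attached(self, cfg):
        merged = merge_clip_into_disc(
            [self.disc_event(4900, 5100, tag="L1")],
            [self.clip_event(5013, 5000, tag5="Alu", tag3="Alu")],
            cfg,
        )
        assert merged[0].clip5 is None and len(merged) == 2


class TestEstimateBreakpoint:
    stats = InsertSizeStats(median=400, sd=30, n_sampled=10000)

    def test_double_clipped(self, cfg):
        event = MEIEvent(
            chrom="chr1",
            clip5=make_cluster("clip5", 4920, 5013, clip_mode_pos=5013),
            clip3=make_cluster("clip3", 5000, 5080, tag="polyA", clip_mode_pos=5000),
            tsd_bp=13,
        )
        estimate_breakpoint(event, self.stats, 100, cfg)
        assert event.breakpoint == (5000, 5013)
        assert event.window == (5000, 5013)

    def test_single_clipped(self, cfg):
        event = MEIEvent(
            chrom="chr1", clip5=make_cluster("clip5", 4920, 5000, clip_mode_pos=5000)
        )
        estimate_breakpoint(event, self.stats, 100, cfg)
        assert event.breakpoint == (5000, 5001)
        assert event.window == (4997, 5004)

    def test_double_discordant_midpoint(self, cfg):
        event = MEIEvent(
            chrom="chr1",
            disc5=make_cluster("disc5", 4700, 4990),
            disc3=make_cluster("disc3", 5020, 5300),
        )
        estimate_breakpoint(event, self.stats, 100, cfg)
        assert event.window == (4990, 5020)
        assert event.breakpoint == (5005, 5006)

    def test_single_disc5_formula(self, cfg):
        event = MEIEvent(chrom="chr1", disc5=make_cluster("disc5", 4000, 4400))
        estimate_breakpoint(event, self.stats, 100, cfg)
        assert event.window == (4400, 4420)  # [end, start + 520 - read_len)

    def test_single_disc3_mirrored(self, cfg):
        event = MEIEvent(chrom="chr1", disc3=make_cluster("disc3", 4000, 4400))
        estimate_breakpoint(event, self.stats, 100, cfg)
        assert event.window == (3980, 4000)

    def test_zero_clusters_fatal(self, cfg):
        with pytest.raises(ValueError):
            estimate_breakpoint(MEIEvent(chrom="chr1"), self.stats, 100, cfg)


class TestBuildEvents:
    def test_no_anchor_double_counted(self, cfg):
        rng = np.random.default_rng(31)
        anchors = []
        for i in range(30):
            anchors.append(disc_anchor(int(rng.integers(0, 5000)),
                                       rng.choice(["+", "-"]), name=f"d{i}"))
        for i in range(20):
            anchors.append(clip_anchor(int(rng.integers(0, 5000)),
                                       rng.choice(["5prime", "3prime"]), name=f"c{i}"))
        events = build_events(anchors, cfg, InsertSizeStats(400, 30, 10000), 100)
        names = [a.name for e in events for a in e.anchors]
        assert len(names) == len(set(names))

    def test_full_pipeline_double_cluster(self, cfg):
        anchors = (
            [disc_anchor(4700 + 40 * i, "+", name=f"p{i}") for i in range(5)]
            + [disc_anchor(5020 + 40 * i, "-", name=f"m{i}") for i in range(5)]
            + [clip_anchor(5013, "5prime", name=f"r{i}") for i in range(3)]
            + [clip_anchor(5000, "3prime", tag="polyA", name=f"l{i}") for i in range(3)]
        )
        events = build_events(anchors, cfg, InsertSizeStats(400, 30, 10000), 100)
        assert len(events) == 1
        event = events[0]
        assert event.tsd_bp == 13
        assert event.breakpoint == (5000, 5013)
        assert event.support == 16
        assert event.family == "Alu"
        assert event.polyA_side == "3prime"
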