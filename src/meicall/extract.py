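"""Candidate-read extraction from coordinate-sorted BAM/SAM alignments.

Discordant read pairs and soft-clipped reads are harvested together with
their uniquely mapped anchors. A pair is discordant when (in this order of
precedence) one end is unmapped, the ends map to different chromosomes, the
orientation deviates from forward-reverse with the forward read upstream, or
the absolute template length falls outside ``median +/- k*sd`` of the
insert-size distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam

from .config import CallerConfig

log = logging.getLogger(__name__)

PAIR_CONCORDANT = "concordant"
PAIR_DISC_ORIENTATION = "disc_orientation"
PAIR_DISC_INSERT_SIZE = "disc_insert_size"
PAIR_DISC_INTERCHROM = "disc_interchrom"
PAIR_DISC_ONE_UNMAPPED = "disc_one_unmapped"
PAIR_SKIP = "skip"

DISCORDANT_CLASSES = frozenset(
    {
        PAIR_DISC_ORIENTATION,
        PAIR_DISC_INSERT_SIZE,
        PAIR_DISC_INTERCHROM,
        PAIR_DISC_ONE_UNMAPPED,
    }
)

ORIGIN_DISCORDANT_MATE = "discordant_mate"
ORIGIN_CLIPPED_TAIL = "clipped_tail"
ORIGIN_UNMAPPED_MATE = "unmapped_mate"
ORIGIN_MULTIMAPPED_MATE = "multimapped_mate"


class ExtractionError(RuntimeError):
    pass


@dataclass
class AlignedRead:
    """Minimal alignment record; the unit the classifiers operate on."""

    name: str
    chrom: Optional[str]
    start: int  # 0-based leftmost reference position
    end: int  # exclusive reference end of the aligned part
    strand: str  # '+' or '-'
    left_clip: int
    right_clip: int
    is_unique: bool
    is_unmapped: bool
    mate_chrom: Optional[str] = None
    mate_start: int = -1
    mate_strand: str = "+"
    mate_unmapped: bool = False
    seq: str = ""
    quals: tuple = ()
    template_len: int = 0

    def __post_init__(self):
        if self.seq and self.quals and len(self.quals) != len(self.seq):
            raise ValueError(f"{self.name}: quals/seq length mismatch")
        if self.seq and self.left_clip + self.right_clip > len(self.seq):
            raise ValueError(f"{self.name}: clips exceed read length")


@dataclass
class InsertSizeStats:
    median: float
    sd: float
    n_sampled: int
    low_sample: bool = False

    @property
    def upper_bound(self) -> float:
        return self.median  # placeholder; bound depends on the multiplier


@dataclass
class CandidateRead:
    """A sequence possibly derived from a mobile element, plus its anchor."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    origin: str  # discordant_mate | clipped_tail | unmapped_mate | multimapped_mate
    candidate_seq: str
    side: Optional[str] = None  # clipped only: '3prime' (right clip) / '5prime' (left)
    clip_pos: Optional[int] = None  # clipped only: reference position of the boundary

    def __post_init__(self):
        if not self.candidate_seq:
            raise ValueError(f"{self.name}: empty candidate sequence")
        if self.origin == ORIGIN_CLIPPED_TAIL and self.clip_pos is None:
            raise ValueError(f"{self.name}: clipped candidate without clip_pos")


def estimate_insert_size(bam, sample_size: int = 10000) -> InsertSizeStats:
    """Estimate median/sd of |template length| over the first proper pairs.

    Values above the 99.5th percentile of the sample are discarded before
    computing the summary statistics (robustness against chimeric outliers).
    ``bam`` may be a path or an open :class:`pysam.AlignmentFile`.
    """
    tlens = []
    own = isinstance(bam, str)
    handle = pysam.AlignmentFile(bam) if own else bam
    try:
        for read in handle.fetch(until_eof=True):
            if (
                read.is_proper_pair
                and not read.is_secondary
                and not read.is_supplementary
                and not read.is_duplicate
                and read.template_length > 0
            ):
                tlens.append(read.template_length)
                if len(tlens) >= sample_size:
                    break
    finally:
        if own:
            handle.close()
        else:
            handle.reset()
    if not tlens:
        raise ExtractionError("no properly paired alignments; cannot estimate insert size")
    return insert_stats_from_tlens(tlens)


def insert_stats_from_tlens(tlens: Iterable[int]) -> InsertSizeStats:
    arr = np.abs(np.asarray(list(tlens), dtype=float))
    cutoff = np.percentile(arr, 99.5)
    trimmed = arr[arr <= cutoff]
    sd = float(np.std(trimmed, ddof=1)) if trimmed.size > 1 else 0.0
    return InsertSizeStats(
        median=float(np.median(trimmed)),
        sd=sd,
        n_sampled=int(trimmed.size),
        low_sample=trimmed.size < 1000,
    )


def classify_pair(
    r1: AlignedRead, r2: AlignedRead, stats: InsertSizeStats, cfg: CallerConfig
) -> str:
    """Classify a mate pair; first matching class in the stated precedence."""
    if r1.is_unmapped and r2.is_unmapped:
        return PAIR_SKIP
    if r1.is_unmapped or r2.is_unmapped:
        return PAIR_DISC_ONE_UNMAPPED
    if r1.chrom != r2.chrom:
        return PAIR_DISC_INTERCHROM
    if r1.strand == r2.strand:
        return PAIR_DISC_ORIENTATION
    fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
    if fwd.start > rev.start:
        return PAIR_DISC_ORIENTATION
    tlen = abs(r1.template_len) if r1.template_len else max(r1.end, r2.end) - min(
        r1.start, r2.start
    )
    slack = cfg.insert_size_sd_multiplier * stats.sd
    if tlen > stats.median + slack or tlen < stats.median - slack:
        return PAIR_DISC_INSERT_SIZE
    return PAIR_CONCORDANT


def clip_filter(read: AlignedRead, cfg: CallerConfig):
    """Return ``(side, reason)``; side is 'left'/'right' if a clip is usable.

    A clip is accepted when it is at least ``min_clip_length`` long, its
    clipped bases average at least ``min_clip_avg_quality``, and the other
    end of the read is clipped by at most ``max_other_end_clip``.
    """
    left, right = read.left_clip, read.right_clip
    if left < cfg.min_clip_length and right < cfg.min_clip_length:
        return None, "too_short"
    if left >= cfg.min_clip_length and right >= cfg.min_clip_length:
        # the other-end rule cannot hold for either side
        return None, "other_end"
    side, clip_len, other_len = (
        ("right", right, left) if right >= cfg.min_clip_length else ("left", left, right)
    )
    if other_len > cfg.max_other_end_clip:
        return None, "other_end"
    if read.quals:
        clipped_quals = read.quals[:left] if side == "left" else read.quals[-right:]
        if clipped_quals and sum(clipped_quals) / len(clipped_quals) < cfg.min_clip_avg_quality:
            return None, "low_quality"
    return side, "ok"


def _from_pysam(read: pysam.AlignedSegment, min_mapq: int) -> AlignedRead:
    cigar = read.cigartuples or []
    left = cigar[0][1] if cigar and cigar[0][0] in (4, 5) else 0
    right = cigar[-1][1] if len(cigar) > 1 and cigar[-1][0] in (4, 5) else 0
    if len(cigar) == 1 and cigar[0][0] in (4, 5):
        left, right = cigar[0][1], 0
    unmapped = read.is_unmapped
    multi_hit = read.has_tag("XA") or (read.has_tag("X0") and read.get_tag("X0") > 1)
    return AlignedRead(
        name=read.query_name,
        chrom=None if unmapped else read.reference_name,
        start=-1 if unmapped else read.reference_start,
        end=-1 if unmapped else read.reference_end,
        strand="-" if read.is_reverse else "+",
        left_clip=0 if unmapped else left,
        right_clip=0 if unmapped else right,
        is_unique=(not unmapped) and read.mapping_quality >= min_mapq and not multi_hit,
        is_unmapped=unmapped,
        mate_chrom=None if read.mate_is_unmapped else read.next_reference_name,
        mate_start=-1 if read.mate_is_unmapped else read.next_reference_start,
        mate_strand="-" if read.mate_is_reverse else "+",
        mate_unmapped=read.mate_is_unmapped,
        seq=read.query_sequence or "",
        quals=tuple(read.query_qualities) if read.query_qualities is not None else (),
        template_len=read.template_length,
    )


def _mate_view(read: AlignedRead) -> AlignedRead:
    """A synthetic AlignedRead for the mate, built from this record's fields.

    Only the fields consulted by :func:`classify_pair` are meaningful.
    """
    return AlignedRead(
        name=read.name,
        chrom=read.mate_chrom,
        start=read.mate_start,
        end=read.mate_start,  # mate end unknown; tlen carries the span
        strand=read.mate_strand,
        left_clip=0,
        right_clip=0,
        is_unique=False,
        is_unmapped=read.mate_unmapped,
        mate_chrom=read.chrom,
        mate_start=read.start,
        mate_strand=read.strand,
        mate_unmapped=read.is_unmapped,
        seq="N",
        template_len=-read.template_len,
    )


def extract_candidates(
    bam_path: str,
    stats: Optional[InsertSizeStats],
    cfg: CallerConfig,
    counts: Optional[dict] = None,
) -> list[CandidateRead]:
    """Harvest clipped-tail and discordant-mate candidates from a BAM/SAM file.

    In paired mode both evidence types are emitted; in single mode only
    clipped tails. Every candidate's anchor is uniquely mapped.
    """
    if counts is None:
        counts = {}
    counts.setdefault("reads_scanned", 0)
    counts.setdefault("clipped_candidates", 0)
    counts.setdefault("discordant_anchors", 0)
    counts.setdefault("hard_clipped_skipped", 0)

    candidates: list[CandidateRead] = []
    # pass 1: anchors + (for paired mode) per-end sequence info of discordant pairs
    anchors: list[tuple[AlignedRead, bool]] = []  # (anchor record, is_read1)
    mate_info: dict[tuple[str, bool], tuple[str, bool, bool]] = {}
    seen_clip: set = set()

    with pysam.AlignmentFile(bam_path) as handle:
        for read in handle.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            counts["reads_scanned"] += 1
            rec = _from_pysam(read, cfg.min_mapq)

            if not rec.is_unmapped and rec.is_unique:
                cigar = read.cigartuples or []
                hard = any(op == 5 for op, _ in cigar)
                side, _reason = clip_filter(rec, cfg)
                if side is not None:
                    if hard and not rec.seq:
                        counts["hard_clipped_skipped"] += 1
                    else:
                        tail = (
                            rec.seq[: rec.left_clip]
                            if side == "left"
                            else rec.seq[-rec.right_clip :]
                        )
                        key = (rec.name, side)  # one clip per template and side
                        if tail and key not in seen_clip:
                            seen_clip.add(key)
                            counts["clipped_candidates"] += 1
                            candidates.append(
                                CandidateRead(
                                    name=rec.name,
                                    chrom=rec.chrom,
                                    start=rec.start,
                                    end=rec.end,
                                    strand=rec.strand,
                                    origin=ORIGIN_CLIPPED_TAIL,
                                    candidate_seq=tail,
                                    side="3prime" if side == "right" else "5prime",
                                    clip_pos=rec.end if side == "right" else rec.start,
                                )
                            )

            if cfg.mode != "paired" or not read.is_paired or stats is None:
                continue
            pair_class = classify_pair(rec, _mate_view(rec), stats, cfg)
            if pair_class not in DISCORDANT_CLASSES:
                continue
            if rec.seq:
                mate_info[(rec.name, read.is_read1)] = (
                    rec.seq,
                    rec.is_unmapped,
                    rec.is_unique,
                )
            if not rec.is_unmapped and rec.is_unique:
                anchors.append((rec, read.is_read1))

    if cfg.mode == "paired":
        emitted: set = set()
        for rec, is_read1 in anchors:
            info = mate_info.get((rec.name, not is_read1))
            if info is None:
                continue  # mate record absent from the file
            mate_seq, mate_unmapped, mate_unique = info
            if mate_unmapped:
                origin = ORIGIN_UNMAPPED_MATE
            elif not mate_unique:
                origin = ORIGIN_MULTIMAPPED_MATE
            else:
                origin = ORIGIN_DISCORDANT_MATE
            key = (rec.name, is_read1, origin)
            if key in emitted:
                continue
            emitted.add(key)
            counts["discordant_anchors"] += 1
            candidates.append(
                CandidateRead(
                    name=rec.name,
                    chrom=rec.chrom,
                    start=rec.start,
                    end=rec.end,
                    strand=rec.strand,
                    origin=origin,
                    candidate_seq=mate_seq,
                )
            )
    return candidates


def write_candidates_tsv(candidates: Iterable[CandidateRead], path: str) -> None:
    """Dump the intermediate candidate table for debugging."""
    with open(path, "wt", encoding="utf-8") as out:
        out.write(
            "chrom\tstart\tend\tstrand\tside\torigin\tcandidate_seq\tclip_pos\tname\n"
        )
        for c in candidates:
            out.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.side or '.'}\t"
                f"{c.origin}\t{c.candidate_seq}\t"
                f"{c.clip_pos if c.clip_pos is not None else '.'}\t{c.name}\n"
            )
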