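"""Mapping candidate sequences against the mobile-element consensus library.

The library ("mobilome") is tiny — a handful of consensus sequences for the
four active families (Alu, L1, SVA, HERV-K) — so the mapper is an exact,
vectorised sliding-window Hamming scan over both strands rather than a
heuristic seeded aligner: every window placement of the query inside every
consensus is scored, and the best placement is reported when its mismatch
fraction is at most ``mobilome_max_mismatch_frac``. ``N`` bases always count
as mismatches. Queries shorter than 18 bp are never mapped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .config import CallerConfig
from .extract import (
    ORIGIN_CLIPPED_TAIL,
    ORIGIN_DISCORDANT_MATE,
    ORIGIN_MULTIMAPPED_MATE,
    ORIGIN_UNMAPPED_MATE,
    CandidateRead,
)

FAMILIES = ("Alu", "L1", "SVA", "HERVK")

#: minimum query length that can map uniquely against the mobilome
MIN_MAPPABLE_LENGTH = 18

TAG_POLYA = "polyA"
TAG_POLYT = "polyT"
TAG_UNMAPPED = "unmapped"

_N_BYTE = ord("N")


class MobilomeError(ValueError):
    pass


def classify_family(name: str) -> Optional[str]:
    """Infer the ME family from a FASTA header name, or None."""
    up = name.upper()
    if "ALU" in up:
        return "Alu"
    if "SVA" in up:
        return "SVA"
    if "HERV" in up:
        return "HERVK"
    if "L1" in up or "LINE1" in up:
        return "L1"
    return None


@dataclass
class MobilomeEntry:
    name: str
    family: str
    sequence: str
    fwd: np.ndarray = field(repr=False, default=None)
    rev: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq or set(seq) - set("ACGTN"):
            raise MobilomeError(f"{self.name}: sequence must be non-empty ACGTN")
        self.sequence = seq
        self.fwd = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        self.rev = np.frombuffer(
            str(Seq(seq).reverse_complement()).encode("ascii"), dtype=np.uint8
        ).copy()


@dataclass
class MobilomeDB:
    entries: list[MobilomeEntry]

    @property
    def families(self) -> set:
        return {e.family for e in self.entries}

    def total_length(self) -> int:
        return sum(len(e.sequence) for e in self.entries)


@dataclass(frozen=True)
class MobilomeHit:
    family: str
    mismatch_frac: float
    ambiguous_across_families: bool
    target_strand: str  # '+' or '-'
    entry_name: str = ""
    mismatches: int = 0


def build_mobilome(fasta_path: str) -> MobilomeDB:
    """Load the consensus library; headers must name one of the four families."""
    entries = []
    for record in SeqIO.parse(fasta_path, "fasta"):
        family = classify_family(record.id)
        if family is None:
            raise MobilomeError(
                f"cannot classify FASTA header {record.id!r} into one of "
                f"{'/'.join(FAMILIES)}"
            )
        entries.append(MobilomeEntry(record.id, family, str(record.seq)))
    if not entries:
        raise MobilomeError(f"no sequences found in {fasta_path}")
    return MobilomeDB(entries)


def db_from_sequences(named_seqs: Iterable[tuple]) -> MobilomeDB:
    """Build a DB from in-memory ``(name, sequence)`` pairs (names carry family)."""
    entries = []
    for name, seq in named_seqs:
        family = classify_family(name)
        if family is None:
            raise MobilomeError(f"cannot classify sequence name {name!r}")
        entries.append(MobilomeEntry(name, family, seq))
    if not entries:
        raise MobilomeError("empty mobilome")
    return MobilomeDB(entries)


def _window_mismatches(target: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of the query at every start offset in the target."""
    windows = np.lib.stride_tricks.sliding_window_view(target, len(query))
    mism = windows != query
    mism |= windows == _N_BYTE
    mism |= query == _N_BYTE
    return mism.sum(axis=1)


def map_to_mobilome(
    seq: str, db: MobilomeDB, cfg: CallerConfig, max_mismatches: Optional[int] = None
) -> Optional[MobilomeHit]:
    """Best full-containment placement of ``seq`` in the library, both strands.

    Returns None when the query is shorter than 18 bp, longer than every
    consensus, or the best placement exceeds the mismatch budget. The budget
    is ``floor(frac * len(seq))`` unless ``max_mismatches`` overrides it.
    Ties within a family resolve to the first entry in library order ('+'
    strand before '-'); ties across families mark the hit ambiguous.
    """
    if len(seq) < MIN_MAPPABLE_LENGTH:
        return None
    query = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    budget = (
        int(cfg.mobilome_max_mismatch_frac * len(seq))
        if max_mismatches is None
        else max_mismatches
    )
    best = None  # (mismatches, entry_index, strand)
    entry_minima: list[tuple[int, int]] = []  # (entry_index, min mismatches)
    for idx, entry in enumerate(db.entries):
        if len(query) > len(entry.fwd):
            continue
        entry_min = None
        for strand, target in (("+", entry.fwd), ("-", entry.rev)):
            mm = int(_window_mismatches(target, query).min())
            if entry_min is None or mm < entry_min:
                entry_min = mm
            if best is None or mm < best[0]:
                best = (mm, idx, strand)
        entry_minima.append((idx, entry_min))
    if best is None or best[0] > budget:
        return None
    mm, idx, strand = best
    best_families = {
        db.entries[i].family for i, entry_min in entry_minima if entry_min == mm
    }
    return MobilomeHit(
        family=db.entries[idx].family,
        mismatch_frac=mm / len(seq),
        ambiguous_across_families=len(best_families) > 1,
        target_strand=strand,
        entry_name=db.entries[idx].name,
        mismatches=mm,
    )


def _terminal_run(seq: str, base: str, min_len: int, purity: float = 0.90) -> int:
    """Longest terminal window (suffix or prefix) that is >= purity `base`."""
    best = 0
    n = len(seq)
    for indices in (range(n - 1, -1, -1), range(n)):  # suffix scan, prefix scan
        count = 0
        length = 0
        run_best = 0
        for i in indices:
            length += 1
            if seq[i] == base:
                count += 1
            if count / length >= purity and seq[i] == base:
                run_best = length
        best = max(best, run_best)
    return best if best > min_len else 0


def detect_polytail(seq: str, cfg: CallerConfig) -> Optional[str]:
    """Detect a terminal polyA (checked first) or polyT stretch.

    A qualifying stretch is a terminal window, at either end, longer than
    ``min_polyA_length`` with at least 90% of the homopolymer base.
    """
    seq = seq.upper()
    if _terminal_run(seq, "A", cfg.min_polyA_length):
        return TAG_POLYA
    if _terminal_run(seq, "T", cfg.min_polyA_length):
        return TAG_POLYT
    return None


@dataclass
class Anchor:
    """A uniquely mapped read localising a candidate insertion."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    evidence: str  # 'discordant' | 'clipped'
    tag: str  # family, polyA, polyT, or unmapped
    origin: str
    side: Optional[str] = None  # clipped only: insertion side, '5prime'/'3prime'
    clip_pos: Optional[int] = None


def _clip_insertion_side(read_side: str) -> str:
    # right-clipped reads ('3prime' read end) sit on the 5' side of the
    # insertion; left-clipped reads on the 3' side
    return "5prime" if read_side == "3prime" else "3prime"


def tag_anchors(
    candidates: Iterable[CandidateRead],
    db: MobilomeDB,
    cfg: CallerConfig,
    counts: Optional[dict] = None,
) -> list[Anchor]:
    """Tag candidate anchors with a family / homopolymer label.

    Clipped tails try the mobilome first, then polyA/polyT. Discordant mates
    try the mobilome only, except unmapped mates which also fall back to the
    homopolymer check and, failing both, keep the 'unmapped' tag. Ambiguous
    cross-family hits are dropped, as are discordant pairs whose two ends
    both map to the mobilome.
    """
    if counts is None:
        counts = {}
    counts.setdefault("anchors", 0)
    counts.setdefault("dropped_ambiguous", 0)
    counts.setdefault("dropped_both_mobilome", 0)
    counts.setdefault("dropped_untagged", 0)

    by_name: dict = {}
    ordered: list[str] = []
    for cand in candidates:
        if cand.name not in by_name:
            by_name[cand.name] = []
            ordered.append(cand.name)
        by_name[cand.name].append(cand)

    anchors: list[Anchor] = []
    for name in ordered:
        group = by_name[name]
        disc = [c for c in group if c.origin != ORIGIN_CLIPPED_TAIL]
        hits = {id(c): map_to_mobilome(c.candidate_seq, db, cfg) for c in group}
        both_me = len(disc) >= 2 and all(hits[id(c)] is not None for c in disc)
        if both_me:
            counts["dropped_both_mobilome"] += len(disc)
        for cand in group:
            if cand.origin != ORIGIN_CLIPPED_TAIL and both_me:
                continue
            hit = hits[id(cand)]
            tag = None
            if hit is not None:
                if hit.ambiguous_across_families:
                    counts["dropped_ambiguous"] += 1
                    continue
                tag = hit.family
            elif cand.origin in (ORIGIN_CLIPPED_TAIL, ORIGIN_UNMAPPED_MATE):
                tag = detect_polytail(cand.candidate_seq, cfg)
            if tag is None:
                if cand.origin == ORIGIN_UNMAPPED_MATE:
                    tag = TAG_UNMAPPED
                else:
                    counts["dropped_untagged"] += 1
                    continue
            counts["anchors"] += 1
            anchors.append(
                Anchor(
                    name=cand.name,
                    chrom=cand.chrom,
                    start=cand.start,
                    end=cand.end,
                    strand=cand.strand,
                    evidence=(
                        "clipped" if cand.origin == ORIGIN_CLIPPED_TAIL else "discordant"
                    ),
                    tag=tag,
                    origin=cand.origin,
                    side=(
                        _clip_insertion_side(cand.side)
                        if cand.origin == ORIGIN_CLIPPED_TAIL
                        else None
                    ),
                    clip_pos=cand.clip_pos,
                )
            )
    return anchors
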